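"""Compositional-hierarchy pattern learning and gapped-regex prediction.

The learner builds a hierarchy of relatively-encoded melodic patterns:
layer 1 holds the single-event leaf part, and each further layer joins
pairs of earlier-layer part activations that co-occur at a fixed pitch
offset within a bounded event gap, keeping compositions that recur at
least ``min_support`` times.  Redundant parts whose occurrences are
largely covered by a retained longer part are inhibited.  The surviving
parts, unrolled to semitone-offset patterns, are the model's knowledge.

For prediction each pattern is turned into a gapped regular expression
over a letter encoding of semitone offsets (0 -> '0', +k -> k-th upper-case
letter, -k -> k-th lower-case letter).  Matching all but the pattern's
final symbol against an excerpt suffix yields a predicted pitch for the
continuation slot, weighted by

    w = n_pattern_events / (segment_length - match_start + 1)

where the segment length counts the excerpt's events plus the prediction
slot and the match start is the 0-based anchor index — longer patterns and
matches beginning nearer the excerpt's end weigh more, and gap-stretched
matches are penalised through the denominator.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .excerpts import Excerpt
from .prediction import Prediction, make_prediction
from .score_io import Melody

#: Regex atom standing for an arbitrary (possibly empty) run of events.
GAP_ATOM = "[0a-zA-Z]*"

#: Largest encodable absolute semitone offset (a-z / A-Z).
MAX_OFFSET = 26


class EncodingError(ValueError):
    """A semitone offset falls outside the letter-encodable range."""


class ConfigError(ValueError):
    """A training configuration value is out of its legal range."""


class UntrainedModelError(RuntimeError):
    """Prediction was requested from a model with no learned hierarchy."""


# ---------------------------------------------------------------------------
# Relative encoding and regexes


def offset_to_symbol(offset: int) -> str:
    """Encode a semitone offset: 0 -> '0', +5 -> 'E', -3 -> 'c'."""
    if offset == 0:
        return "0"
    if not -MAX_OFFSET <= offset <= MAX_OFFSET:
        raise EncodingError(f"offset {offset} outside the +/-{MAX_OFFSET} symbol range")
    if offset > 0:
        return chr(ord("A") + offset - 1)
    return chr(ord("a") - offset - 1)


def symbol_to_offset(symbol: str) -> int:
    """Inverse of :func:`offset_to_symbol`."""
    if symbol == "0":
        return 0
    if "A" <= symbol <= "Z":
        return ord(symbol) - ord("A") + 1
    if "a" <= symbol <= "z":
        return -(ord(symbol) - ord("a") + 1)
    raise EncodingError(f"unknown symbol {symbol!r}")


def encode_relative(pitches: Sequence[int], anchor: int = 0) -> str:
    """Encode pitches from ``anchor`` onward as offsets from the anchor pitch."""
    reference = pitches[anchor]
    return "".join(offset_to_symbol(p - reference) for p in pitches[anchor:])


@dataclass(frozen=True)
class RelativePattern:
    """A melodic shape as semitone offsets from its first (anchor) event."""

    offsets: tuple[int, ...]
    support: int = 0
    layer: int = 0

    def __post_init__(self) -> None:
        if len(self.offsets) < 2:
            raise ValueError("a pattern spans at least 2 events")
        if self.offsets[0] != 0:
            raise ValueError("the anchor offset must be 0")
        if any(abs(o) > MAX_OFFSET for o in self.offsets):
            raise EncodingError("pattern offset outside the symbol range")

    @property
    def symbols(self) -> str:
        return "".join(offset_to_symbol(o) for o in self.offsets)

    def __len__(self) -> int:
        return len(self.offsets)


def pattern_to_regex(pattern: RelativePattern) -> str:
    """Join the pattern's symbols with the indefinite-gap atom."""
    symbols = [offset_to_symbol(o) for o in pattern.offsets]
    return GAP_ATOM.join(re.escape(s) for s in symbols)


def _prefix_regex(pattern: RelativePattern) -> re.Pattern[str]:
    """Regex for all symbols but the last, anchored, with trailing gap.

    Used at prediction time: the excerpt suffix must realise the pattern's
    first k-1 events (gaps allowed) with any remainder absorbed by a final
    gap, leaving the k-th event for the continuation slot.
    """
    symbols = [offset_to_symbol(o) for o in pattern.offsets[:-1]]
    body = GAP_ATOM.join(re.escape(s) for s in symbols)
    return re.compile(body + GAP_ATOM + r"\Z")


def gapped_match(pattern_symbols: str, text: str) -> bool:
    """Does ``pattern_symbols`` occur in ``text`` as an anchored gapped
    subsequence (first symbol at position 0, arbitrary events between the
    rest, arbitrary events after the last)?"""
    body = GAP_ATOM.join(re.escape(s) for s in pattern_symbols)
    return re.fullmatch(body + GAP_ATOM, text) is not None


# ---------------------------------------------------------------------------
# Hierarchy learning

#: One concrete occurrence of a part: (melody index, anchor event index,
#: last matched event index).  Distinct internal gap assignments that
#: realise the same pattern over the same span collapse into one
#: activation, which keeps the composition search tractable.
Activation = tuple[int, int, int]


@dataclass
class _Part:
    """A learned part: the leaf or a composition, with its activations."""

    layer: int
    offsets: tuple[int, ...]  # unrolled, anchor-relative; (0,) for the leaf
    activations: set[Activation] = field(default_factory=set)

    @property
    def support(self) -> int:
        return len(self.activations)

    def coverage(self) -> set[tuple[int, int]]:
        return {(m, i) for m, anchor, end in self.activations for i in range(anchor, end + 1)}


@dataclass
class TrainConfig:
    min_support: int = 3
    max_gap: int = 2
    max_layers: int = 5
    inhibition_overlap: float = 0.8
    #: keep at most this many new parts per layer, best-supported first;
    #: bounds the otherwise exponential growth of gapped shape variants
    max_parts_per_layer: int = 200

    def __post_init__(self) -> None:
        if self.min_support < 2:
            raise ConfigError("min_support must be at least 2")
        if self.max_gap < 0 or self.max_layers < 2:
            raise ConfigError("max_gap must be >= 0 and max_layers >= 2")
        if not 0 < self.inhibition_overlap <= 1:
            raise ConfigError("inhibition_overlap must be in (0, 1]")
        if self.max_parts_per_layer < 1:
            raise ConfigError("max_parts_per_layer must be positive")


@dataclass
class CHModel:
    """A trained compositional hierarchy of melodic patterns."""

    patterns: list[RelativePattern]
    config: TrainConfig
    n_layers: int = 1

    @property
    def trained(self) -> bool:
        return self.n_layers >= 1 and self.patterns is not None

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": vars(self.config),
                "n_layers": self.n_layers,
                "patterns": [
                    {"offsets": list(p.offsets), "support": p.support, "layer": p.layer}
                    for p in self.patterns
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CHModel":
        payload = json.loads(text)
        return cls(
            patterns=[
                RelativePattern(tuple(p["offsets"]), p["support"], p["layer"])
                for p in payload["patterns"]
            ],
            config=TrainConfig(**payload["config"]),
            n_layers=payload["n_layers"],
        )


def _compose_layer(
    parts: list[_Part],
    newest: list[_Part],
    pitches_by_melody: list[list[int]],
    config: TrainConfig,
    next_layer: int,
) -> list[_Part]:
    """Form the next layer's compositions from ordered activation pairs.

    A pair (left, right) qualifies when the right part's anchor follows the
    left part's last matched event by at most ``max_gap`` intervening
    events; pairs are grouped by (left part, right part, anchor pitch
    offset) and kept at ``min_support`` occurrences.  Only pairs touching
    the newest layer are enumerated — older pairings were already formed.
    """
    # index activations by (melody, anchor event)
    by_anchor: dict[tuple[int, int], list[tuple[int, Activation]]] = {}
    for k, part in enumerate(parts):
        for act in part.activations:
            by_anchor.setdefault((act[0], act[1]), []).append((k, act))

    newest_ids = {id(p) for p in newest}
    is_newest = [id(p) in newest_ids for p in parts]
    groups: dict[tuple[int, int, int], set[Activation]] = {}
    for left_idx, left in enumerate(parts):
        for melody, first, last in left.activations:
            n_events = len(pitches_by_melody[melody])
            for anchor in range(last + 1, min(last + 2 + config.max_gap, n_events)):
                for right_idx, ract in by_anchor.get((melody, anchor), ()):
                    if not (is_newest[left_idx] or is_newest[right_idx]):
                        continue
                    offset = (
                        pitches_by_melody[melody][anchor]
                        - pitches_by_melody[melody][first]
                    )
                    if abs(offset) > MAX_OFFSET:
                        continue
                    key = (left_idx, right_idx, offset)
                    groups.setdefault(key, set()).add((melody, first, ract[2]))

    by_shape: dict[tuple[int, ...], set[Activation]] = {}
    for (left_idx, right_idx, offset), acts in sorted(groups.items()):
        if len(acts) < config.min_support:
            continue
        left, right = parts[left_idx], parts[right_idx]
        shape = left.offsets + tuple(o + offset for o in right.offsets)
        if any(abs(o) > MAX_OFFSET for o in shape):
            continue
        by_shape.setdefault(shape, set()).update(acts)
    return [
        _Part(layer=next_layer, offsets=shape, activations=acts)
        for shape, acts in sorted(by_shape.items())
    ]


def _inhibit(parts: list[_Part], threshold: float) -> list[_Part]:
    """Drop a part when a retained strictly longer part covers >= threshold
    of the events its activations touch."""
    ordered = sorted(
        parts, key=lambda p: (-len(p.offsets), -p.support, p.offsets)
    )
    kept: list[_Part] = []
    covers: list[tuple[int, set[tuple[int, int]]]] = []
    for part in ordered:
        cover = part.coverage()
        inhibited = False
        for other_len, other_cover in covers:
            if other_len <= len(part.offsets):
                continue
            if cover and len(cover & other_cover) >= threshold * len(cover):
                inhibited = True
                break
        if not inhibited:
            kept.append(part)
            covers.append((len(part.offsets), cover))
    return kept


def learn_hierarchy(corpus: Sequence[Melody], config: TrainConfig | None = None) -> CHModel:
    """Learn the pattern hierarchy from a corpus of melodies.

    Fully deterministic: no randomness is involved at any stage.
    """
    config = config or TrainConfig()
    if not corpus:
        raise ValueError("cannot train on an empty corpus")
    pitches_by_melody = [m.pitches for m in corpus]

    leaf = _Part(
        layer=1,
        offsets=(0,),
        activations={(m, i, i) for m, ps in enumerate(pitches_by_melody) for i in range(len(ps))},
    )
    composed: list[_Part] = []
    newest: list[_Part] = [leaf]
    layer = 1
    while layer < config.max_layers:
        pool = [leaf] + composed
        fresh = _compose_layer(pool, newest, pitches_by_melody, config, layer + 1)
        # never re-create an already known shape on a later layer
        known = {p.offsets for p in composed}
        fresh = [p for p in fresh if p.offsets not in known]
        if not fresh:
            break
        # part selection: best-supported (longer first on ties) new shapes
        fresh.sort(key=lambda p: (-p.support, -len(p.offsets), p.offsets))
        fresh = fresh[: config.max_parts_per_layer]
        composed = _inhibit(composed + fresh, config.inhibition_overlap)
        newest = [p for p in fresh if p in composed]
        if not newest:
            break
        layer += 1

    patterns = [
        RelativePattern(offsets=p.offsets, support=p.support, layer=p.layer)
        for p in sorted(composed, key=lambda p: (p.layer, -p.support, p.offsets))
    ]
    return CHModel(patterns=patterns, config=config, n_layers=layer)


# ---------------------------------------------------------------------------
# Eq. 1 weight and prediction


def eq1_weight(n_events: int, segment_length: int, match_start: int) -> float:
    """Relevance weight of one pattern match.

    ``n_events`` is the pattern length including the continuation slot,
    ``segment_length`` the excerpt's event count plus the prediction slot,
    ``match_start`` the 0-based anchor index of the match.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    if not 0 <= match_start < segment_length:
        raise ValueError("match_start must lie inside the segment")
    weight = n_events / (segment_length - match_start + 1)
    if weight > 1:
        warnings.warn(
            f"pattern weight {weight:.3f} exceeds 1 "
            f"(n_events={n_events}, segment={segment_length}, start={match_start})",
            stacklevel=2,
        )
    return weight


def iter_matches(model: CHModel, pitches: Sequence[int]) -> Iterable[tuple[RelativePattern, int, int, float]]:
    """Yield (pattern, anchor, predicted_pitch, weight) for every match.

    The segment is the excerpt plus one virtual prediction slot; a match
    realises all but the pattern's final event inside the excerpt (gaps
    allowed, remainder absorbed), leaving the final event as the predicted
    continuation.
    """
    segment_length = len(pitches) + 1
    for pattern in model.patterns:
        regex = _prefix_regex(pattern)
        for anchor in range(len(pitches)):
            try:
                suffix = encode_relative(pitches, anchor)
            except EncodingError:
                continue
            if regex.fullmatch(suffix) is None:
                continue
            predicted = pitches[anchor] + pattern.offsets[-1]
            weight = eq1_weight(len(pattern), segment_length, anchor)
            yield pattern, anchor, predicted, weight


def predict_chm(model: CHModel, excerpt: Excerpt) -> Prediction:
    """Score the 25-candidate window from all pattern matches.

    A candidate's score is the maximum weight over the matches that
    predict it; candidates predicted by no pattern score 0.
    """
    if model is None or not model.trained:
        raise UntrainedModelError("predict_chm needs a trained model")
    pitches = excerpt.melody.pitches
    last = pitches[-1]
    scores: dict[int, float] = {}
    for _, _, predicted, weight in iter_matches(model, pitches):
        if abs(predicted - last) > 12:
            continue
        if weight > scores.get(predicted, 0.0):
            scores[predicted] = weight
    return make_prediction(last, scores)
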