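"""Implication-Realization expectancy scoring of melodic continuations.

The bottom-up model scores a candidate continuation from two intervals:
the *implicative* interval i (penultimate to last heard tone) and the
*realized* interval r (last tone to candidate).  Five original criteria —
registral direction, registral return, intervallic difference, proximity,
closure — encode Narmour's prose thresholds (the 8-semitone direction
rule, the 2-semitone return window, the 5-semitone proximity preference,
the 3-semitone closure margin).  Five extension criteria add tonal and
statistical knowledge: consonance, tonality (probe-tone rating of the
candidate), melodic attraction (anchoring-strength ratio damped by the
squared interval), tessitura (closeness to the melody's median pitch) and
mobility (lag-1 autocorrelation extrapolation).

Two predictors are exposed.  ``original_ir_predict`` averages the five
original criteria; it is deliberately restrictive and systematically
prefers repeating the last tone (the unison maximises proximity), which is
why the task uses the *adjusted* predictor: the unweighted mean of the
min-max-normalised registral return, proximity, tonality, melodic
attraction and tessitura.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median, pstdev
from typing import Sequence

from .excerpts import Excerpt
from .prediction import Prediction, candidate_pitches, make_prediction
from .tonality import ScaleContext

ORIGINAL_CRITERIA = (
    "registral_direction",
    "registral_return",
    "intervallic_difference",
    "proximity",
    "closure",
)
EXTENSION_CRITERIA = (
    "consonance",
    "tonality",
    "melodic_attraction",
    "tessitura",
    "mobility",
)
#: The criteria retained by the adjusted predictor.
RETAINED_CRITERIA = ("registral_return", "proximity", "tonality", "melodic_attraction", "tessitura")


class ContextError(ValueError):
    """The excerpt context is too short or lacks a scale for a criterion."""


@dataclass(frozen=True)
class IRContext:
    """Everything the criteria need about the heard excerpt."""

    pitches: tuple[int, ...]
    scale: ScaleContext | None = None

    def __post_init__(self) -> None:
        if len(self.pitches) < 2:
            raise ContextError("I-R scoring needs at least 2 context pitches")

    @property
    def implicative_interval(self) -> int:
        return self.pitches[-1] - self.pitches[-2]

    @property
    def last_pitch(self) -> int:
        return self.pitches[-1]


def _sign(x: int) -> int:
    return (x > 0) - (x < 0)


def bottom_up_scores(ctx: IRContext, candidate: int) -> dict[str, float]:
    """The five original criteria for one candidate continuation.

    With r the realized and i the implicative interval:

    * registral direction — large implicative intervals (>8 semitones)
      imply a direction change; small ones imply preservation (repetition
      counts as preserving).
    * registral return — a direction change landing within 2 semitones of
      the implicative interval's first tone.
    * intervallic difference — large implicative intervals imply similarly
      large realized ones (2-semitone slack on reversal, 3 on
      continuation); small ones imply smaller realized intervals.
    * proximity — graded preference for realized intervals of 5 semitones
      or fewer: max(0, 6 - |r|).
    * closure — a direction change, or a realized interval at least 3
      semitones smaller than the implicative one.
    """
    i = ctx.implicative_interval
    r = candidate - ctx.last_pitch
    scores: dict[str, float] = {}

    if abs(i) > 8:
        scores["registral_direction"] = 1.0 if _sign(r) != _sign(i) else 0.0
    else:
        scores["registral_direction"] = 1.0 if (_sign(r) == _sign(i) or r == 0) else 0.0

    scores["registral_return"] = float(
        _sign(r) != _sign(i) and abs(candidate - ctx.pitches[-2]) <= 2
    )

    if abs(i) >= 5:
        slack = 2 if _sign(r) != _sign(i) else 3
        scores["intervallic_difference"] = float(abs(abs(r) - abs(i)) <= slack)
    else:
        scores["intervallic_difference"] = float(abs(r) < abs(i))

    scores["proximity"] = float(max(0, 6 - abs(r)))

    scores["closure"] = float(_sign(r) != _sign(i) or (abs(i) - abs(r) >= 3))
    return scores


#: Anchoring strengths of the tonal basic space: tonic 4, triad tones 3,
#: other scale tones 2, non-scale tones 1.
_TRIAD_DEGREES = {"major": {0, 4, 7}, "minor": {0, 3, 7}, "pentatonic": {0, 4, 7}}


def _anchoring_strength(pitch: int, scale: ScaleContext) -> int:
    degree = (pitch - scale.tonic) % 12
    if degree == 0:
        return 4
    if degree in _TRIAD_DEGREES[scale.mode]:
        return 3
    if pitch % 12 in scale.admissible:
        return 2
    return 1


def extended_scores(ctx: IRContext, candidate: int) -> dict[str, float]:
    """The five extension criteria for one candidate continuation."""
    if ctx.scale is None:
        raise ContextError("tonality and melodic attraction need a scale context")
    r = candidate - ctx.last_pitch
    scores: dict[str, float] = {}

    scores["consonance"] = float(abs(r) % 12 in (0, 5, 7) or abs(r) == 12)

    scores["tonality"] = ctx.scale.profile_value(candidate)

    s_candidate = _anchoring_strength(candidate, ctx.scale)
    s_last = _anchoring_strength(ctx.last_pitch, ctx.scale)
    scores["melodic_attraction"] = (s_candidate / s_last) / max(1, abs(r)) ** 2

    mid = median(ctx.pitches)
    spread = pstdev(ctx.pitches)
    scores["tessitura"] = -abs(candidate - mid) / max(1.0, spread)

    scores["mobility"] = _mobility(ctx.pitches, candidate)
    return scores


def _mobility(pitches: Sequence[int], candidate: int) -> float:
    """Lag-1 autocorrelation extrapolation of the pitch series.

    The predicted next deviation from the series mean is the lag-1
    autocorrelation times the last deviation; the criterion is the negated
    distance of the candidate from that predicted position.
    """
    n = len(pitches)
    mean = sum(pitches) / n
    deviations = [p - mean for p in pitches]
    denom = sum(d * d for d in deviations)
    if denom == 0 or n < 2:
        rho = 0.0
    else:
        rho = sum(a * b for a, b in zip(deviations, deviations[1:])) / denom
    predicted = mean + rho * deviations[-1]
    return -abs(candidate - predicted)


def all_criterion_scores(ctx: IRContext, candidate: int) -> dict[str, float]:
    """All ten criteria for one candidate."""
    scores = bottom_up_scores(ctx, candidate)
    scores.update(extended_scores(ctx, candidate))
    return scores


def _normalise(column: Sequence[float]) -> list[float]:
    lo, hi = min(column), max(column)
    if hi == lo:
        return [0.5] * len(column)  # constant criterion carries no signal
    return [(v - lo) / (hi - lo) for v in column]


def _criterion_average_predict(
    excerpt: Excerpt,
    scale: ScaleContext | None,
    criteria: Sequence[str],
) -> Prediction:
    pitches = tuple(excerpt.melody.pitches)
    ctx = IRContext(pitches=pitches, scale=scale)
    window = candidate_pitches(ctx.last_pitch)
    needs_extension = any(name in EXTENSION_CRITERIA for name in criteria)
    table: dict[str, list[float]] = {name: [] for name in criteria}
    for candidate in window:
        scores = all_criterion_scores(ctx, candidate) if needs_extension else bottom_up_scores(ctx, candidate)
        for name in criteria:
            table[name].append(scores[name])
    normalised = {name: _normalise(col) for name, col in table.items()}
    combined = {
        pitch: sum(normalised[name][k] for name in criteria) / len(criteria)
        for k, pitch in enumerate(window)
    }
    return make_prediction(ctx.last_pitch, combined)


def adjusted_ir_predict(excerpt: Excerpt, scale: ScaleContext) -> Prediction:
    """The adjusted predictor: mean of five normalised retained criteria.

    Each retained criterion (registral return, proximity, tonality,
    melodic attraction, tessitura) is min-max normalised across the
    25-candidate window; a constant column contributes 0.5 everywhere.
    """
    return _criterion_average_predict(excerpt, scale, RETAINED_CRITERIA)


def original_ir_predict(excerpt: Excerpt) -> Prediction:
    """The unadjusted predictor over the five original criteria.

    Provided to reproduce the qualitative failure mode: the unison
    candidate (repeating the last tone) maximises proximity and is almost
    always ranked at or near the top.
    """
    return _criterion_average_predict(excerpt, None, ORIGINAL_CRITERIA)
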