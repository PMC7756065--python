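"""Seeded generator of folk-like monophonic corpora with planted motifs.

The generator emulates the summary statistics of short folk-song phrases:
around 15 events per phrase (range 7-24), a tonal range of about 12
semitones, and mostly stepwise motion with the largest leaps inside an
octave.  Pitches follow a first-order walk over scale tones whose
transition weight is the probe-tone tonal-hierarchy rating of the target
pitch class times a geometric decay in interval size, so stable scale
degrees recur often and small intervals dominate; phrases cadence on the
tonic or dominant pitch class.  Repeated relative motifs are spliced in
verbatim at manifest-recorded positions, giving the pattern learner real
structure to discover and the tests an exact ground truth.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .excerpts import (
    Excerpt,
    TooShortError,
    assemble_dataset,
    cut_complete,
    cut_incomplete,
    excerpt_criteria,
    filter_two_sd,
)
from .score_io import Melody, NoteEvent
from .tonality import MODE_DEGREES, PROFILES, ScaleContext

#: Default relative motifs per scale system (anchor-relative semitone
#: offsets, all drawn from the scale's degree set so planted notes stay
#: in-scale at a tonic-class anchor).  The banks are disjoint across
#: systems so that corpus familiarity is distinguishable.
DEFAULT_MOTIFS: dict[str, tuple[tuple[int, ...], ...]] = {
    "major": ((0, 4, 5, 7, 5, 4, 0), (0, 7, 5, 4, 2, 0)),
    "minor": ((0, 3, 5, 7, 5, 3, 0), (0, 7, 5, 3, 2, 0)),
    "pentatonic": ((0, 2, 7, 9, 7, 2, 0), (0, 9, 7, 4, 2, 0)),
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    scale: str = "major"
    tonic: int = 0
    n_songs: int = 100
    events_per_phrase: tuple[int, int] = (7, 24)
    mean_events: float = 15.0
    sd_events: float = 3.5
    phrases_per_song: int = 2
    #: geometric decay base of the interval-size penalty; smaller favours steps
    step_bias: float = 0.6
    #: half-width of the pitch compass around the register centre, semitones
    compass: int = 7
    motif_bank: Optional[tuple[tuple[int, ...], ...]] = None
    #: expected motif plantings per song
    motif_rate: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.events_per_phrase
        if not 2 <= lo <= hi:
            raise ValueError("events_per_phrase range must be non-empty and >= 2")
        if not 0 < self.step_bias <= 1:
            raise ValueError("step_bias must be in (0, 1]")
        if self.motif_bank is None:
            self.motif_bank = DEFAULT_MOTIFS[self.scale]

    @property
    def context(self) -> ScaleContext:
        return ScaleContext(tonic=self.tonic, mode=self.scale)  # type: ignore[arg-type]


@dataclass(frozen=True)
class MotifPlacement:
    start: int
    offsets: tuple[int, ...]


@dataclass
class SongManifest:
    song_id: str
    tonic: int
    mode: str
    phrase_ends: list[int]
    motifs: list[MotifPlacement] = field(default_factory=list)


@dataclass
class CorpusManifest:
    """Ground truth for every generated song, the oracle for tests."""

    config: GeneratorConfig
    songs: list[SongManifest] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": {**vars(self.config), "motif_bank": [list(m) for m in self.config.motif_bank or ()],
                           "events_per_phrase": list(self.config.events_per_phrase)},
                "songs": [
                    {
                        "song_id": s.song_id,
                        "tonic": s.tonic,
                        "mode": s.mode,
                        "phrase_ends": s.phrase_ends,
                        "motifs": [{"start": m.start, "offsets": list(m.offsets)} for m in s.motifs],
                    }
                    for s in self.songs
                ],
            },
            indent=1,
        )


#: Degrees the generator walks over.  Minor songs are generated from the
#: natural-minor scale (the raised 6th/7th of the 9-class admissible set
#: are evaluation leniency, not typical melody material).
GENERATION_DEGREES: dict[str, frozenset[int]] = {
    "major": MODE_DEGREES["major"],
    "minor": frozenset({0, 2, 3, 5, 7, 8, 10}),
    "pentatonic": MODE_DEGREES["pentatonic"],
}


def _scale_domain(config: GeneratorConfig) -> list[int]:
    centre = 60 + config.tonic
    degrees = GENERATION_DEGREES[config.scale]
    return [
        p
        for p in range(centre - config.compass, centre + config.compass + 1)
        if (p - config.tonic) % 12 in degrees
    ]


def _draw_length(config: GeneratorConfig, rng: np.random.Generator) -> int:
    lo, hi = config.events_per_phrase
    raw = rng.normal(config.mean_events, config.sd_events)
    return int(np.clip(round(raw), lo, hi))


def generate_melody(
    config: GeneratorConfig, rng: np.random.Generator, song_id: str = "song"
) -> tuple[Melody, SongManifest]:
    """Generate one song (a few phrases) plus its manifest entry."""
    domain = np.array(_scale_domain(config))
    profile = PROFILES[config.scale]
    hierarchy = np.array([profile.values[(p - config.tonic) % 12] for p in domain])
    cadence_classes = {config.tonic % 12, (config.tonic + 7) % 12}

    pitches: list[int] = []
    phrase_ends: list[int] = []
    centre = 60 + config.tonic
    current = int(domain[np.argmin(np.abs(domain - centre))])
    for phrase in range(config.phrases_per_song):
        length = _draw_length(config, rng)
        # interior phrases may cadence on the dominant; the song closes on
        # the tonic, the strongest tonal cue in folk melody
        final_phrase = phrase == config.phrases_per_song - 1
        classes = {config.tonic % 12} if final_phrase else cadence_classes
        for k in range(length):
            is_cadence = k == length - 1
            weights = hierarchy * np.power(config.step_bias, np.abs(domain - current))
            if is_cadence:
                mask = np.array([p % 12 in classes for p in domain])
                weights = weights * mask
            weights = weights / weights.sum()
            current = int(rng.choice(domain, p=weights))
            pitches.append(current)
        phrase_ends.append(len(pitches) - 1)

    motifs = _plant_motifs(pitches, phrase_ends, config, rng)

    durations = rng.choice([0.5, 1.0, 2.0], size=len(pitches), p=[0.45, 0.45, 0.1])
    # phrase-final tones are held, as in sung folk phrases; this also makes
    # the duration-weighted pitch-class profile bear the cadential signal
    durations[phrase_ends] = 2.0
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    events = [
        NoteEvent(onset=float(o), pitch=int(p), duration=float(d))
        for o, p, d in zip(onsets, pitches, durations)
    ]
    melody = Melody(id=song_id, events=events, phrase_ends=list(phrase_ends), tempo=100.0)
    melody.scale_hint = config.context
    manifest = SongManifest(
        song_id=song_id,
        tonic=config.tonic,
        mode=config.scale,
        phrase_ends=list(phrase_ends),
        motifs=motifs,
    )
    return melody, manifest


def _plant_motifs(
    pitches: list[int],
    phrase_ends: list[int],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[MotifPlacement]:
    """Splice motifs verbatim, avoiding cadences and earlier plantings."""
    bank = config.motif_bank or ()
    if not bank or config.motif_rate <= 0:
        return []
    n_plant = int(rng.poisson(config.motif_rate))
    placements: list[MotifPlacement] = []
    occupied: set[int] = set(phrase_ends)
    domain = set(_scale_domain(config))
    tonic_anchors = sorted(p for p in domain if (p - config.tonic) % 12 == 0)
    for _ in range(n_plant):
        offsets = tuple(bank[rng.integers(len(bank))])
        span = len(offsets)
        candidates = [
            s
            for s in range(0, len(pitches) - span)
            if not any(i in occupied for i in range(s, s + span))
        ]
        if not candidates or not tonic_anchors:
            break
        start = int(candidates[rng.integers(len(candidates))])
        anchor = int(tonic_anchors[rng.integers(len(tonic_anchors))])
        for k, off in enumerate(offsets):
            pitches[start + k] = anchor + off
        occupied.update(range(start, start + span))
        placements.append(MotifPlacement(start=start, offsets=offsets))
    return placements


def generate_corpus(config: GeneratorConfig) -> tuple[list[Melody], CorpusManifest]:
    """Generate ``n_songs`` melodies under one seed."""
    if config.n_songs <= 0:
        raise ValueError("n_songs must be positive")
    rng = np.random.default_rng(config.seed)
    manifest = CorpusManifest(config=config)
    corpus: list[Melody] = []
    for idx in range(config.n_songs):
        melody, entry = generate_melody(config, rng, song_id=f"{config.scale}-{config.seed}-{idx:03d}")
        corpus.append(melody)
        manifest.songs.append(entry)
    return corpus, manifest


def generate_fixture_excerpts(
    corpus: Sequence[Melody],
    manifest: CorpusManifest,
    rng: np.random.Generator,
    n: Optional[int] = None,
    complete_frac: float = 0.75,
    min_len: int = 5,
) -> list[Excerpt]:
    """Cut, filter and mix excerpts from a generated corpus.

    Each song contributes one complete excerpt (cut at its final phrase
    end) and, where long enough, one incomplete excerpt; the pool is
    pruned by the two-standard-deviation balance filter and sampled to the
    requested 75/25 mix.  ``n`` defaults to the largest size the filtered
    pool supports.
    """
    pool: list[Excerpt] = []
    for melody, entry in zip(corpus, manifest.songs):
        try:
            pool.append(cut_complete(melody, entry.phrase_ends[-1]))
        except TooShortError:
            pass
        try:
            pool.append(cut_incomplete(melody, rng, min_len=min_len))
        except TooShortError:
            pass
    criteria = [excerpt_criteria(e) for e in pool]
    kept = [pool[i] for i in filter_two_sd(criteria)]
    n_complete = sum(1 for e in kept if e.completeness == "complete")
    n_incomplete = len(kept) - n_complete
    if n is None:
        n = min(
            int(n_complete / complete_frac) if complete_frac > 0 else n_incomplete,
            int(n_incomplete / (1 - complete_frac)) if complete_frac < 1 else n_complete,
        )
    return assemble_dataset(kept, n, complete_frac, rng)
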