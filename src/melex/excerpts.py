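"""Excerpt generation and dataset-balance filtering.

Full melodies are truncated in two ways: *complete* excerpts stop after
the penultimate tone of a phrase (the removed phrase-final tone is the
prediction target) and *incomplete* excerpts stop at a random mid-phrase
point.  Balanced datasets mix the two classes 75/25 and drop outlier
excerpts whose descriptive criteria (event count, largest interval, tonal
range, duration) fall outside two standard deviations of the pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .score_io import Melody

Completeness = Literal["complete", "incomplete"]


class TooShortError(ValueError):
    """The melody is too short to cut an excerpt at the requested point."""


class InsufficientDataError(ValueError):
    """An aggregate operation needs more inputs than were given."""


class CompositionError(ValueError):
    """The excerpt pool cannot satisfy the requested class mix."""


@dataclass(frozen=True)
class Excerpt:
    """A truncated melody prefix plus its ground-truth continuation."""

    melody: Melody
    true_continuation: int
    completeness: Completeness
    source_id: str

    def __post_init__(self) -> None:
        if len(self.melody) < 2:
            raise TooShortError("an excerpt needs at least 2 events")
        if not 0 <= self.true_continuation <= 127:
            raise ValueError("true continuation outside MIDI range")

    @property
    def last_pitch(self) -> int:
        return self.melody.events[-1].pitch


@dataclass(frozen=True)
class ExcerptCriteria:
    """Dataset-balance descriptors of one excerpt."""

    n_events: int
    largest_interval: int
    tonal_range: int
    duration: float

    def __post_init__(self) -> None:
        if min(self.n_events, self.largest_interval, self.tonal_range) < 0 or self.duration < 0:
            raise ValueError("criteria are non-negative")
        if self.largest_interval > self.tonal_range:
            raise ValueError("largest adjacent interval cannot exceed the tonal range")

    def as_vector(self) -> np.ndarray:
        return np.array([self.n_events, self.largest_interval, self.tonal_range, self.duration])


def cut_complete(melody: Melody, phrase_end: int) -> Excerpt:
    """Cut after the penultimate tone of the phrase ending at ``phrase_end``.

    The excerpt keeps events ``0 .. phrase_end-1``; the phrase-final tone at
    index ``phrase_end`` becomes the prediction target.
    """
    if phrase_end < 2:
        raise TooShortError(f"phrase_end {phrase_end} leaves fewer than 2 context events")
    if phrase_end >= len(melody):
        raise TooShortError(f"phrase_end {phrase_end} beyond melody of length {len(melody)}")
    prefix = Melody(id=f"{melody.id}:complete@{phrase_end}", events=list(melody.events[:phrase_end]), tempo=melody.tempo)
    prefix.scale_hint = melody.scale_hint
    return Excerpt(
        melody=prefix,
        true_continuation=melody.events[phrase_end].pitch,
        completeness="complete",
        source_id=melody.id,
    )


def cut_incomplete(melody: Melody, rng: np.random.Generator, min_len: int = 5) -> Excerpt:
    """Cut at a random mid-phrase point, never at a phrase-final position.

    The cut index (number of retained events) is drawn uniformly from
    ``[min_len, final_phrase_end)`` excluding indices that are phrase ends,
    so the incomplete class is disjoint from the complete one.
    Deterministic under a seeded ``rng``.
    """
    phrase_ends = set(melody.phrase_ends or [len(melody) - 1])
    final_end = max(phrase_ends)
    legal = [c for c in range(min_len, final_end) if c not in phrase_ends]
    if not legal:
        raise TooShortError(
            f"melody {melody.id!r} (length {len(melody)}) has no legal incomplete cut"
        )
    cut = int(legal[rng.integers(len(legal))]) if len(legal) > 1 else legal[0]
    prefix = Melody(id=f"{melody.id}:incomplete@{cut}", events=list(melody.events[:cut]), tempo=melody.tempo)
    prefix.scale_hint = melody.scale_hint
    return Excerpt(
        melody=prefix,
        true_continuation=melody.events[cut].pitch,
        completeness="incomplete",
        source_id=melody.id,
    )


def excerpt_criteria(excerpt: Excerpt, default_tempo: float = 100.0) -> ExcerptCriteria:
    """Compute the balance criteria for one excerpt."""
    pitches = excerpt.melody.pitches
    largest = max((abs(b - a) for a, b in zip(pitches, pitches[1:])), default=0)
    return ExcerptCriteria(
        n_events=len(pitches),
        largest_interval=largest,
        tonal_range=max(pitches) - min(pitches),
        duration=excerpt.melody.duration_seconds(default_tempo),
    )


def filter_two_sd(criteria_list: Sequence[ExcerptCriteria]) -> list[int]:
    """Indices whose every criterion lies within mean ± 2·SD of the pool.

    Population (not sample) standard deviation; statistics are computed on
    the full pre-filter pool, which makes the filter idempotent on its own
    output with respect to those statistics.
    """
    if len(criteria_list) < 2:
        raise InsufficientDataError("the 2-SD filter needs at least 2 excerpts")
    matrix = np.vstack([c.as_vector() for c in criteria_list])
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)  # population SD
    lo, hi = mean - 2 * sd, mean + 2 * sd
    keep = np.all((matrix >= lo) & (matrix <= hi), axis=1)
    return [i for i, ok in enumerate(keep) if ok]


def assemble_dataset(
    pool: Sequence[Excerpt],
    n: int,
    complete_frac: float = 0.75,
    rng: np.random.Generator | None = None,
) -> list[Excerpt]:
    """Draw ``n`` excerpts with ``round(n*complete_frac)`` complete ones."""
    rng = rng if rng is not None else np.random.default_rng(0)
    n_complete = round(n * complete_frac)
    n_incomplete = n - n_complete
    complete = [e for e in pool if e.completeness == "complete"]
    incomplete = [e for e in pool if e.completeness == "incomplete"]
    if len(complete) < n_complete or len(incomplete) < n_incomplete:
        raise CompositionError(
            f"pool has {len(complete)} complete / {len(incomplete)} incomplete excerpts; "
            f"need {n_complete} / {n_incomplete}"
        )
    chosen = [complete[i] for i in rng.choice(len(complete), n_complete, replace=False)]
    chosen += [incomplete[i] for i in rng.choice(len(incomplete), n_incomplete, replace=False)]
    return chosen
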