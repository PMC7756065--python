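"""Tonal-context estimation from probe-tone tonal hierarchies.

The 12-dimensional major and minor probe-tone profiles (Krumhansl's
tonal-hierarchy ratings, indexed from the tonic) are shipped as constants.
Key estimation is the standard profile-correlation procedure: the
duration-weighted pitch-class distribution of a melody is Pearson-correlated
with all 24 rotations of the two profiles and the best-fitting rotation
wins.  Anhemitonic pentatonic contexts (interval pattern 2-2-3-2-3) are
detected structurally, by pitch-class-set inclusion, since no pentatonic
probe-tone profile exists.

Each context exposes the set of *admissible* pitch classes used by relaxed
evaluation: 7 diatonic classes in major, 9 in minor (natural minor plus the
raised sixth and seventh degrees of the melodic/harmonic forms), 5 in
pentatonic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .score_io import EmptyInputError, Melody

#: Probe-tone ratings for a major key, indexed by pitch class relative to
#: the tonic (index 0 = tonic).
MAJOR_PROFILE: tuple[float, ...] = (
    6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88,
)

#: Probe-tone ratings for a minor key, same indexing.
MINOR_PROFILE: tuple[float, ...] = (
    6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.78, 3.98, 2.69, 3.34, 3.17,
)

#: Scale-degree pitch classes (relative to tonic/reference) per mode.
MODE_DEGREES: dict[str, frozenset[int]] = {
    "major": frozenset({0, 2, 4, 5, 7, 9, 11}),
    # natural minor plus raised 6th (9) and raised 7th (11)
    "minor": frozenset({0, 2, 3, 5, 7, 8, 9, 10, 11}),
    "pentatonic": frozenset({0, 2, 4, 7, 9}),
}

Mode = Literal["major", "minor", "pentatonic"]


class DegenerateKeyError(ValueError):
    """Profile correlation is undefined (fewer than 2 distinct pitch classes).

    Callers hitting this should supply an explicit ``scale_hint``.
    """


@dataclass(frozen=True)
class TonalProfile:
    """A 12-vector of tonal-hierarchy ratings relative to a tonic."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 12:
            raise ValueError("a tonal profile has exactly 12 values")
        if any(v <= 0 for v in self.values):
            raise ValueError("tonal-hierarchy ratings are positive")

    def rotated_to(self, tonic: int) -> tuple[float, ...]:
        """Ratings indexed by absolute pitch class for the given tonic."""
        return tuple(self.values[(pc - tonic) % 12] for pc in range(12))


PROFILES: dict[str, TonalProfile] = {
    "major": TonalProfile(MAJOR_PROFILE),
    "minor": TonalProfile(MINOR_PROFILE),
    # the pentatonic repertoire has no probe-tone profile of its own; the
    # major profile rotated to the pentatonic reference stands in
    "pentatonic": TonalProfile(MAJOR_PROFILE),
}


@dataclass(frozen=True)
class ScaleContext:
    """An estimated or annotated tonal context."""

    tonic: int
    mode: Mode
    fit: float = float("nan")
    admissible: frozenset[int] = field(default=frozenset())

    def __post_init__(self) -> None:
        if not 0 <= self.tonic <= 11:
            raise ValueError("tonic must be a pitch class 0-11")
        if self.mode not in MODE_DEGREES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.admissible:
            members = frozenset((self.tonic + d) % 12 for d in MODE_DEGREES[self.mode])
            object.__setattr__(self, "admissible", members)
        if self.tonic not in self.admissible:
            raise ValueError("tonic must be an admissible pitch class")

    def profile_value(self, pitch: int) -> float:
        """Tonal-hierarchy rating of a pitch (class) in this context."""
        return PROFILES[self.mode].values[(pitch - self.tonic) % 12]


def admissible_pitch_classes(context: ScaleContext) -> frozenset[int]:
    """Pitch classes counted correct under relaxed evaluation.

    Cardinality is 7 for major, 9 for minor, 5 for pentatonic, for every
    tonic.
    """
    return frozenset((context.tonic + d) % 12 for d in MODE_DEGREES[context.mode])


def pitch_class_profile(melody: Melody, weighting: str = "duration") -> np.ndarray:
    """Accumulate total duration (or event count) per pitch class.

    The vector sums to the melody's total duration (``weighting="duration"``)
    or its event count (``weighting="count"``).
    """
    if not melody.events:
        raise EmptyInputError("cannot profile an empty melody")
    if weighting not in ("duration", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    vector = np.zeros(12)
    for event in melody.events:
        vector[event.pitch % 12] += event.duration if weighting == "duration" else 1.0
    return vector


def estimate_key(melody: Melody, weighting: str = "duration") -> ScaleContext:
    """Profile-correlation key finding over all 24 major/minor rotations.

    Returns the argmax context with its Pearson fit.  Ties break toward
    higher fit, then major over minor, then the lower tonic pitch class.
    """
    observed = pitch_class_profile(melody, weighting)
    if np.count_nonzero(observed) < 2:
        raise DegenerateKeyError(
            "melody uses a single pitch class; key fit is undefined - "
            "supply a scale_hint instead"
        )
    best: Optional[ScaleContext] = None
    for mode in ("major", "minor"):
        profile = PROFILES[mode]
        for tonic in range(12):
            rotated = np.array(profile.rotated_to(tonic))
            fit = float(np.corrcoef(observed, rotated)[0, 1])
            candidate = ScaleContext(tonic=tonic, mode=mode, fit=fit)  # type: ignore[arg-type]
            if best is None or _key_order(candidate) > _key_order(best):
                best = candidate
    assert best is not None
    return best


def _key_order(ctx: ScaleContext) -> tuple[float, int, int]:
    return (ctx.fit, 1 if ctx.mode == "major" else 0, -ctx.tonic)


def detect_pentatonic(melody: Melody) -> Optional[ScaleContext]:
    """Detect an anhemitonic pentatonic context by pitch-class inclusion.

    If the melody's pitch-class set fits inside some rotation of
    {0, 2, 4, 7, 9}, the rotation with the lowest reference class wins and
    its reference class is reported as the tonic; otherwise ``None``.
    """
    if not melody.events:
        raise EmptyInputError("cannot analyse an empty melody")
    used = {e.pitch % 12 for e in melody.events}
    for reference in range(12):
        members = {(reference + d) % 12 for d in MODE_DEGREES["pentatonic"]}
        if used <= members:
            return ScaleContext(tonic=reference, mode="pentatonic", fit=1.0)
    return None


def resolve_context(melody: Melody, pentatonic_first: bool = False) -> ScaleContext:
    """Pick the melody's tonal context with the documented precedence.

    An explicit ``scale_hint`` always wins (scale systems are assigned per
    repertoire, not re-estimated).  Otherwise pentatonic detection runs
    before diatonic estimation for pentatonic repertoire
    (``pentatonic_first=True``), else after a failed diatonic estimate.
    """
    if melody.scale_hint is not None:
        return melody.scale_hint  # type: ignore[return-value]
    if pentatonic_first:
        pent = detect_pentatonic(melody)
        if pent is not None:
            return pent
    try:
        return estimate_key(melody)
    except DegenerateKeyError:
        pent = detect_pentatonic(melody)
        if pent is not None:
            return pent
        raise
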