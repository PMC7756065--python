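"""Ranked continuation predictions over the ±12-semitone candidate window.

Every predictor in this package scores the same 25 candidate pitches — the
two octaves around the excerpt's final pitch, matching the response window
offered to human listeners — so that model and listener accuracies are
directly comparable.  Ties are broken deterministically: higher score
first, then the smaller absolute interval from the last pitch, then the
lower pitch, which makes reciprocal ranks reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

#: Half-width of the candidate window in semitones.
WINDOW_HALF_WIDTH = 12


def candidate_pitches(last_pitch: int, half_width: int = WINDOW_HALF_WIDTH) -> list[int]:
    """The candidate continuation pitches around the excerpt's last pitch."""
    return list(range(last_pitch - half_width, last_pitch + half_width + 1))


@dataclass(frozen=True)
class Prediction:
    """Scores and a deterministic ranking over the candidate window."""

    last_pitch: int
    candidates: dict[int, float]
    ranking: tuple[int, ...]

    def rank_of(self, pitch: int) -> int:
        """1-based rank of a pitch; window misses rank one past the window."""
        try:
            return self.ranking.index(pitch) + 1
        except ValueError:
            return len(self.ranking) + 1

    @property
    def top(self) -> int:
        return self.ranking[0]


def make_prediction(
    last_pitch: int,
    scores: Mapping[int, float],
    half_width: int = WINDOW_HALF_WIDTH,
) -> Prediction:
    """Assemble a :class:`Prediction` from (possibly partial) pitch scores.

    Candidates missing from ``scores`` get 0; scores for pitches outside
    the window are discarded.
    """
    window = candidate_pitches(last_pitch, half_width)
    full = {pitch: float(scores.get(pitch, 0.0)) for pitch in window}
    if any(v < 0 for v in full.values()):
        raise ValueError("candidate scores must be non-negative")
    ranking = tuple(
        sorted(window, key=lambda p: (-full[p], abs(p - last_pitch), p))
    )
    return Prediction(last_pitch=last_pitch, candidates=full, ranking=ranking)
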