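"""Strict/relaxed scoring of predictions, reciprocal ranks, and reports.

*Strict* evaluation accepts only the exact ground-truth pitch.  *Relaxed*
evaluation accepts any candidate whose pitch class belongs to the
excerpt's tonal hierarchy: 7 admissible classes in major, 9 in minor, 5 in
pentatonic.  The reciprocal rank of the true continuation in the
deterministic candidate ranking summarises how high the truth was scored;
the mean reciprocal rank (MRR) aggregates it over an excerpt set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

from .excerpts import Completeness
from .prediction import Prediction
from .tonality import ScaleContext, admissible_pitch_classes


@dataclass(frozen=True)
class EvaluationRecord:
    """One excerpt's outcome under both criteria."""

    excerpt_id: str
    top_prediction: int
    strict_correct: bool
    relaxed_correct: bool
    reciprocal_rank: float
    completeness: Completeness
    truth_in_window: bool = True


def strict_correct(predicted: int, truth: int) -> bool:
    """Exact-pitch (octave-sensitive) correctness."""
    return predicted == truth


def relaxed_correct(predicted: int, context: ScaleContext) -> bool:
    """Scale-membership (octave-invariant) correctness."""
    return predicted % 12 in admissible_pitch_classes(context)


def reciprocal_rank(prediction: Prediction, truth: int) -> float:
    """1 over the 1-based rank of the truth in the ranking.

    A truth outside the candidate window is ranked one past the window
    (rank 26 for the default ±12 window) so the MRR stays total.
    """
    return 1.0 / prediction.rank_of(truth)


def mrr(reciprocal_ranks: Sequence[float]) -> float:
    """Mean reciprocal rank of a non-empty record set."""
    if not reciprocal_ranks:
        raise ValueError("MRR of an empty record set is undefined")
    return sum(reciprocal_ranks) / len(reciprocal_ranks)


def evaluate_prediction(
    excerpt_id: str,
    prediction: Prediction,
    truth: int,
    context: ScaleContext,
    completeness: Completeness,
) -> EvaluationRecord:
    """Score one prediction under both criteria."""
    top = prediction.top
    return EvaluationRecord(
        excerpt_id=excerpt_id,
        top_prediction=top,
        strict_correct=strict_correct(top, truth),
        relaxed_correct=relaxed_correct(top, context),
        reciprocal_rank=reciprocal_rank(prediction, truth),
        completeness=completeness,
        truth_in_window=truth in prediction.candidates,
    )


def baselines(context: ScaleContext, half_width: int = 12) -> dict[str, float]:
    """Chance accuracies over the candidate window, in percent.

    ``all_notes`` is a uniform guess over the 25 candidates (4%).
    ``scale_notes`` guesses uniformly among the window candidates whose
    pitch class is admissible, for a window centred on an admissible
    pitch: 100/15 ≈ 6.7% for a diatonic-major window, 100/11 ≈ 9.1% for a
    pentatonic one.
    """
    window_size = 2 * half_width + 1
    admissible = admissible_pitch_classes(context)
    centre = context.tonic + 60  # any admissible centre gives the same count
    in_scale = sum(
        1 for p in range(centre - half_width, centre + half_width + 1) if p % 12 in admissible
    )
    return {"all_notes": 100.0 / window_size, "scale_notes": 100.0 / in_scale}


@dataclass(frozen=True)
class Report:
    """Per-group accuracies (percent) and MRRs."""

    counts: dict[str, int]
    strict_accuracy: dict[str, float]
    relaxed_accuracy: dict[str, float]
    mrr: dict[str, float]
    baselines: dict[str, float] | None = None

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "strict_accuracy_pct": {k: round(v, 1) for k, v in self.strict_accuracy.items()},
            "relaxed_accuracy_pct": {k: round(v, 1) for k, v in self.relaxed_accuracy.items()},
            "mrr": {k: round(v, 3) for k, v in self.mrr.items()},
        }
        if self.baselines is not None:
            payload["baselines_pct"] = {k: round(v, 1) for k, v in self.baselines.items()}
        return json.dumps(payload, indent=1)

    def format_table(self) -> str:
        groups = list(self.counts)
        lines = [f"{'group':<12}{'n':>5}{'strict %':>10}{'relaxed %':>11}{'MRR':>8}"]
        for g in groups:
            lines.append(
                f"{g:<12}{self.counts[g]:>5}"
                f"{self.strict_accuracy[g]:>10.1f}{self.relaxed_accuracy[g]:>11.1f}"
                f"{self.mrr[g]:>8.3f}"
            )
        return "\n".join(lines)


def report(
    records: Sequence[EvaluationRecord],
    context: ScaleContext | None = None,
) -> Report:
    """Aggregate records into all/complete/incomplete accuracies and MRRs."""
    if not records:
        raise ValueError("cannot report on an empty record set")
    groups: Mapping[str, list[EvaluationRecord]] = {
        "all": list(records),
        "complete": [r for r in records if r.completeness == "complete"],
        "incomplete": [r for r in records if r.completeness == "incomplete"],
    }
    counts, strict_acc, relaxed_acc, mrrs = {}, {}, {}, {}
    for name, members in groups.items():
        if not members:
            continue
        counts[name] = len(members)
        strict_acc[name] = 100.0 * sum(r.strict_correct for r in members) / len(members)
        relaxed_acc[name] = 100.0 * sum(r.relaxed_correct for r in members) / len(members)
        mrrs[name] = mrr([r.reciprocal_rank for r in members])
    return Report(
        counts=counts,
        strict_accuracy=strict_acc,
        relaxed_accuracy=relaxed_acc,
        mrr=mrrs,
        baselines=baselines(context) if context is not None else None,
    )
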