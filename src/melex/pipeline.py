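"""End-to-end orchestration: simulate -> excerpt -> train -> predict -> evaluate.

A run is fully reproducible from its config and seed.  With one corpus it
trains (where the model needs training), predicts the held-out excerpts
and reports accuracies; with two corpora it emits the 2x2 cross-training
grid (train A/B x test A/B) that exposes the familiarity effect: a
pattern model trained on a scale-matched corpus should beat the
scale-mismatched training on the same test excerpts.  The expectancy
model needs no training at all and ignores the training corpus.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .chm import CHModel, TrainConfig, learn_hierarchy, predict_chm
from .evaluation import EvaluationRecord, Report, evaluate_prediction, report
from .excerpts import Excerpt
from .ir import adjusted_ir_predict, original_ir_predict
from .prediction import Prediction
from .score_io import Melody, NoteEvent
from .synth import CorpusManifest, GeneratorConfig, generate_corpus, generate_fixture_excerpts
from .tonality import ScaleContext, resolve_context

MODEL_CHOICES = ("chm", "ir-adjusted", "ir-original")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One reproducible experiment."""

    corpus: GeneratorConfig
    model: str = "chm"
    corpus_b: Optional[GeneratorConfig] = None
    n_excerpts: Optional[int] = 20
    complete_frac: float = 0.75
    train_fraction: float = 0.8
    train_config: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_CHOICES:
            raise ValueError(f"model must be one of {MODEL_CHOICES}")


Predictor = Callable[[Excerpt], Prediction]


def make_predictor(model: str, chm_model: Optional[CHModel] = None) -> Predictor:
    """Build the excerpt -> prediction callable for a model choice."""
    if model == "chm":
        if chm_model is None:
            raise StageError("predict: the pattern model requires training first")
        return lambda excerpt: predict_chm(chm_model, excerpt)
    if model == "ir-adjusted":
        return lambda excerpt: adjusted_ir_predict(excerpt, resolve_context(excerpt.melody))
    if model == "ir-original":
        return original_ir_predict
    raise StageError(f"predict: unknown model {model!r}")


def evaluate_excerpts(excerpts: Sequence[Excerpt], predictor: Predictor) -> list[EvaluationRecord]:
    """Predict and score every excerpt."""
    records = []
    for k, excerpt in enumerate(excerpts):
        prediction = predictor(excerpt)
        context = resolve_context(excerpt.melody)
        records.append(
            evaluate_prediction(
                excerpt_id=f"{excerpt.source_id}:{k}",
                prediction=prediction,
                truth=excerpt.true_continuation,
                context=context,
                completeness=excerpt.completeness,
            )
        )
    return records


def _split_and_excerpt(
    config: GeneratorConfig,
    n_excerpts: Optional[int],
    complete_frac: float,
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[Melody], list[Excerpt], ScaleContext]:
    corpus, manifest = generate_corpus(config)
    n_train = int(len(corpus) * train_fraction)
    train = corpus[:n_train]
    held_out = corpus[n_train:] or corpus
    held_manifest = CorpusManifest(config=config, songs=manifest.songs[n_train:] or manifest.songs)
    excerpts = generate_fixture_excerpts(
        held_out, held_manifest, rng, n=n_excerpts, complete_frac=complete_frac
    )
    return train, excerpts, config.context


def run(config: RunConfig) -> dict[str, Report]:
    """Execute a run; returns reports keyed by "train-on/test-on" labels.

    With a single corpus the only key is ``"a/a"``.  Artifacts
    (predictions, reports, run log) are written under ``out_dir`` when
    given.
    """
    rng = np.random.default_rng(config.seed)
    try:
        corpora = {"a": config.corpus}
        if config.corpus_b is not None:
            corpora["b"] = config.corpus_b
        splits = {
            label: _split_and_excerpt(
                c, config.n_excerpts, config.complete_frac, config.train_fraction, rng
            )
            for label, c in corpora.items()
        }
    except Exception as exc:  # noqa: BLE001 - stage context for the caller
        raise StageError(f"simulate/excerpt: {exc}") from exc

    models: dict[str, Optional[CHModel]] = {}
    for label, (train, _, _) in splits.items():
        if config.model == "chm":
            try:
                models[label] = learn_hierarchy(train, config.train_config)
            except Exception as exc:
                raise StageError(f"train[{label}]: {exc}") from exc
        else:
            models[label] = None

    reports: dict[str, Report] = {}
    all_records: dict[str, list[EvaluationRecord]] = {}
    for train_label in splits:
        predictor = make_predictor(config.model, models[train_label])
        for test_label, (_, excerpts, context) in splits.items():
            key = f"{train_label}/{test_label}"
            try:
                records = evaluate_excerpts(excerpts, predictor)
            except Exception as exc:
                raise StageError(f"predict/evaluate[{key}]: {exc}") from exc
            all_records[key] = records
            reports[key] = report(records, context)

    if config.out_dir:
        _write_artifacts(config, all_records, reports)
    return reports


def _write_artifacts(
    config: RunConfig,
    records: dict[str, list[EvaluationRecord]],
    reports: dict[str, Report],
) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    log = {
        "seed": config.seed,
        "model": config.model,
        "corpus": {**vars(config.corpus), "motif_bank": [list(m) for m in config.corpus.motif_bank or ()]},
        "train_config": vars(config.train_config),
    }
    if config.corpus_b is not None:
        log["corpus_b"] = {**vars(config.corpus_b), "motif_bank": [list(m) for m in config.corpus_b.motif_bank or ()]}
    with open(os.path.join(config.out_dir, "run.json"), "w") as handle:
        json.dump(log, handle, indent=1, sort_keys=True)
    for key, recs in records.items():
        path = os.path.join(config.out_dir, f"records-{key.replace('/', '-')}.jsonl")
        with open(path, "w") as handle:
            for r in recs:
                handle.write(json.dumps(vars(r), sort_keys=True) + "\n")
    with open(os.path.join(config.out_dir, "report.json"), "w") as handle:
        payload = {key: json.loads(rep.to_json()) for key, rep in reports.items()}
        json.dump(payload, handle, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Excerpt dataset (de)serialisation — JSON-lines, one excerpt per line


def excerpt_to_dict(excerpt: Excerpt) -> dict:
    scale = excerpt.melody.scale_hint
    return {
        "source_id": excerpt.source_id,
        "completeness": excerpt.completeness,
        "true_continuation": excerpt.true_continuation,
        "tempo": excerpt.melody.tempo,
        "events": [[e.onset, e.pitch, e.duration] for e in excerpt.melody.events],
        "scale": None if scale is None else {"tonic": scale.tonic, "mode": scale.mode},
    }


def excerpt_from_dict(payload: dict) -> Excerpt:
    melody = Melody(
        id=payload["source_id"],
        events=[NoteEvent(onset=o, pitch=int(p), duration=d) for o, p, d in payload["events"]],
        tempo=payload.get("tempo"),
    )
    if payload.get("scale"):
        melody.scale_hint = ScaleContext(
            tonic=payload["scale"]["tonic"], mode=payload["scale"]["mode"]
        )
    return Excerpt(
        melody=melody,
        true_continuation=payload["true_continuation"],
        completeness=payload["completeness"],
        source_id=payload["source_id"],
    )


def save_excerpts(excerpts: Sequence[Excerpt], path: str) -> None:
    with open(path, "w") as handle:
        for excerpt in excerpts:
            handle.write(json.dumps(excerpt_to_dict(excerpt)) + "\n")


def load_excerpts(path: str) -> list[Excerpt]:
    out = []
    with open(path) as handle:
        for line in handle:
            if line.strip():
                out.append(excerpt_from_dict(json.loads(line)))
    return out
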