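"""Implication-Realization criteria against an independent re-implementation."""

import statistics

import pytest

from melex import IRContext, ScaleContext, adjusted_ir_predict, bottom_up_scores, extended_scores, original_ir_predict
from melex.excerpts import Excerpt
from melex.ir import ContextError, RETAINED_CRITERIA, all_criterion_scores
from melex.prediction import candidate_pitches

from conftest import make_melody


# --- independent oracle: a literal transcription of the five original
# criteria, written without reference to the package implementation -------

def _oracle_bottom_up(i, r, candidate, first_tone):
    def sgn(x):
        return 0 if x == 0 else (1 if x > 0 else -1)

    same_direction = sgn(r) == sgn(i)
    if abs(i) > 8:
        direction = 0.0 + (sgn(r) != sgn(i))
    else:
        direction = 0.0 + (same_direction or r == 0)

    ret = 0.0 + (sgn(r) != sgn(i) and abs(candidate - first_tone) <= 2)

    if abs(i) >= 5:
        allowed = 3 if same_direction else 2
        diff = 0.0 + (abs(abs(r) - abs(i)) <= allowed)
    else:
        diff = 0.0 + (abs(r) < abs(i))

    prox = float(6 - abs(r)) if abs(r) < 6 else 0.0

    clos = 0.0 + ((sgn(r) != sgn(i)) or (abs(i) - abs(r) >= 3))
    return {
        "registral_direction": direction,
        "registral_return": ret,
        "intervallic_difference": diff,
        "proximity": prox,
        "closure": clos,
    }


def test_bottom_up_exhaustive_against_oracle():
    for i in range(-12, 13):
        ctx = IRContext(pitches=(60, 60 + i))
        for r in range(-12, 13):
            candidate = 60 + i + r
            assert bottom_up_scores(ctx, candidate) == _oracle_bottom_up(i, r, candidate, 60), (i, r)


def test_bottom_up_walkthrough_small_interval():
    ctx = IRContext(pitches=(60, 62))  # i = +2
    scores = bottom_up_scores(ctx, 63)  # r = +1
    assert scores["registral_direction"] == 1
    assert scores["proximity"] == 5
    assert scores["closure"] == 0


def test_bottom_up_walkthrough_large_interval_return():
    ctx = IRContext(pitches=(60, 70))  # i = +10
    scores = bottom_up_scores(ctx, 61)  # r = -9, lands within 2 of the first tone
    assert scores["registral_return"] == 1
    assert scores["registral_direction"] == 1


def test_context_needs_two_pitches():
    with pytest.raises(ContextError):
        IRContext(pitches=(60,))


C_MAJOR = ScaleContext(tonic=0, mode="major")


def test_tonality_rating_of_tonic():
    ctx = IRContext(pitches=(64, 62), scale=C_MAJOR)
    assert extended_scores(ctx, 60)["tonality"] == pytest.approx(6.35)


def test_consonance_intervals():
    ctx = IRContext(pitches=(60, 62), scale=C_MAJOR)
    for r, expected in [(0, 1), (5, 1), (7, 1), (12, 1), (-12, 1), (1, 0), (6, 0), (11, 0)]:
        assert extended_scores(ctx, 62 + r)["consonance"] == expected


def test_tessitura_zero_at_median():
    ctx = IRContext(pitches=(60, 60, 60), scale=C_MAJOR)
    assert extended_scores(ctx, 60)["tessitura"] == 0.0
    assert extended_scores(ctx, 65)["tessitura"] < 0.0


def test_melodic_attraction_prefers_stable_near_tones():
    ctx = IRContext(pitches=(62, 59), scale=C_MAJOR)  # last tone is the leading tone
    attraction = {c: extended_scores(ctx, c)["melodic_attraction"] for c in (60, 58, 67)}
    assert attraction[60] > attraction[58]  # resolving up a semitone to the tonic
    assert attraction[60] > attraction[67]  # ... beats the distant fifth


def _toy_excerpt():
    return Excerpt(make_melody([60, 62, 64, 65, 67]), 69, "complete", "toy")


def test_adjusted_prediction_matches_spreadsheet_recomputation():
    excerpt = _toy_excerpt()
    prediction = adjusted_ir_predict(excerpt, C_MAJOR)
    pitches = (60, 62, 64, 65, 67)
    ctx = IRContext(pitches=pitches, scale=C_MAJOR)
    window = candidate_pitches(67)
    columns = {name: [] for name in RETAINED_CRITERIA}
    for candidate in window:
        scores = all_criterion_scores(ctx, candidate)
        for name in RETAINED_CRITERIA:
            columns[name].append(scores[name])
    normalised = {}
    for name, col in columns.items():
        lo, hi = min(col), max(col)
        normalised[name] = [0.5] * len(col) if hi == lo else [(v - lo) / (hi - lo) for v in col]
    expected = {
        pitch: statistics.mean(normalised[name][k] for name in RETAINED_CRITERIA)
        for k, pitch in enumerate(window)
    }
    reranked = sorted(window, key=lambda p: (-expected[p], abs(p - 67), p))
    assert list(prediction.ranking) == reranked
    for pitch in window:
        assert prediction.candidates[pitch] == pytest.approx(expected[pitch])
        assert 0.0 <= prediction.candidates[pitch] <= 1.0


@pytest.mark.parametrize("shift", [2, 5, 9])
def test_adjusted_ranking_transposition_equivariant(shift):
    base = adjusted_ir_predict(_toy_excerpt(), C_MAJOR)
    moved_excerpt = Excerpt(
        make_melody([p + shift for p in [60, 62, 64, 65, 67]]), 69 + shift, "complete", "toy",
    )
    moved = adjusted_ir_predict(moved_excerpt, ScaleContext(tonic=shift % 12, mode="major"))
    assert [p + shift for p in base.ranking] == list(moved.ranking)


def test_original_prefers_repeating_the_last_tone():
    # the unison uniquely maximises proximity, for every implicative interval
    for i in range(-12, 13):
        ctx = IRContext(pitches=(60, 60 + i))
        unison = bottom_up_scores(ctx, 60 + i)["proximity"]
        assert unison == 6
        for r in range(-12, 13):
            if r != 0:
                assert bottom_up_scores(ctx, 60 + i + r)["proximity"] < unison
    # and the original predictor puts the unison at the very top for
    # small implicative intervals
    excerpt = Excerpt(make_melody([64, 62, 64, 62, 64]), 62, "complete", "o")
    assert original_ir_predict(excerpt).top == 64


def test_extended_scores_require_scale():
    with pytest.raises(ContextError):
        extended_scores(IRContext(pitches=(60, 62)), 64)
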