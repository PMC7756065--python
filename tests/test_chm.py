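"""Relative encoding, gapped-regex matching, hierarchy learning, Eq.-1-style weights."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from melex import (
    CHModel,
    RelativePattern,
    TrainConfig,
    encode_relative,
    eq1_weight,
    learn_hierarchy,
    pattern_to_regex,
    predict_chm,
)
from melex.chm import (
    EncodingError,
    UntrainedModelError,
    gapped_match,
    iter_matches,
    offset_to_symbol,
    symbol_to_offset,
)
from melex.excerpts import Excerpt

from conftest import make_melody

TABLE_PITCHES = [64, 62, 64, 62, 64, 62, 71, 71, 71, 72, 71, 69, 74, 74, 72]


def test_encode_segment_letters():
    assert encode_relative(TABLE_PITCHES) == "0b0b0bGGGHGEJJH"
    assert encode_relative([60]) == "0"
    assert offset_to_symbol(5) == "E" and offset_to_symbol(-3) == "c"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(-26, 26), min_size=1, max_size=20))
def test_encoding_is_invertible(offsets):
    pitches = [60 + 0] + [60 + o for o in offsets]
    pitches = [p for p in pitches if 0 <= p <= 127]
    encoded = encode_relative(pitches, anchor=0)
    decoded = [symbol_to_offset(s) for s in encoded]
    assert decoded == [p - pitches[0] for p in pitches]


def test_encode_out_of_range():
    with pytest.raises(EncodingError):
        encode_relative([60, 90])


def test_pattern_regex_form():
    assert pattern_to_regex(RelativePattern((0, 5, -3, 0))) == "0[0a-zA-Z]*E[0a-zA-Z]*c[0a-zA-Z]*0"
    assert pattern_to_regex(RelativePattern((0, 1))) == "0[0a-zA-Z]*A"


def test_pattern_matches_own_gap_free_encoding():
    for offsets in [(0, 5, -3, 0), (0, 1), (0, -2, 4, 4, -7)]:
        pattern = RelativePattern(offsets)
        assert gapped_match(pattern.symbols, pattern.symbols)


@pytest.mark.parametrize(
    "n_events, segment, start, expected",
    [
        (32, 32, 0, 32 / 33),
        (4, 20, 0, 4 / 21),
        (8, 16, 6, 8 / 11),
        (4, 16, 11, 4 / 6),
        (4, 16, 0, 4 / 17),
    ],
)
def test_eq1_weight_worked_examples(n_events, segment, start, expected):
    assert eq1_weight(n_events, segment, start) == pytest.approx(expected)


def test_eq1_weight_monotonicity():
    # longer patterns weigh more; matches nearer the end weigh more;
    # longer segments dilute the weight
    assert eq1_weight(5, 16, 4) > eq1_weight(4, 16, 4)
    assert eq1_weight(4, 16, 6) > eq1_weight(4, 16, 4)
    assert eq1_weight(4, 20, 4) < eq1_weight(4, 16, 4)


def test_eq1_weight_domain_errors():
    with pytest.raises(ValueError):
        eq1_weight(0, 10, 0)
    with pytest.raises(ValueError):
        eq1_weight(4, 10, 10)


def _brute_gapped(pattern: str, text: str) -> bool:
    """Enumerate all increasing index assignments, anchored at position 0."""
    if not pattern:
        return True
    if not text or text[0] != pattern[0]:
        return False
    positions = [range(1) if k == 0 else range(1, len(text)) for k in range(len(pattern))]
    for assignment in itertools.product(*positions):
        if all(a < b for a, b in zip(assignment, assignment[1:])) and all(
            text[i] == s for i, s in zip(assignment, pattern)
        ):
            return True
    return False


def test_regex_matcher_equals_brute_force_small_alphabet():
    alphabet = "0Ab"
    patterns = [
        "".join(p)
        for length in (1, 2, 3)
        for p in itertools.product(alphabet, repeat=length)
    ]
    texts = [
        "".join(t)
        for length in range(0, 6)
        for t in itertools.product(alphabet, repeat=length)
    ]
    for pattern in patterns:
        for text in texts:
            assert gapped_match(pattern, text) == _brute_gapped(pattern, text), (pattern, text)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.text(alphabet="0ABCabc", min_size=1, max_size=4),
    st.text(alphabet="0ABCabc", min_size=0, max_size=10),
)
def test_regex_matcher_equals_brute_force_random(pattern, text):
    assert gapped_match(pattern, text) == _brute_gapped(pattern, text)


def _copies(pitches, n, melody_id="motif"):
    return [make_melody(pitches, melody_id=f"{melody_id}{k}") for k in range(n)]


def test_learn_recovers_planted_motif_with_support():
    corpus = _copies([60, 65, 57, 60], 10)
    model = learn_hierarchy(corpus, TrainConfig(min_support=3))
    by_shape = {p.offsets: p for p in model.patterns}
    assert (0, 5, -3, 0) in by_shape
    assert by_shape[(0, 5, -3, 0)].support == 10


def test_learn_nothing_from_unrepeated_intervals():
    # pairwise offsets within the gap window are all distinct, so no
    # composition reaches support 2
    corpus = [make_melody([60, 61, 63, 67, 75])]
    model = learn_hierarchy(corpus, TrainConfig(min_support=2))
    assert model.patterns == []


def test_learn_rejects_bad_inputs():
    with pytest.raises(ValueError):
        learn_hierarchy([])
    with pytest.raises(ValueError):
        TrainConfig(min_support=1)


def _excerpt(pitches):
    return Excerpt(make_melody(pitches), 60, "complete", "t")


def test_predict_table_style_weight():
    model = CHModel(patterns=[RelativePattern((0, 0, 0, 4), support=5, layer=3)], config=TrainConfig())
    prediction = predict_chm(model, _excerpt(TABLE_PITCHES))
    # anchor 0 realises the three repeated tones with gaps; the predicted
    # pitch is 64 + 4 = 68 with weight 4/(16 - 0 + 1)
    assert prediction.candidates[68] == pytest.approx(4 / 17)


def test_predict_no_match_scores_zero_with_tie_break():
    model = CHModel(patterns=[RelativePattern((0, 25, 25, 25))], config=TrainConfig())
    prediction = predict_chm(model, _excerpt([60, 62, 64]))
    assert all(v == 0.0 for v in prediction.candidates.values())
    assert prediction.top == 64  # unison first under the documented tie-break
    assert list(prediction.ranking[:3]) == [64, 63, 65]


def test_predict_requires_trained_model():
    with pytest.raises(UntrainedModelError):
        predict_chm(None, _excerpt([60, 62]))


def test_planted_motif_continuation_ranked_first():
    motif = [62, 67, 64, 62, 59, 62]
    corpus = _copies(motif, 8)
    model = learn_hierarchy(corpus, TrainConfig(min_support=3))
    excerpt = _excerpt(motif[:-1])
    prediction = predict_chm(model, excerpt)
    assert prediction.top == motif[-1]


@pytest.mark.parametrize("shift", [-5, 3, 7])
def test_pattern_learning_and_prediction_transposition_invariant(shift):
    corpus = _copies([60, 65, 57, 60], 6) + _copies([62, 64, 66, 62], 6, "b")
    excerpt_pitches = [60, 65, 57]
    base_model = learn_hierarchy(corpus)
    moved_model = learn_hierarchy([m.transposed(shift) for m in corpus])
    assert {(p.offsets, p.support) for p in base_model.patterns} == {
        (p.offsets, p.support) for p in moved_model.patterns
    }
    base = predict_chm(base_model, _excerpt(excerpt_pitches))
    moved = predict_chm(moved_model, _excerpt([p + shift for p in excerpt_pitches]))
    assert [p + shift for p in base.ranking] == list(moved.ranking)
    assert base.candidates[60] == moved.candidates[60 + shift]


def test_model_json_round_trip():
    corpus = _copies([60, 65, 57, 60], 5)
    model = learn_hierarchy(corpus)
    restored = CHModel.from_json(model.to_json())
    assert [(p.offsets, p.support, p.layer) for p in restored.patterns] == [
        (p.offsets, p.support, p.layer) for p in model.patterns
    ]
    assert vars(restored.config) == vars(model.config)


def test_iter_matches_reports_anchor_and_weight():
    model = CHModel(patterns=[RelativePattern((0, -2, 0))], config=TrainConfig())
    pitches = [64, 62, 64, 62]
    matches = list(iter_matches(model, pitches))
    assert matches, "pattern should match"
    for _, anchor, predicted, weight in matches:
        assert weight == pytest.approx(eq1_weight(3, 5, anchor))
        assert predicted == pitches[anchor]
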