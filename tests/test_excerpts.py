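"""Excerpt cutting, balance criteria and the two-standard-deviation filter."""

import numpy as np
import pytest
from scipy import stats

from melex import assemble_dataset, cut_complete, cut_incomplete, excerpt_criteria, filter_two_sd
from melex.excerpts import CompositionError, Excerpt, ExcerptCriteria, InsufficientDataError, TooShortError

from conftest import make_melody


def test_cut_complete_keeps_prefix_and_target():
    melody = make_melody(list(range(60, 70)))  # 10 events
    excerpt = cut_complete(melody, phrase_end=9)
    assert len(excerpt.melody) == 9
    assert excerpt.true_continuation == melody.events[9].pitch
    assert excerpt.completeness == "complete"


def test_cut_complete_too_short():
    with pytest.raises(TooShortError):
        cut_complete(make_melody([60, 62, 64]), phrase_end=1)


def test_cut_complete_matches_generator_manifest(major_corpus):
    _, corpus, manifest = major_corpus
    for melody, entry in list(zip(corpus, manifest.songs))[:10]:
        end = entry.phrase_ends[-1]
        excerpt = cut_complete(melody, end)
        assert excerpt.true_continuation == melody.pitches[end]
        assert excerpt.melody.pitches == melody.pitches[:end]


def test_cut_incomplete_deterministic_and_avoids_phrase_ends():
    melody = make_melody(list(range(50, 70)), phrase_ends=[9, 19])
    first = cut_incomplete(melody, np.random.default_rng(7))
    second = cut_incomplete(melody, np.random.default_rng(7))
    assert first.melody.pitches == second.melody.pitches
    assert len(first.melody) not in (9, 19)
    assert first.completeness == "incomplete"


def test_cut_incomplete_single_legal_position():
    # length min_len + 2 with the only phrase end at the last event leaves
    # exactly one legal cut, returned for any seed
    melody = make_melody(list(range(60, 67)))  # 7 events, min_len 5
    for seed in (0, 1, 99):
        excerpt = cut_incomplete(melody, np.random.default_rng(seed), min_len=5)
        assert len(excerpt.melody) == 5


def test_cut_incomplete_uniform_over_legal_positions():
    melody = make_melody(list(range(50, 70)))  # phrase end 19; legal cuts 5..18
    counts = {}
    rng = np.random.default_rng(123)
    for _ in range(1000):
        cut = len(cut_incomplete(melody, rng).melody)
        counts[cut] = counts.get(cut, 0) + 1
    observed = [counts.get(c, 0) for c in range(5, 19)]
    assert stats.chisquare(observed).pvalue > 0.01


@pytest.mark.parametrize(
    "pitches, largest, tonal_range",
    [([60, 72], 12, 12), ([60, 60, 60], 0, 0), ([60, 65, 62, 58], 5, 7)],
)
def test_excerpt_criteria_examples(pitches, largest, tonal_range):
    excerpt = Excerpt(make_melody(pitches), 60, "complete", "x")
    crit = excerpt_criteria(excerpt)
    assert (crit.n_events, crit.largest_interval, crit.tonal_range) == (
        len(pitches), largest, tonal_range,
    )


def test_excerpt_criteria_against_pairwise_scan(rng):
    pitches = list(rng.integers(55, 80, size=15))
    excerpt = Excerpt(make_melody(pitches), 60, "incomplete", "x")
    crit = excerpt_criteria(excerpt)
    assert crit.largest_interval == max(abs(pitches[i + 1] - pitches[i]) for i in range(14))
    assert crit.tonal_range == max(pitches) - min(pitches)
    assert crit.duration == excerpt.melody.duration_beats() * 60 / 100.0


def test_criteria_invariant_violation():
    with pytest.raises(ValueError):
        ExcerptCriteria(n_events=3, largest_interval=10, tonal_range=5, duration=1.0)


def test_filter_two_sd_identical_all_retained():
    crits = [ExcerptCriteria(10, 4, 8, 9.0)] * 6
    assert filter_two_sd(crits) == list(range(6))


def test_filter_two_sd_drops_extreme_outlier():
    crits = [ExcerptCriteria(10 + (i % 3), 4, 8, 9.0) for i in range(20)]
    crits.append(ExcerptCriteria(200, 4, 8, 9.0))
    kept = filter_two_sd(crits)
    assert 20 not in kept
    assert set(kept) == set(range(20))


def test_filter_two_sd_matches_brute_force(rng):
    crits = [
        ExcerptCriteria(int(rng.integers(5, 25)), int(rng.integers(0, 8)),
                        int(rng.integers(8, 20)), float(rng.uniform(5, 20)))
        for _ in range(30)
    ]
    matrix = np.array([[c.n_events, c.largest_interval, c.tonal_range, c.duration] for c in crits])
    mean, sd = matrix.mean(0), matrix.std(0)
    expected = [
        i for i in range(30)
        if all(mean[j] - 2 * sd[j] <= matrix[i, j] <= mean[j] + 2 * sd[j] for j in range(4))
    ]
    assert filter_two_sd(crits) == expected


def test_filter_two_sd_insufficient():
    with pytest.raises(InsufficientDataError):
        filter_two_sd([ExcerptCriteria(10, 4, 8, 9.0)])


def _pool(n_complete, n_incomplete):
    pool = []
    for k in range(n_complete):
        pool.append(Excerpt(make_melody([60, 62, 64]), 65, "complete", f"c{k}"))
    for k in range(n_incomplete):
        pool.append(Excerpt(make_melody([60, 62, 64]), 65, "incomplete", f"i{k}"))
    return pool


def test_assemble_dataset_mix_and_determinism():
    pool = _pool(30, 10)
    chosen = assemble_dataset(pool, 20, 0.75, np.random.default_rng(5))
    assert sum(e.completeness == "complete" for e in chosen) == 15
    again = assemble_dataset(pool, 20, 0.75, np.random.default_rng(5))
    assert [e.source_id for e in chosen] == [e.source_id for e in again]
    all_complete = assemble_dataset(pool, 4, 1.0, np.random.default_rng(5))
    assert all(e.completeness == "complete" for e in all_complete)


def test_assemble_dataset_deficit_reported():
    with pytest.raises(CompositionError, match="incomplete"):
        assemble_dataset(_pool(30, 1), 20, 0.75, np.random.default_rng(0))
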