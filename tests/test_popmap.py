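import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cctopo.popmap import (DetectabilityCriteria, PASSAGE_FIELD, UNDETECTABLE,
                           WIDESPREAD_WEAK, ThresholdScheme,
                           binarize_at_threshold, classify_detectability,
                           normalize_streamlines, population_average,
                           roi_mean_profile)

from conftest import counts_from_array, flat_grid, nm_from_values


# --------------------------------------------------------------------- #
# normalization (Eq. 1 behaviour)


def test_normalize_simple_row():
    grid = flat_grid(2)
    counts = np.array([[3, 1, 0], [0, 0, 0]])
    nm = normalize_streamlines(counts_from_array(grid, counts))
    assert np.allclose(nm.values[0], [0.75, 0.25, 0.0])
    assert np.array_equal(nm.values[1], [0.0, 0.0, 0.0])
    assert list(nm.zero_total_flags) == [False, True]


def test_normalize_matches_bruteforce(rng):
    grid = flat_grid(50)
    counts = rng.integers(0, 20, size=(50, 10))
    nm = normalize_streamlines(counts_from_array(grid, counts))
    for i in range(50):
        total = counts[i].sum()
        for j in range(10):
            want = 0.0 if total == 0 else counts[i, j] / total
            assert abs(nm.values[i, j] - want) < 1e-15


def test_negative_counts_rejected():
    grid = flat_grid(2)
    with pytest.raises(ValueError, match="negative"):
        counts_from_array(grid, np.array([[1, -1], [0, 0]]))


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=50, deadline=None)
def test_normalization_conservation_property(seed):
    rng = np.random.default_rng(seed)
    grid = flat_grid(20)
    counts = rng.integers(0, 8, size=(20, 6))
    nm = normalize_streamlines(counts_from_array(grid, counts))
    sums = nm.values.sum(axis=1)
    assert np.all(np.abs(sums[~nm.zero_total_flags] - 1.0) < 1e-12)
    assert np.all(sums[nm.zero_total_flags] == 0.0)


# --------------------------------------------------------------------- #
# thresholding (Eq. 2 behaviour)


def test_threshold_scheme_defaults_exact():
    scheme = ThresholdScheme()
    assert scheme.milli == (100, 125, 150, 175, 200)
    assert np.allclose(scheme.values, [0.100, 0.125, 0.150, 0.175, 0.200])


def test_threshold_scheme_validation():
    with pytest.raises(ValueError):
        ThresholdScheme((200, 100))
    with pytest.raises(ValueError):
        ThresholdScheme((0,))
    with pytest.raises(ValueError):
        ThresholdScheme(())
    assert ThresholdScheme.from_values([0.1, 0.2]).milli == (100, 200)


def test_binarize_strict_inequality():
    grid = flat_grid(2)
    nm = nm_from_values(grid, np.array([[0.11, 0.89], [0.150, 0.850]]))
    assert binarize_at_threshold(nm, 0.100)[0, 0] == 1
    assert binarize_at_threshold(nm, 0.150)[1, 0] == 0  # equality maps to 0


def test_binarize_matches_elementwise_oracle(rng):
    grid = flat_grid(30)
    vals = rng.random((30, 4))
    nm = nm_from_values(grid, vals)
    for thr in (0.1, 0.125, 0.5, 0.9):
        got = binarize_at_threshold(nm, thr)
        for i in range(30):
            for j in range(4):
                assert got[i, j] == (1 if vals[i, j] > thr else 0)


def test_binarize_rejects_bad_threshold():
    grid = flat_grid(2)
    nm = nm_from_values(grid, np.zeros((2, 1)))
    for thr in (0.0, 1.0, -0.2):
        with pytest.raises(ValueError):
            binarize_at_threshold(nm, thr)


# --------------------------------------------------------------------- #
# population average (Eq. 3 behaviour)


def test_population_average_single_sample_printed_thresholds():
    grid = flat_grid(2)
    nm = nm_from_values(grid, np.full((2, 1), 0.12))
    pop = population_average([nm])
    # 0.12 exceeds only threshold 0.100 -> 1 of 5 thresholds
    assert np.allclose(pop.values, 0.2)


def test_population_average_all_zero():
    grid = flat_grid(2)
    pop = population_average([nm_from_values(grid, np.zeros((2, 3)))])
    assert np.all(pop.values == 0.0)


def test_population_average_saturated():
    grid = flat_grid(2)
    samples = [nm_from_values(grid, np.full((2, 2), 0.5), subject=f"s{i}")
               for i in range(4)]
    pop = population_average(samples)
    assert np.all(pop.values == 1.0)


def test_population_average_exceedance_oracle(rng):
    grid = flat_grid(20)
    scheme = ThresholdScheme()
    samples = [nm_from_values(grid, rng.random((20, 5)), subject=f"s{i}")
               for i in range(10)]
    pop = population_average(samples, scheme)
    thr = scheme.values
    for v in range(20):
        for a in range(5):
            hits = sum(1 for s in samples for t in thr if s.values[v, a] > t)
            assert pop.values[v, a] == pytest.approx(hits / (10 * len(thr)))


def test_threshold_monotonicity(rng):
    grid = flat_grid(20)
    nm = nm_from_values(grid, rng.random((20, 5)))
    prev = None
    for thr in ThresholdScheme().values:
        cur = binarize_at_threshold(nm, thr)
        if prev is not None:
            assert np.all(prev >= cur)
        prev = cur


def test_population_average_permutation_invariant(rng):
    grid = flat_grid(20)
    samples = [nm_from_values(grid, rng.random((20, 5)), subject=f"s{i}")
               for i in range(8)]
    pop1 = population_average(samples)
    shuffled = list(samples)
    rng.shuffle(shuffled)
    pop2 = population_average(shuffled)
    assert np.array_equal(pop1.values, pop2.values)


def test_population_average_rational_support(rng):
    grid = flat_grid(20)
    samples = [nm_from_values(grid, rng.random((20, 3)), subject=f"s{i}")
               for i in range(7)]
    pop = population_average(samples)
    scaled = pop.values * pop.n_samples * len(pop.scheme)
    assert np.all(np.abs(scaled - np.rint(scaled)) < 1e-9)


def test_population_average_subject_mode():
    grid = flat_grid(2)
    # subject A: two scans (0.12 and 0.3); subject B: one scan (0.3)
    samples = [nm_from_values(grid, np.full((2, 1), 0.12), subject="A"),
               nm_from_values(grid, np.full((2, 1), 0.30), subject="A"),
               nm_from_values(grid, np.full((2, 1), 0.30), subject="B")]
    pop = population_average(samples, sample_unit="subject")
    # per scan: 0.12 -> 1/5, 0.30 -> 5/5; A averages to 0.6, B is 1.0
    assert pop.n_samples == 2
    assert np.allclose(pop.values, (0.6 + 1.0) / 2)


def test_population_average_validation(rng):
    grid = flat_grid(4)
    nm = nm_from_values(grid, rng.random((4, 2)))
    with pytest.raises(ValueError):
        population_average([])
    other = nm_from_values(flat_grid(6), rng.random((6, 2)))
    with pytest.raises(ValueError, match="grid"):
        population_average([nm, other])
    wrong_side = nm_from_values(grid, rng.random((4, 2)), side="right")
    with pytest.raises(ValueError, match="hemisphere"):
        population_average([nm, wrong_side])


# --------------------------------------------------------------------- #
# ROI profiles and detectability


def test_roi_mean_profile_constant_map():
    grid = flat_grid(4)
    pop = population_average([nm_from_values(grid, np.full((4, 2), 0.5))])
    prof = roi_mean_profile(pop, {"a0": 10, "a1": 4})
    assert prof.loc[0, "mean_p"] == pytest.approx(1.0)
    assert prof.loc[0, "size_normalized_mean"] == pytest.approx(0.1)


def test_roi_mean_profile_zero_map():
    grid = flat_grid(4)
    pop = population_average([nm_from_values(grid, np.zeros((4, 1)))])
    prof = roi_mean_profile(pop, {"a0": 3})
    assert prof.loc[0, "mean_p"] == 0.0


def test_roi_mean_profile_matches_bruteforce(rng):
    grid = flat_grid(20)
    pop = population_average(
        [nm_from_values(grid, rng.random((20, 3)), subject=f"s{i}")
         for i in range(5)])
    prof = roi_mean_profile(pop, {"a0": 2, "a1": 3, "a2": 7})
    for j, size in enumerate((2, 3, 7)):
        brute = sum(pop.values[v, j] for v in range(20)) / 20
        assert abs(prof.loc[j, "mean_p"] - brute) < 1e-12
        assert abs(prof.loc[j, "size_normalized_mean"] - brute / size) < 1e-12


def test_roi_mean_profile_missing_size_rejected(rng):
    grid = flat_grid(4)
    pop = population_average([nm_from_values(grid, rng.random((4, 2)))])
    with pytest.raises(ValueError, match="missing"):
        roi_mean_profile(pop, {"a0": 5})


def _pop_with_column(col):
    grid = flat_grid(len(col))
    vals = np.asarray(col, dtype=float)[:, None]
    pop = population_average([nm_from_values(grid, np.zeros((len(col), 1)))])
    pop.values = vals
    return pop


def test_detectability_passage_field():
    pop = _pop_with_column([0.30, 0.0, 0.0, 0.0])
    out = classify_detectability(pop)
    assert out.loc[0, "class"] == PASSAGE_FIELD


def test_detectability_undetectable():
    out = classify_detectability(_pop_with_column([0.0, 0.0]))
    assert out.loc[0, "class"] == UNDETECTABLE


def test_detectability_widespread_weak():
    out = classify_detectability(_pop_with_column([0.02, 0.05, 0.02, 0.01, 0.0, 0.02]))
    # mean 0.02 > 0.01 and max 0.05 < 0.08
    assert out.loc[0, "class"] == WIDESPREAD_WEAK
    assert out.loc[0, "peak_high"] == 0.15


def test_roi_mean_sem_both_variants():
    grid = flat_grid(4)
    # subject A: two scans with per-scan means 0.2 and 1.0; subject B: one 1.0
    samples = [nm_from_values(grid, np.full((4, 1), 0.12), subject="A"),
               nm_from_values(grid, np.full((4, 1), 0.30), subject="A"),
               nm_from_values(grid, np.full((4, 1), 0.30), subject="B")]
    from cctopo.popmap import roi_mean_sem
    out = roi_mean_sem(samples)
    scan_means = np.array([0.2, 1.0, 1.0])
    subj_means = np.array([0.6, 1.0])
    assert out.loc[0, "mean_p"] == pytest.approx(scan_means.mean())
    assert out.loc[0, "sem_scans"] == pytest.approx(
        scan_means.std(ddof=1) / np.sqrt(3))
    assert out.loc[0, "sem_subjects"] == pytest.approx(
        subj_means.std(ddof=1) / np.sqrt(2))


def test_detectability_criteria_validation():
    with pytest.raises(ValueError):
        DetectabilityCriteria(peak_high=0.05, peak_low=0.08)
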