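"""Transition counting, peak detection, shift analysis, Fisher test."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from huecat import borders as bd
from huecat.colorspace import circular_distance, make_uniform_bands


def brute_mode(column):
    counts = Counter(column)
    best = max(counts.values())
    return min(k for k, v in counts.items() if v == best)


def brute_transitions(row):
    n = len(row)
    return sorted(e for e in range(n) if row[e] != row[(e - 1) % n])


def brute_optimal_shift(row_a, row_b, centers, period):
    n = len(row_a)
    ax = np.cos(2 * np.pi * centers[row_a])
    ay = np.sin(2 * np.pi * centers[row_a])
    bx = np.cos(2 * np.pi * centers[row_b])
    by = np.sin(2 * np.pi * centers[row_b])
    best = -np.inf
    cands = []
    for lag in range(n):
        c = sum(ax[i] * bx[(i + lag) % n] + ay[i] * by[(i + lag) % n] for i in range(n))
        if c > best + 1e-9:
            best, cands = c, [lag]
        elif abs(c - best) <= 1e-9:
            cands.append(lag)
    folded = [bd.fold_lag(l, period) for l in cands]
    return sorted(folded, key=lambda s: (abs(s), s))[0]


class TestModes:
    def test_constant_and_tie_examples(self):
        assert bd.column_mode([3] * 60) == 3
        assert bd.column_mode([1] * 30 + [4] * 30) == 1  # tie -> lowest index

    def test_matches_counting_oracle(self, rng):
        for _ in range(50):
            col = rng.integers(0, 5, size=rng.integers(1, 40))
            assert bd.column_mode(col) == brute_mode(col.tolist())

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            bd.column_mode([])


class TestTransitions:
    def test_constant_row_has_none(self):
        assert len(bd.find_transitions([2] * 100)) == 0

    def test_two_block_row_closes_circle(self):
        row = [0] * 50 + [1] * 50
        assert list(bd.find_transitions(row)) == [0, 50]

    def test_never_exactly_one_transition_exhaustive(self):
        # circular sequences change class an even-or-zero... at least twice:
        # enumerate every 3-bin row over a 3-letter alphabet
        for row in itertools.product(range(3), repeat=3):
            assert len(bd.find_transitions(list(row))) != 1

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            row = rng.integers(0, 4, size=20)
            assert list(bd.find_transitions(row)) == brute_transitions(row.tolist())


class TestAccumulation:
    def test_identical_two_class_rows(self):
        rows = [np.array([0] * 30 + [1] * 70)] * 10
        tc = bd.accumulate_transition_counts(rows)
        assert tc.raw[0] == 10 and tc.raw[30] == 10
        assert tc.raw.sum() == 20

    def test_count_conservation(self, rng):
        rows = [rng.integers(0, 3, size=50) for _ in range(20)]
        tc = bd.accumulate_transition_counts(rows)
        assert tc.raw.sum() == sum(len(bd.find_transitions(r)) for r in rows)

    def test_smoothing_preserves_mass(self, rng):
        tc = bd.TransitionCount(raw=rng.integers(0, 20, 100), sigma=1.5)
        assert tc.smoothed.sum() == pytest.approx(tc.raw.sum(), abs=1e-9)

    def test_mixed_bin_counts_rejected(self):
        with pytest.raises(ValueError):
            bd.accumulate_transition_counts([np.zeros(10, int), np.zeros(12, int)])


class TestPeakDetection:
    def test_single_triangular_bump(self):
        raw = np.zeros(100, int)
        raw[40:51] = [1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1]
        est = bd.detect_peaks(bd.TransitionCount(raw))
        assert est.n_borders == 1
        assert est.edge_indices[0] == 45

    def test_seven_separated_bumps(self, rng):
        raw = np.zeros(100, int)
        apexes = [3, 16, 30, 45, 60, 75, 90]
        for a in apexes:
            for off, v in zip((-2, -1, 0, 1, 2), (1, 4, 9, 4, 1)):
                raw[(a + off) % 100] += v
        est = bd.detect_peaks(bd.TransitionCount(raw))
        assert est.n_borders == 7
        assert np.array_equal(est.edge_indices, apexes)

    def test_bump_across_the_wrap_point(self):
        raw = np.zeros(100, int)
        for off, v in zip((-2, -1, 0, 1, 2), (1, 4, 9, 4, 1)):
            raw[off % 100] += v
        est = bd.detect_peaks(bd.TransitionCount(raw))
        assert est.n_borders == 1 and est.edge_indices[0] == 0

    def test_flat_signal_yields_nothing(self):
        assert bd.detect_peaks(bd.TransitionCount(np.full(100, 5))).n_borders == 0
        assert bd.detect_peaks(bd.TransitionCount(np.zeros(100, int))).n_borders == 0


class TestPrototypes:
    def test_uniform_weights_give_interval_midpoint(self):
        tc = bd.TransitionCount(np.full(100, 3))
        est = bd.BorderEstimate(positions=np.array([0.2, 0.4]), n_bins=100)
        protos = bd.compute_prototypes(est, tc)
        assert protos.prototype[0] == pytest.approx(0.3, abs=1e-6)
        assert circular_distance(protos.prototype[1], 0.8) < 1e-6

    def test_wrap_category_matches_resultant_oracle(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 10, 100)
        tc = bd.TransitionCount(raw)
        est = bd.BorderEstimate(positions=np.array([0.9, 0.1]), n_bins=100)
        protos = bd.compute_prototypes(est, tc)
        centers = (np.arange(100) + 0.5) / 100
        member = (centers >= 0.9) | (centers < 0.1)
        w = 1.0 / (raw[member] + 1.0)
        ang = 2 * np.pi * centers[member]
        expect = (np.arctan2((w * np.sin(ang)).sum(), (w * np.cos(ang)).sum())
                  / (2 * np.pi)) % 1.0
        wrap_idx = int(np.argwhere(np.isclose(protos.left, 0.9))[0, 0])
        assert circular_distance(protos.prototype[wrap_idx], expect) < 1e-9

    def test_edge_heavy_counts_pull_prototype_inward(self):
        # raising the transition count near both borders should push the
        # prototype toward the interval midpoint relative to a lopsided start
        raw = np.ones(100, int)
        raw[20:25] = 50  # heavy counts just inside the left border
        est = bd.BorderEstimate(positions=np.array([0.2, 0.4]), n_bins=100)
        lop = bd.compute_prototypes(est, bd.TransitionCount(raw)).prototype[0]
        assert lop > 0.3  # pushed right, away from the down-weighted left edge

    def test_prototype_lies_inside_its_category(self, rng):
        raw = rng.integers(0, 30, 100)
        est = bd.BorderEstimate(positions=np.array([0.1, 0.35, 0.7]), n_bins=100)
        protos = bd.compute_prototypes(est, bd.TransitionCount(raw))
        for left, right, p in zip(protos.left, protos.right, protos.prototype):
            assert (p - left) % 1.0 < (right - left) % 1.0


class TestShiftAnalysis:
    def test_unit_circle_coordinates(self):
        bands = make_uniform_bands(4, 0.0)
        x, y = bd.row_to_unit_circle(np.zeros(10, int), bands)
        assert np.allclose(x, 1.0) and np.allclose(y, 0.0, atol=1e-12)
        x, y = bd.row_to_unit_circle(np.array([0, 1, 2, 3]), bands)
        assert np.allclose(x**2 + y**2, 1.0)

    def test_self_shift_is_zero(self, rng):
        bands = make_uniform_bands(7, 0.0)
        row = rng.integers(0, 7, 100)
        assert bd.optimal_circular_shift(row, row, bands) == 0

    def test_rotation_recovers_lag(self):
        bands = make_uniform_bands(7, 0.0)
        row = np.repeat(np.arange(7), 15)[:100]
        rotated = np.roll(row, 3)
        assert bd.optimal_circular_shift(row, rotated, bands) == 3

    def test_folding_arithmetic(self):
        assert bd.fold_lag(10, 14) == -4
        assert bd.fold_lag(7, 14) == 7
        assert bd.fold_lag(8, 14) == -6
        assert bd.fold_lag(95, 14) == -3  # 95 mod 14 = 11 -> -3

    def test_matches_brute_force_oracle(self, rng):
        bands = make_uniform_bands(5, 0.0)
        period = round(40 / 5)
        for _ in range(15):
            a = np.repeat(rng.integers(0, 5, 8), 5)
            b = np.roll(a, rng.integers(0, 40))
            got = bd.optimal_circular_shift(a, b, bands)
            want = brute_optimal_shift(a, b, bands.centers, period)
            assert got == want

    def test_identical_rows_have_all_mass_at_zero(self):
        bands = make_uniform_bands(7, 0.0)
        row = np.repeat(np.arange(7), 15)[:100]
        hist = bd.shift_distribution([row] * 5, bands)
        assert hist.frac_within(0) == 1.0
        assert hist.signed_counts().sum() == 10  # C(5,2) pairs


class TestFisher:
    def test_identical_columns_p_one(self):
        res = bd.fisher_exact_table([5, 1], [5, 1])
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_against_scipy(self):
        res = bd.fisher_exact_table([5, 1], [1, 5])
        want = stats.fisher_exact([[5, 1], [1, 5]])[1]
        assert res.p_value == pytest.approx(want, rel=1e-9)
        assert res.p_value == pytest.approx(0.0801, abs=5e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monte_carlo_agrees_with_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, 4)
        b = rng.integers(0, 8, 4)
        if a.sum() == 0 or b.sum() == 0:
            a[0] += 1
            b[0] += 1
        exact = bd.fisher_exact_table(a, b).p_value
        mc = bd.fisher_exact_table(a, b, enumeration_cap=0, n_mc=20000,
                                   rng=np.random.default_rng(99))
        se = max(mc.se, 1e-3)
        assert abs(mc.p_value - exact) < 3 * se + 0.01

    def test_three_way_table_supported(self):
        res = bd.fisher_exact_table([4, 0], [0, 4], [2, 2])
        assert 0 <= res.p_value <= 1
        assert res.method == "enumeration"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            bd.fisher_exact_table([1, -2], [3, 4])
        with pytest.raises(ValueError):
            bd.fisher_exact_table([1.5, 2.0], [3, 4])


class TestOverlap:
    def test_extremes(self):
        assert bd.distribution_overlap([1, 2, 3], [1, 2, 3]) == pytest.approx(100.0)
        assert bd.distribution_overlap([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert bd.distribution_overlap([0.5, 0.5], [0.8, 0.2]) == pytest.approx(70.0)

    def test_mismatched_support_rejected(self):
        with pytest.raises(ValueError):
            bd.distribution_overlap([1, 2], [1, 2, 3])
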