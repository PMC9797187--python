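"""Generalization experiments and the psychophysics analysis."""

import numpy as np
import pytest

from huecat import experiments as ex
from huecat import probes as pr
from huecat.colorspace import bin_centers, circular_distance
from huecat.probes import ResponderModel, category_of


class TestPlace14Bands:
    def test_uniform_category_arithmetic(self):
        borders = np.arange(7) / 7
        bands = ex.place_14_bands(borders)
        assert len(bands) == 14
        assert bands[0].center == pytest.approx(1 / 28)
        assert bands[1].center == pytest.approx(3 / 28)
        assert bands[0].width == pytest.approx(1 / 35)

    def test_disjoint_for_random_borders(self, rng):
        for _ in range(10):
            pos = np.sort(rng.uniform(0, 1, 7))
            if ((np.roll(pos, -1) - pos) % 1.0).min() < 0.02:
                continue
            bands = ex.place_14_bands(pos)
            probe = rng.uniform(0, 1, 3000)
            member = np.stack([b.contains(probe) for b in bands])
            assert member.sum(axis=0).max() <= 1


class TestWithinCategoryCurve:
    def test_categorical_responder_error_peaks_at_borders(self, planted_borders):
        model = ResponderModel("categorical", planted_borders, 0.02)
        curve = ex.within_category_error_curve(model, planted_borders,
                                               n_repetitions=3, seed=1)
        mean = curve.mean.mean(axis=0)  # over categories, per step
        assert np.all((curve.errors >= 0) & (curve.errors <= 1))
        assert curve.errors.shape == (7, 10, 3)
        # steps on the borders misclassify about half their band; interior
        # steps only at the noise level
        assert mean[0] > 0.3 and mean[-1] > 0.3
        assert mean[1:-1].max() < 0.15
        interior = mean[3:7].mean()
        assert interior < mean[0] and interior < mean[-1]


class TestObjectExperiment:
    @pytest.fixture(scope="class")
    def results(self, planted_borders):
        color_only = ex.object_color_experiment(
            pr.ForegroundMeanColor(), planted_borders, n_permutations=2,
            n_train_per_class=30, n_val_per_class=8, n_eval_outlines=6,
            n_bins=25, seed=0,
        )
        shape_color = ex.object_color_experiment(
            pr.DownsampleExtractor(), planted_borders, n_permutations=2,
            n_train_per_class=30, n_val_per_class=8, n_eval_outlines=6,
            n_bins=25, seed=0,
        )
        return color_only, shape_color

    @staticmethod
    def _home_away(res, planted):
        centers = bin_centers(res.median.shape[1])
        cats = category_of(centers, planted)
        home_acc, away_acc = [], []
        for cls in range(14):
            home = cats == int(category_of(res.bands[cls].center, planted))
            home_acc.append(res.median[cls][home].mean())
            away_acc.append(res.median[cls][~home].mean())
        return float(np.mean(home_acc)), float(np.mean(away_acc))

    def test_color_only_splits_the_home_category(self, results, planted_borders):
        # two classes share each category: a purely chromatic code cannot
        # exceed ~50% inside the home category and ~0 outside it
        color_only, _ = results
        home, away = self._home_away(color_only, planted_borders)
        assert 0.25 <= home <= 0.62
        assert away < 0.12

    def test_shape_features_beat_the_color_ceiling(self, results, planted_borders):
        color_only, shape_color = results
        home_c, _ = self._home_away(color_only, planted_borders)
        home_s, away_s = self._home_away(shape_color, planted_borders)
        assert home_s > home_c
        assert home_s > 0.5
        assert away_s < home_s

    def test_accuracies_bounded(self, results):
        for res in results:
            assert np.all((res.accuracy >= 0) & (res.accuracy <= 1))


class TestObserverSimulation:
    def test_table_complete_and_deterministic(self, planted_borders):
        t1 = ex.simulate_observer(planted_borders, np.random.default_rng(3))
        t2 = ex.simulate_observer(planted_borders, np.random.default_rng(3))
        assert t1.n_trials == 1225
        assert np.array_equal(t1.choices, t2.choices)

    def test_noiseless_observer_is_category_consistent(self, planted_borders):
        table = ex.simulate_observer(planted_borders, np.random.default_rng(0))
        targets = (np.arange(35) + 0.5) / 35
        for s in range(0, 35, 7):
            choice_hues = (np.arange(7) / 7 + s / 35) % 1.0
            choice_cats = category_of(choice_hues, planted_borders)
            for t in range(0, 35, 5):
                cat = category_of(targets[t], planted_borders)
                if cat not in choice_cats:
                    continue  # no choice in the target's category this trial
                chosen = table.choices[t, s]
                assert category_of(choice_hues[chosen], planted_borders) == cat

    def test_jitter_broadens_transition_peaks(self, planted_borders):
        def mean_peak_width(jitter, seeds=range(4)):
            widths = []
            for s in seeds:
                rng = np.random.default_rng(s)
                tabs = [ex.simulate_observer(planted_borders, rng,
                                             border_jitter_sd=jitter)
                        for _ in range(6)]
                tc, _, _ = ex.observer_transition_analysis(tabs)
                total = tc.raw.sum()
                # spread = entropy-like occupancy of the count distribution
                p = tc.raw / total
                widths.append(float((p > 0).sum()))
            return np.mean(widths)

        assert mean_peak_width(0.03) > mean_peak_width(0.002)

    def test_table_frame_round_trip(self, planted_borders):
        table = ex.simulate_observer(planted_borders, np.random.default_rng(1))
        back = ex.ObserverTable.from_frame(table.to_frame(), observer_id="x")
        assert np.array_equal(back.choices, table.choices)

    def test_incomplete_table_rejected(self):
        grid = np.zeros((35, 35), int)
        grid[3, 4] = -1
        with pytest.raises(ValueError, match="target 3, shift 4"):
            ex.ObserverTable(choices=grid)


class TestObserverAnalysis:
    def test_single_noiseless_observer_peaks_at_planted(self, planted_borders):
        table = ex.simulate_observer(planted_borders, np.random.default_rng(5))
        tc, est, protos = ex.observer_transition_analysis([table])
        assert tc.raw.sum() > 0
        assert est.n_borders >= 7
        # the seven dominant peaks sit on the planted borders; weaker bumps
        # may appear where a category holds no choice and matching falls
        # back to the nearest hue
        strongest = sorted(est.positions, key=lambda p: -tc.raw[int(round(p * 35))])[:7]
        for p in strongest:
            assert circular_distance(p, planted_borders).min() <= 1 / 35 + 1e-9
        for b in planted_borders:
            assert circular_distance(b, np.array(strongest)).min() <= 1 / 35 + 1e-9

    def test_count_conservation(self, planted_borders):
        rng = np.random.default_rng(8)
        tabs = [ex.simulate_observer(planted_borders, rng, lapse_rate=0.05)
                for _ in range(3)]
        tc, _, _ = ex.observer_transition_analysis(tabs)
        total = 0
        for tb in tabs:
            for s in range(35):
                seq = tb.choices[:, s]
                total += int((seq != np.roll(seq, 1)).sum())
        assert tc.raw.sum() == total

    def test_pooling_observers_sharpens_peaks(self, planted_borders):
        rng = np.random.default_rng(2)
        tabs = [ex.simulate_observer(planted_borders, rng, lapse_rate=0.1)
                for _ in range(10)]
        # transition edge for border b: first target bin whose center
        # crosses it, i.e. ceil(b * 35 - 0.5)
        border_bins = np.ceil(planted_borders * 35 - 0.5).astype(int) % 35
        mask = np.zeros(35, bool)
        mask[border_bins] = True

        def peak_to_background(tables):
            tc, _, _ = ex.observer_transition_analysis(tables)
            return tc.raw[mask].min() / max(tc.raw[~mask].max(), 1)

        pooled = peak_to_background(tabs)
        singles = [peak_to_background([tb]) for tb in tabs]
        assert pooled > np.mean(singles)


class TestBootstrap:
    def test_identical_observers_maximal_statistic(self, planted_borders):
        rng = np.random.default_rng(0)
        table = ex.simulate_observer(planted_borders, rng, lapse_rate=0.02)
        counts = ex.observer_transition_count(table)
        res = ex.bootstrap_correlation_test([counts] * 4, n_boot=1000,
                                            rng=np.random.default_rng(1))
        assert res["statistic"] == pytest.approx(1.0)
        assert res["p_value"] <= 1 / 1000

    def test_joint_rotation_leaves_statistic_unchanged(self, planted_borders):
        rng = np.random.default_rng(4)
        tabs = [ex.simulate_observer(planted_borders, rng, lapse_rate=0.1)
                for _ in range(4)]
        counts = [ex.observer_transition_count(tb) for tb in tabs]
        rolled = [np.roll(c, 9) for c in counts]
        a = ex.bootstrap_correlation_test(counts, n_boot=10,
                                          rng=np.random.default_rng(0))
        b = ex.bootstrap_correlation_test(rolled, n_boot=10,
                                          rng=np.random.default_rng(0))
        assert a["statistic"] == pytest.approx(b["statistic"])

    def test_small_n_boot_warned_or_rejected(self, planted_borders):
        rng = np.random.default_rng(6)
        tabs = [ex.simulate_observer(planted_borders, rng) for _ in range(2)]
        with pytest.raises(ValueError):
            ex.bootstrap_correlation_test(tabs, n_boot=5)
        with pytest.warns(UserWarning):
            ex.bootstrap_correlation_test(tabs, n_boot=100,
                                          rng=np.random.default_rng(0))
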