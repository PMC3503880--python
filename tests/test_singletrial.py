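import numpy as np
import pytest
from scipy.stats import norm

from cfassess.core import Epochs
from cfassess.singletrial import (
    BANDS,
    FeatureTensor,
    band_restricted_classification,
    crossval_accuracy,
    extract_bandpower,
    familywise_permutation_test,
    nb_fit,
    nb_predict,
    smooth_timecourse,
    _stratified_folds,
)


def _tensor(values, conditions):
    n, t, f = values.shape
    names = [f"C3':{b}" for b in BANDS] + [f"C4':{b}" for b in BANDS]
    return FeatureTensor(
        values, np.arange(t) * 0.05 - 1.0, names[:f], np.asarray(conditions, dtype=object)
    )


def _random_tensor(rng, n=70, t=100, f=8):
    y = np.array(["left"] * (n // 2) + ["rest"] * (n - n // 2), dtype=object)
    return _tensor(rng.standard_normal((n, t, f)), y)


class TestExtractBandpower:
    def test_feature_and_time_dimensions(self, responder_epochs):
        ft = extract_bandpower(responder_epochs)
        assert ft.n_features == 8
        assert ft.n_times == 100

    def test_monopolar_rejected(self, responder_epochs):
        mono = Epochs(
            responder_epochs.data, responder_epochs.sfreq,
            responder_epochs.ch_names, responder_epochs.conditions,
            montage="monopolar",
        )
        with pytest.raises(ValueError, match="bipolar"):
            extract_bandpower(mono)

    def test_band_selectivity_27hz(self):
        t = np.arange(600) / 100.0
        x = np.sin(2 * np.pi * 27 * t)
        data = np.stack([np.tile(x, (2, 1)), 0.01 * np.tile(x, (2, 1))])
        ep = Epochs(data, 100.0, ["C3'", "C4'"], ["left", "rest"], montage="bipolar")
        ft = extract_bandpower(ep)
        hb = ft.values[0, :, ft.feature_names.index("C3':high-beta")]
        for other in ("mu", "low-beta", "mid-beta"):
            assert np.all(hb > ft.values[0, :, ft.feature_names.index(f"C3':{other}")])


class TestNaiveBayes:
    def test_separable_classes(self, rng):
        x = np.concatenate([np.zeros((10, 3)), np.ones((10, 3))])
        x += rng.normal(0, 1e-4, x.shape)
        y = np.array(["rest"] * 10 + ["left"] * 10)
        model = nb_fit(x, y)
        ir = list(model.classes).index("rest")
        assert model.means[ir] == pytest.approx(np.zeros(3), abs=1e-3)
        pred, _ = nb_predict(model, x)
        assert np.array_equal(pred, y)

    def test_identical_distributions_posterior_matches_prior(self, rng):
        # both classes share the exact same feature rows; with priors
        # (0.25, 0.75) the posterior at a class mean stays near the prior
        base = rng.normal(size=(10, 2))
        x = np.vstack([base, np.tile(base, (3, 1))])
        y = np.array(["left"] * 10 + ["rest"] * 30)
        model = nb_fit(x, y)
        _, post = nb_predict(model, base.mean(axis=0))
        # small deviation from ddof=1 variance of the tiled rows is expected
        assert post[list(model.classes).index("rest")] == pytest.approx(0.75, abs=0.05)

    def test_closed_form_two_gaussian_oracle(self, rng):
        x = np.concatenate([rng.normal(0, 1, (15, 1)), rng.normal(1.5, 2.0, (12, 1))])
        y = np.array(["left"] * 15 + ["rest"] * 12)
        model = nb_fit(x, y)
        for xv in np.linspace(-3, 5, 33):
            _, post = nb_predict(model, np.array([xv]))
            dens = np.array([
                norm.pdf(xv, model.means[k, 0], model.sds[k, 0]) * model.priors[k]
                for k in range(2)
            ])
            oracle = dens / dens.sum()
            assert np.abs(post - oracle).max() < 1e-10

    def test_oracle_decision_equivalence_exhaustive(self, rng):
        # <=12 trials x 1 feature: NB decisions equal the closed-form
        # two-Gaussian Bayes rule exactly
        for rep in range(20):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            x = np.concatenate([rng.normal(0, 1, (n1, 1)), rng.normal(1, 1, (n2, 1))])
            y = np.array(["left"] * n1 + ["rest"] * n2)
            model = nb_fit(x, y)
            grid = rng.uniform(-4, 5, size=25)
            pred, _ = nb_predict(model, grid[:, None])
            il = list(model.classes).index("left")
            ir = list(model.classes).index("rest")
            for xv, p in zip(grid, pred):
                score = [
                    norm.logpdf(xv, model.means[k, 0], model.sds[k, 0])
                    + np.log(model.priors[k])
                    for k in range(2)
                ]
                expected = (
                    model.classes[il] if score[il] > score[ir] else model.classes[ir]
                )
                assert p == expected

    def test_midpoint_tie_goes_to_rest(self):
        x = np.array([[-1.0], [-1.0], [1.0], [1.0]]) + np.array(
            [[-0.1], [0.1], [-0.1], [0.1]]
        )
        y = np.array(["left", "left", "rest", "rest"])
        model = nb_fit(x, y)
        label, post = nb_predict(model, np.array([0.0]))
        assert label == "rest"
        assert post == pytest.approx([0.5, 0.5])

    def test_prior_dominance(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-1, 1, (18, 1)), rng.normal(1, 1, (2, 1))])
        y = np.array(["left"] * 18 + ["rest"] * 2)
        model = nb_fit(x, y)
        # force symmetric densities, test the prior effect only
        model.means[:] = np.array([[-1.0], [1.0]])
        model.sds[:] = 1.0
        label, _ = nb_predict(model, np.array([0.0]))
        assert label == "left"  # prior 0.9

    def test_one_class_absent(self):
        with pytest.raises(ValueError):
            nb_fit(np.zeros((5, 2)), np.array(["rest"] * 5))

    def test_nonfinite_feature_rejected(self):
        x = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array(["left", "left", "rest", "rest"])
        model = nb_fit(x, y)
        with pytest.raises(ValueError):
            nb_predict(model, np.array([np.nan]))


class TestSmoothing:
    def test_constant_unchanged(self):
        x = np.full(50, 0.7)
        assert np.allclose(smooth_timecourse(x), x)

    def test_bounded_by_raw_extremes(self, rng):
        x = rng.uniform(0, 1, 100)
        s = smooth_timecourse(x)
        assert s.max() <= x.max() + 1e-12
        assert s.min() >= x.min() - 1e-12

    def test_width(self):
        x = np.zeros(51)
        x[25] = 1.0
        s = smooth_timecourse(x, width=11)
        assert np.count_nonzero(s) == 11


class TestCrossval:
    def test_partition_each_trial_tested_once(self, rng):
        y = np.array(["left"] * 36 + ["rest"] * 34, dtype=object)
        folds = _stratified_folds(y, 10, rng)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 70
        assert np.array_equal(np.sort(all_idx), np.arange(70))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 2

    def test_separable_window_detected(self, rng):
        values = rng.standard_normal((60, 100, 8)) * 0.01
        y = np.array(["left"] * 30 + ["rest"] * 30, dtype=object)
        values[:30, 40:61, :] += 5.0  # separable only at time-points 40-60
        ft = _tensor(values, y)
        acc = crossval_accuracy(ft, seed=0)
        assert acc.raw[45:56].min() > 0.95
        assert abs(acc.raw[:30].mean() - 0.5) < 0.15
        assert abs(acc.raw[70:].mean() - 0.5) < 0.15

    def test_determinism(self, rng):
        ft = _random_tensor(rng)
        a = crossval_accuracy(ft, seed=3)
        b = crossval_accuracy(ft, seed=3)
        assert np.array_equal(a.raw, b.raw)
        assert np.array_equal(a.smoothed, b.smoothed)

    def test_smoothed_is_moving_average(self, rng):
        ft = _random_tensor(rng, n=30, t=40)
        acc = crossval_accuracy(ft, seed=1)
        assert np.allclose(acc.smoothed, smooth_timecourse(acc.raw))
        assert acc.max_smoothed[0] <= acc.max_raw[0] + 1e-12

    def test_null_accuracy_near_chance(self):
        # random labels, i.i.d. features: smoothed accuracy within [.35, .65]
        inside = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(9000 + seed)
            ft = _random_tensor(rng)
            acc = crossval_accuracy(ft, seed=seed)
            if acc.smoothed.min() >= 0.35 and acc.smoothed.max() <= 0.65:
                inside += 1
        assert inside >= 0.9 * n_seeds


class TestFamilywise:
    def test_constant_features_no_significance(self):
        values = np.zeros((40, 50, 4))
        y = np.array(["left"] * 20 + ["rest"] * 20, dtype=object)
        ft = FeatureTensor(values, np.arange(50) * 0.05, [f"C3':{b}" for b in BANDS], y)
        with pytest.warns(UserWarning):
            res = familywise_permutation_test(ft, n_perm=50, seed=0)
        assert not res.any_significant
        # all-constant features: every prediction ties to rest -> chance
        assert np.allclose(res.observed.raw, 0.5)

    def test_detects_strong_effect(self, rng):
        values = rng.standard_normal((60, 60, 4)) * 0.05
        values[:30, 20:40, :] += 3.0
        y = np.array(["left"] * 30 + ["rest"] * 30, dtype=object)
        ft = FeatureTensor(values, np.arange(60) * 0.05, [f"C3':{b}" for b in BANDS], y)
        res = familywise_permutation_test(ft, n_perm=200, seed=0)
        assert res.any_significant
        assert res.p.min() == pytest.approx(1 / 201)

    def test_p_monotone_in_effect_depth(self):
        # median p over seeds decreases as the injected effect grows
        med_p = []
        for depth in (0.0, 0.25, 0.5, 1.0):
            ps = []
            for seed in range(7):
                rng = np.random.default_rng(100 * seed + 7)
                values = rng.standard_normal((50, 40, 4))
                values[:25, 15:25, :] += depth * 1.5
                y = np.array(["left"] * 25 + ["rest"] * 25, dtype=object)
                ft = FeatureTensor(
                    values, np.arange(40) * 0.05, [f"C3':{b}" for b in BANDS], y
                )
                res = familywise_permutation_test(ft, n_perm=100, seed=seed)
                ps.append(res.p.min())
            med_p.append(np.median(ps))
        assert med_p[0] > med_p[-1]
        assert all(a >= b - 0.05 for a, b in zip(med_p, med_p[1:]))

    def test_determinism(self, rng):
        ft = _random_tensor(rng, n=40, t=30)
        a = familywise_permutation_test(ft, n_perm=100, seed=5)
        b = familywise_permutation_test(ft, n_perm=100, seed=5)
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.null_max, b.null_max)

    def test_low_n_perm_warns(self, rng):
        ft = _random_tensor(rng, n=30, t=20)
        with pytest.warns(UserWarning, match="unstable"):
            familywise_permutation_test(ft, n_perm=50, seed=0)


class TestBandRestriction:
    def test_all_bands_identity(self, rng):
        ft = _random_tensor(rng, n=40, t=30)
        full = familywise_permutation_test(ft, n_perm=50, seed=2)
        acc, res = band_restricted_classification(
            ft, list(BANDS), n_perm=50, seed=2
        )
        assert np.array_equal(acc.raw, full.observed.raw)
        assert np.array_equal(res.p, full.p)

    def test_single_band_feature_count(self, rng):
        ft = _random_tensor(rng, n=30, t=20)
        sub = ft.select_bands(["high-beta"])
        assert sub.n_features == 2
        assert all("high-beta" in n for n in sub.feature_names)

    def test_empty_subset_rejected(self, rng):
        ft = _random_tensor(rng, n=30, t=20)
        with pytest.raises(ValueError):
            ft.select_bands([])

    def test_band_restriction_boosts_confined_effect(self, rng):
        # effect confined to high-beta: restricted accuracy >= full at peak
        wins = 0
        n_runs = 15
        for seed in range(n_runs):
            r = np.random.default_rng(3000 + seed)
            values = r.standard_normal((50, 30, 8))
            hb = [3, 7]  # high-beta columns for both channels
            values[:25, 10:20, hb] += 1.2
            y = np.array(["left"] * 25 + ["rest"] * 25, dtype=object)
            names = [f"C3':{b}" for b in BANDS] + [f"C4':{b}" for b in BANDS]
            ft = FeatureTensor(values, np.arange(30) * 0.05, names, y)
            full = crossval_accuracy(ft, seed=seed)
            restricted = crossval_accuracy(ft.select_bands(["high-beta"]), seed=seed)
            peak = np.argmax(full.smoothed)
            if restricted.smoothed[peak] >= full.smoothed[peak]:
                wins += 1
        assert wins >= 0.6 * n_runs
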