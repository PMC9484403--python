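import numpy as np
import pytest
from scipy.special import logsumexp

from coastsdm.evaluation import (
    aicc,
    aicc_formula,
    checkerboard2_partition,
    jackknife_gain,
    kfold_cv,
    kfold_folds,
    partial_roc,
    percent_contribution,
    training_gain,
    tune,
)
from coastsdm.features import build_features
from coastsdm.grids import GridSpec
from coastsdm.maxent import fit

from oracles import penalized_objective, solve_with_generic_optimizer


class TestCheckerboard2:
    def test_lattice_two_scale_pattern(self):
        # 4x4 lattice of cell centers; fine boards are single cells,
        # coarse boards 2x2 blocks -> 4 points in each of the 4 bins
        spec = GridSpec(n_rows=4, n_cols=4, west=0.0, south=0.0, cell_size=1.0)
        lons, lats = np.meshgrid(np.arange(4) + 0.5, np.arange(4) + 0.5)
        bins = checkerboard2_partition(
            lons.ravel(), lats.ravel(), spec, aggregation_factors=(1, 2)
        )
        assert sorted(np.bincount(bins)[1:]) == [4, 4, 4, 4]
        # neighbouring cells always land on opposite fine boards
        grid = bins.reshape(4, 4)
        assert (grid[:, :-1] % 2 != grid[:, 1:] % 2).all()
        assert (grid[:-1, :] % 2 != grid[1:, :] % 2).all()

    def test_points_in_one_cell_share_a_bin(self):
        spec = GridSpec(n_rows=8, n_cols=8, west=0.0, south=0.0, cell_size=1.0)
        lons = np.array([3.1, 3.5, 3.9])
        lats = np.array([5.1, 5.5, 5.9])
        bins = checkerboard2_partition(lons, lats, spec)
        assert len(set(bins)) == 1

    def test_matches_parity_oracle(self):
        spec = GridSpec(n_rows=20, n_cols=30, west=-10.0, south=0.0, cell_size=0.5)
        rng = np.random.default_rng(1)
        lons = rng.uniform(-10, 5, 200)
        lats = rng.uniform(0, 10, 200)
        f1, f2 = 2, 3
        bins = checkerboard2_partition(lons, lats, spec, (f1, f2))
        for lon, lat, b in zip(lons, lats, bins):
            row = int((spec.north - lat) // spec.cell_size)
            col = int((lon - spec.west) // spec.cell_size)
            fine = ((row // f1) + (col // f1)) % 2
            coarse = ((row // (f1 * f2)) + (col // (f1 * f2))) % 2
            assert b == 1 + fine + 2 * coarse


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc_formula(2, -100.0, 50) == pytest.approx(204 + 12 / 47)

    def test_undefined_when_m_too_small(self):
        assert aicc_formula(5, -10.0, 6) == float("inf")

    def test_ranking_invariant_under_lnl_shift(self):
        lnls = [-120.0, -100.0, -140.0]
        base = [aicc_formula(3, l, 60) for l in lnls]
        shifted = [aicc_formula(3, l + 55.5, 60) for l in lnls]
        assert np.argsort(base).tolist() == np.argsort(shifted).tolist()

    def test_lnl_matches_brute_force_normalization(self):
        rng = np.random.default_rng(2)
        land = rng.uniform(0, 5, (400, 2))
        pres = land[land[:, 0] > 2.5][:60]
        model = fit(pres, land, [6, 12], "lq")
        a = aicc(model, pres, land)
        # brute force: normalize raw over the landscape explicitly
        raw_land = model.raw(land, clamp=False)
        raw_pres = model.raw(pres, clamp=False)
        lnL = float(np.sum(np.log(raw_pres / raw_land.sum())))
        k = model.n_parameters
        assert a == pytest.approx(aicc_formula(k, lnL, len(pres)), rel=1e-12)


class TestKfold:
    def test_five_presences_one_per_fold(self):
        folds = kfold_folds(5, k=5, seed=0)
        assert [len(f) for f in folds] == [1, 1, 1, 1, 1]
        assert sorted(np.concatenate(folds).tolist()) == list(range(5))

    def test_same_seed_same_folds(self):
        a = kfold_folds(37, k=5, seed=9)
        b = kfold_folds(37, k=5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    @pytest.mark.parametrize("m", [5, 23, 50, 101])
    def test_fold_sizes_differ_by_at_most_one(self, m):
        sizes = [len(f) for f in kfold_folds(m, k=5, seed=1)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == m

    def test_cv_reports_per_fold_metrics(self):
        rng = np.random.default_rng(3)
        bg = rng.uniform(0, 5, (500, 2))
        pres = bg[bg[:, 0] > 2][:60]
        out = kfold_cv(pres, bg, [6, 12], "lq", 1.0, landscape_env=bg,
                       k=5, seed=0, proc_kwargs={"n_boot": 50})
        assert len(out["fold_omission"]) == 5
        assert 0.0 <= out["mean_omission"] <= 1.0
        assert out["mean_proc_ratio"] > 0


class TestPartialRoc:
    def test_random_predictions_ratio_near_one(self):
        rng = np.random.default_rng(4)
        land = rng.uniform(0, 1, 5000)
        test = rng.uniform(0, 1, 100)
        ratio, _ = partial_roc(test, land, n_boot=1000, seed=0)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_perfect_discrimination(self):
        rng = np.random.default_rng(5)
        land = rng.uniform(0, 0.5, 2000)
        test = rng.uniform(0.9, 1.0, 50)  # all above every landscape cell
        ratio, p = partial_roc(test, np.concatenate([land, test]), n_boot=200, seed=0)
        assert ratio > 1.5
        assert p < 0.05

    def test_anti_predictor_below_one(self):
        rng = np.random.default_rng(6)
        land = rng.uniform(0, 1, 3000)
        test = rng.uniform(0, 0.05, 50)  # concentrated at the worst cells
        ratio, p = partial_roc(test, land, n_boot=200, seed=0)
        assert ratio < 1.0
        assert p > 0.5

    def test_matches_brute_force_trapezoid(self):
        rng = np.random.default_rng(7)
        land = rng.uniform(0, 1, 200)
        test = rng.uniform(0.3, 1.0, 20)
        E = 0.05
        n_thr = 400
        ratio, _ = partial_roc(
            test, land, E=E, n_boot=1, boot_frac=1.0, seed=0, n_thresholds=n_thr
        )
        # brute force on the same threshold sweep, one full-sample "bootstrap"
        sample = test[np.random.default_rng(0).integers(0, 20, 20)]
        thrs = np.linspace(land.min(), land.max(), n_thr)
        pts = []
        for t in thrs:
            sens = np.mean(sample >= t)
            area = np.mean(land >= t)
            if sens >= 1 - E:
                pts.append((area, sens))
        pts = sorted(pts)
        x = [p[0] for p in pts]
        y = [p[1] for p in pts]
        auc_model = np.trapezoid(y, x)
        auc_rand = np.trapezoid(x, x)
        assert ratio == pytest.approx(auc_model / auc_rand, rel=1e-9)

    def test_too_few_test_points_rejected(self):
        with pytest.raises(ValueError):
            partial_roc(np.ones(5), np.random.default_rng(0).uniform(0, 1, 100))

    def test_constant_landscape_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            partial_roc(np.ones(20), np.full(100, 0.5))


class TestJackknife:
    @pytest.fixture
    def informative_setup(self):
        rng = np.random.default_rng(8)
        n = 1500
        informative = rng.uniform(0, 10, n)
        noise = rng.uniform(0, 10, n)
        bg = np.column_stack([informative, noise])
        p = np.exp(0.8 * informative)
        pres = bg[rng.choice(n, 300, p=p / p.sum())]
        return pres, bg

    def test_informative_variable_has_max_alone_gain(self, informative_setup):
        pres, bg = informative_setup
        gains = jackknife_gain(pres, bg, [6, 12], "lq", 1.0)
        assert gains[6][0] > gains[12][0]

    def test_duplicate_variable_leaves_without_gain_high(self, informative_setup):
        pres, bg = informative_setup
        pres3 = np.column_stack([pres, pres[:, 0]])
        bg3 = np.column_stack([bg, bg[:, 0]])
        full = training_gain(fit(pres3, bg3, [6, 12, 16], "lq", 1.0))
        gains = jackknife_gain(pres3, bg3, [6, 12, 16], "lq", 1.0)
        # dropping either copy of the informative variable barely hurts
        assert gains[6][1] == pytest.approx(full, abs=0.05 * max(full, 1e-6))
        assert gains[16][1] == pytest.approx(full, abs=0.05 * max(full, 1e-6))

    def test_alone_gain_not_above_full_gain(self, informative_setup):
        pres, bg = informative_setup
        full = training_gain(fit(pres, bg, [6, 12], "lq", 1.0))
        gains = jackknife_gain(pres, bg, [6, 12], "lq", 1.0)
        for alone, _ in gains.values():
            assert alone <= full + 1e-3

    def test_gains_match_independent_optimizer(self):
        rng = np.random.default_rng(9)
        bg = rng.uniform(0, 5, (400, 2))
        pres = bg[bg[:, 0] + 0.3 * bg[:, 1] > 3][:80]
        gains = jackknife_gain(pres, bg, [6, 12], "lq", 1.0)
        for j, v in enumerate([6, 12]):
            model = fit(pres[:, [j]], bg[:, [j]], [v], "lq", 1.0)
            Fp, _ = build_features(pres[:, [j]], [v], model.feature_spec,
                                   feats=model.features)
            Fb, _ = build_features(bg[:, [j]], [v], model.feature_spec,
                                   feats=model.features)
            oracle_obj, oracle_beta = solve_with_generic_optimizer(Fp, Fb, model.reg)
            oracle_gain = oracle_obj + float(
                np.sum(model.reg * np.abs(oracle_beta))
            )
            assert gains[v][0] == pytest.approx(oracle_gain, abs=1e-3)


class TestPercentContribution:
    def test_single_variable_gets_everything(self):
        rng = np.random.default_rng(10)
        bg = rng.uniform(0, 5, (400, 1))
        pres = bg[bg[:, 0] > 3][:60]
        model = fit(pres, bg, [6], "lq")
        contrib = percent_contribution(model)
        assert contrib[6] == pytest.approx(100.0)

    def test_contributions_sum_to_100(self):
        rng = np.random.default_rng(11)
        bg = rng.uniform(0, 5, (600, 3))
        pres = bg[(bg[:, 0] > 2) & (bg[:, 2] < 4)][:90]
        model = fit(pres, bg, [2, 6, 12], "lqhp")
        contrib = percent_contribution(model)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.1)
        assert all(c >= 0 for c in contrib.values())

    def test_dominant_driver_gets_largest_share(self):
        rng = np.random.default_rng(12)
        n = 2000
        b6 = rng.uniform(-5, 15, n)
        b12 = rng.uniform(500, 3000, n)
        bg = np.column_stack([b6, b12])
        p = np.exp(0.7 * b6)
        pres = bg[rng.choice(n, 400, p=p / p.sum())]
        model = fit(pres, bg, [6, 12], "lq")
        contrib = percent_contribution(model)
        assert contrib[6] == max(contrib.values())


class TestTune:
    def test_delta_aicc_zero_for_selected(self):
        rng = np.random.default_rng(13)
        bg = rng.uniform(0, 5, (400, 2))
        pres = bg[bg[:, 0] > 2.5][:80]
        result = tune(pres, bg, [6, 12], combos=("l", "lq"),
                      multipliers=(1.0, 2.0), cv_omission=False)
        assert result.selected.delta_aicc == 0.0
        deltas = [c.delta_aicc for c in result.candidates if c.valid]
        assert min(deltas) == 0.0
        assert all(d >= 0 for d in deltas)

    def test_checkerboard_omission_reported(self):
        spec = GridSpec(n_rows=20, n_cols=20, west=0.0, south=0.0, cell_size=1.0)
        rng = np.random.default_rng(14)
        lonlat = np.column_stack([rng.uniform(0, 20, 120), rng.uniform(0, 20, 120)])
        bg = rng.uniform(0, 5, (300, 2))
        pres = bg[:120] + 1.0
        result = tune(pres, bg, [6, 12], presence_lonlat=lonlat, spec=spec,
                      combos=("l",), multipliers=(1.0,))
        assert 0.0 <= result.selected.mean_cv_omission <= 1.0
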