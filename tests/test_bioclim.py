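import statistics

import numpy as np
import pytest

from coastsdm.bioclim import (
    BioclimStack,
    compute_bioclim,
    correlation_prune,
    window_average,
)
from coastsdm.grids import GridSpec, RasterGrid

from conftest import make_grid


# ---------------------------------------------------------------------------
# Independent reference: the 19 bioclim formulas written as plain per-cell
# loops over 12-month vectors, using the statistics module (not numpy), so
# it shares no code path with the implementation under test.
# ---------------------------------------------------------------------------
def reference_biovars(tmin, tmax, prec):
    tavg = [(a + b) / 2.0 for a, b in zip(tmax, tmin)]
    bio = {}
    bio[1] = statistics.mean(tavg)
    bio[2] = statistics.mean(a - b for a, b in zip(tmax, tmin))
    bio[4] = 100.0 * statistics.stdev(tavg)
    bio[5] = max(tmax)
    bio[6] = min(tmin)
    bio[7] = bio[5] - bio[6]
    bio[3] = 100.0 * bio[2] / bio[7] if bio[7] != 0 else None
    bio[12] = sum(prec)
    bio[13] = max(prec)
    bio[14] = min(prec)
    bio[15] = 100.0 * statistics.stdev(prec) / (1.0 + statistics.mean(prec))
    quarters = [[i % 12, (i + 1) % 12, (i + 2) % 12] for i in range(12)]
    psum = [sum(prec[j] for j in q) for q in quarters]
    tq = [statistics.mean(tavg[j] for j in q) for q in quarters]
    wet = psum.index(max(psum))  # index() takes the earliest on ties
    dry = psum.index(min(psum))
    warm = tq.index(max(tq))
    cold = tq.index(min(tq))
    bio[8] = tq[wet]
    bio[9] = tq[dry]
    bio[10] = tq[warm]
    bio[11] = tq[cold]
    bio[16] = psum[wet]
    bio[17] = psum[dry]
    bio[18] = psum[warm]
    bio[19] = psum[cold]
    return bio


def normals_from_vectors(tmin, tmax, prec):
    """Wrap per-cell 12-month vectors into a MonthlyClimateNormals."""
    from coastsdm.bioclim import MonthlyClimateNormals

    tmin = np.asarray(tmin)  # (12, ncells)
    n = tmin.shape[1]
    rows = 1
    spec = GridSpec(n_rows=rows, n_cols=n, west=0.0, south=0.0, cell_size=1.0)
    as_grids = lambda arr: [RasterGrid(spec, arr[m].reshape(rows, n)) for m in range(12)]
    return MonthlyClimateNormals(
        window=(2013, 2018),
        tmin=as_grids(np.asarray(tmin)),
        tmax=as_grids(np.asarray(tmax)),
        prec=as_grids(np.asarray(prec)),
    )


def random_monthly_vectors(rng, n_cells):
    tmin = rng.uniform(-5, 25, (12, n_cells))
    tmax = tmin + rng.uniform(0.5, 15, (12, n_cells))
    prec = rng.uniform(0, 400, (12, n_cells))
    return tmin, tmax, prec


class TestWindowAverage:
    @staticmethod
    def series(grids_by_year_month):
        return {
            (y, m): {k: v for k, v in entry.items()}
            for (y, m), entry in grids_by_year_month.items()
        }

    def test_identical_years_equal_any_single_year(self):
        base = {v: make_grid(np.full((2, 2), x)) for v, x in
                [("tmin", 10.0), ("tmax", 20.0), ("prec", 100.0)]}
        series = {(y, m): base for y in (2000, 2001) for m in range(1, 13)}
        normals = window_average(series, (2000, 2001))
        np.testing.assert_array_equal(normals.tmin[0].values, base["tmin"].values)

    def test_two_year_january_mean(self):
        def entry(tmin_val):
            return {
                "tmin": make_grid(np.full((2, 2), tmin_val)),
                "tmax": make_grid(np.full((2, 2), tmin_val + 10)),
                "prec": make_grid(np.full((2, 2), 50.0)),
            }

        series = {}
        for m in range(1, 13):
            series[(2000, m)] = entry(10.0)
            series[(2001, m)] = entry(20.0)
        normals = window_average(series, (2000, 2001))
        assert normals.tmin[0].values[0, 0] == 15.0

    def test_matches_stacked_mean_oracle(self):
        rng = np.random.default_rng(4)
        series = {}
        raw = {}
        for y in range(2013, 2019):
            for m in range(1, 13):
                tmin = rng.uniform(0, 20, (3, 4))
                series[(y, m)] = {
                    "tmin": make_grid(tmin),
                    "tmax": make_grid(tmin + 8),
                    "prec": make_grid(rng.uniform(0, 300, (3, 4))),
                }
                raw[(y, m)] = tmin
        normals = window_average(series, (2013, 2018))
        for m in range(1, 13):
            oracle = np.mean([raw[(y, m)] for y in range(2013, 2019)], axis=0)
            np.testing.assert_allclose(normals.tmin[m - 1].values, oracle)

    def test_missing_month_lists_gap(self):
        series = {
            (2000, m): {
                "tmin": make_grid(np.zeros((2, 2))),
                "tmax": make_grid(np.ones((2, 2))),
                "prec": make_grid(np.zeros((2, 2))),
            }
            for m in range(1, 12)  # December missing
        }
        with pytest.raises(ValueError, match=r"\(2000, 12\)"):
            window_average(series, (2000, 2000))


class TestComputeBioclim:
    def test_constant_climate_identities(self):
        tmin = np.full((12, 1), 15.0)
        tmax = np.full((12, 1), 25.0)
        prec = np.full((12, 1), 100.0)
        stack = compute_bioclim(normals_from_vectors(tmin, tmax, prec))
        get = lambda i: stack.bio[i].values[0, 0]
        assert get(1) == 20.0
        assert get(2) == 10.0
        assert get(4) == 0.0
        assert get(5) == 25.0
        assert get(6) == 15.0
        assert get(7) == 10.0
        assert get(12) == 1200.0
        assert get(15) == 0.0
        assert get(18) == 300.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(12)
        n = 1000
        tmin, tmax, prec = random_monthly_vectors(rng, n)
        stack = compute_bioclim(normals_from_vectors(tmin, tmax, prec))
        for c in range(n):
            ref = reference_biovars(tmin[:, c], tmax[:, c], prec[:, c])
            for i in range(1, 20):
                assert stack.bio[i].values[0, c] == pytest.approx(ref[i], abs=1e-9)

    def test_stack_invariants_on_random_inputs(self):
        rng = np.random.default_rng(77)
        tmin, tmax, prec = random_monthly_vectors(rng, 500)
        stack = compute_bioclim(normals_from_vectors(tmin, tmax, prec))
        b = {i: stack.bio[i].values[0] for i in range(1, 20)}
        np.testing.assert_allclose(b[7], b[5] - b[6], atol=1e-12)
        assert (b[5] >= b[6]).all()
        np.testing.assert_allclose(b[12], prec.sum(axis=0), atol=1e-9)
        assert (b[13] >= b[14]).all() and (b[14] >= 0).all()
        assert (b[16] >= b[17]).all()

    def test_quarters_invariant_under_month_rotation(self):
        rng = np.random.default_rng(8)
        tmin, tmax, prec = random_monthly_vectors(rng, 50)
        base = compute_bioclim(normals_from_vectors(tmin, tmax, prec))
        for shift in (3, 7):
            rolled = compute_bioclim(
                normals_from_vectors(
                    np.roll(tmin, shift, axis=0),
                    np.roll(tmax, shift, axis=0),
                    np.roll(prec, shift, axis=0),
                )
            )
            for i in (8, 9, 10, 11, 16, 17, 18, 19):
                np.testing.assert_allclose(
                    rolled.bio[i].values, base.bio[i].values, atol=1e-9
                )

    def test_nodata_propagates(self):
        tmin = np.full((12, 2), 10.0)
        tmax = np.full((12, 2), 20.0)
        prec = np.full((12, 2), 50.0)
        normals = normals_from_vectors(tmin, tmax, prec)
        vals = normals.tmin[3].values.copy()
        vals[0, 1] = normals.spec.nodata
        normals.tmin[3] = RasterGrid(normals.spec, vals)
        stack = compute_bioclim(normals)
        assert not stack.bio[1].valid_mask[0, 1]
        assert stack.bio[1].valid_mask[0, 0]

    def test_zero_range_bio3_flagged(self):
        tmin = np.full((12, 1), 10.0)
        tmax = np.full((12, 1), 10.0)
        prec = np.full((12, 1), 50.0)
        with pytest.warns(UserWarning, match="BIO3"):
            stack = compute_bioclim(normals_from_vectors(tmin, tmax, prec))
        assert not stack.bio[3].valid_mask[0, 0]


def stack_from_layers(layers):
    spec = GridSpec(n_rows=1, n_cols=len(next(iter(layers.values()))),
                    west=0.0, south=0.0, cell_size=1.0)
    return BioclimStack(
        window=(2013, 2018),
        bio={i: RasterGrid(spec, np.asarray(v, dtype=float).reshape(1, -1))
             for i, v in layers.items()},
    )


class TestCorrelationPrune:
    def test_identical_layers_drop_lower_priority(self):
        x = np.arange(10.0)
        stack = stack_from_layers({6: x, 12: x})
        out = correlation_prune(stack, priority=(6, 12))
        assert out.retained == [6]
        assert out.dropped == [(12, 6, pytest.approx(1.0))]

    def test_orthogonal_layers_all_retained(self):
        # orthogonal contrasts over 4 cells
        stack = stack_from_layers(
            {2: [1, 1, -1, -1], 5: [1, -1, 1, -1], 6: [1, -1, -1, 1]}
        )
        out = correlation_prune(stack, priority=(6, 2, 5))
        assert sorted(out.retained) == [2, 5, 6]

    def test_cold_extreme_outranks_annual_mean(self):
        # annual-mean-like layer strongly correlated (r ~ .95) with the
        # cold-extreme layer: the higher-priority cold extreme is kept
        rng = np.random.default_rng(6)
        b6 = rng.normal(size=400)
        b1 = 0.9 * b6 + 0.3 * rng.normal(size=400)
        stack = stack_from_layers({6: b6, 1: b1})
        out = correlation_prune(stack, priority=(6, 1))
        r = np.corrcoef(b6, b1)[0, 1]
        assert abs(r) > 0.7
        assert out.retained == [6]
        dropped, kept, r_rec = out.dropped[0]
        assert (dropped, kept) == (1, 6)
        assert r_rec == pytest.approx(r)

    def test_no_retained_pair_violates_threshold(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=200)
        layers = {
            i: base * rng.uniform(-1, 1) + rng.normal(size=200) for i in range(1, 11)
        }
        stack = stack_from_layers(layers)
        out = correlation_prune(stack, threshold=0.7, priority=tuple(range(1, 11)))
        data = {i: stack.bio[i].values[0] for i in out.retained}
        for a in out.retained:
            for b in out.retained:
                if a < b:
                    assert abs(np.corrcoef(data[a], data[b])[0, 1]) <= 0.7

    def test_threshold_one_retains_everything(self):
        rng = np.random.default_rng(14)
        layers = {i: rng.normal(size=50) + i for i in range(1, 7)}
        stack = stack_from_layers(layers)
        out = correlation_prune(stack, threshold=1.0, priority=tuple(range(1, 7)))
        assert sorted(out.retained) == list(range(1, 7))

    def test_zero_variance_layer_excluded(self):
        stack = stack_from_layers({6: np.arange(5.0), 12: np.ones(5)})
        with pytest.warns(UserWarning, match="BIO12"):
            out = correlation_prune(stack, priority=(6, 12))
        assert out.retained == [6]
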