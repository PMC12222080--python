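"""AR fitting, the GC statistic, AIC order selection, sliding windows."""

import numpy as np
import pandas as pd
import pytest

from tvgc import synth
from tvgc.gc import (
    DegenerateSeriesError,
    SingularDesignError,
    SlidingWindowSpec,
    aic,
    fit_ar,
    gc_cells,
    gc_matrix,
    gc_pair,
    lag_matrix,
    make_windows,
    select_order,
)
from tvgc.preprocess import EpochSet


def simulate_pair(coupling, n, rng, lag=1, self_coeff=0.5):
    """y drives x with the given coupling at the given lag."""
    g = synth.GroundTruthGraph(
        2, edges=((1, 0, coupling, lag),), self_coeffs=(self_coeff,)
    )
    out = synth.simulate_var(synth.build_var_coefficients(g), n, 1.0, rng)[0]
    return out[0], out[1]  # x (driven), y (driver)


class TestMakeWindows:
    def test_default_tiling_five_windows(self):
        windows = make_windows(SlidingWindowSpec(), 500.0)
        assert windows == [(0, 500), (250, 750), (500, 1000), (750, 1250), (1000, 1500)]

    def test_window_equal_to_epoch_is_single(self):
        spec = SlidingWindowSpec(window_length=3.0, overlap=0.0)
        assert make_windows(spec, 500.0) == [(0, 1500)]

    def test_no_overlap_tiles_disjointly(self):
        spec = SlidingWindowSpec(window_length=1.0, overlap=0.0)
        assert make_windows(spec, 500.0) == [(0, 500), (500, 1000), (1000, 1500)]

    def test_degenerate_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            make_windows(SlidingWindowSpec(window_length=1.0, overlap=0.999), 100.0)
        with pytest.raises(ValueError):
            SlidingWindowSpec(overlap=1.0)


class TestFitAr:
    def test_white_noise_has_no_structure(self, rng):
        x = rng.standard_normal(5000)
        fit = fit_ar(x, [x], p=1)
        assert abs(fit.coeffs[0, 0]) < 3.0 / np.sqrt(len(x))
        assert fit.residual_variance == pytest.approx(x.var(), rel=0.05)
        assert fit.n_obs == 4999

    def test_recovers_ar1_coefficient(self, rng):
        g = synth.GroundTruthGraph(1, self_coeffs=(0.9,))
        x = synth.simulate_var(synth.build_var_coefficients(g), 5000, 1.0, rng)[0, 0]
        fit = fit_ar(x, [x], p=1)
        assert abs(fit.coeffs[0, 0] - 0.9) < 0.05

    def test_residuals_orthogonal_to_design(self, rng):
        x, y = rng.standard_normal((2, 400))
        fit = fit_ar(x, [x, y], p=3)
        design = np.hstack([lag_matrix(x, 3), lag_matrix(y, 3)])
        resid = x[3:] - design @ fit.coeffs.ravel()
        assert fit.rss == pytest.approx(resid @ resid, rel=1e-9)
        np.testing.assert_allclose(design.T @ resid, 0.0, atol=1e-7)

    def test_duplicated_predictor_is_singular(self, rng):
        x = rng.standard_normal(200)
        with pytest.raises(SingularDesignError):
            fit_ar(x, [x, x], p=2)


class TestAic:
    @pytest.mark.parametrize(
        "n,rss,k,expected",
        [(100, 100.0, 5, 10.0), (500, 50.0, 24, 500 * np.log(0.1) + 48)],
    )
    def test_closed_form(self, n, rss, k, expected):
        assert aic(n, rss, k) == pytest.approx(expected)

    def test_linear_in_parameter_count(self):
        assert aic(200, 37.0, 20) - aic(200, 37.0, 10) == pytest.approx(20.0)

    def test_zero_rss_rejected(self):
        with pytest.raises(ValueError, match="RSS"):
            aic(100, 0.0, 5)


class TestGcPair:
    def test_planted_direction_dominates(self, rng):
        hits = 0
        for _ in range(200):
            x, y = simulate_pair(0.6, 500, rng)
            f_yx, f_xy = gc_pair(x, y, p=2)
            hits += f_yx > f_xy
        assert hits >= 190  # >= 95% of simulations

    def test_null_level_reproducible_across_batches(self, rng):
        # small-sample bias of F under independence, two matched batches
        def batch(r):
            vals = []
            for _ in range(200):
                x, y = r.standard_normal((2, 500))
                vals.extend(gc_pair(x, y, p=12))
            return np.asarray(vals)

        a = batch(np.random.default_rng(1))
        b = batch(np.random.default_rng(2))
        se = np.sqrt(a.var() / a.size + b.var() / b.size)
        assert abs(a.mean() - b.mean()) < 3 * se
        assert a.mean() > 0  # positive small-sample bias

    def test_identical_series_fail(self, rng):
        x = rng.standard_normal(300)
        with pytest.raises((SingularDesignError, DegenerateSeriesError)):
            gc_pair(x, x.copy(), p=2)

    def test_nonnegative_and_scale_invariant(self, rng):
        x, y = simulate_pair(0.4, 400, rng)
        f = gc_pair(x, y, p=4)
        assert min(f) >= 0.0
        f_scaled = gc_pair(137.0 * x, 0.003 * y, p=4)
        np.testing.assert_allclose(f, f_scaled, rtol=1e-8, atol=1e-12)

    def test_monotone_in_coupling_strength(self):
        f_prev = -np.inf
        for c in (0.1, 0.2, 0.3, 0.4):
            # identical innovations at every magnitude: same seed
            x, y = simulate_pair(c, 800, np.random.default_rng(99))
            f_yx, _ = gc_pair(x, y, p=2)
            assert f_yx > f_prev
            f_prev = f_yx

    def test_matches_naive_normal_equations_oracle(self, rng):
        # independent route: explicit lag design + normal equations
        def naive_gc(x, y, p):
            x, y = x - x.mean(), y - y.mean()
            zx, zy = lag_matrix(x, p), lag_matrix(y, p)
            t = x[p:]

            def rss(design):
                beta = np.linalg.solve(design.T @ design, design.T @ t)
                r = t - design @ beta
                return r @ r

            return np.log(rss(zx) / rss(np.hstack([zx, zy])))

        g = synth.make_group_graphs(n_channels=3, n_edges=3, seed=8)["novice"]
        data = synth.simulate_var(
            synth.build_var_coefficients(g), 300, 1.0, rng, n_series=5
        )
        for trial in data:
            for i in range(3):
                for j in range(i + 1, 3):
                    f_ji, f_ij = gc_pair(trial[i], trial[j], p=3)
                    assert f_ji == pytest.approx(
                        naive_gc(trial[i], trial[j], 3), abs=1e-8
                    )
                    assert f_ij == pytest.approx(
                        naive_gc(trial[j], trial[i], 3), abs=1e-8
                    )


class TestGcMatrix:
    def test_planted_edge_direction(self, rng):
        x, y = simulate_pair(0.5, 1000, rng)
        m = gc_matrix(np.stack([y, x])[None], p=2)  # channel 0 drives channel 1
        assert m.weights[0, 1] > m.weights[1, 0]
        assert m.weights[0, 0] == 0.0 and m.weights[1, 1] == 0.0
        np.testing.assert_array_equal(
            m.symmetric_max, np.maximum(m.weights, m.weights.T)
        )

    def test_independent_channels_stay_below_null_ceiling(self):
        null = []
        for s in range(40):
            data = np.random.default_rng(1000 + s).standard_normal((4, 300))
            w = gc_matrix(data, p=3).weights
            null.extend(w[~np.eye(4, dtype=bool)])
        ceiling = np.quantile(null, 0.999)
        w = gc_matrix(np.random.default_rng(7).standard_normal((4, 300)), p=3).weights
        assert w[~np.eye(4, dtype=bool)].max() <= ceiling

    def test_trial_averaging(self, rng):
        data = rng.standard_normal((3, 2, 200))
        avg = gc_matrix(data, p=2).weights
        singles = [gc_matrix(d, p=2).weights for d in data]
        np.testing.assert_allclose(avg, np.mean(singles, axis=0), atol=1e-12)

    def test_matrix_agrees_with_pairwise_route(self, rng):
        # the batched block-orthogonalization path vs the 2-channel QR path
        data = rng.standard_normal((5, 400))
        w = gc_matrix(data, p=6).weights
        for i in range(5):
            for j in range(i + 1, 5):
                f_ji, f_ij = gc_pair(data[i], data[j], p=6)
                assert w[j, i] == pytest.approx(f_ji, abs=1e-12)
                assert w[i, j] == pytest.approx(f_ij, abs=1e-12)

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError, match="2 channels"):
            gc_matrix(rng.standard_normal((1, 1, 100)), p=2)


def _epochs_from_array(data, rate=500.0, conditions=None):
    n = data.shape[0]
    meta = pd.DataFrame(
        {
            "condition": conditions or ["collision"] * n,
            "correct": [True] * n,
            "subject_id": ["s1"] * n,
            "group": ["experienced"] * n,
        }
    )
    return EpochSet(
        data=data, sample_rate=rate, t_zero_index=0, trial_meta=meta, band="beta"
    )


class TestSelectOrder:
    def test_collapsed_range_returns_that_order(self, rng):
        data = rng.standard_normal((2, 2, 400))
        sel = select_order(_epochs_from_array(data), p_range=(4, 4))
        assert sel.p0 == 4
        assert sel.trace["p"].tolist() == [4]

    def test_ar1_pair_prefers_low_order(self, rng):
        g = synth.GroundTruthGraph(2, edges=((0, 1, 0.4, 1),), self_coeffs=(0.6,))
        data = synth.simulate_var(
            synth.build_var_coefficients(g), 2000, 1.0, rng, n_series=2
        )
        sel = select_order(_epochs_from_array(data), p_range=(1, 5))
        assert sel.p0 in (1, 2)

    def test_empty_selection_rejected(self, rng):
        data = rng.standard_normal((2, 2, 300))
        ep = _epochs_from_array(data, conditions=["non_collision"] * 2)
        with pytest.raises(ValueError, match="empty trial selection"):
            select_order(ep, p_range=(1, 2), n_lead_trials=0, trial_subsample=0.0)


class TestGcCells:
    def test_cells_cover_conditions_and_windows(self, rng):
        data = rng.standard_normal((6, 3, 1500))
        ep = _epochs_from_array(
            data, conditions=["collision"] * 3 + ["non_collision"] * 3
        )
        mats, long = gc_cells(ep, p=3)
        assert len(mats) == 10  # 2 conditions x 5 windows
        assert set(long["window"]) == {f"SW{i}" for i in range(1, 6)}
        assert set(long["condition"]) == {"collision", "non_collision"}
        # one row per ordered pair per cell
        assert len(long) == 10 * 3 * 2
        assert (long["F"] >= 0).all()
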