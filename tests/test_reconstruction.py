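import numpy as np
import pandas as pd
import pytest

from gazefield.encoding import PEGFParams, pegf_gain
from gazefield.reconstruction import (
    EyeGrid,
    GainTrace,
    correlation_at_lag,
    crosscorr_lag,
    estimate_gain,
    fisher_average,
    pegf_basis,
    permutation_pvalue,
    permutation_test,
    reconstruct,
    roi_equalized_correlation,
)


def _pegf_table(rows, roi="V1"):
    df = pd.DataFrame(rows, columns=["x_e0", "y_e0", "sigma_e", "a"])
    df["roi"] = roi
    return df


class TestEstimateGain:
    def test_identity_gives_unit_gain(self):
        rng = np.random.default_rng(0)
        y = rng.random((3, 50))
        gains = estimate_gain(y, y.copy())
        assert np.allclose(gains.g_hat, 1.0, atol=1e-9)

    def test_absolute_clipping(self):
        # one voxel whose ratio swings far outside the absolute bounds
        pred = np.concatenate([np.full(25, 0.2), np.full(25, 0.8)])
        data = pred.copy()
        data[3] = 3.5 * pred[3]
        data[7] = 0.002 * pred[7]
        gains = estimate_gain(data[None], pred[None],
                              trim_percentiles=(0, 100))
        assert gains.g_hat.max() <= 2.5
        assert gains.g_hat.min() >= 0.05

    def test_percentile_winsorization(self):
        # ratio spikes rarer than 1% are pulled down to the 99th percentile
        rng = np.random.default_rng(1)
        pred = rng.uniform(0.3, 1.0, size=400)
        ratio = rng.uniform(0.9, 1.1, size=400)
        ratio[[5, 100, 250]] = 2.0
        gains = estimate_gain((pred * ratio)[None], pred[None])
        assert gains.g_hat[0].max() < 1.8

    def test_constant_prediction_excluded(self):
        y = np.random.default_rng(2).random((2, 30))
        p = np.vstack([y[0], np.ones(30)])
        gains = estimate_gain(y, p)
        assert gains.included[0] and not gains.included[1]


class TestReconstruct:
    def test_matches_bruteforce_two_voxel_toy(self):
        """Scaled-sum field equals a literal per-node evaluation of the
        normalized reconstruction equations, to 1e-10."""
        table = _pegf_table([(2.0, 1.0, 3.0, 0.8), (-3.0, -1.0, 5.0, 0.5)])
        grid = EyeGrid.from_extent((10.0, 6.0), 1.0)
        g_hat = np.array([[1.3, 0.7, 1.0], [0.9, 1.2, 1.0]])
        gains = GainTrace(g_hat, np.ones(2, bool))
        rmap, trace = reconstruct(gains, table, grid, return_map=True)
        X, Y = grid.meshes()
        for t in range(3):
            scaled = np.zeros_like(X)
            unscaled = np.zeros_like(X)
            g_bar = g_hat[:, t].mean()
            for v in range(2):
                p = PEGFParams(*table.iloc[v][["x_e0", "y_e0", "sigma_e",
                                               "a"]])
                field = (p.a * np.exp(-((X - p.x_e0) ** 2 +
                                        (Y - p.y_e0) ** 2)
                                      / (2 * p.sigma_e ** 2)) + 1 - p.a)
                scaled += g_hat[v, t] * field
                unscaled += g_bar * field
            assert np.max(np.abs(rmap.f[t] - scaled / unscaled)) < 1e-10

    def test_equal_gains_flat_field_tie(self):
        table = _pegf_table([(2.0, 0.0, 3.0, 0.8), (-2.0, 0.0, 4.0, 0.5)])
        grid = EyeGrid.from_extent((8.0, 4.0), 1.0)
        gains = GainTrace(np.full((2, 2), 0.7), np.ones(2, bool))
        rmap, trace = reconstruct(gains, table, grid, return_map=True)
        assert np.allclose(rmap.f, 1.0)
        assert trace["tie_flag"].all()
        assert trace["x_hat"].iloc[0] == pytest.approx(0.0)

    def test_gain_rescaling_invariance(self):
        """Scaling all voxel gains at one TR by a common factor leaves the
        normalized field unchanged (the mean gain cancels)."""
        table = _pegf_table([(2.0, 1.0, 3.0, 0.8), (-3.0, -1.0, 5.0, 0.5),
                             (0.0, 0.0, 4.0, 0.9)])
        grid = EyeGrid.from_extent((10.0, 6.0), 0.5)
        g = np.random.default_rng(3).uniform(0.5, 1.5, size=(3, 4))
        r1, _ = reconstruct(GainTrace(g, np.ones(3, bool)), table, grid,
                            return_map=True)
        g2 = g.copy()
        g2[:, 1] *= 7.0
        r2, _ = reconstruct(GainTrace(g2, np.ones(3, bool)), table, grid,
                            return_map=True)
        assert np.allclose(r1.f, r2.f, atol=1e-10)

    def test_dense_population_decodes_trajectory(self):
        """Noise-free gains from a known trajectory through a uniform
        gain-field population yield a near-perfect decoded trace."""
        rng = np.random.default_rng(4)
        n = 400
        table = _pegf_table(np.column_stack([
            rng.uniform(-8, 8, n), rng.uniform(-4, 4, n),
            rng.uniform(2, 6, n), rng.uniform(0.5, 1.0, n)]))
        t = np.linspace(0, 4 * np.pi, 60)
        truth = np.column_stack([6 * np.sin(t), 3 * np.cos(1.7 * t)])
        g = np.stack([pegf_gain(PEGFParams(*row[["x_e0", "y_e0", "sigma_e",
                                                 "a"]]), truth)
                      for _, row in table.iterrows()])
        _, trace = reconstruct(GainTrace(g, np.ones(n, bool)), table,
                               EyeGrid.from_extent((20.0, 10.0), 0.25))
        r = np.corrcoef(trace["x_hat"], truth[:, 0])[0, 1]
        assert r > 0.95

    def test_readout_precision_grows_with_voxel_count(self):
        """Decoding fidelity improves with population size: the trace
        correlation rises and the across-draw dispersion shrinks.  (The
        absolute error saturates at the readout's central-tendency bias, so
        correlation, not raw error, is the precision measure here.)"""
        rng = np.random.default_rng(5)
        t = np.linspace(0, 4 * np.pi, 40)
        truth = np.column_stack([6 * np.sin(t), 2 * np.cos(t)])
        med_r, spread = [], []
        for n in (10, 100, 1000):
            per_draw = []
            for _ in range(8):
                table = _pegf_table(np.column_stack([
                    rng.uniform(-8, 8, n), rng.uniform(-4, 4, n),
                    rng.uniform(2, 6, n), rng.uniform(0.5, 1.0, n)]))
                g = np.stack([pegf_gain(PEGFParams(*row[["x_e0", "y_e0",
                                                         "sigma_e", "a"]]),
                                        truth)
                              for _, row in table.iterrows()])
                _, trace = reconstruct(GainTrace(g, np.ones(n, bool)),
                                       table,
                                       EyeGrid.from_extent((20.0, 10.0),
                                                           0.25))
                per_draw.append(np.corrcoef(trace["x_hat"],
                                            truth[:, 0])[0, 1])
            med_r.append(np.median(per_draw))
            spread.append(np.std(per_draw))
        assert med_r[0] < med_r[1] < med_r[2]
        assert spread[0] > spread[1] > spread[2]

    def test_too_few_voxels(self):
        table = _pegf_table([(0.0, 0.0, 3.0, 0.5)])
        gains = GainTrace(np.ones((1, 3)), np.ones(1, bool))
        with pytest.raises(ValueError):
            reconstruct(gains, table, EyeGrid.from_extent((4, 4), 1.0))


class TestCrosscorrLag:
    def test_identity(self):
        xy = np.random.default_rng(6).random((50, 2))
        best, tab = crosscorr_lag(xy, xy)
        assert best == 0
        assert tab.loc[tab["lag"] == 0, "r_x"].iloc[0] == pytest.approx(1.0)

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(7)
        truth = rng.random((80, 2))
        recon = np.roll(truth, 2, axis=0)   # reconstruction delayed by 2
        best, _ = crosscorr_lag(recon, truth)
        assert best == 2

    def test_lag_count(self):
        xy = np.random.default_rng(8).random((50, 2))
        _, tab = crosscorr_lag(xy, xy, max_lag=10)
        assert len(tab) == 21

    def test_zero_variance_truth(self):
        xy = np.random.default_rng(9).random((20, 2))
        with pytest.raises(ValueError):
            crosscorr_lag(xy, np.ones((20, 2)))


class TestPermutation:
    @pytest.mark.parametrize("null,obs,expected", [
        ([0.1, 0.2, 0.3], 0.5, 0.0),
        ([0.4, 0.4, 0.4], 0.4, 1.0),
        ([0.1, 0.2, 0.3, 0.4], 0.25, 0.5),
    ])
    def test_pvalue_rule(self, null, obs, expected):
        assert permutation_pvalue(np.array(null), obs) == expected

    def test_permutation_destroys_reconstruction(self):
        rng = np.random.default_rng(10)
        n = 150
        table = _pegf_table(np.column_stack([
            rng.uniform(-8, 8, n), rng.uniform(-4, 4, n),
            rng.uniform(2, 6, n), rng.uniform(0.5, 1.0, n)]))
        t = np.linspace(0, 4 * np.pi, 60)
        truth = np.column_stack([6 * np.sin(t), 3 * np.cos(1.3 * t)])
        g = np.stack([pegf_gain(PEGFParams(*row[["x_e0", "y_e0", "sigma_e",
                                                 "a"]]), truth)
                      for _, row in table.iterrows()])
        gains = GainTrace(g, np.ones(n, bool))
        grid = EyeGrid.from_extent((20.0, 10.0), 0.5)
        res = permutation_test(gains, table, grid, truth, n_perm=50,
                               rng_seed=0, lag=0)
        assert res["p_x"] <= 0.02
        assert np.median(res["null_r"][:, 0]) < res["observed_r"][0]

    def test_nperm_validated(self):
        gains = GainTrace(np.ones((2, 3)), np.ones(2, bool))
        table = _pegf_table([(0, 0, 3, 0.5), (1, 0, 3, 0.5)])
        with pytest.raises(ValueError):
            permutation_test(gains, table, EyeGrid.from_extent((4, 4), 1),
                             np.zeros((3, 2)), n_perm=0)


class TestRoiEqualized:
    def test_fisher_average_examples(self):
        assert fisher_average(0.0, 0.0) == 0.0
        assert fisher_average(0.5, 0.5) == pytest.approx(0.5493061443)

    def test_identical_rois_indistinguishable(self):
        rng = np.random.default_rng(11)
        n = 40
        params = np.column_stack([rng.uniform(-8, 8, n),
                                  rng.uniform(-4, 4, n),
                                  rng.uniform(2, 6, n),
                                  rng.uniform(0.5, 1.0, n)])
        table = pd.concat([_pegf_table(params, "A"),
                           _pegf_table(params, "B")], ignore_index=True)
        t = np.linspace(0, 4 * np.pi, 40)
        truth = np.column_stack([6 * np.sin(t), 2 * np.cos(t)])
        g1 = np.stack([pegf_gain(PEGFParams(*row[["x_e0", "y_e0", "sigma_e",
                                                  "a"]]), truth)
                       for _, row in table.iterrows()])
        gains = GainTrace(g1, np.ones(2 * n, bool))
        out = roi_equalized_correlation(table, gains, truth,
                                        EyeGrid.from_extent((20, 10), 0.5),
                                        n_boot=20, min_voxels=20,
                                        rng_seed=0, lag=0)
        med = out.groupby("roi")["fisher_avg"].median()
        assert abs(med["A"] - med["B"]) < 0.2

    def test_small_roi_excluded_with_warning(self):
        rng = np.random.default_rng(12)
        big = _pegf_table(np.column_stack([
            rng.uniform(-8, 8, 30), rng.uniform(-4, 4, 30),
            rng.uniform(2, 6, 30), rng.uniform(0.5, 1.0, 30)]), "big")
        small = _pegf_table([(0, 0, 3, 0.5)] * 3, "small")
        table = pd.concat([big, small], ignore_index=True)
        t = np.linspace(0, 4 * np.pi, 30)
        truth = np.column_stack([6 * np.sin(t), 2 * np.cos(t)])
        g = np.stack([pegf_gain(PEGFParams(*row[["x_e0", "y_e0", "sigma_e",
                                                 "a"]]), truth)
                      for _, row in table.iterrows()])
        gains = GainTrace(g, np.ones(33, bool))
        with pytest.warns(UserWarning, match="small"):
            out = roi_equalized_correlation(
                table, gains, truth, EyeGrid.from_extent((20, 10), 1.0),
                n_boot=5, min_voxels=20, rng_seed=0, lag=0)
        assert set(out["roi"]) == {"big"}
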