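import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazefield.encoding import (
    HRFParams,
    PEGFParams,
    PRFParams,
    pegf_gain,
    predict_bold,
)
from gazefield.fitting import (
    K_PRF_PEGF,
    PegfGridEngine,
    build_pegf_grid,
    build_prf_grid,
    fit_pegf,
    fit_prf,
    ols_scale,
    optimize_stim_config,
    prf_grid_predictions,
    r2_adjusted,
    select_voxels,
)
from gazefield.stimulus import (
    RenderConfig,
    render_retinotopic_movie,
    target_trace,
)


class TestGrids:
    def test_default_sizes(self):
        assert build_prf_grid().n_combinations == 5400
        assert build_pegf_grid().n_combinations == 3888

    def test_single_member_grid(self):
        g = build_prf_grid({"x_r0": [0], "y_r0": [0], "sigma_r": [1],
                            "n": [1]})
        assert g.n_combinations == 1
        assert len(g.combinations()) == 1

    def test_count_equals_axis_product(self, small_pegf_grid):
        combos = small_pegf_grid.combinations()
        assert len(combos) == np.prod([len(v) for _, v
                                       in small_pegf_grid.axes])

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            build_prf_grid({"x_r0": []})


class TestOlsScale:
    def test_exact_affine_relation(self):
        p = np.arange(10.0)
        fit = ols_scale(p, 2.0 * p + 3.0)
        assert fit.scale == pytest.approx(2.0)
        assert fit.offset == pytest.approx(3.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_orthogonal_prediction(self):
        p = np.array([1.0, -1.0] * 5)
        y = np.array([1.0, 1.0, -1.0, -1.0] * 2 + [1.0, 1.0])
        fit = ols_scale(p, y)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        p = np.array([0.3, 1.2, -0.7, 2.4, 0.9])
        y = np.array([1.1, 2.0, 0.2, 3.5, 1.4])
        A = np.column_stack([p, np.ones(5)])
        slope, offset = np.linalg.lstsq(A, y, rcond=None)[0]
        fit = ols_scale(p, y)
        assert fit.scale == pytest.approx(slope)
        assert fit.offset == pytest.approx(offset)

    def test_degenerate_prediction(self):
        fit = ols_scale(np.ones(6), np.arange(6.0))
        assert fit.degenerate and fit.r2 == 0.0


class TestR2Adjusted:
    @pytest.mark.parametrize("r2,n,k,expected", [
        (1.0, 100, 4, 1.0),
        (0.5, 179, 4, 0.4885057471264368),
        (0.0, 20, 4, -0.2666666666666666),
    ])
    def test_examples(self, r2, n, k, expected):
        assert r2_adjusted(r2, n, k) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(r2=st.floats(0.0, 0.999), n=st.integers(20, 500))
    def test_strictly_decreasing_in_k(self, r2, n):
        vals = [r2_adjusted(r2, n, k) for k in range(0, 10)]
        assert np.all(np.diff(vals) < 1e-15)

    def test_invalid_dof(self):
        with pytest.raises(ValueError):
            r2_adjusted(0.5, 5, 4)


@pytest.fixture(scope="module")
def bar_movie(small_bar_design):
    return render_retinotopic_movie(small_bar_design, None,
                                    RenderConfig(ppd=3.0))


class TestFitPrf:
    def test_noiseless_exact_recovery(self, bar_movie, small_prf_grid):
        combos = small_prf_grid.combinations()
        picks = [3, 17, 30]
        hrf = HRFParams(dt_s=1.0 / 6.0)
        bold = np.stack([
            2.0 * predict_bold(PRFParams(*combos.iloc[i]), None, bar_movie,
                               None, hrf, 2.0) + 1.0
            for i in picks])
        fits = fit_prf(bold, bar_movie, small_prf_grid, hrf)
        for row, i in zip(fits.itertuples(), picks):
            expect = combos.iloc[i]
            assert (row.x_r0, row.y_r0, row.sigma_r, row.n) == \
                tuple(expect)
            assert row.r2 == pytest.approx(1.0)
            assert row.scale == pytest.approx(2.0)

    def test_constant_series_degenerate(self, bar_movie, small_prf_grid):
        bold = np.full((1, bar_movie.n_frames // 12), 3.0)
        fits = fit_prf(bold, bar_movie, small_prf_grid)
        assert fits["degenerate"].iloc[0]
        assert fits["r2"].iloc[0] == 0.0

    def test_argmax_matches_naive_loop(self, bar_movie, small_prf_grid):
        """Grid-search oracle: an explicit per-member loop finds the same
        best member as the vectorized path, on randomly generated voxels."""
        rng = np.random.default_rng(0)
        preds = prf_grid_predictions(bar_movie, small_prf_grid)
        n_tr = preds.shape[1]
        bold = rng.normal(size=(20, n_tr))
        fits = fit_prf(bold, bar_movie, small_prf_grid)
        combos = small_prf_grid.combinations()
        for v in range(20):
            best_naive, r2_naive = 0, -np.inf
            for i in range(len(combos)):
                r2 = ols_scale(preds[i].astype(float), bold[v]).r2
                if r2 > r2_naive:
                    best_naive, r2_naive = i, r2
            assert fits["x_r0"].iloc[v] == combos["x_r0"].iloc[best_naive]
            assert fits["sigma_r"].iloc[v] == \
                combos["sigma_r"].iloc[best_naive]
            assert fits["r2"].iloc[v] == pytest.approx(r2_naive)


@pytest.fixture(scope="module")
def eye_movie(small_eye_design, small_scene, small_render_cfg):
    return render_retinotopic_movie(small_eye_design, small_scene,
                                    small_render_cfg)


@pytest.fixture(scope="module")
def eye_trace(small_eye_design):
    return target_trace(small_eye_design, 6.0)


def _prf_table(rows):
    return pd.DataFrame(rows, columns=["x_r0", "y_r0", "sigma_r", "n"]) \
        .assign(voxel_id=np.arange(len(rows)))


class TestFitPegf:
    def test_noiseless_exact_recovery(self, eye_movie, eye_trace,
                                      small_pegf_grid):
        prfs = _prf_table([(0.0, 0.0, 1.0, 0.5), (2.0, 1.0, 1.5, 1.0)])
        true = [PEGFParams(3.0, 0.0, 4.0, 0.6), PEGFParams(-3.0, 0.0, 8.0,
                                                           0.3)]
        hrf = HRFParams(dt_s=1.0 / 6.0)
        bold = np.stack([
            predict_bold(PRFParams(*prfs.iloc[v][:4]), true[v], eye_movie,
                         eye_trace, hrf, 2.0)
            for v in range(2)])
        fits = fit_pegf(bold, prfs, eye_movie, eye_trace, small_pegf_grid,
                        hrf)
        for v, t in enumerate(true):
            assert fits["x_e0"].iloc[v] == t.x_e0
            assert fits["sigma_e"].iloc[v] == t.sigma_e
            assert fits["a"].iloc[v] == t.a
            assert fits["r2"].iloc[v] == pytest.approx(1.0)

    def test_feasibility_restricts_sigma(self, eye_movie, eye_trace,
                                         small_pegf_grid):
        prfs = _prf_table([(0.0, 0.0, 5.0, 1.0)])  # wider than most sigma_e
        rng = np.random.default_rng(1)
        bold = rng.normal(size=(1, 60))
        fits = fit_pegf(bold, prfs, eye_movie, eye_trace, small_pegf_grid)
        assert fits["sigma_e"].iloc[0] > 5.0

    def test_no_feasible_member_flagged(self, eye_movie, eye_trace,
                                        small_pegf_grid):
        prfs = _prf_table([(0.0, 0.0, 9.0, 1.0)])
        bold = np.random.default_rng(2).normal(size=(1, 60))
        fits = fit_pegf(bold, prfs, eye_movie, eye_trace, small_pegf_grid)
        assert not fits["feasible"].iloc[0]
        assert np.isnan(fits["x_e0"].iloc[0])

    def test_argmax_matches_naive_loop(self, eye_movie, eye_trace,
                                       small_pegf_grid):
        prfs = _prf_table([(0.0, 0.0, 1.0, 0.5)])
        engine = PegfGridEngine(eye_movie, eye_trace, prfs, small_pegf_grid)
        rng = np.random.default_rng(3)
        bold = rng.normal(size=(1, 60))
        fits = engine.fit(bold)
        combos = small_pegf_grid.combinations()
        preds = engine.predictions(0)
        best, r2b = None, -np.inf
        for i in range(len(combos)):
            if combos["sigma_e"].iloc[i] <= 1.0:
                continue
            r2 = ols_scale(preds[i], bold[0]).r2
            if r2 > r2b:
                best, r2b = i, r2
        assert fits["x_e0"].iloc[0] == combos["x_e0"].iloc[best]
        assert fits["r2"].iloc[0] == pytest.approx(r2b)

    def test_permuted_trace_degrades_fit(self, eye_movie, eye_trace,
                                         small_pegf_grid):
        rng = np.random.default_rng(4)
        prfs = _prf_table([(0.0, 0.0, 1.0, 0.5)] * 5)
        hrf = HRFParams(dt_s=1.0 / 6.0)
        bold = []
        for v in range(5):
            pegf = PEGFParams(rng.uniform(-4, 4), rng.uniform(-2, 2),
                              rng.uniform(2, 6), rng.uniform(0.4, 1.0))
            y = predict_bold(PRFParams(0, 0, 1.0, 0.5), pegf, eye_movie,
                             eye_trace, hrf, 2.0)
            bold.append(y + rng.normal(0, 0.02 * y.std(), size=len(y)))
        bold = np.stack(bold)
        good = fit_pegf(bold, prfs, eye_movie, eye_trace, small_pegf_grid,
                        hrf)
        perm = rng.permutation(len(eye_trace))
        bad = fit_pegf(bold, prfs, eye_movie, eye_trace[perm],
                       small_pegf_grid, hrf)
        assert good["r2"].median() > bad["r2"].median()


class TestSelectVoxels:
    def _tables(self, rows_a, rows_b):
        cols = ["r2_prf", "r2_pegf", "r2_adj_prf", "r2_adj_pegf"]
        return (pd.DataFrame(rows_a, columns=cols),
                pd.DataFrame(rows_b, columns=cols))

    def test_visual_inclusion(self):
        a, b = self._tables([(0.2, 0.25, 0.18, 0.20)],
                            [(0.15, 0.16, 0.13, 0.14)])
        assert select_voxels(a, b, "visual").iloc[0]

    def test_visual_rejects_weak_version_b(self):
        a, b = self._tables([(0.2, 0.25, 0.18, 0.20)],
                            [(0.09, 0.16, 0.13, 0.14)])
        assert not select_voxels(a, b, "visual").iloc[0]

    def test_control_inclusion(self):
        a, b = self._tables([(0.05, 0.05, 0.0, 0.0)],
                            [(0.05, 0.05, 0.0, 0.0)])
        assert select_voxels(a, b, "control").iloc[0]


@pytest.fixture(scope="module")
def sweep_setup(small_eye_design, small_scene):
    rng = np.random.default_rng(5)
    hrf = HRFParams(dt_s=1.0 / 6.0)
    rows = []
    prfs = []
    # synthesize voxels under the (c_fix=0, c_post=1) representation
    movie = render_retinotopic_movie(
        small_eye_design, small_scene,
        RenderConfig(ppd=2.0, c_fix=0.0, c_post=1.0, d_post_frames=2))
    for v in range(12):
        prf = PRFParams(rng.uniform(-6, 6), rng.uniform(-4, 4),
                        rng.uniform(0.8, 2.0), 0.5)
        y = predict_bold(prf, None, movie, None, hrf, 2.0)
        rows.append(y + rng.normal(0, 0.01 * (y.std() + 1e-9), size=len(y)))
        prfs.append((prf.x_r0, prf.y_r0, prf.sigma_r, prf.n))
    table = _prf_table(prfs)
    table["r2"] = rng.uniform(0.3, 0.9, size=len(table))
    return np.stack(rows), table


class TestOptimizeStimConfig:
    def test_counts_and_self_consistency(self, sweep_setup, small_eye_design,
                                         small_scene):
        bold, prf_fits = sweep_setup
        tab = optimize_stim_config(bold, prf_fits, small_eye_design,
                                   small_scene,
                                   render_cfg=RenderConfig(ppd=2.0))
        contrast = tab[tab["phase"] == "contrast"]
        assert len(contrast) == 49
        assert len(tab[tab["phase"] == "duration"]) == 10
        best = contrast.iloc[contrast["median_r2"].idxmax()]
        assert best["c_fix"] == 0.0
        assert best["c_post"] == 1.0

    def test_deterministic(self, sweep_setup, small_eye_design, small_scene):
        bold, prf_fits = sweep_setup
        args = (bold, prf_fits, small_eye_design, small_scene)
        t1 = optimize_stim_config(*args, render_cfg=RenderConfig(ppd=2.0))
        t2 = optimize_stim_config(*args, render_cfg=RenderConfig(ppd=2.0))
        pd.testing.assert_frame_equal(t1, t2)
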