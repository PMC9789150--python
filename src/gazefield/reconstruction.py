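"""Decode eye position over time from BOLD data via fitted gain fields.

The decoder inverts the forward model without ever seeing eye positions:
dividing each voxel's measured series by its (scaled) pRF-only prediction
yields a per-TR gain estimate; each voxel's fitted pEGF, scaled by that
gain, votes for the eye positions compatible with it.  The normalized
scaled sum

    f(x, y, t) = sum_i ghat_i(t) pEGF_i(x, y) / [ gbar(t) sum_i pEGF_i(x, y) ]

peaks at the most likely gaze position; the per-TR argmax is the decoded
eye trace.  Because the gain is read off the HRF-convolved signal, the
decoded trace lags the true one by a small number of TRs; the lag is
assessed by cross-correlation over integer lags and the reconstruction is
evaluated at the best (or a fixed) lag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TRIM_PERCENTILES = (1.0, 99.0)
DEFAULT_ABS_BOUNDS = (0.05, 2.5)
DENOMINATOR_FLOOR = 1e-3


@dataclass
class GainTrace:
    """Per-voxel, per-TR gain estimates and their across-voxel mean."""

    g_hat: np.ndarray          # (n_voxels, n_tr), trimmed and clipped
    included: np.ndarray       # bool per voxel (False: degenerate prediction)
    abs_bounds: tuple[float, float] = DEFAULT_ABS_BOUNDS

    @property
    def g_bar(self) -> np.ndarray:
        return self.g_hat[self.included].mean(axis=0)

    @property
    def n_tr(self) -> int:
        return self.g_hat.shape[1]


@dataclass(frozen=True)
class EyeGrid:
    """Uniform readout grid over the screen extent (deg)."""

    x_e: np.ndarray
    y_e: np.ndarray

    @classmethod
    def from_extent(cls, fov: tuple[float, float] = (40.0, 22.0),
                    resolution: float = 0.25) -> "EyeGrid":
        w, h = fov
        nx = int(round(w / resolution)) + 1
        ny = int(round(h / resolution)) + 1
        return cls(np.linspace(-w / 2, w / 2, nx),
                   np.linspace(-h / 2, h / 2, ny))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.y_e), len(self.x_e))

    def meshes(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_e, self.y_e)


def _minmax01(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def estimate_gain(bold_b: np.ndarray, prfonly_pred_b: np.ndarray,
                  trim_percentiles=DEFAULT_TRIM_PERCENTILES,
                  abs_bounds=DEFAULT_ABS_BOUNDS) -> GainTrace:
    """Per-voxel gain over time: data divided by the scaled pRF-only prediction.

    Both series are first bounded to [0, 1] (per-voxel min-max over the
    run); the prediction is then linearly scaled to the data by OLS, the
    ratio is winsorized at the per-voxel trim percentiles and clipped to
    ``abs_bounds``.  Voxels with a constant prediction are flagged excluded.
    """
    from gazefield.fitting import ols_scale

    y = np.asarray(bold_b, dtype=float)
    p = np.asarray(prfonly_pred_b, dtype=float)
    if y.shape != p.shape:
        raise ValueError("data and prediction shapes differ")
    n_vox, n_tr = y.shape
    g = np.ones((n_vox, n_tr))
    included = np.ones(n_vox, dtype=bool)
    lo_p, hi_p = trim_percentiles
    for v in range(n_vox):
        if np.ptp(p[v]) <= 0 or np.ptp(y[v]) <= 0:
            included[v] = False
            continue
        y01 = _minmax01(y[v])
        p01 = _minmax01(p[v])
        fit = ols_scale(p01, y01)
        if fit.degenerate:
            included[v] = False
            continue
        # floor both series so near-zero stretches divide to ~1, not 0
        den = np.maximum(fit.scaled, DENOMINATOR_FLOOR)
        gv = np.maximum(y01, DENOMINATOR_FLOOR) / den
        qlo, qhi = np.percentile(gv, [lo_p, hi_p])
        gv = np.clip(gv, qlo, qhi)
        g[v] = np.clip(gv, abs_bounds[0], abs_bounds[1])
    if not included.any():
        raise ValueError("no voxel with a usable pRF-only prediction")
    return GainTrace(g, included, tuple(abs_bounds))


@dataclass
class ReconMap:
    """Normalized scaled-sum field per TR (f == 1 wherever gains are equal)."""

    f: np.ndarray              # (n_tr, ny, nx)
    grid: EyeGrid


def pegf_basis(pegf_table: pd.DataFrame, grid: EyeGrid,
               dtype=np.float64) -> np.ndarray:
    """Stack of gain fields on the readout grid; (n_voxels, ny * nx)."""
    X, Y = grid.meshes()
    x = X.ravel()[None, :]
    y = Y.ravel()[None, :]
    x0 = pegf_table["x_e0"].to_numpy()[:, None]
    y0 = pegf_table["y_e0"].to_numpy()[:, None]
    sig = pegf_table["sigma_e"].to_numpy()[:, None]
    a = pegf_table["a"].to_numpy()[:, None]
    return (a * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sig ** 2))
            + (1.0 - a)).astype(dtype)


def _readout(f_rows: np.ndarray, grid: EyeGrid,
             rtol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Per-TR global argmax of the field; exact ties -> centroid + flag."""
    X, Y = grid.meshes()
    xf, yf = X.ravel(), Y.ravel()
    m = f_rows.max(axis=1)
    tol = rtol * np.maximum(np.abs(m), 1.0)
    at_max = f_rows >= (m - tol)[:, None]
    counts = at_max.sum(axis=1)
    ties = counts > 1
    j = np.argmax(f_rows, axis=1)
    xy = np.column_stack([xf[j], yf[j]])
    for t in np.flatnonzero(ties):
        sel = at_max[t]
        xy[t] = (xf[sel].mean(), yf[sel].mean())
    return xy, ties


def reconstruct(gains: GainTrace, pegf_table: pd.DataFrame,
                eye_grid: EyeGrid | None = None,
                return_map: bool = False) -> tuple[ReconMap | None, pd.DataFrame]:
    """Normalized scaled-sum reconstruction of the eye trace.

    Only voxels flagged included in ``gains`` contribute.  Returns the
    decoded positions per TR (columns ``x_hat``, ``y_hat``, ``tie_flag``)
    and, optionally, the full per-TR field.
    """
    grid = eye_grid or EyeGrid.from_extent()
    table = pegf_table.reset_index(drop=True)[gains.included]
    if len(table) < 2:
        raise ValueError("need at least 2 voxels with usable gains")
    PE = pegf_basis(table, grid)
    base = PE.sum(axis=0).astype(np.float64)       # sum of all pEGFs
    if np.any(base <= 0):
        raise ValueError("degenerate pEGF population: zero unscaled field")
    g = gains.g_hat[gains.included]
    g_bar = g.mean(axis=0)
    scaled = g.T @ PE                              # (n_tr, nodes)
    f = scaled / (g_bar[:, None] * base[None, :])
    xy, ties = _readout(f, grid)
    trace = pd.DataFrame({"tr_index": np.arange(gains.n_tr),
                          "x_hat": xy[:, 0], "y_hat": xy[:, 1],
                          "tie_flag": ties})
    rmap = ReconMap(f.reshape(-1, *grid.shape), grid) if return_map else None
    return rmap, trace


def _lagged_corr(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Pearson r of a[t] against b[t - lag] (positive lag: a lags b)."""
    n = len(a)
    if lag >= 0:
        x, y = a[lag:], b[: n - lag]
    else:
        x, y = a[: n + lag], b[-lag:]
    if np.std(x) <= 0 or np.std(y) <= 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def crosscorr_lag(recon_xy: np.ndarray, truth_xy: np.ndarray,
                  max_lag: int = 10) -> tuple[int, pd.DataFrame]:
    """Component-wise Pearson r over integer lags in [-max_lag, max_lag].

    Positive lags shift the reconstruction backwards (the reconstruction
    lagging the truth).  The best lag maximizes the across-component median
    correlation.
    """
    recon_xy = np.asarray(recon_xy, dtype=float)
    truth_xy = np.asarray(truth_xy, dtype=float)
    if recon_xy.shape != truth_xy.shape:
        raise ValueError("traces must have equal shapes")
    if np.ptp(truth_xy[:, 0]) <= 0 and np.ptp(truth_xy[:, 1]) <= 0:
        raise ValueError("zero-variance truth trace")
    lags = np.arange(-max_lag, max_lag + 1)
    rows = [dict(lag=int(k),
                 r_x=_lagged_corr(recon_xy[:, 0], truth_xy[:, 0], int(k)),
                 r_y=_lagged_corr(recon_xy[:, 1], truth_xy[:, 1], int(k)))
            for k in lags]
    tab = pd.DataFrame(rows)
    score = np.nanmedian(tab[["r_x", "r_y"]].to_numpy(), axis=1)
    best = int(tab["lag"].iloc[int(np.nanargmax(score))])
    return best, tab


def correlation_at_lag(recon_xy: np.ndarray, truth_xy: np.ndarray,
                       lag: int = 1) -> tuple[float, float]:
    """(r_x, r_y) at a fixed assessment lag."""
    return (_lagged_corr(np.asarray(recon_xy)[:, 0],
                         np.asarray(truth_xy)[:, 0], lag),
            _lagged_corr(np.asarray(recon_xy)[:, 1],
                         np.asarray(truth_xy)[:, 1], lag))


def permutation_pvalue(null_r: np.ndarray, observed_r: float) -> float:
    """Proportion of the null distribution >= the observed correlation."""
    null_r = np.asarray(null_r, dtype=float)
    return float(np.mean(null_r >= observed_r))


def permutation_test(gains: GainTrace, pegf_table: pd.DataFrame,
                     eye_grid: EyeGrid, truth_xy: np.ndarray,
                     n_perm: int = 1000, rng_seed: int = 0,
                     lag: int = 1) -> dict:
    """Shuffle the voxel <-> pEGF assignment and rebuild the null.

    Each iteration permutes which voxel owns which fitted gain field (the
    gains stay with their voxels), reconstructs, and correlates with the
    true trace at the assessment lag.  p per component is the proportion of
    null correlations >= the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grid = eye_grid or EyeGrid.from_extent()
    table = pegf_table.reset_index(drop=True)[gains.included]
    PE = pegf_basis(table, grid, dtype=np.float32)  # speed over precision
    base = PE.sum(axis=0).astype(np.float64)
    g = gains.g_hat[gains.included].astype(np.float32)
    g_bar = g.mean(axis=0).astype(np.float64)
    denom = (g_bar[:, None] * base[None, :])

    def run(PE_rows):
        f = (g.T @ PE_rows) / denom
        xy, _ = _readout(f, grid)
        return correlation_at_lag(xy, truth_xy, lag)

    obs = run(PE)
    rng = np.random.default_rng(rng_seed)
    null = np.empty((n_perm, 2))
    for i in range(n_perm):
        null[i] = run(PE[rng.permutation(len(PE))])
    with np.errstate(invalid="ignore"):
        obs_comb = fisher_average(*np.clip(obs, -0.999999, 0.999999))
        null_comb = np.arctanh(np.clip(null, -0.999999,
                                       0.999999)).mean(axis=1)
    return dict(observed_r=obs, null_r=null,
                p_x=permutation_pvalue(null[:, 0], obs[0]),
                p_y=permutation_pvalue(null[:, 1], obs[1]),
                p_combined=permutation_pvalue(null_comb, obs_comb))


def fisher_average(r_x: float, r_y: float) -> float:
    """(arctanh(r_x) + arctanh(r_y)) / 2 — the combined reconstruction score."""
    return float((np.arctanh(r_x) + np.arctanh(r_y)) / 2.0)


def roi_equalized_correlation(pegf_table: pd.DataFrame, gains: GainTrace,
                              truth_xy: np.ndarray,
                              eye_grid: EyeGrid | None = None,
                              n_boot: int = 1000, min_voxels: int = 150,
                              frac: float = 0.9, rng_seed: int = 0,
                              lag: int = 1) -> pd.DataFrame:
    """Bootstrap a fixed voxel count per ROI and Fisher-average (r_x, r_y).

    The drawn count is max(min_voxels, frac * smallest eligible ROI); ROIs
    with fewer eligible voxels than ``min_voxels`` are dropped with a
    warning.  Returns one row per (roi, draw).
    """
    grid = eye_grid or EyeGrid.from_extent()
    table = pegf_table.reset_index(drop=True)
    table = table[gains.included].reset_index(drop=True)
    g_all = gains.g_hat[gains.included]
    sizes = table.groupby("roi").size()
    eligible = sizes[sizes >= min_voxels]
    for roi in sizes.index.difference(eligible.index):
        warnings.warn(f"ROI {roi!r} has {sizes[roi]} voxels "
                      f"(< {min_voxels}); excluded")
    if eligible.empty:
        raise ValueError("no ROI meets the minimum voxel count")
    count = max(min_voxels, int(np.floor(frac * eligible.min())))
    count = min(count, int(eligible.min()))
    rng = np.random.default_rng(rng_seed)
    rows = []
    for roi in eligible.index:
        idx = np.flatnonzero((table["roi"] == roi).to_numpy())
        PE_roi = pegf_basis(table.iloc[idx], grid, dtype=np.float32)
        g_roi = g_all[idx].astype(np.float32)
        for b in range(n_boot):
            take = rng.choice(len(idx), size=count, replace=False)
            PE = PE_roi[take]
            base = PE.sum(axis=0).astype(np.float64)
            g = g_roi[take]
            g_bar = g.mean(axis=0).astype(np.float64)
            f = (g.T @ PE) / (g_bar[:, None] * base[None, :])
            xy, _ = _readout(f, grid)
            r_x, r_y = correlation_at_lag(xy, truth_xy, lag)
            rows.append(dict(roi=roi, draw=b, r_x=r_x, r_y=r_y,
                             fisher_avg=fisher_average(r_x, r_y)))
    return pd.DataFrame(rows)
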