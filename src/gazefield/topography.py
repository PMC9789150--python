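"""Distributional analysis of fitted gain-field centers over the visual field.

Groups fitted voxels by pRF eccentricity and visual hemifield, summarizes
the horizontal gain-field center (X0) per bin, and fits least-squares lines
of median X0 on eccentricity per hemifield.  A contralateral-to-ipsilateral
inversion shows up as opposite-sign slopes in the two hemifields whose
bootstrap confidence intervals exclude zero; the eccentricity where each
fitted line crosses zero estimates where the shift happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

REQUIRED = ("x_r0", "y_r0", "x_e0", "y_e0", "r2")


def _prepare(fits: pd.DataFrame, selection: str) -> pd.DataFrame:
    for col in REQUIRED:
        if col not in fits:
            raise ValueError(f"fits table lacks column {col!r}")
    df = fits.copy()
    if "roi" not in df:
        df["roi"] = "all"
    if selection == "best-half":
        thresh = df.groupby("roi")["r2"].transform("median")
        df = df[df["r2"] >= thresh].reset_index(drop=True)
    elif selection != "all":
        raise ValueError("selection must be 'best-half' or 'all'")
    df["eccentricity"] = np.hypot(df["x_r0"], df["y_r0"])
    # x_r0 == 0 voxels go to the right hemifield (deterministic, flagged)
    on_meridian = df["x_r0"] == 0
    if on_meridian.any():
        logger.info("%d voxels on the vertical meridian assigned to the "
                    "right hemifield", int(on_meridian.sum()))
    df["hemifield"] = np.where(df["x_r0"] < 0, "L", "R")
    df["meridian_flag"] = on_meridian
    return df


def bin_by_eccentricity(fits: pd.DataFrame, bin_width: float = 1.0,
                        max_ecc: float = 10.0,
                        selection: str = "best-half") -> pd.DataFrame:
    """Per (roi, hemifield, eccentricity bin) medians of gain-field centers.

    The best half of voxels per ROI (by pRF x pEGF variance explained)
    enters the table; empty bins are kept with ``n_voxels = 0``.
    """
    df = _prepare(fits, selection)
    edges = np.arange(0.0, max_ecc + bin_width / 2, bin_width)
    rows = []
    for (roi, hemi), g in df.groupby(["roi", "hemifield"]):
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = g[(g["eccentricity"] >= lo) & (g["eccentricity"] < hi)]
            rows.append(dict(
                roi=roi, hemifield=hemi, bin_center_deg=(lo + hi) / 2,
                n_voxels=len(sel),
                median_x0=float(sel["x_e0"].median()) if len(sel) else np.nan,
                median_y0=float(sel["y_e0"].median()) if len(sel) else np.nan,
                mean_x0=float(sel["x_e0"].mean()) if len(sel) else np.nan))
    return pd.DataFrame(rows)


def laterality_lines(table: pd.DataFrame) -> pd.DataFrame:
    """Weighted least-squares line of median X0 on bin eccentricity, per
    (roi, hemifield); weights are the per-bin voxel counts.

    The crossing eccentricity is where the fitted line changes sign
    (NaN for a flat line or a crossing outside the binned range).
    """
    rows = []
    for (roi, hemi), g in table.groupby(["roi", "hemifield"]):
        g = g[(g["n_voxels"] > 0) & np.isfinite(g["median_x0"])]
        if len(g) < 2:
            raise ValueError(f"need >= 2 populated bins for {roi}/{hemi}")
        slope, intercept = np.polyfit(g["bin_center_deg"], g["median_x0"],
                                      1, w=g["n_voxels"].to_numpy(float))
        if slope != 0:
            crossing = -intercept / slope
            if not (g["bin_center_deg"].min() - 1
                    <= crossing <= g["bin_center_deg"].max() + 1):
                crossing = np.nan
        else:
            crossing = np.nan
        rows.append(dict(roi=roi, hemifield=hemi, slope=float(slope),
                         intercept=float(intercept),
                         crossing_ecc=float(crossing)))
    return pd.DataFrame(rows)


def inversion_statistic(fits: pd.DataFrame, bin_width: float = 1.0,
                        max_ecc: float = 10.0, n_boot: int = 500,
                        rng_seed: int = 0,
                        selection: str = "best-half") -> pd.DataFrame:
    """Per-ROI test for a contra-to-ipsilateral inversion of X0 with
    eccentricity.

    Bootstraps voxels within each (roi, hemifield), refits the laterality
    line, and reports slope signs, percentile CIs, and crossing
    eccentricities.  ``inversion_present`` requires both hemifield slope
    CIs to exclude zero with opposite signs.
    """
    df = _prepare(fits, selection)
    if df["hemifield"].nunique() < 2:
        raise ValueError("both hemifields are required")
    rng = np.random.default_rng(rng_seed)
    out = []
    for roi, g_roi in df.groupby("roi"):
        res: dict = dict(roi=roi)
        ok = True
        for hemi in ("L", "R"):
            g = g_roi[g_roi["hemifield"] == hemi]
            if len(g) < 4:
                raise ValueError(f"too few voxels in {roi}/{hemi}")
            tab = bin_by_eccentricity(g.assign(roi=roi), bin_width, max_ecc,
                                      selection="all")
            line = laterality_lines(tab).iloc[0]
            res[f"slope_{hemi}"] = line["slope"]
            res[f"crossing_{hemi}"] = line["crossing_ecc"]
            boots = np.empty(n_boot)
            for b in range(n_boot):
                take = g.sample(len(g), replace=True,
                                random_state=int(rng.integers(2 ** 31)))
                tab_b = bin_by_eccentricity(take.assign(roi=roi), bin_width,
                                            max_ecc, selection="all")
                tab_b = tab_b[tab_b["n_voxels"] > 0]
                if len(tab_b) < 2:
                    boots[b] = np.nan
                    continue
                boots[b] = np.polyfit(tab_b["bin_center_deg"],
                                      tab_b["median_x0"], 1,
                                      w=tab_b["n_voxels"].to_numpy(float))[0]
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
            res[f"slope_ci_lo_{hemi}"] = float(lo)
            res[f"slope_ci_hi_{hemi}"] = float(hi)
            ok = ok and (lo > 0 or hi < 0)
        opposite = np.sign(res["slope_L"]) * np.sign(res["slope_R"]) < 0
        res["inversion_present"] = bool(ok and opposite)
        out.append(res)
    return pd.DataFrame(out)


def density_summary(values: pd.DataFrame, value_col: str = "x_e0",
                    group_cols=("hemifield",), bandwidth: float | None = None,
                    grid: np.ndarray | None = None) -> pd.DataFrame:
    """Gaussian-kernel density of a fitted parameter per group on a fixed
    grid; each group's numeric integral is normalized to 1."""
    if grid is None:
        lo, hi = values[value_col].min(), values[value_col].max()
        pad = 0.1 * (hi - lo + 1e-9)
        grid = np.linspace(lo - pad, hi + pad, 256)
    rows = []
    for keys, g in values.groupby(list(group_cols)):
        if len(g) < 2:
            raise ValueError("need >= 2 values per group")
        x = g[value_col].to_numpy(float)
        if np.ptp(x) <= 0:
            # point mass: spike at the unique value
            dens = np.zeros_like(grid)
            dens[np.argmin(np.abs(grid - x[0]))] = 1.0
        else:
            kde = gaussian_kde(x, bw_method=bandwidth)
            dens = kde(grid)
        area = np.trapezoid(dens, grid)
        if area > 0:
            dens = dens / area
        keys = keys if isinstance(keys, tuple) else (keys,)
        for gv, dv in zip(grid, dens):
            rows.append(dict(**dict(zip(group_cols, keys)),
                             value=float(gv), density=float(dv)))
    return pd.DataFrame(rows)
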