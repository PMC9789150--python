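"""Forward model: pRF spatial summation, eye-position gain, HRF, TR prediction.

A voxel's neural response to a contrast movie S is

    r(t) = [ sum_{x,y} pRF(x, y) * S(x, y, t) ]^n * g(t)

where pRF is an unnormalized isotropic 2D Gaussian (peak 1), n in (0, 1] is
the compressive spatial-summation exponent applied after the spatial sum,
and g(t) is the eye-position dependent gain

    g(t) = pEGF(x_eye(t), y_eye(t)),
    pEGF(x, y) = a * exp(-((x - x0)^2 + (y - y0)^2) / (2 sigma_e^2)) + (1 - a)

so g is bounded in [1 - a, 1] and peaks at the gain-field center.  The BOLD
prediction is the causal convolution of r with a difference-of-gammas HRF,
averaged within each TR window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from gazefield.stimulus import StimulusMovie, _coord_grids


@dataclass(frozen=True)
class PRFParams:
    """Population receptive field: center (deg), s.d. (deg), exponent."""

    x_r0: float
    y_r0: float
    sigma_r: float
    n: float

    def __post_init__(self):
        if self.sigma_r <= 0:
            raise ValueError("sigma_r must be positive")
        if not (0 < self.n <= 1):
            raise ValueError("compressive exponent n must lie in (0, 1]")


@dataclass(frozen=True)
class PEGFParams:
    """Eye-position gain field: center (deg, screen coords), s.d., amplitude."""

    x_e0: float
    y_e0: float
    sigma_e: float
    a: float

    def __post_init__(self):
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        if not (0 < self.a <= 1):
            raise ValueError("amplitude a must lie in (0, 1]")


@dataclass(frozen=True)
class HRFParams:
    """Difference-of-gammas hemodynamic response function.

    h(t) ~ (t/d1)^n1 exp(-(t-d1)/t1) - a2 (t/d2)^n2 exp(-(t-d2)/t2) with
    di = ni * ti, peak-normalized to 1.  Defaults follow the standard
    two-gamma parameterization (n1=6, t1=0.9 s, n2=12, t2=0.9 s, a2=0.35):
    positive lobe peaking at 5.4 s with an undershoot around 10.8 s.
    """

    n1: float = 6.0
    t1_s: float = 0.9
    n2: float = 12.0
    t2_s: float = 0.9
    a2: float = 0.35
    kernel_len_s: float = 32.0
    dt_s: float = 1.0 / 6.0

    def __post_init__(self):
        if min(self.n1, self.t1_s, self.n2, self.t2_s) <= 0:
            raise ValueError("gamma shape parameters must be positive")
        if self.dt_s <= 0 or self.kernel_len_s <= 0:
            raise ValueError("dt_s and kernel_len_s must be positive")


@dataclass(frozen=True)
class RetinotopicGrid:
    """Pixel-center coordinates (deg) of a movie raster; fovea at center."""

    x_r: np.ndarray
    y_r: np.ndarray

    @classmethod
    def from_movie(cls, movie: StimulusMovie) -> "RetinotopicGrid":
        X, Y = _coord_grids(movie.fov, movie.ppd)
        return cls(X, Y)

    @classmethod
    def from_fov(cls, fov: tuple[float, float], ppd: float) -> "RetinotopicGrid":
        X, Y = _coord_grids(fov, ppd)
        return cls(X, Y)


def prf_field(params: PRFParams, grid: RetinotopicGrid) -> np.ndarray:
    """Unnormalized Gaussian pRF weights on the grid (peak value 1)."""
    d2 = (grid.x_r - params.x_r0) ** 2 + (grid.y_r - params.y_r0) ** 2
    return np.exp(-d2 / (2.0 * params.sigma_r ** 2))


def prf_size(params: PRFParams) -> float:
    """Effective pRF size sigma_r / sqrt(n): compression widens summation."""
    return params.sigma_r / np.sqrt(params.n)


def prf_response(params: PRFParams, movie: StimulusMovie) -> np.ndarray:
    """Per-frame neural drive: spatial sum of pRF * S, then exponent n."""
    grid = RetinotopicGrid.from_movie(movie)
    field = prf_field(params, grid).astype(np.float32)
    if field.shape != movie.unique_frames.shape[1:]:
        raise ValueError("movie raster does not match the retinotopic grid")
    drive_u = np.tensordot(movie.unique_frames, field, axes=((1, 2), (0, 1)))
    drive = drive_u[movie.index]
    return np.asarray(drive, np.float64) ** params.n


def pegf_gain(params: PEGFParams, eye_xy: np.ndarray) -> np.ndarray:
    """Gain at screen eye positions; bounded in [1 - a, 1], 1 at the center."""
    eye_xy = np.atleast_2d(np.asarray(eye_xy, dtype=float))
    d2 = ((eye_xy[..., 0] - params.x_e0) ** 2
          + (eye_xy[..., 1] - params.y_e0) ** 2)
    g = params.a * np.exp(-d2 / (2.0 * params.sigma_e ** 2)) + (1.0 - params.a)
    return g[0] if g.shape == (1,) else g


def pegf_field(params: PEGFParams, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate the gain field on coordinate arrays (used by reconstruction)."""
    d2 = (x - params.x_e0) ** 2 + (y - params.y_e0) ** 2
    return params.a * np.exp(-d2 / (2.0 * params.sigma_e ** 2)) + (1.0 - params.a)


def hrf_kernel(params: HRFParams | None = None) -> np.ndarray:
    """Sampled HRF kernel, peak-normalized to 1; h(0) = 0."""
    p = params or HRFParams()
    t = np.arange(0.0, p.kernel_len_s, p.dt_s)
    d1, d2 = p.n1 * p.t1_s, p.n2 * p.t2_s
    with np.errstate(divide="ignore", invalid="ignore"):
        lobe1 = (t / d1) ** p.n1 * np.exp(-(t - d1) / p.t1_s)
        lobe2 = (t / d2) ** p.n2 * np.exp(-(t - d2) / p.t2_s)
    h = np.nan_to_num(lobe1 - p.a2 * lobe2)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF parameters: non-positive peak")
    return h / peak


def convolve_hrf(r: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution with zero-padded past, truncated to len(r).

    Accepts 1D (T,) or 2D (rows, T) input; rows are convolved independently.
    """
    r = np.asarray(r, dtype=np.float64)
    if r.ndim == 1:
        return fftconvolve(r, kernel)[: r.shape[0]]
    out = fftconvolve(r, kernel[None, :], axes=1)
    return out[:, : r.shape[1]]


def downsample_to_tr(x: np.ndarray, frame_rate_hz: float,
                     tr_s: float) -> np.ndarray:
    """Average frames within each TR window (last axis)."""
    fpt = frame_rate_hz * tr_s
    if abs(fpt - round(fpt)) > 1e-9:
        raise ValueError("tr_s must be an integer number of frames")
    fpt = int(round(fpt))
    n_tr = x.shape[-1] // fpt
    x = x[..., : n_tr * fpt]
    return x.reshape(x.shape[:-1] + (n_tr, fpt)).mean(axis=-1)


def predict_bold(prf: PRFParams, pegf: PEGFParams | None,
                 movie: StimulusMovie, eye_trace: np.ndarray | None,
                 hrf: HRFParams | None = None,
                 tr_s: float = 2.0) -> np.ndarray:
    """BOLD prediction at TR rate for one voxel.

    The gain is applied after the compressive exponent and before the HRF
    convolution; ``pegf=None`` yields the pRF-only prediction (g == 1).
    ``eye_trace`` must be sampled at the movie frame rate.
    """
    r = prf_response(prf, movie)
    if pegf is not None:
        if eye_trace is None:
            raise ValueError("eye_trace is required when a pEGF is given")
        eye_trace = np.asarray(eye_trace, dtype=float)
        if len(eye_trace) != movie.n_frames:
            raise ValueError("eye_trace length must match the movie")
        r = r * pegf_gain(pegf, eye_trace)
    hrf = hrf or HRFParams(dt_s=1.0 / movie.frame_rate_hz)
    kern = hrf_kernel(hrf)
    conv = convolve_hrf(r, kern)
    return downsample_to_tr(conv, movie.frame_rate_hz, tr_s)
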