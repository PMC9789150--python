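"""Synthetic voxel populations, fMRI noise, and the two validation studies.

The generator emulates the study conditions end to end: a population of
voxels with eccentricity-scaled pRF sizes and gain fields constrained wider
than their pRF; the two active eye-movement task designs (versions A and B
with uncorrelated target trajectories); and a three-component noise model
(physiological drift + sinusoids, white system noise, and task noise
modulated by each voxel's retinotopic response) mixed at a 1:1:0.1 variance
ratio and rescaled to a total standard deviation.

Study 1 (``run_simulation1``) asks whether leftover retinotopic stimulation
alone could support eye-position reconstruction: four scenarios cross the
existence of gain fields with the presence of peripheral stimulation in the
simulated world and in the model's retinotopic representation.  Study 2
(``run_simulation2``) assigns uniform-random gain fields to a realistic
population and re-estimates them through the standard pipeline to expose
estimation biases in the fitted parameter distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gazefield.encoding import (
    HRFParams,
    PEGFParams,
    PRFParams,
    convolve_hrf,
    downsample_to_tr,
    hrf_kernel,
    pegf_gain,
    prf_response,
)
from gazefield.fitting import ParamGrid, PegfGridEngine, build_pegf_grid
from gazefield.reconstruction import (
    EyeGrid,
    correlation_at_lag,
    crosscorr_lag,
    estimate_gain,
    reconstruct,
)
from gazefield.stimulus import (
    EyeTaskConfig,
    RenderConfig,
    SceneLayout,
    default_scene,
    make_design_eye_task,
    render_layers,
    target_trace,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# scenarios (the four rows of the leftover-stimulation study)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One simulated world/model configuration.

    ``pegf_exists``: voxels carry true gain fields; ``periphery_in_world``:
    peripheral scene elements drive simulated responses;
    ``periphery_in_model``: the retinotopic representation used to *fit*
    pEGFs includes the peripheral elements.
    """

    pegf_exists: bool
    periphery_in_world: bool
    periphery_in_model: bool


SCENARIOS: dict[str, Scenario] = {
    "t1a": Scenario(True, True, True),    # pEGFs exist, accurate model
    "t1b": Scenario(True, True, False),   # pEGFs exist, leftover stimulation
    "t1c": Scenario(False, True, False),  # no pEGFs, leftover stimulation
    "t1d": Scenario(False, False, True),  # no pEGFs, spurious model elements
}


# --------------------------------------------------------------------------
# population sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationConfig:
    """Defaults emulate a mapped visual-field extent of ~10 deg eccentricity
    and the eye-position range of the step task (12 x 6.3 deg)."""

    x_extent: tuple[float, float] = (-8.0, 8.0)
    y_extent: tuple[float, float] = (-5.0, 5.0)
    sigma_slope: float = 0.15        # deg sigma_r per deg eccentricity
    sigma_intercept: float = 0.35
    sigma_jitter: float = 0.1
    n_values: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    eye_x_half: float = 6.0
    eye_y_half: float = 3.15
    sigma_e_range: tuple[float, float] = (2.0, 12.0)
    a_range: tuple[float, float] = (1.0 / 6.0, 1.0)
    rois: tuple[str, ...] = ("V1",)
    pegf_on_grid: bool = False       # snap pEGF params to the fitting grid


def sample_population(n_voxels: int, config: PopulationConfig | None = None,
                      rng_seed: int = 0,
                      pegf_grid: ParamGrid | None = None) -> pd.DataFrame:
    """Sample a voxel population with pRFs and gain fields.

    pRF sizes scale with eccentricity (positive slope plus jitter) and every
    gain field is wider than its voxel's pRF (sigma_e resampled until
    > sigma_r).  With ``pegf_on_grid`` the gain-field parameters are drawn
    from the fitting grid's axis values, which makes noiseless recovery
    exact up to enumeration.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(rng_seed)
    x0 = rng.uniform(*cfg.x_extent, size=n_voxels)
    y0 = rng.uniform(*cfg.y_extent, size=n_voxels)
    ecc = np.hypot(x0, y0)
    sigma_r = (cfg.sigma_intercept + cfg.sigma_slope * ecc
               + np.abs(rng.normal(0, cfg.sigma_jitter, size=n_voxels)))
    n = rng.choice(cfg.n_values, size=n_voxels)

    grid = pegf_grid or build_pegf_grid()
    axes = dict(grid.axes)
    if cfg.pegf_on_grid:
        xe = rng.choice(axes["x_e0"], size=n_voxels)
        ye = rng.choice(axes["y_e0"], size=n_voxels)
        amp = rng.choice(axes["a"], size=n_voxels)
        sig_pool = np.asarray(axes["sigma_e"], dtype=float)
        sigma_e = np.empty(n_voxels)
        for v in range(n_voxels):
            ok = sig_pool[sig_pool > sigma_r[v]]
            if ok.size == 0:
                raise ValueError("no feasible sigma_e grid value for a voxel")
            sigma_e[v] = rng.choice(ok)
    else:
        xe = rng.uniform(-cfg.eye_x_half, cfg.eye_x_half, size=n_voxels)
        ye = rng.uniform(-cfg.eye_y_half, cfg.eye_y_half, size=n_voxels)
        amp = rng.uniform(*cfg.a_range, size=n_voxels)
        lo, hi = np.log(cfg.sigma_e_range)
        sigma_e = np.exp(rng.uniform(lo, hi, size=n_voxels))
        for v in range(n_voxels):
            while sigma_e[v] <= sigma_r[v]:
                sigma_e[v] = np.exp(rng.uniform(lo, hi))
    return pd.DataFrame({
        "voxel_id": np.arange(n_voxels),
        "x_r0": x0, "y_r0": y0, "sigma_r": sigma_r, "n": n,
        "x_e0": xe, "y_e0": ye, "sigma_e": sigma_e, "a": amp,
        "roi": np.asarray(cfg.rois)[np.arange(n_voxels) % len(cfg.rois)],
        "hemifield": np.where(x0 < 0, "L", "R"),
    })


# --------------------------------------------------------------------------
# noise model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Three-component noise mix (physiological : system : task)."""

    total_sd: float = 0.1
    ratio: tuple[float, float, float] = (1.0, 1.0, 0.1)

    def __post_init__(self):
        if self.total_sd < 0:
            raise ValueError("total_sd must be non-negative")


def _scale_to_sd(x: np.ndarray, sd: float) -> np.ndarray:
    s = x.std()
    return x * (sd / s) if s > 0 else x


def noise_series(length: int, rate_hz: float, cfg: NoiseConfig,
                 rng: np.random.Generator,
                 task_weight: np.ndarray | None = None,
                 return_components: bool = False):
    """One noise rendition of the stated structure.

    Physiological: quadratic drift plus two sinusoids (one slow at
    0.01-0.03 Hz, one respiratory-band at 0.25-0.3 Hz, random phase).
    System: white Gaussian.  Task: white Gaussian multiplied by the voxel's
    normalized retinotopic response (zero when no weight is given).  The
    components are mixed at the configured variance ratio and the sum is
    rescaled analytically to ``total_sd``.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    t = np.arange(length) / rate_hz
    u = t / t[-1] * 2.0 - 1.0
    coef = rng.normal(size=3)
    phys = coef[0] * u + coef[1] * u ** 2
    for flo, fhi in ((0.01, 0.03), (0.25, 0.30)):
        f = rng.uniform(flo, fhi)
        phys = phys + rng.normal() * np.sin(2 * np.pi * f * t
                                            + rng.uniform(0, 2 * np.pi))
    system = rng.normal(size=length)
    task = rng.normal(size=length)
    if task_weight is not None:
        w = np.asarray(task_weight, dtype=float)
        mx = np.abs(w).max()
        task = task * (w / mx if mx > 0 else 0.0)
    else:
        task = np.zeros(length)
    parts = [phys, system, task]
    mixed = np.zeros(length)
    scaled_parts = []
    for comp, ratio in zip(parts, cfg.ratio):
        if comp.std() > 0 and ratio > 0:
            comp = _scale_to_sd(comp, np.sqrt(ratio))
        else:
            comp = np.zeros(length)
        scaled_parts.append(comp)
        mixed = mixed + comp
    if cfg.total_sd == 0:
        out = np.zeros(length)
        scale = 0.0
    else:
        scale = cfg.total_sd / mixed.std()
        out = mixed * scale
    if return_components:
        return out, [p * scale for p in scaled_parts]
    return out


def _minmax01_rows(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return (x - lo) / span


# --------------------------------------------------------------------------
# forward simulation
# --------------------------------------------------------------------------

class EyeTaskSimulator:
    """Shared forward-model state for repeated simulations of tasks A and B.

    Renders both task versions once (bar and periphery layers), computes the
    clean per-voxel signals with and without gain modulation, and caches the
    grid-search engines, so that repeated noise renditions only pay for the
    noise and the model fit.
    """

    def __init__(self, population: pd.DataFrame, rng_seed: int = 0,
                 design_cfg: EyeTaskConfig | None = None,
                 scene: SceneLayout | None = None,
                 render_cfg: RenderConfig | None = None,
                 hrf: HRFParams | None = None,
                 pegf_grid: ParamGrid | None = None,
                 tr_s: float = 2.0):
        self.population = population.reset_index(drop=True)
        self.cfg = design_cfg or EyeTaskConfig()
        self.scene = scene or default_scene(self.cfg.fov)
        self.render_cfg = render_cfg or RenderConfig(ppd=self.scene.ppd)
        self.hrf = hrf or HRFParams(dt_s=1.0 / self.cfg.frame_rate_hz)
        self.pegf_grid = pegf_grid or build_pegf_grid()
        self.tr_s = tr_s
        self.designs = {
            "A": make_design_eye_task("A", self.cfg, rng_seed),
            "B": make_design_eye_task("B", self.cfg, rng_seed),
        }
        self._layers = {t: render_layers(self.designs[t], self.scene,
                                         self.render_cfg)
                        for t in ("A", "B")}
        self._kernel = hrf_kernel(self.hrf)
        self._movies: dict = {}
        self._drives: dict = {}
        self._engines: dict = {}
        # modeled gaze trace (target followed with the rendering latency)
        self.gaze = {}
        for t in ("A", "B"):
            tgt = target_trace(self.designs[t], self.cfg.frame_rate_hz)
            lat = self.render_cfg.latency_frames
            gz = np.vstack([np.repeat(tgt[:1], lat, axis=0),
                            tgt[: len(tgt) - lat]]) if lat else tgt
            self.gaze[t] = gz

    def movie(self, task: str, periphery: bool):
        key = (task, periphery)
        if key not in self._movies:
            rc = self.render_cfg
            c_post = rc.c_post if periphery else 0.0
            c_fix = rc.c_fix if periphery else 0.0
            self._movies[key] = self._layers[task].compose(
                c_fix, c_post, rc.d_post_frames)
        return self._movies[key]

    def _neural(self, task: str, periphery: bool) -> np.ndarray:
        """(n_voxels, n_frames) retinotopic drives r(t), without gain."""
        key = (task, periphery)
        if key not in self._drives:
            movie = self.movie(task, periphery)
            rows = [prf_response(PRFParams(p.x_r0, p.y_r0, p.sigma_r, p.n),
                                 movie)
                    for p in self.population.itertuples()]
            self._drives[key] = np.stack(rows)
        return self._drives[key]

    def prfonly_prediction(self, task: str, periphery: bool) -> np.ndarray:
        """pRF-only TR-rate predictions (the gain-estimation denominator)."""
        r = self._neural(task, periphery)
        conv = convolve_hrf(r, self._kernel)
        return downsample_to_tr(conv, self.cfg.frame_rate_hz, self.tr_s)

    def clean_bold(self, task: str, scenario: Scenario) -> np.ndarray:
        """Noise-free voxel x TR signals, min-max scaled to [0, 1]."""
        r = self._neural(task, scenario.periphery_in_world)
        if scenario.pegf_exists:
            gains = np.stack([
                pegf_gain(PEGFParams(p.x_e0, p.y_e0, p.sigma_e, p.a),
                          self.gaze[task])
                for p in self.population.itertuples()])
            r = r * gains
        conv = convolve_hrf(r, self._kernel)
        bold = downsample_to_tr(conv, self.cfg.frame_rate_hz, self.tr_s)
        return _minmax01_rows(bold)

    def add_noise(self, clean: np.ndarray, task: str, noise_cfg: NoiseConfig,
                  rng: np.random.Generator,
                  scenario: Scenario | None = None) -> np.ndarray:
        periphery = scenario.periphery_in_world if scenario else True
        weights = _minmax01_rows(self.prfonly_prediction(task, periphery))
        out = clean.copy()
        for v in range(len(out)):
            out[v] += noise_series(clean.shape[1], 1.0 / self.tr_s,
                                   noise_cfg, rng, task_weight=weights[v])
        return out

    def subset(self, mask: np.ndarray) -> "EyeTaskSimulator":
        """Simulator restricted to a voxel subset (boolean mask or integer
        positions); rendered state is shared."""
        mask = np.asarray(mask)
        sub = EyeTaskSimulator.__new__(EyeTaskSimulator)
        sub.__dict__.update(self.__dict__)
        sub.population = self.population.iloc[mask].reset_index(drop=True)
        sub._drives = {k: v[mask] for k, v in self._drives.items()}
        sub._engines = {}
        return sub

    def engine(self, periphery_in_model: bool) -> PegfGridEngine:
        if periphery_in_model not in self._engines:
            self._engines[periphery_in_model] = PegfGridEngine(
                self.movie("A", periphery_in_model), self.gaze["A"],
                self.population, self.pegf_grid, self.hrf, self.tr_s)
        return self._engines[periphery_in_model]


def simulate_bold(population: pd.DataFrame, rng_seed: int,
                  scenario: Scenario | str = "t1a",
                  noise_cfg: NoiseConfig | None = None,
                  simulator: EyeTaskSimulator | None = None,
                  **simulator_kwargs) -> dict:
    """One noise rendition of both task versions under a scenario.

    Returns the noisy voxel x TR matrices, the clean signals, and the
    simulator (reusable across renditions).
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    noise_cfg = noise_cfg or NoiseConfig()
    sim = simulator or EyeTaskSimulator(population, rng_seed,
                                        **simulator_kwargs)
    rng = np.random.default_rng([rng_seed & 0x7FFFFFFF, 17])
    out = {"simulator": sim, "scenario": scenario}
    for task in ("A", "B"):
        clean = sim.clean_bold(task, scenario)
        out[f"clean_{task}"] = clean
        out[f"bold_{task}"] = sim.add_noise(clean, task, noise_cfg, rng,
                                            scenario)
    return out


# --------------------------------------------------------------------------
# study 1: leftover retinotopic input
# --------------------------------------------------------------------------

def run_simulation1(population: pd.DataFrame, n_reps: int = 100,
                    noise_cfg: NoiseConfig | None = None, rng_seed: int = 0,
                    scenarios: dict[str, Scenario] | None = None,
                    eye_grid: EyeGrid | None = None,
                    assessment_lag: int = 1,
                    simulator: EyeTaskSimulator | None = None) -> pd.DataFrame:
    """Simulate, fit and reconstruct under each scenario, ``n_reps`` times.

    Per rendition: task-A data are fitted with the scenario's (possibly
    mismatched) retinotopic representation, gains are estimated on task B,
    the eye trace is reconstructed and correlated with the true target
    trace.  Returns one row per (scenario, rep) with the correlations at
    the assessment lag and the best cross-correlation lag.
    """
    noise_cfg = noise_cfg or NoiseConfig()
    scenarios = scenarios or SCENARIOS
    sim = simulator or EyeTaskSimulator(population, rng_seed)
    grid = eye_grid or EyeGrid.from_extent(sim.cfg.fov)
    truth = target_trace(sim.designs["B"], 1.0 / sim.tr_s)
    rows = []
    for s_i, (name, scn) in enumerate(scenarios.items()):
        engine = sim.engine(scn.periphery_in_model)
        pred_b = sim.prfonly_prediction("B", scn.periphery_in_model)
        clean = {t: sim.clean_bold(t, scn) for t in ("A", "B")}
        for rep in range(n_reps):
            rng = np.random.default_rng([rng_seed & 0x7FFFFFFF, s_i, rep])
            bold_a = sim.add_noise(clean["A"], "A", noise_cfg, rng, scn)
            bold_b = sim.add_noise(clean["B"], "B", noise_cfg, rng, scn)
            fits = engine.fit(bold_a)
            gains = estimate_gain(bold_b, pred_b)
            _, trace = reconstruct(gains, fits, grid)
            xy = trace[["x_hat", "y_hat"]].to_numpy()
            best_lag, _ = crosscorr_lag(xy, truth)
            r_x, r_y = correlation_at_lag(xy, truth, assessment_lag)
            rows.append(dict(scenario=name, rep=rep, r_x=r_x, r_y=r_y,
                             best_lag=best_lag))
            logger.debug("sim1 %s rep %d: r_x=%.3f r_y=%.3f lag=%d",
                         name, rep, r_x, r_y, best_lag)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# study 2: pEGF parameter-distribution bias
# --------------------------------------------------------------------------

def moving_bar_r2_proxy(clean01: np.ndarray, noise_sd: float) -> np.ndarray:
    """Expected pRF-only R^2 of a [0,1]-scaled clean signal under white noise
    of the given s.d.: var_s / (var_s + sd^2)."""
    v = clean01.var(axis=1)
    return v / (v + noise_sd ** 2)


def run_simulation2(population: pd.DataFrame,
                    noise_sds=(0.05, 0.1, 0.2), rng_seed: int = 0,
                    min_r2_proxy: float = 0.25,
                    simulator: EyeTaskSimulator | None = None,
                    n_reps: int = 1) -> pd.DataFrame:
    """Assign-and-recover check of the pEGF estimation framework on task A.

    Voxels keep their population pEGFs (uniform over the eye-position
    extent, wider than their pRF); the forward model generates task-A data,
    noise is added at each stated s.d., and the standard grid search
    re-estimates the gain-field parameters with the pRFs frozen at truth.
    Voxels whose retinotopically driven signal would not reach the
    variance-explained floor under the weakest noise level are dropped
    (the selection analogue of fitting only well-mapped voxels).

    Returns one row per (voxel, noise_sd, rep) pairing true and estimated
    parameters.
    """
    sim = simulator or EyeTaskSimulator(population, rng_seed)
    scn = SCENARIOS["t1a"]
    clean = sim.clean_bold("A", scn)
    proxy = moving_bar_r2_proxy(clean, float(min(noise_sds)))
    keep = proxy >= min_r2_proxy
    logger.info("simulation 2: %d/%d voxels pass the R2 proxy floor",
                int(keep.sum()), len(keep))
    sub = sim.subset(keep)
    pop = sub.population
    clean = clean[keep]
    engine = sub.engine(scn.periphery_in_model)
    rows = []
    for s_i, sd in enumerate(noise_sds):
        cfg = NoiseConfig(total_sd=float(sd))
        for rep in range(n_reps):
            rng = np.random.default_rng([rng_seed & 0x7FFFFFFF, 101 + s_i,
                                         rep])
            bold = sub.add_noise(clean.copy(), "A", cfg, rng, scn)
            fits = engine.fit(bold)
            for v in range(len(pop)):
                rows.append(dict(
                    voxel_id=pop["voxel_id"].iloc[v], noise_sd=sd, rep=rep,
                    x_r0=pop["x_r0"].iloc[v], y_r0=pop["y_r0"].iloc[v],
                    sigma_r=pop["sigma_r"].iloc[v], n=pop["n"].iloc[v],
                    hemifield=pop["hemifield"].iloc[v],
                    roi=pop["roi"].iloc[v],
                    true_x_e0=pop["x_e0"].iloc[v],
                    true_y_e0=pop["y_e0"].iloc[v],
                    true_sigma_e=pop["sigma_e"].iloc[v],
                    true_a=pop["a"].iloc[v],
                    est_x_e0=fits["x_e0"].iloc[v],
                    est_y_e0=fits["y_e0"].iloc[v],
                    est_sigma_e=fits["sigma_e"].iloc[v],
                    est_a=fits["a"].iloc[v],
                    r2=fits["r2"].iloc[v]))
    return pd.DataFrame(rows)
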