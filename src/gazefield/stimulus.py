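"""Experiment designs and gaze-centered (retinotopic) stimulus rendering.

Two task families are generated here.  The moving-bar task maps population
receptive fields: a contrast bar sweeps across the screen in 8 directions
with 20 steps per sweep while the observer fixates centrally.  The active
eye-movement tasks (versions A and B) map eye-position gain fields: a
fixation target steps across the screen in 13 sweeps of 8 steps and the
observer's gaze follows it, so the whole visual scene — screen edge,
coil-mirror, eye tracker, bore — slides across the retina with every
saccade.

Rendering produces a *retinotopic* contrast movie: each frame is the screen
content re-centered on the modeled gaze position (the target position with a
fixed latency).  Peripheral scene elements can be given a different contrast
during fixation and during a short post-saccadic window, which models
transient visual responses after each eye movement.

Coordinate convention (used package-wide): degrees of visual angle, origin
at screen center, +x rightward, +y upward; raster row 0 is the top of the
visual field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
import numpy as np

logger = logging.getLogger(__name__)

ORIENTATIONS = ("horizontal", "vertical", "diagonal-45", "diagonal-135")


# --------------------------------------------------------------------------
# design containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    """A fixation epoch: the target sits at (target_x, target_y)."""

    onset_s: float
    duration_s: float
    target_x: float
    target_y: float


@dataclass(frozen=True)
class BarEvent:
    onset_s: float
    offset_s: float
    orientation: str
    center_x: float
    center_y: float
    width: float
    flicker: bool = True

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown bar orientation {self.orientation!r}")


@dataclass(frozen=True)
class DesignSpec:
    """Timeline of one run: fixation epochs, bar events and baselines.

    Epochs are contiguous and cover [0, run_duration_s); baselines are a
    subset of epochs during which no bars are shown.  Saccade times are the
    epoch boundaries at which the target position changes.
    """

    epochs: tuple[Epoch, ...]
    bar_events: tuple[BarEvent, ...]
    baselines: tuple[tuple[float, float], ...]  # (onset_s, duration_s)
    tr_s: float
    run_duration_s: float
    frame_rate_hz: float

    def __post_init__(self):
        t = 0.0
        for ep in self.epochs:
            if abs(ep.onset_s - t) > 1e-9:
                raise ValueError("epochs must be contiguous and ordered")
            t += ep.duration_s
        if abs(t - self.run_duration_s) > 1e-9:
            raise ValueError("epochs must cover the whole run")
        n_tr = self.run_duration_s / self.tr_s
        if abs(n_tr - round(n_tr)) > 1e-9:
            raise ValueError("run_duration_s must be an integer multiple of tr_s")
        for ev in self.bar_events:
            if ev.onset_s < 0 or ev.offset_s > self.run_duration_s + 1e-9:
                raise ValueError("bar event outside the run")

    @property
    def n_trs(self) -> int:
        return int(round(self.run_duration_s / self.tr_s))

    @property
    def n_frames(self) -> int:
        return int(round(self.run_duration_s * self.frame_rate_hz))

    def saccade_times(self) -> np.ndarray:
        """Onsets of epochs whose target differs from the previous epoch."""
        times = []
        for prev, cur in zip(self.epochs, self.epochs[1:]):
            if (cur.target_x, cur.target_y) != (prev.target_x, prev.target_y):
                times.append(cur.onset_s)
        return np.asarray(times)


def target_trace(design: DesignSpec, rate_hz: float) -> np.ndarray:
    """Sample the fixation-target position at ``rate_hz``; shape (T, 2).

    The trace is piecewise constant and changes exactly at epoch boundaries.
    ``rate_hz`` must divide the frame rate or equal 1/tr_s.
    """
    fr = design.frame_rate_hz
    ratio = fr / rate_hz
    if abs(ratio - round(ratio)) > 1e-9 and abs(rate_hz * design.tr_s - 1.0) > 1e-9:
        raise ValueError(f"rate {rate_hz} Hz incompatible with the design timeline")
    n = int(round(design.run_duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    onsets = np.array([ep.onset_s for ep in design.epochs])
    idx = np.searchsorted(onsets, t + 1e-9) - 1
    xy = np.array([(ep.target_x, ep.target_y) for ep in design.epochs])
    return xy[idx]


# --------------------------------------------------------------------------
# design generators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MovingBarConfig:
    n_sweeps: int = 8
    n_steps: int = 20
    step_s: float = 1.6
    bar_width: float = 1.75
    n_baselines: int = 8
    baseline_s: float = 12.0
    tr_s: float = 2.0
    frame_rate_hz: float = 6.0
    fov: tuple[float, float] = (24.0, 18.0)  # mapped extent (w, h) in deg


# motion direction (deg, CCW from +x) -> bar orientation (perpendicular)
_DIRECTION_ORIENTATION = {
    0: "vertical", 180: "vertical",
    90: "horizontal", 270: "horizontal",
    45: "diagonal-135", 225: "diagonal-135",
    135: "diagonal-45", 315: "diagonal-45",
}


def make_design_moving_bar(config: MovingBarConfig | None = None,
                           rng_seed: int = 0) -> DesignSpec:
    """Moving-bar pRF-mapping design: 8 sweep directions x 20 steps of 1.6 s,
    interleaved 12-s baselines, central fixation throughout.

    The design is fully deterministic; ``rng_seed`` is accepted for interface
    symmetry with the eye-task generator.
    """
    cfg = config or MovingBarConfig()
    directions = [0, 180, 90, 270, 45, 225, 135, 315][: cfg.n_sweeps]
    w, h = cfg.fov
    bars: list[BarEvent] = []
    baselines: list[tuple[float, float]] = []
    t = 0.0
    for i, ang in enumerate(directions):
        u = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
        half_span = 0.5 * (w * abs(u[0]) + h * abs(u[1]))
        pos = np.linspace(-half_span, half_span, cfg.n_steps)
        orient = _DIRECTION_ORIENTATION[ang]
        for d in pos:
            bars.append(BarEvent(t, t + cfg.step_s, orient,
                                 float(d * u[0]), float(d * u[1]),
                                 cfg.bar_width))
            t += cfg.step_s
        if i < cfg.n_baselines:
            baselines.append((t, cfg.baseline_s))
            t += cfg.baseline_s
    # closed form avoids float accumulation drift in the run length
    run = (cfg.n_sweeps * cfg.n_steps * cfg.step_s
           + min(cfg.n_baselines, cfg.n_sweeps) * cfg.baseline_s)
    n_tr = run / cfg.tr_s
    if abs(n_tr - round(n_tr)) > 1e-9:
        pad = (np.ceil(n_tr) - n_tr) * cfg.tr_s
        run += pad
        if baselines:
            on, du = baselines[-1]
            baselines[-1] = (on, du + pad)
    epochs = (Epoch(0.0, run, 0.0, 0.0),)
    return DesignSpec(epochs, tuple(bars), tuple(baselines),
                      cfg.tr_s, run, cfg.frame_rate_hz)


@dataclass(frozen=True)
class EyeTaskConfig:
    n_sweeps: int = 13
    n_steps: int = 8
    step_min: float = 1.28
    step_max: float = 1.40
    step_durations: tuple[float, ...] = (1.5, 5.0 / 3.0)
    n_baselines: int = 9
    baseline_min: float = 20.0
    baseline_max: float = 25.0
    tr_s: float = 2.0
    frame_rate_hz: float = 6.0
    fov: tuple[float, float] = (40.0, 22.0)
    y_half_range: float = 3.15
    run_duration_s: float = 358.0
    n_bar_instances: int = 7
    bar_width: float = 1.75
    decorr_threshold: float = 0.15
    max_resample_attempts: int = 1000


def _quantize(t: float, rate: float) -> float:
    return round(t * rate) / rate


def _eye_task_timeline(cfg: EyeTaskConfig, rng: np.random.Generator) -> DesignSpec:
    """One random rendition of the eye-task timeline."""
    fr = cfg.frame_rate_hz
    # step durations (already exact multiples of the frame interval)
    step_durs = rng.choice(cfg.step_durations,
                           size=cfg.n_sweeps * cfg.n_steps)
    steps_total = float(np.sum(step_durs))
    # draw 9 baselines then rescale so the run hits run_duration_s
    base_durs = rng.uniform(cfg.baseline_min, cfg.baseline_max,
                            size=cfg.n_baselines)
    budget = cfg.run_duration_s - steps_total
    if budget <= cfg.n_baselines * 2.0:
        raise ValueError("run_duration_s too short for the requested timeline")
    base_durs = base_durs * (budget / base_durs.sum())
    base_durs = np.array([_quantize(b, fr) for b in base_durs])
    # interior baselines after 7 of the 12 inter-sweep gaps
    gaps = rng.choice(np.arange(1, cfg.n_sweeps), size=cfg.n_baselines - 2,
                      replace=False)
    gaps = set(int(g) for g in gaps)

    # horizontal sweeps alternate direction; vertical position wanders
    epochs: list[Epoch] = []
    baselines: list[tuple[float, float]] = []
    t = 0.0
    base_i = 0

    def add_baseline(tx, ty):
        nonlocal t, base_i
        dur = float(base_durs[base_i])
        epochs.append(Epoch(t, dur, tx, ty))
        baselines.append((t, dur))
        t += dur
        base_i += 1

    x, y = 0.0, 0.0
    add_baseline(x, y)
    direction = 1 if rng.random() < 0.5 else -1
    k = 0
    for sweep in range(cfg.n_sweeps):
        sizes = rng.uniform(cfg.step_min, cfg.step_max, size=cfg.n_steps - 1)
        span = float(sizes.sum())
        x = -direction * span / 2.0
        for j in range(cfg.n_steps):
            if j > 0:
                x += direction * float(sizes[j - 1])
            y = float(np.clip(y + rng.uniform(-0.6, 0.6),
                              -cfg.y_half_range, cfg.y_half_range))
            dur = float(step_durs[k])
            epochs.append(Epoch(t, dur, round(x, 4), round(y, 4)))
            t += dur
            k += 1
        if (sweep + 1) in gaps:
            add_baseline(round(x, 4), round(y, 4))
        direction *= -1
    # final baseline absorbs rounding so the run is an exact TR multiple
    last = cfg.run_duration_s - t
    epochs.append(Epoch(t, last, round(x, 4), round(y, 4)))
    baselines.append((t, last))
    return DesignSpec(tuple(epochs), (), tuple(baselines),
                      cfg.tr_s, cfg.run_duration_s, fr)


_BAR_PATTERNS = (
    ("h-center",), ("v-center",), ("diag-corner",),
    ("h-center", "diag-corner"), ("v-center", "diag-corner"),
    ("h-center",), ("v-center",),
)


def _eye_task_bars(design: DesignSpec, cfg: EyeTaskConfig,
                   rng: np.random.Generator) -> tuple[BarEvent, ...]:
    """Place 7 bar-presentation instances at step onsets outside baselines."""
    base = {b[0] for b in design.baselines}
    onsets = [ep.onset_s for ep in design.epochs if ep.onset_s not in base]
    # spread instances over the run, one per ~equal segment
    onsets = np.asarray(onsets)
    chosen = []
    for q in np.linspace(0.05, 0.9, cfg.n_bar_instances):
        target_t = q * design.run_duration_s
        chosen.append(float(onsets[np.argmin(np.abs(onsets - target_t))]))
    patterns = list(_BAR_PATTERNS[: cfg.n_bar_instances])
    rng.shuffle(patterns)
    w, h = cfg.fov
    events = []
    for on, pat in zip(chosen, patterns):
        dur = _quantize(float(rng.uniform(3.0, 6.0)), design.frame_rate_hz)
        off = min(on + dur, design.run_duration_s)
        for name in pat:
            if name == "h-center":
                events.append(BarEvent(on, off, "horizontal", 0.0, 0.0,
                                       cfg.bar_width))
            elif name == "v-center":
                events.append(BarEvent(on, off, "vertical", 0.0, 0.0,
                                       cfg.bar_width))
            else:  # diagonal bar toward a corner of the screen
                sx = 1.0 if rng.random() < 0.5 else -1.0
                sy = 1.0 if rng.random() < 0.5 else -1.0
                events.append(BarEvent(on, off, "diagonal-45",
                                       sx * 8.0, sy * 5.0, cfg.bar_width))
    return tuple(sorted(events, key=lambda e: e.onset_s))


def make_design_eye_task(version: str, config: EyeTaskConfig | None = None,
                         rng_seed: int = 0) -> DesignSpec:
    """Active eye-movement task design, version ``"A"`` or ``"B"``.

    The two versions share a seed but are drawn so that their target
    trajectories are uncorrelated: version B is resampled until the Pearson
    correlation of both trace components with version A falls below the
    configured threshold.
    """
    cfg = config or EyeTaskConfig()
    if version not in ("A", "B"):
        raise ValueError("version must be 'A' or 'B'")

    def build(stream: int, attempt: int = 0) -> DesignSpec:
        rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, stream, attempt])
        d = _eye_task_timeline(cfg, rng)
        return replace(d, bar_events=_eye_task_bars(d, cfg, rng))

    design_a = build(0)
    if version == "A":
        return design_a
    trace_a = target_trace(design_a, 1.0 / cfg.tr_s)
    for attempt in range(cfg.max_resample_attempts):
        design_b = build(1, attempt)
        trace_b = target_trace(design_b, 1.0 / cfg.tr_s)
        rx = np.corrcoef(trace_a[:, 0], trace_b[:, 0])[0, 1]
        ry = np.corrcoef(trace_a[:, 1], trace_b[:, 1])[0, 1]
        if abs(rx) < cfg.decorr_threshold and abs(ry) < cfg.decorr_threshold:
            logger.info("eye task B decorrelated after %d attempts "
                        "(rx=%.3f, ry=%.3f)", attempt + 1, rx, ry)
            return design_b
    raise RuntimeError("could not decorrelate version B from version A "
                       f"within {cfg.max_resample_attempts} attempts")


# --------------------------------------------------------------------------
# scene and rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneLayout:
    """Binary masks of the static scene elements, in screen coordinates.

    The stylized default scene places a rectangular screen-edge frame, two
    lateral blobs (coil-mirror, eye tracker) and a lower arc (bore) outside
    the screen rectangle.  Element photometry is irrelevant to the model;
    only geometry enters the retinotopic representation.
    """

    elements: dict[str, np.ndarray]
    fov: tuple[float, float]
    ppd: float
    screen_size: tuple[float, float] = (24.0, 18.0)
    fixation_radius: float = 0.65

    def __post_init__(self):
        shapes = {m.shape for m in self.elements.values()}
        if len(shapes) > 1:
            raise ValueError("scene element masks must share raster dimensions")
        for name, m in self.elements.items():
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"element {name!r} mask must be binary")

    def combined_mask(self) -> np.ndarray:
        out = None
        for m in self.elements.values():
            out = m.astype(np.float32) if out is None else np.maximum(out, m)
        if out is None:
            h, w = raster_shape(self.fov, self.ppd)
            out = np.zeros((h, w), np.float32)
        return out


def raster_shape(fov: tuple[float, float], ppd: float) -> tuple[int, int]:
    w_deg, h_deg = fov
    return int(round(h_deg * ppd)), int(round(w_deg * ppd))


def _coord_grids(fov, ppd):
    h, w = raster_shape(fov, ppd)
    x = (np.arange(w) - (w - 1) / 2.0) / ppd
    y = ((h - 1) / 2.0 - np.arange(h)) / ppd
    return np.meshgrid(x, y)


def default_scene(fov: tuple[float, float] = (40.0, 22.0), ppd: float = 6.7,
                  screen_size: tuple[float, float] = (24.0, 18.0)) -> SceneLayout:
    """Stylized scanner-interior scene on the given raster.

    All elements are zeroed inside the screen rectangle so the peripheral
    layer is spatially disjoint from bars and fixation target (which live on
    the screen); the contrast sweep exploits this.
    """
    X, Y = _coord_grids(fov, ppd)
    sw, sh = screen_size
    inside = (np.abs(X) <= sw / 2) & (np.abs(Y) <= sh / 2)
    edge = ((np.abs(X) <= sw / 2 + 0.6) & (np.abs(Y) <= sh / 2 + 0.6)) & ~inside
    coil = ((X + 16.0) ** 2 / 2.5 ** 2 + (Y + 2.0) ** 2 / 2.0 ** 2) <= 1.0
    tracker = ((X - 15.5) ** 2 / 2.2 ** 2 + (Y + 4.0) ** 2 / 1.8 ** 2) <= 1.0
    rad = np.sqrt(X ** 2 + (Y + 30.0) ** 2)
    bore = (rad >= 19.5) & (rad <= 22.0)
    elements = {
        "screen_edge": edge.astype(np.uint8),
        "coil_mirror": (coil & ~inside).astype(np.uint8),
        "eye_tracker": (tracker & ~inside).astype(np.uint8),
        "bore": (bore & ~inside).astype(np.uint8),
    }
    return SceneLayout(elements, fov, ppd, screen_size)


@dataclass(frozen=True)
class RenderConfig:
    ppd: float = 6.7
    c_fix: float = 0.0
    c_post: float = 1.0
    d_post_frames: int = 3
    latency_frames: int = 1

    def __post_init__(self):
        if self.ppd <= 0:
            raise ValueError("ppd must be positive")
        if not (0 <= self.c_fix <= 1 and 0 <= self.c_post <= 1):
            raise ValueError("contrasts must lie in [0, 1]")
        if self.d_post_frames < 0:
            raise ValueError("d_post_frames must be >= 0")


class StimulusMovie:
    """Gaze-centered contrast frame stack with values in [0, 1].

    Frames are stored deduplicated (``unique_frames`` plus a per-frame
    ``index``): task movies repeat identical content for many consecutive
    frames, and downstream spatial products only ever need the distinct
    frames.  ``dense()`` materializes the full (T, H, W) stack.
    """

    def __init__(self, unique_frames: np.ndarray, index: np.ndarray,
                 ppd: float, frame_rate_hz: float, fov: tuple[float, float]):
        unique_frames = np.asarray(unique_frames, dtype=np.float32)
        if unique_frames.ndim != 3:
            raise ValueError("unique_frames must be (U, H, W)")
        if unique_frames.size and (unique_frames.min() < -1e-6
                                   or unique_frames.max() > 1 + 1e-6):
            raise ValueError("frame values must lie in [0, 1]")
        index = np.asarray(index, dtype=np.int32)
        if index.size and (index.min() < 0 or index.max() >= len(unique_frames)):
            raise ValueError("frame index out of range")
        self.unique_frames = np.clip(unique_frames, 0.0, 1.0)
        self.index = index
        self.ppd = float(ppd)
        self.frame_rate_hz = float(frame_rate_hz)
        self.fov = (float(fov[0]), float(fov[1]))

    @classmethod
    def from_frames(cls, frames: np.ndarray, ppd: float, frame_rate_hz: float,
                    fov: tuple[float, float]) -> "StimulusMovie":
        frames = np.asarray(frames, dtype=np.float32)
        seen: dict[bytes, int] = {}
        index = np.empty(len(frames), np.int32)
        unique = []
        for i, f in enumerate(frames):
            key = f.tobytes()
            if key not in seen:
                seen[key] = len(unique)
                unique.append(f)
            index[i] = seen[key]
        return cls(np.stack(unique) if unique else
                   np.zeros((0,) + frames.shape[1:], np.float32),
                   index, ppd, frame_rate_hz, fov)

    @property
    def n_frames(self) -> int:
        return len(self.index)

    @property
    def height(self) -> int:
        return self.unique_frames.shape[1]

    @property
    def width(self) -> int:
        return self.unique_frames.shape[2]

    def frame(self, t: int) -> np.ndarray:
        return self.unique_frames[self.index[t]]

    def dense(self) -> np.ndarray:
        return self.unique_frames[self.index]


def _shift_into(canvas: np.ndarray, mask: np.ndarray, dy: int, dx: int,
                value: float) -> None:
    """canvas <- max(canvas, value * mask shifted so source (r+dy, c+dx))."""
    h, w = canvas.shape
    r0, r1 = max(0, -dy), min(h, h - dy)
    c0, c1 = max(0, -dx), min(w, w - dx)
    if r0 >= r1 or c0 >= c1:
        return
    src = mask[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
    region = canvas[r0:r1, c0:c1]
    np.maximum(region, value * src, out=region)


def _paint_bar(canvas, X, Y, ev: BarEvent, gx: float, gy: float,
               screen: tuple[float, float]) -> None:
    """Paint a contrast-1 bar (retinotopic coords), clipped to the screen."""
    cx, cy = ev.center_x - gx, ev.center_y - gy
    if ev.orientation == "horizontal":
        dist = np.abs(Y - cy)
    elif ev.orientation == "vertical":
        dist = np.abs(X - cx)
    elif ev.orientation == "diagonal-45":     # bar along y = x
        dist = np.abs((Y - cy) - (X - cx)) / np.sqrt(2)
    else:                                      # diagonal-135, along y = -x
        dist = np.abs((Y - cy) + (X - cx)) / np.sqrt(2)
    sw, sh = screen
    on_screen = (np.abs(X + gx) <= sw / 2) & (np.abs(Y + gy) <= sh / 2)
    np.maximum(canvas, ((dist <= ev.width / 2) & on_screen).astype(np.float32),
               out=canvas)


@dataclass
class LayeredStimulus:
    """Deduplicated bar and periphery layers of a rendered run.

    The full movie at any (c_fix, c_post, d_post) configuration is
    ``clip(bar + c(t) * periphery, 0, 1)``; bar and periphery supports are
    disjoint by scene construction, so the composition is exact.
    """

    bar_unique: np.ndarray     # (Ub, H, W)
    bar_index: np.ndarray      # (T,)
    periph_unique: np.ndarray  # (Up, H, W)
    periph_index: np.ndarray   # (T,)
    saccade_frames: np.ndarray  # frame indices where modeled gaze changes
    ppd: float
    frame_rate_hz: float
    fov: tuple[float, float]

    @property
    def n_frames(self) -> int:
        return len(self.bar_index)

    def periph_contrast(self, c_fix: float, c_post: float,
                        d_post_frames: int) -> np.ndarray:
        """Per-frame peripheral contrast for a post-saccadic window length."""
        c = np.full(self.n_frames, c_fix, dtype=np.float32)
        for k in self.saccade_frames:
            c[k:k + d_post_frames] = c_post
        return c

    def compose(self, c_fix: float, c_post: float,
                d_post_frames: int) -> StimulusMovie:
        c = self.periph_contrast(c_fix, c_post, d_post_frames)
        keys: dict[tuple, int] = {}
        index = np.empty(self.n_frames, np.int32)
        frames = []
        for t in range(self.n_frames):
            key = (int(self.bar_index[t]), int(self.periph_index[t]),
                   float(c[t]))
            if key not in keys:
                keys[key] = len(frames)
                bi, pi, ct = key
                frames.append(np.clip(self.bar_unique[bi]
                                      + ct * self.periph_unique[pi], 0, 1))
            index[t] = keys[key]
        return StimulusMovie(np.stack(frames), index, self.ppd,
                             self.frame_rate_hz, self.fov)


def render_layers(design: DesignSpec, scene: SceneLayout | None,
                  cfg: RenderConfig) -> LayeredStimulus:
    """Render bar and periphery layers of a run at the design frame rate."""
    if scene is not None:
        if abs(scene.ppd - cfg.ppd) > 1e-9:
            raise ValueError("scene and render config disagree on ppd")
        fov = scene.fov
        screen = scene.screen_size
    elif design.bar_events:
        # scene-less (moving-bar) run: raster just covers the sweeps
        ext = max(max(abs(ev.center_x), abs(ev.center_y))
                  for ev in design.bar_events) + 2.0
        fov = (2 * ext, 2 * ext)
        screen = fov
    else:
        fov = (40.0, 22.0)
        screen = fov
    H, W = raster_shape(fov, cfg.ppd)
    X, Y = _coord_grids(fov, cfg.ppd)

    T = design.n_frames
    tgt = target_trace(design, design.frame_rate_hz)
    lat = cfg.latency_frames
    if lat > 0:
        gaze = np.vstack([np.repeat(tgt[:1], lat, axis=0), tgt[: T - lat]])
    else:
        gaze = tgt.copy()
    sacc = np.flatnonzero(np.any(np.diff(gaze, axis=0) != 0, axis=1)) + 1

    frame_t = np.arange(T) / design.frame_rate_hz
    active: list[tuple[int, ...]] = []
    for t in frame_t:
        active.append(tuple(i for i, ev in enumerate(design.bar_events)
                            if ev.onset_s - 1e-9 <= t < ev.offset_s - 1e-9))

    # bar layer: key on (gaze shift px, target offset px, active bars)
    bar_keys: dict[tuple, int] = {}
    bar_index = np.empty(T, np.int32)
    bar_frames: list[np.ndarray] = []
    draw_fix = scene is not None
    for t in range(T):
        gx, gy = gaze[t]
        off = (int(round((tgt[t, 0] - gx) * cfg.ppd)),
               int(round((tgt[t, 1] - gy) * cfg.ppd)))
        key = (round(gx * cfg.ppd), round(gy * cfg.ppd), off, active[t])
        if key not in bar_keys:
            canvas = np.zeros((H, W), np.float32)
            for i in active[t]:
                _paint_bar(canvas, X, Y, design.bar_events[i], gx, gy, screen)
            if draw_fix:
                fx = (tgt[t, 0] - gx, tgt[t, 1] - gy)
                dot = ((X - fx[0]) ** 2 + (Y - fx[1]) ** 2
                       <= scene.fixation_radius ** 2)
                np.maximum(canvas, dot.astype(np.float32), out=canvas)
            bar_keys[key] = len(bar_frames)
            bar_frames.append(canvas)
        bar_index[t] = bar_keys[key]

    # periphery layer: key on gaze shift only
    per_keys: dict[tuple, int] = {}
    per_index = np.empty(T, np.int32)
    per_frames: list[np.ndarray] = []
    for t in range(T):
        gx, gy = gaze[t]
        dy = -int(round(gy * cfg.ppd))
        dx = int(round(gx * cfg.ppd))
        key = (dy, dx)
        if key not in per_keys:
            canvas = np.zeros((H, W), np.float32)
            if scene is not None:
                for m in scene.elements.values():
                    _shift_into(canvas, m.astype(np.float32), dy, dx, 1.0)
            per_keys[key] = len(per_frames)
            per_frames.append(canvas)
        per_index[t] = per_keys[key]

    return LayeredStimulus(np.stack(bar_frames), bar_index,
                           np.stack(per_frames), per_index,
                           sacc, cfg.ppd, design.frame_rate_hz, fov)


def render_retinotopic_movie(design: DesignSpec, scene: SceneLayout | None,
                             cfg: RenderConfig) -> StimulusMovie:
    """Render the gaze-centered contrast movie of a run.

    Bars and the fixation target are drawn at contrast 1; peripheral scene
    elements at ``c_post`` for ``d_post_frames`` frames after each modeled
    gaze shift and ``c_fix`` otherwise.  The modeled gaze follows the target
    with ``latency_frames`` frames of lag.
    """
    layers = render_layers(design, scene, cfg)
    return layers.compose(cfg.c_fix, cfg.c_post, cfg.d_post_frames)


def downsample_movie(movie: StimulusMovie, ppd_out: float,
                     rate_out: float) -> StimulusMovie:
    """Spatial block-averaging and temporal within-bin averaging.

    Non-divisible factors fall back to nearest-integer resampling of the
    raster (local-mean resize) with a logged warning.
    """
    if ppd_out > movie.ppd + 1e-9 or rate_out > movie.frame_rate_hz + 1e-9:
        raise ValueError("downsampling only: ppd_out <= ppd, rate_out <= rate")
    from skimage.transform import resize_local_mean

    sf = movie.ppd / ppd_out
    if abs(sf - round(sf)) < 1e-9 and movie.height % round(sf) == 0 \
            and movie.width % round(sf) == 0:
        f = int(round(sf))
        u = movie.unique_frames
        uh, uw = u.shape[1] // f, u.shape[2] // f
        spat = u.reshape(len(u), uh, f, uw, f).mean(axis=(2, 4))
    else:
        h_out, w_out = raster_shape(movie.fov, ppd_out)
        logger.warning("non-integer spatial factor %.3f: resampling %dx%d "
                       "-> %dx%d by local mean", sf, movie.height,
                       movie.width, h_out, w_out)
        spat = np.stack([resize_local_mean(f_, (h_out, w_out))
                         for f_ in movie.unique_frames]).astype(np.float32)
    spat = np.clip(spat, 0.0, 1.0)

    tf = movie.frame_rate_hz / rate_out
    if abs(tf - round(tf)) > 1e-9:
        logger.warning("non-integer temporal factor %.3f: using %d",
                       tf, round(tf))
    tf = max(1, int(round(tf)))
    if tf == 1:
        return StimulusMovie(spat, movie.index, ppd_out, rate_out, movie.fov)
    n_out = movie.n_frames // tf
    idx = movie.index[: n_out * tf].reshape(n_out, tf)
    out = np.empty((n_out,) + spat.shape[1:], np.float32)
    for i in range(n_out):
        out[i] = spat[idx[i]].mean(axis=0)
    return StimulusMovie.from_frames(out, ppd_out, rate_out, movie.fov)
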