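import numpy as np
import pytest

from gazefield.fitting import build_pegf_grid, build_prf_grid
from gazefield.stimulus import (
    EyeTaskConfig,
    MovingBarConfig,
    RenderConfig,
    default_scene,
    make_design_eye_task,
    make_design_moving_bar,
)

# reduced rasters and timelines keep unit tests fast; the full-size defaults
# are exercised in the acceptance suite

SMALL_PPD = 2.0


@pytest.fixture(scope="session")
def small_eye_cfg():
    return EyeTaskConfig(n_sweeps=4, n_steps=6, n_baselines=3,
                         run_duration_s=120.0)


@pytest.fixture(scope="session")
def small_scene():
    return default_scene(ppd=SMALL_PPD)


@pytest.fixture(scope="session")
def small_render_cfg():
    return RenderConfig(ppd=SMALL_PPD)


@pytest.fixture(scope="session")
def small_eye_design(small_eye_cfg):
    return make_design_eye_task("A", small_eye_cfg, rng_seed=11)


@pytest.fixture(scope="session")
def small_bar_cfg():
    return MovingBarConfig(n_sweeps=4, n_steps=8, n_baselines=2,
                           fov=(12.0, 12.0))


@pytest.fixture(scope="session")
def small_bar_design(small_bar_cfg):
    return make_design_moving_bar(small_bar_cfg)


@pytest.fixture(scope="session")
def small_prf_grid():
    return build_prf_grid({"x_r0": np.linspace(-4, 4, 4),
                           "y_r0": np.linspace(-3, 3, 3),
                           "sigma_r": [0.7, 1.4, 2.8],
                           "n": [0.5, 1.0]})


@pytest.fixture(scope="session")
def small_pegf_grid():
    return build_pegf_grid({"x_e0": np.linspace(-6, 6, 5),
                            "y_e0": np.linspace(-3, 3, 3),
                            "sigma_e": [2.0, 4.0, 8.0],
                            "a": [0.3, 0.6, 1.0]})
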