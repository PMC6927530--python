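import numpy as np
import pytest
from hypothesis import settings

from ms2quant import synthetic
from ms2quant.movie_io import max_project
from ms2quant.segmentation import estimate_geometry, segment_nuclei

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def small_config(seed: int = 0, **overrides) -> synthetic.SimulationConfig:
    """A fast, down-scaled embryo used by unit tests: same structure as the
    default conditions, smaller field and fewer frames."""
    base = dict(
        shape=(192, 256),
        semi_axes=(70.0, 100.0),
        n_nuclei=30,
        window_frames={"nc12": 3, "nc13": 3, "nc14a": 3},
        activity={
            "nc12": synthetic.WindowActivity(4),
            "nc13": synthetic.WindowActivity(7),
            "nc14a": synthetic.WindowActivity(5),
        },
        seed=seed,
    )
    base.update(overrides)
    return synthetic.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config(seed=11)


@pytest.fixture(scope="session")
def small_movie(small_cfg):
    movie, truth = synthetic.generate_movie(small_cfg)
    return movie, truth


@pytest.fixture(scope="session")
def small_scene(small_movie):
    """Projection, geometry and nuclei for the small synthetic movie."""
    movie, truth = small_movie
    proj = max_project(movie)
    geometry = estimate_geometry(proj.channel("NUP")[0])
    nuclei = segment_nuclei(proj.channel("NUP")[0], geometry)
    return proj, geometry, nuclei, truth
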