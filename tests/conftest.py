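import numpy as np
import pytest

from forageq.rasters import GridSpec, RasterStack
from forageq.synthetic import EnvScenario, TruthParams, generate_env
from forageq.trajectory import Trip

np.seterr(all="ignore")


@pytest.fixture(scope="session")
def small_scenario():
    return EnvScenario(grid=GridSpec(0, 0, 1000.0, 40, 40),
                       years=(2015,), days=tuple(range(120, 141, 4)),
                       colony_xy=(20_000.0, 33_000.0))


@pytest.fixture(scope="session")
def truth():
    return TruthParams()

@pytest.fixture(scope="session")
def small_stacks(small_scenario, truth):
    return generate_env(small_scenario, truth, seed=11)


def make_trip(x, y, t=None, bird="b0", trip_id="b0_000", year=2015, day=150,
              step=None):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if t is None:
        t = np.arange(len(x), dtype=float) * 100.0
    return Trip(bird_id=bird, trip_id=trip_id, year=year, day=day,
                x=x, y=np.asarray(y, float), t=np.asarray(t, float),
                step_length=step)


def constant_stacks(values: dict, grid=None, days=(2015120,)):
    """Stacks with spatially constant layers (keys are year*1000+day)."""
    grid = grid or GridSpec(0, 0, 1000.0, 20, 20)
    out = {}
    for name, v in values.items():
        layers = {d: np.full((grid.ny, grid.nx), float(v)) for d in days}
        out[name] = RasterStack(name, grid, layers)
    return out
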