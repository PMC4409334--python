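import numpy as np
import pytest

from firescape.grid import BINARY, CATEGORICAL, CONTINUOUS, GridGeometry, Raster
from firescape.synthetic import LandscapeConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_raster(values, kind=CONTINUOUS, cell_size=1.0, nodata=None, name=""):
    values = np.asarray(values)
    geom = GridGeometry(values.shape[0], values.shape[1], cell_size)
    if nodata is None:
        nodata = np.nan if kind == CONTINUOUS else (255 if kind == BINARY else -1)
    return Raster(geom, values, kind=kind, nodata=nodata, name=name)


def recovery_config(n_rows=100, n_cols=100):
    """Moderately confounded landscape used by the ATT-recovery tests.

    Confounding is strong enough that the naive difference-in-means is
    visibly biased, yet overlap is good enough for 1-SD-caliper matching
    to stay close to the generator's closed-form truth.
    """
    cfg = LandscapeConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        confound_elevation=0.5,
        confound_population=-0.5,
        protected_fraction=0.15,
        smoothing_scale=8.0,
    )
    cfg.fire_coefficients = {
        "temperature": 0.8,
        "population_density": 0.6,
        "tree_cover": -0.3,
        "dist_road": -0.4,
        "elevation": -0.3,
    }
    return cfg
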