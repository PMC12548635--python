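import numpy as np
import pytest

from ctspacing import make_series, w584_series_spec, uniform_series_spec
from ctspacing.synthetic_data import PHANTOM_ELLIPSOID, SyntheticSeriesSpec


@pytest.fixture(scope="session")
def w584_geometry():
    geometry, _ = make_series(w584_series_spec())
    return geometry


@pytest.fixture(scope="session")
def uniform_geometry():
    geometry, _ = make_series(uniform_series_spec(spacing_mm=0.75, n_slices=10))
    return geometry


@pytest.fixture()
def small_multivolume_spec():
    return SyntheticSeriesSpec(
        specimen_id="SYN3x4",
        n_volumes=3,
        slices_per_volume=4,
        within_gap_mm=0.6,
        between_gap_mm=0.5,
        stated_spacing_mm=0.6,
    )


@pytest.fixture()
def phantom_spec():
    return SyntheticSeriesSpec(
        specimen_id="PHANTOM",
        n_volumes=5,
        slices_per_volume=6,
        within_gap_mm=0.6,
        between_gap_mm=0.5,
        stated_spacing_mm=0.6,
        n_rows=48,
        n_cols=48,
        phantom=PHANTOM_ELLIPSOID,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
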