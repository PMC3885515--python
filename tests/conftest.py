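import numpy as np
import pytest
from shapely.geometry import box

from fencekit.geo_core import ModelConfig, Parcel, ParcelSet

CRS = "EPSG:32613"


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


def km2_box(x0_km: float, y0_km: float, w_km: float, h_km: float):
    """Axis-aligned box given in kilometres (coordinates in metres)."""
    return box(x0_km * 1e3, y0_km * 1e3, (x0_km + w_km) * 1e3, (y0_km + h_km) * 1e3)


def parcel_set(*parcels: Parcel) -> ParcelSet:
    for i, p in enumerate(parcels):
        p.fid = i
    return ParcelSet(list(parcels), CRS)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
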