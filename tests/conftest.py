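import numpy as np
import pandas as pd
import pytest

from nircal.dataset import META_COLUMNS, SpectrumSet, WavenumberGrid
from nircal.protocol import build_protocol
from nircal.synth import NoiseModel, generate_protocol_dataset, make_pure_library


def make_set(values, wavenumbers=None, roles=None, nominals=None, series=None):
    """Small ad-hoc SpectrumSet for unit tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    if wavenumbers is None:
        wavenumbers = np.arange(p, dtype=float)[::-1]  # descending, step 1
    grid = WavenumberGrid.from_values(np.asarray(wavenumbers, dtype=float))
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "role": roles if roles is not None else ["cal"] * n,
        "series": series if series is not None else [1] * n,
        "level_index": [1] * n,
        "nominal_pct_ww": nominals if nominals is not None else [12.5] * n,
    }, columns=META_COLUMNS)
    return SpectrumSet(grid=grid, values=values, meta=meta, check_reflectance=False)


@pytest.fixture(scope="session")
def protocol():
    return build_protocol()


@pytest.fixture(scope="session")
def library():
    return make_pure_library(seed=7)


@pytest.fixture(scope="session")
def noiseless_data(protocol, library):
    return generate_protocol_dataset(protocol, library, NoiseModel.noiseless(), seed=7)


@pytest.fixture(scope="session")
def noisy_data(protocol, library):
    return generate_protocol_dataset(protocol, library, NoiseModel(), seed=7)
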