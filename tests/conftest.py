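import numpy as np
import pytest

from prairieq import GridSpec, LandCoverGrid, load_config
from prairieq.synth import DEFAULT_LEGEND

NAME_TO_CODE = {name: code for code, name in DEFAULT_LEGEND.items()}


def grid_from_names(rows, cell_size=30.0, origin=(0.0, 0.0)):
    """Build a LandCoverGrid from a nested list of class names."""
    codes = np.array([[NAME_TO_CODE[name] for name in row] for row in rows], dtype=np.int32)
    spec = GridSpec(codes.shape[0], codes.shape[1], cell_size, origin)
    return LandCoverGrid(spec, codes, dict(DEFAULT_LEGEND))


def uniform_grid(class_name, n_rows=9, n_cols=9, cell_size=30.0):
    return grid_from_names([[class_name] * n_cols] * n_rows, cell_size)


@pytest.fixture(scope="session")
def params():
    """Packaged default parameter bundle."""
    return load_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
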