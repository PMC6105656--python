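import numpy as np
import pandas as pd
import pytest

from ramancellid.spectral_data import (
    SpectralDataset,
    Spectrum,
    WavenumberAxis,
)
from ramancellid.synthetic_data import (
    SimulationConfig,
    default_templates,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def fingerprint_axis() -> WavenumberAxis:
    return WavenumberAxis.regular(600.0, 1800.0, 1.0)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


def make_dataset(matrix, axis=None, labels=None, cells=None) -> SpectralDataset:
    """Small dataset builder used across test modules."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = matrix.shape[0]
    if axis is None:
        axis = WavenumberAxis(np.arange(matrix.shape[1], dtype=float))
    meta = pd.DataFrame(
        {
            "cell_line": labels if labels is not None else ["X"] * n,
            "cell_id": cells if cells is not None else [f"c{i}" for i in range(n)],
        }
    )
    return SpectralDataset(axis, matrix, meta)


def lorentzian(v, center, fwhm, amplitude):
    g = fwhm / 2.0
    return amplitude * g * g / ((v - center) ** 2 + g * g)


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down five-class simulation shared by several test modules."""
    cfg = SimulationConfig(n_cells_per_class=4, n_points_per_cell=5, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_spectrum(fingerprint_axis) -> Spectrum:
    v = fingerprint_axis.values
    y = lorentzian(v, 1003.0, 12.0, 1.0) + lorentzian(v, 1440.0, 12.0, 0.8)
    return Spectrum(fingerprint_axis, y)
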