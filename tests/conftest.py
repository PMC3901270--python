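import numpy as np
import pytest

from mccims.model import MeasurementGrid, MeasurementMetadata
from mccims.synthdata import CohortSpec, peak_at


def make_grid(S, T=None, R=None, measurement_id="m1", **meta):
    """Wrap a raw array in a MeasurementGrid with default unit axes."""
    S = np.asarray(S, dtype=float)
    n_r, n_t = S.shape
    if T is None:
        T = 0.4 + 0.002 * np.arange(n_t)
    if R is None:
        R = 5.0 + 2.0 * np.arange(n_r)
    return MeasurementGrid(
        T=np.asarray(T, dtype=float),
        R=np.asarray(R, dtype=float),
        S=S,
        metadata=MeasurementMetadata(measurement_id=measurement_id, **meta),
    )


def random_grid(rng, n_r=20, n_t=20, lo=0.0, hi=20.0):
    return make_grid(rng.uniform(lo, hi, size=(n_r, n_t)))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """A reduced cohort for fast end-to-end tests: 6+6 measurements,
    small grid, four well-separated peaks (one differential)."""
    return CohortSpec(
        n_K=6,
        n_D=6,
        peaks=[
            peak_at(0.49, 30.0, volume=60.0),
            peak_at(0.52, 90.0, volume=50.0, class_effect=2.0),
            peak_at(0.55, 50.0, volume=55.0),
            peak_at(0.58, 130.0, volume=45.0),
        ],
        n_t=180,
        n_r=90,
        t_range=(0.44, 0.62),
        r_range=(0.0, 180.0),
        seed=7,
    )
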