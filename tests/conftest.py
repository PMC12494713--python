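import numpy as np
import pandas as pd
import pytest

from driftconn import (
    GeneratorParams,
    SessionImage,
    make_layout,
    make_schedule,
    simulate_covariates,
    simulate_sessions,
)


@pytest.fixture(scope="session")
def layout():
    return make_layout()


@pytest.fixture(scope="session")
def female_schedule():
    return make_schedule("female30")


@pytest.fixture(scope="session")
def quick_params():
    """Shorter sessions to keep simulation-backed unit tests fast."""
    return GeneratorParams(n_timepoints=120)


@pytest.fixture(scope="session")
def phantom(layout, female_schedule, quick_params):
    """One simulated 30-session phantom with covariates and ground truth."""
    rng = np.random.default_rng(20240917)
    covariates = simulate_covariates(female_schedule, quick_params, rng)
    images, truth = simulate_sessions(
        female_schedule, layout, quick_params, covariates, rng
    )
    return {"images": images, "truth": truth, "covariates": covariates}


def toy_session(signal, tr_s=0.72, labels=None, session_id="ses-01", y_mm=None):
    """Build a SessionImage straight from a voxel x time array."""
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[0]
    if labels is None:
        labels = ["roi"] * n
    voxels = pd.DataFrame(
        {
            "voxel_id": np.arange(n),
            "i": np.arange(n),
            "j": np.zeros(n, dtype=int),
            "k": np.zeros(n, dtype=int),
            "x_mm": np.arange(n, dtype=float),
            "y_mm": np.zeros(n) if y_mm is None else np.asarray(y_mm, float),
            "z_mm": np.zeros(n),
            "label": labels,
        }
    )
    return SessionImage(
        session_id=session_id, signal=signal, voxels=voxels, tr_s=tr_s
    )
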