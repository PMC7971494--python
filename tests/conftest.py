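import numpy as np
import pytest

from copulagm.model_core import MixedDataset
from copulagm.synthetic_data import discretize, simulate_latent


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_spd(rng, p, jitter=0.5):
    """Well-conditioned random SPD matrix."""
    A = rng.standard_normal((p, p))
    return A @ A.T + (p * jitter) * np.eye(p)


@pytest.fixture
def mixed_dataset(rng):
    """Small mixed-type multilevel dataset with some missing cells."""
    p = 5
    corr = np.full((p, p), 0.3) + 0.7 * np.eye(p)
    Omega = np.linalg.inv(0.85 * corr)
    Psi = 0.15 * np.eye(p)
    Z, cluster, _ = simulate_latent(6, 40.0, Omega, Psi, rng)
    spec = [
        ("continuous", None),
        ("binary", [0.6]),
        ("ordinal", [0.2, 0.4, 0.6, 0.8]),
        ("binary", [0.5]),
        ("continuous", None),
    ]
    data = discretize(Z, spec, cluster)
    mask = rng.random(data.values.shape) < 0.07
    values = data.values.copy()
    values[mask] = np.nan
    return MixedDataset(values=values, var_kind=data.var_kind,
                        cluster=cluster, missing_mask=mask,
                        columns=data.columns)
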