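"""Generators for multilevel mixed-type survey-like data.

Data are simulated from the same latent hierarchy the model assumes:
cluster effects b_c ~ N(0, Psi_true), latent rows z_ic ~ N(b_c,
Omega_true^{-1}), and observed columns obtained by monotone discretisation
of the latent scores (binary and ordinal columns cut at quantiles,
continuous columns passed through).  A built-in 4-variable benchmark
configuration with fixed true Psi and Omega -- chosen on the identified
scale where diag(Omega^{-1}) + diag(Psi) = 1 -- supports the coverage
experiment; missingness can be injected completely at random or
at random conditional on a fully observed driver column.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .model_core import MixedDataset, assert_spd

#: true random-effect covariance of the built-in 4-variable benchmark
BENCHMARK_PSI = np.array([
    [0.562, 0.090, 0.140, -0.028],
    [0.090, 0.212, 0.053, 0.030],
    [0.140, 0.053, 0.379, 0.050],
    [-0.028, 0.030, 0.050, 0.505],
])

#: true latent precision of the built-in 4-variable benchmark
BENCHMARK_OMEGA = np.array([
    [3.183, -0.918, 0.067, 1.209],
    [-0.918, 1.545, -0.028, -0.498],
    [0.067, -0.028, 1.613, 0.046],
    [1.209, -0.498, 0.046, 2.497],
])


def poisson_cluster_sizes(m: int, mean: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(mean) cluster sizes; zeros are redrawn (an empty cluster has
    no random-effect update)."""
    sizes = rng.poisson(mean, size=m)
    while np.any(sizes == 0):
        zero = sizes == 0
        sizes[zero] = rng.poisson(mean, size=int(zero.sum()))
    return sizes


def simulate_latent(m: int, cluster_size_mean: float, Omega_true: np.ndarray,
                    Psi_true: np.ndarray, rng: np.random.Generator):
    """Latent multilevel Gaussian sample.

    Returns ``(Z, cluster, B_true)`` with b_c ~ N(0, Psi_true) and rows
    z_ic ~ N(b_c, Omega_true^{-1}); cluster sizes are Poisson with zeros
    redrawn.
    """
    Omega_true = np.asarray(Omega_true, dtype=float)
    Psi_true = np.asarray(Psi_true, dtype=float)
    assert_spd(Omega_true, "Omega_true")
    assert_spd(Psi_true, "Psi_true")
    p = Omega_true.shape[0]
    sizes = poisson_cluster_sizes(m, cluster_size_mean, rng)
    cluster = np.repeat(np.arange(m), sizes)
    B_true = rng.multivariate_normal(np.zeros(p), Psi_true, size=m,
                                     method="cholesky")
    Sigma = np.linalg.inv(Omega_true)
    eps = rng.multivariate_normal(np.zeros(p), Sigma, size=cluster.size,
                                  method="cholesky")
    Z = B_true[cluster] + eps
    return Z, cluster, B_true


def benchmark_dataset(rng: np.random.Generator) -> MixedDataset:
    """One replicate of the built-in benchmark: m = 20 clusters, Poisson(50)
    sizes, four continuous columns generated from BENCHMARK_PSI /
    BENCHMARK_OMEGA, fully observed."""
    Z, cluster, _ = simulate_latent(20, 50.0, BENCHMARK_OMEGA, BENCHMARK_PSI, rng)
    return MixedDataset(
        values=Z,
        var_kind=["continuous"] * 4,
        cluster=cluster,
        missing_mask=np.zeros(Z.shape, dtype=bool),
        columns=[f"v{j + 1}" for j in range(4)],
    )


def discretize(Z: np.ndarray, column_spec: list, cluster: np.ndarray,
               columns=None, cohort_of_cluster=None) -> MixedDataset:
    """Monotone discretisation of latent columns into a mixed-type dataset.

    ``column_spec`` holds one ``(kind, thresholds)`` pair per column:
    ``("continuous", None)`` passes the column through, ``("binary", [q])``
    cuts at one quantile and ``("ordinal", [q_1 < ... < q_{k-1}])`` at k-1
    quantiles of the realised column, so observed ranks are coarsenings of
    the latent ranks.
    """
    Z = np.asarray(Z, dtype=float)
    values = np.empty_like(Z)
    kinds = []
    for j, (kind, qs) in enumerate(column_spec):
        kinds.append(kind)
        if kind == "continuous":
            values[:, j] = Z[:, j]
            continue
        qs = np.asarray(qs, dtype=float)
        if np.any(qs <= 0) or np.any(qs >= 1) or np.any(np.diff(qs) <= 0):
            raise ValueError("thresholds must be strictly increasing within (0, 1)")
        if kind == "binary" and qs.size != 1:
            raise ValueError("binary columns take exactly one threshold")
        cuts = np.quantile(Z[:, j], qs)
        values[:, j] = np.searchsorted(cuts, Z[:, j], side="right")
    return MixedDataset(
        values=values,
        var_kind=kinds,
        cluster=cluster,
        missing_mask=np.zeros(values.shape, dtype=bool),
        columns=columns,
        cohort_of_cluster=cohort_of_cluster,
    )


def inject_missing(data: MixedDataset, rate: float, mechanism: str = "mcar",
                   rng: np.random.Generator | None = None,
                   driver: int = 0, slope: float = 1.0) -> MixedDataset:
    """Blank out cells completely at random or at random given a driver.

    MCAR sets each cell missing with probability ``rate``.  The MAR
    mechanism leaves the driver column fully observed and blanks the other
    columns with probability ``expit(a + slope * x)`` of the standardised
    driver value ``x``, with the intercept ``a`` solved so the expected
    rate equals ``rate`` -- missingness then depends on observed data
    only.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    mask = data.missing_mask.copy()
    values = data.values.copy()
    N, p = values.shape
    if rate > 0:
        if mechanism == "mcar":
            mask |= rng.random((N, p)) < rate
        elif mechanism == "mar":
            x = values[:, driver]
            x = (x - x.mean()) / (x.std() or 1.0)
            a = brentq(lambda a0: expit(a0 + slope * x).mean() - rate, -40, 40)
            prob = expit(a + slope * x)
            new = rng.random((N, p)) < prob[:, None]
            new[:, driver] = False
            mask |= new
        else:
            raise ValueError(f"unknown mechanism {mechanism!r}")
        # keep every cluster represented and avoid fully missing columns
    values[mask] = np.nan
    return MixedDataset(values=values, var_kind=list(data.var_kind),
                        cluster=data.cluster.copy(), missing_mask=mask,
                        columns=list(data.columns),
                        cohort_of_cluster=data.cohort_of_cluster)


def rare_outcome_dataset(rng: np.random.Generator, m: int = 20,
                         cluster_size_mean: float = 50.0,
                         prevalence_quantile: float = 0.994,
                         signal: float = 0.7):
    """Mixed-type dataset with a rare binary outcome driven by three latent
    coordinates; used to exercise the posterior-predictive risk score.

    The last of eight variables is the outcome: its latent score loads
    with weight ``signal`` on the equally weighted sum of the first three
    latent coordinates, and is dichotomised at the ``prevalence_quantile``
    of its realised values (0.994 emulates a ~0.6% prevalence).  Columns
    span all three ordered types.  Returns ``(MixedDataset, truth dict)``.

    ``signal`` defaults to 0.7 (half the outcome's latent variance
    explained): a strong but imperfect coupling.  Loadings much closer to
    1 make the handful of observed cases quasi-separable on the latent
    index, and the outcome's precision entries then have no finite
    posterior mode to settle on -- the analogue of likelihood divergence
    under separation in probit regression.
    """
    p = 8
    e = p - 1
    corr = np.eye(p)
    load = signal / np.sqrt(3.0)
    for j in range(3):
        corr[e, j] = corr[j, e] = load
    Gamma_true = 0.9 * corr          # total latent variance 1 with Psi below
    Psi_true = 0.1 * np.eye(p)
    Omega_true = np.linalg.inv(Gamma_true)
    Z, cluster, B_true = simulate_latent(m, cluster_size_mean, Omega_true,
                                         Psi_true, rng)
    spec = [
        ("continuous", None),
        ("continuous", None),
        ("ordinal", np.linspace(1 / 11, 10 / 11, 10)),   # 11-point scale
        ("binary", [0.5]),
        ("binary", [0.7]),
        ("ordinal", [0.25, 0.5, 0.75]),
        ("continuous", None),
        ("binary", [prevalence_quantile]),
    ]
    data = discretize(Z, spec, cluster,
                      columns=[f"q{j + 1}" for j in range(p - 1)] + ["outcome"])
    truth = {"Omega": Omega_true, "Psi": Psi_true, "Gamma": Gamma_true,
             "Z": Z, "B": B_true, "outcome_index": e}
    return data, truth
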