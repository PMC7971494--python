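"""Core domain types and shared linear-algebra primitives.

The model couples mixed-type ordered variables (continuous / ordinal /
binary) through a Gaussian copula on latent scores ``z``.  Rows are grouped
into clusters (e.g. schools) whose latent means are shifted by random
effects ``b_c`` with covariance ``Psi``; conditional dependence between
variables, after adjusting for the cluster effects, is encoded in the
latent precision matrix ``Omega``.

Everything in this module is deterministic: container dataclasses with
their validity invariants, and the column-partition / conditional-
coefficient / partial-correlation algebra used by both the Gibbs sampler
and the posterior summaries.  All indices are 0-based; user-facing column
names are resolved in :mod:`copulagm.cli_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

VAR_KINDS = ("continuous", "ordinal", "binary")

#: relative eigenvalue floor below which a symmetric matrix is treated as
#: numerically non-SPD (floating-point drift over thousands of sweeps)
SPD_RTOL = 1e-10


def symmetrize(M: np.ndarray) -> np.ndarray:
    """Return ``(M + M.T) / 2``; applied after every stochastic update."""
    return (M + M.T) / 2.0


def assert_spd(M: np.ndarray, name: str = "matrix") -> None:
    """Raise ``ValueError`` unless ``M`` is symmetric positive definite.

    Positive definiteness is judged relative to the largest eigenvalue
    (min eig > SPD_RTOL * max eig) to be robust to accumulated round-off.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(symmetrize(M))
    if eig[0] <= SPD_RTOL * max(eig[-1], 1e-300):
        raise ValueError(f"{name} is not positive definite (min eig {eig[0]:.3e})")


@dataclass
class MixedDataset:
    """Observed mixed-type data with cluster labels and a missing mask.

    Parameters
    ----------
    values
        ``(N, p)`` float array of observed responses.  Ordinal/binary
        levels are stored as integer-valued floats; missing cells hold NaN.
    var_kind
        Per-column label, each one of ``{"continuous", "ordinal", "binary"}``.
    cluster
        ``(N,)`` integer cluster index in ``0..m-1``; every index occupied.
    missing_mask
        ``(N, p)`` booleans, True where the response is missing.
    columns
        Optional column names (defaults ``v0..v{p-1}``).
    cohort_of_cluster
        Optional map cluster index -> cohort label, used by cohort
        contrasts.
    """

    values: np.ndarray
    var_kind: Sequence[str]
    cluster: np.ndarray
    missing_mask: np.ndarray
    columns: Sequence[str] | None = None
    cohort_of_cluster: Mapping[int, object] | None = None

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        self.cluster = np.asarray(self.cluster, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.columns is None:
            self.columns = [f"v{j}" for j in range(self.values.shape[1])]
        self.columns = list(self.columns)
        self.values[self.missing_mask] = np.nan
        self.validate()

    # -- shape properties ------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_var(self) -> int:
        return self.values.shape[1]

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max()) + 1

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster, minlength=self.n_clusters)

    def validate(self) -> None:
        N, p = self.values.shape
        if p < 1:
            raise ValueError("need at least one variable")
        if len(self.var_kind) != p:
            raise ValueError("var_kind length mismatch")
        for kind in self.var_kind:
            if kind not in VAR_KINDS:
                raise ValueError(f"unknown variable kind {kind!r}")
        if self.cluster.shape != (N,) or self.missing_mask.shape != (N, p):
            raise ValueError("cluster / missing_mask shape mismatch")
        if self.cluster.min() < 0:
            raise ValueError("cluster indices must be non-negative")
        if np.any(self.cluster_sizes == 0):
            empty = np.where(self.cluster_sizes == 0)[0]
            raise ValueError(f"empty cluster index {empty.tolist()}")
        # observed NaN cells must be declared missing
        undeclared = np.isnan(self.values) & ~self.missing_mask
        if undeclared.any():
            raise ValueError("NaN values present outside the missing mask")
        for j, kind in enumerate(self.var_kind):
            col = self.values[~self.missing_mask[:, j], j]
            if kind == "binary" and col.size and not np.isin(col, (0.0, 1.0)).all():
                raise ValueError(
                    f"binary column {self.columns[j]!r} has levels outside {{0,1}}"
                )
        if self.cohort_of_cluster is not None:
            missing = set(range(self.n_clusters)) - set(self.cohort_of_cluster)
            if missing:
                raise ValueError(f"clusters without cohort label: {sorted(missing)}")


@dataclass
class LatentState:
    """Latent Gaussian matrix ``Z`` consistent with the observed ranks."""

    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.array(self.Z, dtype=float)

    def rank_violations(self, data: MixedDataset) -> int:
        """Count observed pairs (h, n) within a column with
        ``y_h < y_n`` but ``z_h >= z_n`` (should be zero for a valid state).
        """
        total = 0
        for j in range(data.n_var):
            obs = ~data.missing_mask[:, j]
            y, z = data.values[obs, j], self.Z[obs, j]
            levels = np.unique(y)
            # max z of each level must stay below min z of every higher level
            prev_max = -np.inf
            for lev in levels:
                zl = z[y == lev]
                total += int(np.sum(zl <= prev_max))
                prev_max = max(prev_max, zl.max())
        return total


@dataclass
class PrecisionState:
    """Precision matrix with its element-wise shrinkage and scale-mixture
    auxiliaries.

    ``omega`` is the p x p latent precision, ``lam`` the matching matrix of
    adaptive shrinkage rates (one per unique element), ``tau`` the
    inverse-Gaussian scale-mixture auxiliaries (zero diagonal).
    """

    omega: np.ndarray
    lam: np.ndarray
    tau: np.ndarray

    def validate(self) -> None:
        assert_spd(self.omega, "omega")
        if np.any(self.lam <= 0):
            raise ValueError("lam entries must be positive")
        if np.any(np.diag(self.tau) != 0):
            raise ValueError("tau diagonal must be zero")
        off = self.tau[~np.eye(self.tau.shape[0], dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("tau off-diagonals must be positive")


@dataclass
class RandomEffects:
    """Per-cluster latent mean shifts ``B`` (m x p) and their covariance ``psi``."""

    B: np.ndarray
    psi: np.ndarray

    def validate(self) -> None:
        assert_spd(self.psi, "psi")
        if self.B.shape[1] != self.psi.shape[0]:
            raise ValueError("B / psi dimension mismatch")


@dataclass
class Hyperparameters:
    """Sampler configuration.

    ``s`` and ``t`` are the Gamma hyper-prior shape/rate controlling the
    adaptive shrinkage rates: the full conditional of each lambda_ij is
    Gamma(1 + s, |omega_ij| + t), so smaller ``t`` pushes the penalty on
    weak entries towards infinity.  ``nu`` and ``Lambda_prior`` are the
    Inverse-Wishart degrees of freedom and scale for the random-effect
    covariance (weakly informative defaults ``nu = p + 2``, identity scale).
    """

    s: float = 0.01
    t: float = 1e-4
    nu: float | None = None          # resolved to p + 2 at fit time
    Lambda_prior: np.ndarray | None = None  # resolved to identity at fit time
    n_iter: int = 20000
    thin: int = 10
    burn_frac: float = 0.5
    n_chains: int = 3
    seed: int = 0

    def resolved(self, p: int) -> "Hyperparameters":
        """Fill dimension-dependent defaults for a p-variable problem."""
        nu = self.nu if self.nu is not None else p + 2
        Lam = self.Lambda_prior if self.Lambda_prior is not None else np.eye(p)
        hp = Hyperparameters(self.s, self.t, nu, np.asarray(Lam, float),
                             self.n_iter, self.thin, self.burn_frac,
                             self.n_chains, self.seed)
        hp.validate(p)
        return hp

    def validate(self, p: int) -> None:
        if self.s <= 0 or self.t <= 0:
            raise ValueError("hyper-parameters s and t must be positive")
        if self.nu is not None and self.nu < p:
            raise ValueError("Inverse-Wishart degrees of freedom must be >= p")
        if not 0 <= self.burn_frac < 1:
            raise ValueError("burn_frac must lie in [0, 1)")
        if self.n_iter <= 0 or self.thin <= 0:
            raise ValueError("n_iter and thin must be positive")


@dataclass
class PosteriorDraws:
    """Thinned, post-burn-in draws saved by a chain.

    All matrices are stored on the identified (rescaled) scale on which
    ``diag(Gamma) + diag(Psi) = 1`` element-wise; ``Omega`` is the matching
    precision ``Gamma^{-1}``.
    """

    Gamma: np.ndarray            # (K, p, p)
    Omega: np.ndarray            # (K, p, p)
    Psi: np.ndarray              # (K, p, p)
    B: np.ndarray                # (K, m, p)
    Z: np.ndarray | None = None  # (K, N, p) when latent storage is enabled
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.Gamma.shape[0]

    @property
    def n_var(self) -> int:
        return self.Gamma.shape[1]


# ---------------------------------------------------------------------------
# deterministic linear algebra shared by sampler and summaries
# ---------------------------------------------------------------------------

def partition_column(M: np.ndarray, l: int):
    """Partition a symmetric matrix about column ``l``.

    Permutes row/column ``l`` to the last position and returns the blocks
    ``(M11, m12, m22)`` where ``M11`` is the (p-1) x (p-1) block over the
    remaining variables, ``m12`` the cross vector and ``m22`` the scalar
    diagonal element of variable ``l``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    p = M.shape[0]
    if not 0 <= l < p:
        raise IndexError(f"column index {l} out of range for p={p}")
    keep = np.r_[0:l, l + 1:p]
    return M[np.ix_(keep, keep)], M[keep, l], M[l, l]


def reassemble_column(M11: np.ndarray, m12: np.ndarray, m22: float, l: int) -> np.ndarray:
    """Inverse of :func:`partition_column`: rebuild the full matrix."""
    q = M11.shape[0]
    p = q + 1
    out = np.empty((p, p), dtype=float)
    keep = np.r_[0:l, l + 1:p]
    out[np.ix_(keep, keep)] = M11
    out[keep, l] = m12
    out[l, keep] = m12
    out[l, l] = m22
    return out


def conditional_coefficients(Gamma: np.ndarray, l: int, method: str = "gamma") -> np.ndarray:
    """Regression-type coefficients of the remaining variables on variable ``l``.

    From the conditional multivariate normal, the coefficient vector is
    ``Gamma_{-l,-l}^{-1} Gamma_{-l,l}``; equivalently ``-Omega_{l,-l} / Omega_{ll}``
    with ``Omega = Gamma^{-1}``.  Both routes are exposed (``method`` in
    ``{"gamma", "omega"}``) and agree to numerical tolerance.
    """
    Gamma = np.asarray(Gamma, dtype=float)
    p = Gamma.shape[0]
    if not 0 <= l < p:
        raise IndexError(f"response index {l} out of range for p={p}")
    if method == "gamma":
        G11, g12, _ = partition_column(Gamma, l)
        try:
            return np.linalg.solve(G11, g12)
        except np.linalg.LinAlgError as err:  # pragma: no cover - rare
            raise ValueError("singular Gamma block") from err
    elif method == "omega":
        omega = np.linalg.inv(Gamma)
        keep = np.r_[0:l, l + 1:p]
        return -omega[keep, l] / omega[l, l]
    raise ValueError(f"unknown method {method!r}")


def conditional_variance(Gamma: np.ndarray, l: int) -> float:
    """Schur complement ``Gamma_ll - Gamma_{l,-l} Gamma_{-l,-l}^{-1} Gamma_{-l,l}``,
    the residual variance of variable ``l`` given the others."""
    G11, g12, g22 = partition_column(np.asarray(Gamma, float), l)
    v = float(g22 - g12 @ np.linalg.solve(G11, g12))
    if v <= 0:
        raise ValueError("non-positive conditional variance (Gamma not SPD?)")
    return v


def partial_correlation(omega: np.ndarray) -> np.ndarray:
    """Standardize a precision matrix to partial correlations.

    Entry (i, j) is ``-omega_ij / sqrt(omega_ii * omega_jj)`` off the
    diagonal, 1 on the diagonal.
    """
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    scale = np.sqrt(np.outer(d, d))
    pc = -omega / scale
    np.fill_diagonal(pc, 1.0)
    return pc
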