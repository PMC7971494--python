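"""Block Gibbs sampler for the copula graphical model with cluster effects.

One iteration cycles:

1. cluster random effects  b_c | z, Psi, Omega
2. random-effect covariance  Psi | b  (Inverse-Wishart)
3. adaptive shrinkage rates  lambda_ij | omega_ij  (Gamma)
4. scale-mixture auxiliaries  tau_ij | lambda_ij, omega_ij  (reciprocal
   inverse-Gaussian)
5. precision matrix Omega, column by column, via the graphical-lasso data
   augmentation (each column's conditional is Gamma x multivariate normal,
   positive definite by Schur-complement construction)
6. rescaling of (Gamma = Omega^{-1}, Psi, B) to the identified scale on
   which each variable's total latent variance Gamma_gg + Psi_gg is 1 --
   the copula determines the latent scale only up to this normalisation
7. a full extended-rank-likelihood sweep of the latent matrix Z.

The rescaling is applied to the chain state itself (not just stored
draws), so Omega, Psi and B always live on the identified scale and the
saved draws are directly comparable across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import invwishart

from .model_core import (
    Hyperparameters,
    LatentState,
    MixedDataset,
    PosteriorDraws,
    RandomEffects,
    symmetrize,
)
from .rank_likelihood import column_rank_structure, normal_scores_init, update_latent_matrix

#: floor applied to |omega_ij| in the inverse-Gaussian mean (the scale
#: mixture requires a positive mean even when an entry passes through 0)
OMEGA_FLOOR = 1e-10

#: support truncation for the precision prior: Omega is restricted to the
#: cone of SPD matrices with condition number below this bound.  The
#: adaptive prior's penalty is scale-free for large entries (lambda ~
#: 1/|omega|), so for discrete columns -- whose rank event never excludes a
#: deterministic latent relationship -- the posterior has a degenerate
#: absorbing direction (the analogue of a mixture variance collapsing to
#: zero).  Truncating the support restores propriety; a sweep whose draw
#: leaves the cone is rejected, which is the exact Gibbs step for the
#: truncated model.  The bound still allows partial
#: correlations beyond 0.999, far past anything interpretable in survey
#: data, so inference in the interior is unchanged.
OMEGA_MAX_COND = 1e3


def _spd_cholesky(M: np.ndarray) -> np.ndarray:
    """Cholesky factor of a nominally-SPD matrix, eigen-clipping when
    accumulated round-off has pushed an eigenvalue through 0 (arises under
    extreme shrinkage where the precision spans many orders of magnitude)."""
    M = symmetrize(M)
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        floor = max(w[-1], 1.0) * 1e-12
        M = symmetrize((V * np.maximum(w, floor)) @ V.T)
        return np.linalg.cholesky(M)


def _spd_inverse(M: np.ndarray):
    """Stable inverse of a nominally-SPD matrix via :func:`_spd_cholesky`."""
    L = _spd_cholesky(M)
    inv_L = solve_triangular(L, np.eye(M.shape[0]), lower=True)
    return symmetrize(inv_L.T @ inv_L)


def sample_random_effects(Z: np.ndarray, data: MixedDataset, omega: np.ndarray,
                          psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw all cluster effects b_c ~ N((Psi^-1 + n_c Omega)^-1 Omega sum_i z_i,
    (Psi^-1 + n_c Omega)^-1), vectorised over clusters."""
    Z = np.asarray(Z, dtype=float)
    m, p = data.n_clusters, data.n_var
    n_c = data.cluster_sizes
    if np.any(n_c == 0):
        raise ValueError("empty cluster: random-effect update undefined")
    psi_inv = _spd_inverse(psi)
    sums = np.zeros((m, p))
    np.add.at(sums, data.cluster, Z)
    prec = psi_inv[None, :, :] + n_c[:, None, None] * omega[None, :, :]
    prec = (prec + np.transpose(prec, (0, 2, 1))) / 2.0
    try:
        L = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError:
        # extreme-shrinkage states can push a cluster's conditional
        # precision to the edge of definiteness; repair cluster-by-cluster
        L = np.stack([_spd_cholesky(prec[c]) for c in range(m)])
    # posterior mean solves prec b = Omega sum_i z_i; the draw adds
    # L^{-T} eps so its covariance is prec^{-1}
    means = np.linalg.solve(prec, (sums @ omega.T)[..., None])[..., 0]
    eps = rng.standard_normal((m, p, 1))
    noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), eps)[..., 0]
    return means + noise


def sample_psi(B: np.ndarray, nu: float, Lambda_prior: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart draw of the random-effect covariance:
    Psi ~ IW(nu + m, Lambda + sum_c b_c b_c^T)."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    m = B.shape[0] if B.size else 0
    p = Lambda_prior.shape[0]
    df = nu + m
    if df <= p - 1:
        raise ValueError("Inverse-Wishart degrees of freedom too small")
    scale = symmetrize(np.asarray(Lambda_prior, float) + (B.T @ B if m else 0.0))
    draw = invwishart.rvs(df=df, scale=scale, random_state=rng)
    return symmetrize(np.atleast_2d(draw))


def sample_shrinkage(omega: np.ndarray, s: float, t: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Adaptive shrinkage rates: lambda_ij ~ Gamma(1 + s, rate = |omega_ij| + t)
    independently for each unique element, symmetrised."""
    if s <= 0 or t <= 0:
        raise ValueError("s and t must be positive")
    p = omega.shape[0]
    iu = np.triu_indices(p)
    rate = np.abs(omega[iu]) + t
    draws = rng.gamma(shape=1.0 + s, scale=1.0 / rate)
    lam = np.zeros((p, p))
    lam[iu] = draws
    lam = lam + lam.T - np.diag(np.diag(lam))
    return lam


def sample_scaling(omega: np.ndarray, lam: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Scale-mixture auxiliaries: tau_ij = 1 / InverseGaussian(lambda_ij /
    |omega_ij|, lambda_ij^2) for i < j; zero diagonal."""
    p = omega.shape[0]
    iu = np.triu_indices(p, k=1)
    absw = np.maximum(np.abs(omega[iu]), OMEGA_FLOOR)
    mean = lam[iu] / absw
    ig = rng.wald(mean, lam[iu] ** 2)
    # clip to a finite range: a mixture precision of 1e12 is already an
    # effectively hard zero, and unbounded draws (|omega| ~ floor) make the
    # conditional precision of step 6 numerically indefinite
    ig = np.clip(ig, 1e-12, 1e12)
    tau = np.zeros((p, p))
    tau[iu] = 1.0 / ig
    return tau + tau.T


def update_precision_column(omega: np.ndarray, S: np.ndarray, tau: np.ndarray,
                            lam: np.ndarray, l: int, N: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Redraw column/row ``l`` of the precision matrix.

    With the column permuted last: gamma ~ Gamma(N/2 + 1, rate = (s22 +
    lambda22)/2), beta ~ N(-C s12, C) with C = ((s22 + lambda22)
    Omega11^{-1} + diag(tau12))^{-1}; then omega_12 = beta and omega_22 =
    gamma + beta^T Omega11^{-1} beta, so the Schur complement equals gamma
    > 0 and the update preserves positive definiteness exactly.
    """
    p = omega.shape[0]
    keep = np.r_[0:l, l + 1:p]
    s22 = float(S[l, l])
    lam22 = float(lam[l, l])
    gamma_draw = rng.gamma(shape=N / 2.0 + 1.0, scale=2.0 / (s22 + lam22))
    out = omega.copy()
    if p == 1:
        out[0, 0] = gamma_draw
        return out
    O11 = omega[np.ix_(keep, keep)]
    if not np.all(np.isfinite(O11)):
        raise ValueError("Omega_11 block is not finite")
    if O11.shape[0] == 1 and O11[0, 0] <= 0:
        raise ValueError("Omega_11 block is singular")
    try:
        inv11 = _spd_inverse(O11)
    except np.linalg.LinAlgError as err:
        raise ValueError("Omega_11 block is singular") from err
    s12 = S[keep, l]
    # tau holds the normal-mixture variances of the Laplace prior, so the
    # prior contribution to the conditional precision of omega_12 is 1/tau.
    # C = Cinv^{-1} is never formed: under heavy shrinkage 1/tau spans many
    # orders of magnitude and explicit inversion loses definiteness, while
    # the Cholesky factor of the (SPD by construction) Cinv stays stable.
    tau12 = tau[keep, l]
    Cinv = symmetrize((s22 + lam22) * inv11 + np.diag(1.0 / tau12))
    try:
        Lc = np.linalg.cholesky(Cinv)
    except np.linalg.LinAlgError:
        # near the edge of double precision (condition ~1e16 under extreme
        # shrinkage) the factorisation can fail although Cinv is SPD by
        # construction; a relative diagonal jitter restores it
        jitter = 1e-10 * np.trace(Cinv) / (p - 1)
        try:
            Lc = np.linalg.cholesky(Cinv + jitter * np.eye(p - 1))
        except np.linalg.LinAlgError as err:
            raise ValueError("conditional precision of the column is not SPD") from err
    # mean -C s12 and draw beta ~ N(-C s12, C) via two triangular solves
    mean = -solve_triangular(
        Lc.T, solve_triangular(Lc, s12, lower=True), lower=False)
    beta = mean + solve_triangular(Lc.T, rng.standard_normal(p - 1), lower=False)
    out[keep, l] = beta
    out[l, keep] = beta
    out[l, l] = gamma_draw + beta @ inv11 @ beta
    return out


def rescale_draws(Gamma_raw: np.ndarray, Psi_raw: np.ndarray, B_raw: np.ndarray):
    """Normalise to the identified copula scale.

    Entry (g, h) of both matrices is divided by sqrt((Gamma_gg + Psi_gg)
    (Gamma_hh + Psi_hh)) and column g of B by sqrt(Gamma_gg + Psi_gg), so
    that afterwards diag(Gamma) + diag(Psi) = 1 element-wise.  Idempotent
    on already-rescaled input.
    """
    d = np.diag(Gamma_raw) + np.diag(Psi_raw)
    if np.any(d <= 0):
        raise ValueError("non-positive total latent variance")
    denom = np.sqrt(np.outer(d, d))
    root = np.sqrt(d)
    return Gamma_raw / denom, Psi_raw / denom, np.atleast_2d(B_raw) / root


# ---------------------------------------------------------------------------
# chain orchestration
# ---------------------------------------------------------------------------

def run_chain(data: MixedDataset, hp: Hyperparameters,
              rng: np.random.Generator | int | None = None,
              chain_id: int = 0, store_z: bool = False,
              structure=None) -> PosteriorDraws:
    """Run one chain and return thinned post-burn-in draws.

    Draws are stored (and the chain state kept) on the identified scale
    where each variable's total latent variance is 1.  Fully reproducible
    from ``(hp.seed, chain_id)`` when ``rng`` is not given.
    """
    hp = hp.resolved(data.n_var)
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = hp.seed if rng is None else int(rng)
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(chain_id + 1)[chain_id])
    N, p = data.n_obs, data.n_var
    m = data.n_clusters
    if structure is None:
        structure = column_rank_structure(data)

    # --- initial state: normal-score latents, identity covariances ----------
    state = normal_scores_init(data, rng)
    omega = np.eye(p)
    psi = np.eye(p)
    lam = sample_shrinkage(omega, hp.s, hp.t, rng)  # one draw; overwritten each scan

    burn = int(hp.burn_frac * hp.n_iter)
    n_save = (hp.n_iter - burn) // hp.thin
    if n_save < 1:
        raise ValueError("no draws would be saved; lower burn_frac or thin")
    Gs = np.empty((n_save, p, p))
    Os = np.empty((n_save, p, p))
    Ps = np.empty((n_save, p, p))
    Bs = np.empty((n_save, m, p))
    Zs = np.empty((n_save, N, p)) if store_z else None

    k = 0
    for it in range(hp.n_iter):
        Z = state.Z
        B_raw = sample_random_effects(Z, data, omega, psi, rng)
        psi_raw = sample_psi(B_raw, hp.nu, hp.Lambda_prior, rng)
        lam = sample_shrinkage(omega, hp.s, hp.t, rng)
        tau = sample_scaling(omega, lam, rng)
        resid = Z - B_raw[data.cluster]
        S = resid.T @ resid
        prev_block = (omega, Gamma, psi, B) if it > 0 else None
        for l in range(p):
            omega = update_precision_column(omega, S, tau, lam, l, N, rng)
        Gamma_raw = _spd_inverse(omega)
        Gamma, psi, B = rescale_draws(Gamma_raw, psi_raw, B_raw)
        d = np.diag(Gamma_raw) + np.diag(psi_raw)
        omega = symmetrize(omega * np.sqrt(np.outer(d, d)))  # = Gamma^{-1}
        # support truncation on the post-rescale state: reject the whole
        # block if the precision left the bounded cone (see OMEGA_MAX_COND)
        eig = np.linalg.eigvalsh(omega)
        if (eig[0] <= 0 or eig[-1] > OMEGA_MAX_COND * eig[0]) and prev_block:
            omega, Gamma, psi, B = prev_block
        effects = RandomEffects(B=B, psi=psi)
        state = update_latent_matrix(data, state, Gamma, effects, rng, structure)
        if it >= burn and (it - burn) % hp.thin == hp.thin - 1 and k < n_save:
            Gs[k] = Gamma
            Os[k] = omega
            Ps[k] = psi
            Bs[k] = B
            if store_z:
                Zs[k] = state.Z
            k += 1

    meta = {"seed": hp.seed, "chain_id": chain_id, "s": hp.s, "t": hp.t,
            "nu": hp.nu, "n_iter": hp.n_iter, "thin": hp.thin,
            "burn_frac": hp.burn_frac, "columns": list(data.columns)}
    return PosteriorDraws(Gamma=Gs[:k], Omega=Os[:k], Psi=Ps[:k], B=Bs[:k],
                          Z=Zs[:k] if store_z else None, meta=meta)


def psrf(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor for one scalar
    parameter traced by ``chains`` of shape (n_chains, n_draws)."""
    x = np.asarray(chains, dtype=float)
    M, L = x.shape
    if M < 2 or L < 2:
        raise ValueError("need at least two chains of length two")
    W = x.var(axis=1, ddof=1).mean()
    Bn = x.mean(axis=1).var(ddof=1)  # = B / L
    if W <= 0:
        return 1.0 if Bn == 0 else np.inf
    var_hat = (L - 1) / L * W + Bn
    # floor at 1: values below 1 are finite-length artifacts of the
    # (L-1)/L factor, not evidence of convergence failure
    return float(max(1.0, np.sqrt(var_hat / W)))


def psrf_report(draws_list: list[PosteriorDraws], threshold: float = 1.05) -> pd.DataFrame:
    """Per-parameter PSRF over the unique Omega and Psi entries of several
    chains; the returned frame carries the fraction exceeding ``threshold``
    per matrix in ``.attrs['frac_above']``."""
    p = draws_list[0].n_var
    iu = np.triu_indices(p)
    rows = []
    for mat in ("Omega", "Psi"):
        stack = np.stack([getattr(d, mat) for d in draws_list])  # (M, K, p, p)
        for i, j in zip(*iu):
            r = psrf(stack[:, :, i, j])
            rows.append({"matrix": mat, "i": int(i), "j": int(j),
                         "param": f"{mat.lower()}_{i + 1}{j + 1}", "psrf": r})
    df = pd.DataFrame(rows)
    df.attrs["frac_above"] = {
        mat: float((df.loc[df.matrix == mat, "psrf"] > threshold).mean())
        for mat in ("Omega", "Psi")
    }
    return df


def run_chains(data: MixedDataset, hp: Hyperparameters, store_z: bool = False):
    """Run ``hp.n_chains`` independently seeded chains and compute the
    convergence report.  Returns ``(list of PosteriorDraws, psrf table)``."""
    hp = hp.resolved(data.n_var)
    if hp.n_chains < 2:
        warnings.warn("PSRF needs at least two chains; report will be empty")
    structure = column_rank_structure(data)
    children = np.random.SeedSequence(hp.seed).spawn(hp.n_chains)
    draws_list = []
    for c, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        draws_list.append(run_chain(data, replace(hp, seed=hp.seed), rng=rng,
                                    chain_id=c, store_z=store_z,
                                    structure=structure))
    report = psrf_report(draws_list) if hp.n_chains >= 2 else pd.DataFrame()
    return draws_list, report


# ---------------------------------------------------------------------------
# penalised-likelihood connection (used as a cross-check)
# ---------------------------------------------------------------------------

def log_posterior_omega(omega: np.ndarray, S: np.ndarray, N: int, lam: float) -> float:
    """Log posterior of Omega under a COMMON fixed shrinkage rate ``lam``,
    no random effects and fully observed Gaussian rows with scatter ``S``:

        (N/2) log det(Omega) - (1/2) tr(S Omega)
        - lam * (sum_{i<j} |omega_ij| + (1/2) sum_i omega_ii).

    Its maximiser coincides with the penalised-likelihood (graphical
    lasso) solution at penalty rho = lam / N on the full matrix l1 norm.
    Returns -inf outside the positive-definite cone.
    """
    omega = symmetrize(np.asarray(omega, dtype=float))
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    eig_min = np.linalg.eigvalsh(omega)[0]
    if eig_min <= 0:
        return -np.inf
    p = omega.shape[0]
    iu = np.triu_indices(p, k=1)
    pen = lam * (np.abs(omega[iu]).sum() + 0.5 * np.trace(omega))
    return 0.5 * N * logdet - 0.5 * float(np.sum(S * omega)) - pen


def map_omega(S: np.ndarray, N: int, lam: float, x0: np.ndarray | None = None) -> np.ndarray:
    """Numerically maximise :func:`log_posterior_omega` over symmetric
    matrices (parametrised by the lower triangle).  Intended for small p
    where the maximiser has no exactly-zero entries."""
    from scipy.optimize import minimize

    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    il = np.tril_indices(p)

    def unpack(x):
        M = np.zeros((p, p))
        M[il] = x
        return symmetrize(M + M.T - np.diag(np.diag(M)))

    def nll(x):
        val = log_posterior_omega(unpack(x), S, N, lam)
        return np.inf if not np.isfinite(val) else -val

    if x0 is None:
        x0 = np.linalg.inv(S / N + (lam / N) * np.eye(p))
    x_init = x0[il]
    res = minimize(nll, x_init, method="Nelder-Mead",
                   options={"maxiter": 20000, "xatol": 1e-9, "fatol": 1e-12})
    res = minimize(nll, res.x, method="Powell",
                   options={"maxiter": 20000, "xtol": 1e-10, "ftol": 1e-14})
    return unpack(res.x)
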