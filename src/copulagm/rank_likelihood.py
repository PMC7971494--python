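"""Extended-rank-likelihood truncation bounds and latent-variable updates.

Inference never touches the marginal distributions of the observed
variables: for each ordered column the latent Gaussian scores ``z`` are
only constrained to share the ordering of the observed values (the rank
event ``z in D``).  A Gibbs sweep therefore redraws every observed cell
from a univariate normal truncated between the largest latent value of any
strictly smaller observation and the smallest latent value of any strictly
larger observation (pooled over all N rows); missing cells are redrawn
from the untruncated conditional normal, which is exactly how
missing-at-random cells are integrated out.

The per-column sweep is a sequential scan over the distinct observed
levels in ascending order: lower bounds come from already-updated lower
levels (running maximum), upper bounds from the not-yet-updated higher
levels (suffix minima of the current state).  Ties share a level and do
not constrain each other.  The scan is compiled with numba; all
randomness enters as a vector of uniforms drawn from the caller's
``numpy.random.Generator``, so sweeps are reproducible from the seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model_core import (
    LatentState,
    MixedDataset,
    RandomEffects,
    conditional_coefficients,
    conditional_variance,
)

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def _ndtr(x):
    """Standard normal CDF via erfc; accurate in the lower tail."""
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _ndtri(u):
    """Standard normal quantile (Acklam's rational approximation with one
    Halley refinement); relative error near machine precision except in
    the extreme far tail (|x| > 8) where the raw approximation (~1e-9) is
    kept to avoid overflow in the refinement factor."""
    if u <= 0.0:
        return -np.inf
    if u >= 1.0:
        return np.inf
    p_low = 0.02425
    if u < p_low:
        q = math.sqrt(-2.0 * math.log(u))
        x = ((((( -7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
                + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            (((( 7.784695709041462e-03 * q + 3.224671290700398e-01) * q
                + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    elif u <= 1.0 - p_low:
        q = u - 0.5
        r = q * q
        x = ((((( -3.969683028665376e+01 * r + 2.209460984245205e+02) * r
                - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
                - 3.066479806614716e+01) * r + 2.506628277459239e+00) * q / \
            ((((( -5.447609879822406e+01 * r + 1.615858368580409e+02) * r
                - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
                - 1.328068155288572e+01) * r + 1.0)
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - u))
        x = -((((( -7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
                + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            (((( 7.784695709041462e-03 * q + 3.224671290700398e-01) * q
                + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    if abs(x) < 8.0:
        # one step of Halley's method; u and ndtr(x) share tail accuracy
        e = _ndtr(x) - u
        f = e * _SQRT2PI * math.exp(0.5 * x * x)
        x = x - f / (1.0 + 0.5 * x * f)
    return x


@njit(cache=True)
def _tail_exp_draw(a, b, u):
    """Quantile of the truncated-exponential approximation to a standard
    normal conditioned on (a, b), valid for a >> 0; used only when the
    interval mass underflows double precision."""
    rate = max(a, 1e-10)
    if b == np.inf:
        w = 1.0
    else:
        w = -math.expm1(-rate * (b - a))
    x = a - math.log1p(-u * w) / rate
    if x >= b:
        x = a + 0.999 * (b - a)
    return x


@njit(cache=True)
def _tn_std_draw(a, b, u):
    """Standard-normal draw truncated to (a, b) by inversion of u in (0,1).

    Works on whichever of the CDF / survival scales keeps precision: the
    survival function for intervals in the upper half, the CDF for the
    lower half (mirror symmetry)."""
    if a == -np.inf and b == np.inf:
        return _ndtri(u)
    if a + b > 0.0 or b == np.inf:
        # upper-half interval: survival scale
        sa = _ndtr(-a) if a > -np.inf else 1.0
        sb = _ndtr(-b) if b < np.inf else 0.0
        s = sa * (1.0 - u) + sb * u
        if s <= 0.0 or sa <= sb:
            x = _tail_exp_draw(a, b, u)
        else:
            x = -_ndtri(s)
    else:
        fa = _ndtr(a) if a > -np.inf else 0.0
        fb = _ndtr(b) if b < np.inf else 1.0
        f = fa * (1.0 - u) + fb * u
        if f <= 0.0 or fb <= fa:
            x = -_tail_exp_draw(-b, -a, 1.0 - u)
        else:
            x = _ndtri(f)
    # guard against round-off landing on a closed endpoint
    if x <= a:
        x = a + 1e-12 * (1.0 + abs(a)) if b == np.inf else a + 1e-12 * (b - a)
    elif x >= b:
        x = b - 1e-12 * (1.0 + abs(b)) if a == -np.inf else b - 1e-12 * (b - a)
    return x


@njit(cache=True)
def _sweep_column(zcol, mu, sd, order, level_ptr, u):
    """Sequential truncated-normal redraw of one column's observed cells.

    ``order`` lists observed row indices sorted by the observed value;
    ``level_ptr`` delimits runs of tied values (levels).  Upper bounds are
    suffix minima of the pre-sweep latent values over strictly higher
    levels; lower bounds are the running maximum over already-updated
    strictly lower levels.
    """
    n_levels = level_ptr.size - 1
    # per-level minima of the current (pre-sweep) state, then suffix minima
    sufmin = np.empty(n_levels + 1)
    sufmin[n_levels] = np.inf
    for k in range(n_levels - 1, -1, -1):
        lev_min = np.inf
        for t in range(level_ptr[k], level_ptr[k + 1]):
            v = zcol[order[t]]
            if v < lev_min:
                lev_min = v
        sufmin[k] = min(lev_min, sufmin[k + 1])
    run_lb = -np.inf
    for k in range(n_levels):
        lb = run_lb
        ub = sufmin[k + 1]
        lev_max = -np.inf
        for t in range(level_ptr[k], level_ptr[k + 1]):
            i = order[t]
            a = (lb - mu[i]) / sd
            b = (ub - mu[i]) / sd
            x = mu[i] + sd * _tn_std_draw(a, b, u[t])
            zcol[i] = x
            if x > lev_max:
                lev_max = x
        if lev_max > run_lb:
            run_lb = lev_max


def compute_rank_bounds(y_col: np.ndarray, z_col: np.ndarray, row: int,
                        missing: np.ndarray | None = None):
    """Truncation interval for the latent value of one observed cell.

    ``lb`` is the maximum current latent value over all rows (pooled
    across clusters) whose observed value is strictly smaller, ``ub`` the
    minimum over rows strictly larger; rows with missing observations are
    excluded and ties impose no constraint.
    """
    y_col = np.asarray(y_col, dtype=float)
    z_col = np.asarray(z_col, dtype=float)
    if missing is None:
        missing = np.isnan(y_col)
    if missing[row]:
        raise ValueError("row refers to a missing cell; use the untruncated update")
    yv = y_col[row]
    obs = ~missing
    below = obs & (y_col < yv)
    above = obs & (y_col > yv)
    lb = z_col[below].max() if below.any() else -np.inf
    ub = z_col[above].min() if above.any() else np.inf
    return lb, ub


def sample_latent_cell(mean: float, var: float, lb: float, ub: float,
                       rng: np.random.Generator) -> float:
    """One draw from Normal(mean, var) truncated to the open interval (lb, ub)."""
    if var <= 0:
        raise ValueError("variance must be positive")
    if lb >= ub:
        raise ValueError(
            f"invalid truncation interval ({lb}, {ub}); latent rank state corrupted"
        )
    sd = math.sqrt(var)
    u = float(rng.random())
    # keep u strictly inside (0,1)
    u = min(max(u, 1e-16), 1.0 - 1e-16)
    return mean + sd * _tn_std_draw((lb - mean) / sd, (ub - mean) / sd, u)


def column_rank_structure(data: MixedDataset):
    """Precompute, per column, the level structure used by the sweep:
    (observed rows sorted by value, level boundary pointers, missing rows)."""
    structure = []
    for l in range(data.n_var):
        miss = data.missing_mask[:, l]
        obs_idx = np.where(~miss)[0]
        y = data.values[obs_idx, l]
        srt = np.argsort(y, kind="stable")
        order = obs_idx[srt].astype(np.int64)
        ys = y[srt]
        if ys.size:
            starts = np.r_[0, np.where(np.diff(ys) > 0)[0] + 1, ys.size]
        else:
            starts = np.array([0], dtype=np.int64)
        structure.append((order, starts.astype(np.int64), np.where(miss)[0]))
    return structure


def update_latent_matrix(data: MixedDataset, state: LatentState, Gamma: np.ndarray,
                         effects: RandomEffects, rng: np.random.Generator,
                         structure=None) -> LatentState:
    """One full sweep of the latent matrix (all columns, all rows).

    Observed cells are redrawn from their rank-truncated conditional
    normals given the other p-1 latent coordinates of the row and the
    row's cluster effect; missing cells from the same conditionals without
    truncation.  The rank event is preserved by construction.
    """
    if structure is None:
        structure = column_rank_structure(data)
    Z = state.Z.copy()
    p = data.n_var
    Brow = effects.B[data.cluster]          # (N, p) per-row cluster effect
    for l in range(p):
        if p == 1:
            mu = Brow[:, 0].copy()
            var = float(np.asarray(Gamma).reshape(1, 1)[0, 0])
        else:
            # same algebra as conditional_coefficients/conditional_variance,
            # inlined without the symmetry re-validation (hot loop)
            keep = np.concatenate((np.arange(l), np.arange(l + 1, p)))
            G11 = Gamma[np.ix_(keep, keep)]
            g12 = Gamma[keep, l]
            w = np.linalg.solve(G11, g12)
            var = float(Gamma[l, l] - g12 @ w)
            if var <= 0:
                raise ValueError("non-positive conditional variance in sweep")
            mu = Brow[:, l] + (Z[:, keep] - Brow[:, keep]) @ w
        sd = math.sqrt(var)
        order, level_ptr, miss_idx = structure[l]
        zcol = Z[:, l].copy()
        if order.size:
            u = rng.random(order.size)
            np.clip(u, 1e-16, 1.0 - 1e-16, out=u)
            _sweep_column(zcol, mu, sd, order, level_ptr, u)
        if miss_idx.size:
            zcol[miss_idx] = mu[miss_idx] + sd * rng.standard_normal(miss_idx.size)
        Z[:, l] = zcol
    return LatentState(Z)


def normal_scores_init(data: MixedDataset, rng: np.random.Generator) -> LatentState:
    """Starting latent matrix: normal scores of within-column average ranks
    (ties share a score, so the start lies inside the rank event); missing
    cells start at standard-normal draws."""
    from scipy.stats import rankdata
    from scipy.special import ndtri

    N, p = data.values.shape
    Z = rng.standard_normal((N, p))
    for l in range(p):
        obs = ~data.missing_mask[:, l]
        y = data.values[obs, l]
        if y.size:
            r = rankdata(y, method="average")
            Z[obs, l] = ndtri(r / (y.size + 1.0))
    return LatentState(Z)
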