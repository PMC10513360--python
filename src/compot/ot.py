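"""Entropic, partially balanced optimal transport for annotation transfer.

The solver maps reference category profiles to observations in a shared
expression space.  The observation-side marginal (total counts per object)
is enforced exactly; the category-side marginal is relaxed toward a prior
through a Kullback-Leibler penalty with weight ``lam``.  With entropic
regularization ``epsilon`` the problem is strictly convex and solved by
Sinkhorn-Knopp alternating scaling, where the category-side update uses the
damped exponent lam / (lam + epsilon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data import CompositionMatrix, CountMatrix, ReferenceProfiles, log1p_normalize

__all__ = [
    "OTParams",
    "TransportPlan",
    "bhattacharyya",
    "cost_matrix",
    "sinkhorn_semi_unbalanced",
    "plan_to_composition",
]


@dataclass
class OTParams:
    """Solver parameters.

    epsilon : entropy regularization weight; values well below 0.005 stress
        the exp ranges of the scaling iteration and are not recommended.
    lam : weight of the KL penalty tying the category marginal to the prior.
    metric : 'bc' (Bhattacharyya), 'cos', or 'cos-log1p'.
    """

    epsilon: float = 0.005
    lam: float = 0.1
    metric: str = "bc"
    max_iter: int = 10000
    tol: float = 1e-8


@dataclass
class TransportPlan:
    """Coupling gamma (categories x observations) with its marginals."""

    category_ids: list
    obs_ids: list
    gamma: np.ndarray
    obs_marginal: np.ndarray
    type_prior: np.ndarray
    converged: bool = True

    def type_marginal(self) -> np.ndarray:
        return self.gamma.sum(axis=1)


def bhattacharyya(p: np.ndarray, q: np.ndarray) -> float:
    """Bhattacharyya coefficient sum_g sqrt(p_g q_g) of two distributions.

    Returns 1 for identical distributions, 0 for disjoint supports.  Zero
    vectors are allowed and give 0.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries in probability vector")
    return float(np.sqrt(p * q).sum())


def _row_normalize(values) -> np.ndarray:
    if sp.issparse(values):
        values = np.asarray(values.todense())
    values = np.asarray(values, dtype=np.float64)
    totals = values.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return values / totals


def cost_matrix(
    profiles: ReferenceProfiles, data: CountMatrix, metric: str = "bc"
) -> np.ndarray:
    """Dissimilarity M_tb between each category profile and observation.

    Cost is 1 - similarity so it is bounded in [0, 1] and vanishes when an
    observation equals a profile.  All-zero observations get cost 1 for all
    categories.
    """
    if list(profiles.gene_ids) != list(data.gene_ids):
        raise ValueError("profiles and data must share an aligned gene space")
    zero_obs = data.obs_totals() == 0
    if zero_obs.any():
        warnings.warn(f"{int(zero_obs.sum())} all-zero observations: cost set to 1")
    if metric == "bc":
        rows = _row_normalize(data.values)
        sim = np.sqrt(rows) @ np.sqrt(profiles.profiles)  # obs x cats
    elif metric in ("cos", "cos-log1p"):
        if metric == "cos-log1p":
            rows = log1p_normalize(data)
            cols = log1p_normalize(profiles.profiles.T)
        else:
            rows = _row_normalize(data.values)
            cols = profiles.profiles.T
        rn = np.linalg.norm(rows, axis=1, keepdims=True)
        cn = np.linalg.norm(cols, axis=1, keepdims=True)
        rn[rn == 0] = 1.0
        cn[cn == 0] = 1.0
        sim = (rows / rn) @ (cols / cn).T
    else:
        raise ValueError(f"unknown metric {metric!r}")
    M = 1.0 - sim.T  # categories x observations
    M[:, zero_obs] = 1.0
    return np.clip(M, 0.0, None)


def sinkhorn_semi_unbalanced(
    M: np.ndarray,
    c_b: np.ndarray,
    c_t: np.ndarray,
    params: OTParams | None = None,
    category_ids=None,
    obs_ids=None,
) -> TransportPlan:
    """Solve the entropy-regularized, category-side-relaxed transport problem.

        argmin_gamma  <gamma, M> + epsilon * sum gamma log gamma
                      + lam * KL(sum_b gamma_tb || c_t)
        s.t.          sum_t gamma_tb = c_b,   gamma >= 0

    The final update is on the observation side, so the observation marginal
    holds exactly.  Internally the marginals are normalized to unit mass and
    the solution rescaled, keeping epsilon's meaning independent of the total
    count scale.  Scaling runs in the exp domain and falls back to the log
    domain on under/overflow.
    """
    params = params or OTParams()
    M = np.asarray(M, dtype=np.float64)
    c_b = np.asarray(c_b, dtype=np.float64)
    c_t = np.asarray(c_t, dtype=np.float64)
    if not np.isfinite(M).all():
        raise ValueError("non-finite cost matrix")
    if (c_b <= 0).any() or (c_t <= 0).any():
        raise ValueError("marginals must be positive")
    total = c_b.sum()
    a = c_t / c_t.sum()  # category prior, unit mass
    b = c_b / total  # observation marginal, unit mass
    eps, lam = params.epsilon, params.lam
    fi = lam / (lam + eps)

    logK = -M / eps
    K = np.exp(logK)
    u = np.ones_like(a)
    v = np.ones_like(b)
    converged = False
    log_domain = not np.isfinite(K).all() or K.max() == 0
    if not log_domain:
        for _ in range(params.max_iter):
            Kv = K @ v
            u_new = np.where(Kv > 0, (a / np.maximum(Kv, 1e-300)) ** fi, 0.0)
            Ktu = K.T @ u_new
            v_new = b / np.maximum(Ktu, 1e-300)
            if (
                not np.isfinite(u_new).all()
                or not np.isfinite(v_new).all()
                or u_new.max() > 1e290
                or v_new.max() > 1e290
            ):
                log_domain = True
                break
            du = np.abs(u_new - u) / np.maximum(np.abs(u_new), 1e-300)
            dv = np.abs(v_new - v) / np.maximum(np.abs(v_new), 1e-300)
            u, v = u_new, v_new
            if max(du.max(), dv.max()) < params.tol:
                converged = True
                break
        gamma = (u[:, None] * K) * v[None, :]
    if log_domain:
        # stabilized iteration on f = eps*log(u), g = eps*log(v)
        f = np.zeros_like(a)
        g = np.zeros_like(b)
        loga = np.log(a)
        logb = np.log(b)
        converged = False
        for _ in range(params.max_iter):
            # logsumexp over observations of (logK + g/eps)
            S = logK + g[None, :] / eps
            lse_b = _logsumexp(S, axis=1)
            f_new = fi * eps * (loga - lse_b)
            S2 = logK + f_new[:, None] / eps
            lse_t = _logsumexp(S2, axis=0)
            g_new = eps * (logb - lse_t)
            df = np.abs(f_new - f).max()
            dg = np.abs(g_new - g).max()
            f, g = f_new, g_new
            if max(df, dg) < params.tol * eps:
                converged = True
                break
        gamma = np.exp(logK + f[:, None] / eps + g[None, :] / eps)
    if not converged:
        warnings.warn("Sinkhorn scaling did not converge within max_iter")
    gamma = gamma * total
    n_t, n_b = M.shape
    return TransportPlan(
        category_ids=list(category_ids) if category_ids is not None else list(range(n_t)),
        obs_ids=list(obs_ids) if obs_ids is not None else list(range(n_b)),
        gamma=gamma,
        obs_marginal=c_b,
        type_prior=c_t,
        converged=converged,
    )


def _logsumexp(x: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(x - m), axis=axis)) + m.squeeze(axis)
    return out


def plan_to_composition(plan: TransportPlan) -> CompositionMatrix:
    """Normalize the coupling per observation into composition rows.

    Observations that received no mass (zero column) get a uniform row with
    a warning.
    """
    gamma = plan.gamma
    colsums = gamma.sum(axis=0)
    zero = colsums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} observations received no transport mass")
    rho = np.empty_like(gamma.T)
    rho[~zero] = (gamma[:, ~zero] / colsums[~zero]).T
    rho[zero] = 1.0 / gamma.shape[0]
    return CompositionMatrix(plan.obs_ids, plan.category_ids, rho, "probability")
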