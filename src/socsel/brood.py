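"""Variance partitioning of arrival time among brood, year and residual.

If siblings from the same natal brood arrive at correlated times, part
of the apparent social structure in arrival phenotype may cascade from
natal effects. An intercept-only Gaussian mixed model with crossed
random intercepts for brood and year,

    y_ij = mu + b_brood(i) + c_year(i) + e_ij,

is fitted by maximum likelihood via an EM algorithm written against the
joint Gaussian posterior of all random effects, and the variance is
reported as fractions explained by brood and by year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

__all__ = ["VarianceComponents", "NonIdentifiableWarning", "variance_components"]


class NonIdentifiableWarning(UserWarning):
    """Design cannot separate a variance component from the residual."""


@dataclass(frozen=True)
class VarianceComponents:
    var_brood: float
    var_year: float
    var_resid: float
    n_used: int
    n_excluded: int
    n_broods: int
    n_years: int
    converged: bool
    n_iter: int
    loglik: float

    @property
    def total(self) -> float:
        return self.var_brood + self.var_year + self.var_resid

    @property
    def frac_brood(self) -> float:
        return self.var_brood / self.total

    @property
    def frac_year(self) -> float:
        return self.var_year / self.total


def _design(labels: np.ndarray):
    levels, codes = np.unique(labels, return_inverse=True)
    Z = sparse.coo_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), len(levels)),
    ).tocsr()
    return Z, len(levels)


def variance_components(
    arrival,
    brood_id,
    year_id,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> VarianceComponents:
    """ML variance components for crossed brood and year intercepts.

    EM iterates the Gaussian posterior of the stacked random effects
    (a dense q x q solve, cheap at field scales) until the marginal
    log-likelihood changes by less than ``tol``; non-convergence within
    ``maxiter`` iterations raises with the iteration trace. Individuals
    with unknown brood are dropped and counted. Component estimates are
    truncated at zero; a design with one observation per brood level
    cannot separate brood from residual variance and triggers
    :class:`NonIdentifiableWarning`.
    """
    y = np.asarray(arrival, dtype=float)
    brood = pd.Series(brood_id)
    year = pd.Series(year_id)
    keep = np.isfinite(y) & brood.notna().to_numpy() & year.notna().to_numpy()
    n_excluded = int((~keep).sum())
    y = y[keep]
    brood = brood[keep].to_numpy()
    year = year[keep].to_numpy()
    n = len(y)
    if n < 4:
        raise ValueError("too few observations for variance partitioning")

    Zb, qb = _design(brood)
    Zy, qy = _design(year)
    if qb < 2:
        raise ValueError("need at least two broods")
    if qb == n:
        warnings.warn(
            "one observation per brood: brood variance is confounded with "
            "the residual and the fit is not identifiable",
            NonIdentifiableWarning,
        )
    Z = sparse.hstack([Zb, Zy]).tocsr()
    q = qb + qy
    ZtZ = (Z.T @ Z).toarray()
    Zty = np.asarray(Z.T @ y).ravel()
    Zt1 = np.asarray(Z.T @ np.ones(n)).ravel()

    total = y.var(ddof=0)
    if total == 0:
        raise ValueError("arrival values are constant")
    mu = y.mean()
    vb, vy, ve = 0.2 * total, 0.2 * total, 0.6 * total
    floor = 1e-10 * total
    ll_old = -np.inf
    trace = []
    converged = False
    sb, sy = slice(0, qb), slice(qb, q)
    for it in range(1, maxiter + 1):
        g = np.concatenate([np.full(qb, max(vb, floor)), np.full(qy, max(vy, floor))])
        A = ZtZ / ve + np.diag(1.0 / g)
        cf = cho_factor(A, lower=True)
        r = Zty - mu * Zt1
        m = cho_solve(cf, r) / ve
        V = cho_solve(cf, np.eye(q))

        # marginal log-likelihood via the Woodbury identity
        logdet = (
            n * np.log(ve)
            + 2.0 * np.sum(np.log(np.diag(cf[0])))
            + np.sum(np.log(g))
        )
        r0 = y - mu
        quad = (r0 @ r0) / ve - (r @ m) / ve
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
        trace.append(ll)

        # PX-EM M-step (parameter-expanded: the working model carries a
        # free scale per factor, y = mu + a_b*Zb*ub + a_y*Zy*uy + e;
        # collapsing a back into the variances makes the plain-EM creep
        # near the optimum vanish while every step still increases the
        # likelihood)
        ezz = np.outer(m, m) + V           # E[u u']
        M = np.empty((2, 2))
        M[0, 0] = np.sum(ZtZ[sb, sb] * ezz[sb, sb])
        M[1, 1] = np.sum(ZtZ[sy, sy] * ezz[sy, sy])
        M[0, 1] = M[1, 0] = np.sum(ZtZ[sb, sy] * ezz[sb, sy])
        bvec = np.array([m[sb] @ r[sb], m[sy] @ r[sy]])
        try:
            a = np.linalg.solve(M + 1e-12 * np.trace(M) * np.eye(2), bvec)
        except np.linalg.LinAlgError:
            a = np.ones(2)
        vb = float(a[0] ** 2 * (np.trace(ezz[sb, sb])) / qb)
        vy = float(a[1] ** 2 * (np.trace(ezz[sy, sy])) / qy)
        ve = float((r0 @ r0 - 2.0 * a @ bvec + a @ M @ a) / n)
        scaled = np.concatenate([a[0] * m[sb], a[1] * m[sy]])
        mu = float((y - np.asarray(Z @ scaled).ravel()).mean())

        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    if not converged:
        raise RuntimeError(
            f"EM did not converge in {maxiter} iterations; "
            f"last log-likelihoods: {[round(v, 6) for v in trace[-5:]]}"
        )
    vb = max(vb, 0.0) if vb > floor else 0.0
    vy = max(vy, 0.0) if vy > floor else 0.0
    return VarianceComponents(
        var_brood=vb,
        var_year=vy,
        var_resid=max(ve, 0.0),
        n_used=n,
        n_excluded=n_excluded,
        n_broods=qb,
        n_years=qy,
        converged=converged,
        n_iter=it,
        loglik=float(trace[-1]),
    )
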