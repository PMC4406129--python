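"""Selection gradients on a trait and its social environment.

Total selection on a single trait splits into a nonsocial part acting
through an individual's own phenotype and a social part acting through
the phenotypes of its associates:

    s = P * beta_N + C_I * beta_S

where P is the phenotypic variance (1 after standardization), C_I is
the covariance of interacting phenotypes (the network assortativity
coefficient for one trait), and beta_N, beta_S are partial regression
gradients of fitness on the individual's own standardized trait z and
on the weighted mean trait of its associates zbar. With binary fitness
(territory acquired or not) the gradients are estimated by logistic
regression; a Gaussian option on relative fitness gives the classical
linear gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "StandardizedTrait",
    "SelectionGradients",
    "SelectionDecomposition",
    "standardize",
    "fit_gradients",
    "decompose",
]


@dataclass(frozen=True)
class StandardizedTrait:
    """Trait rescaled to zero mean and unit (population) variance."""

    z: np.ndarray
    mean: float
    sd: float

    @property
    def P(self) -> float:
        """Phenotypic variance after standardization (exactly 1)."""
        return 1.0


@dataclass(frozen=True)
class SelectionGradients:
    beta_N: float
    beta_S: float
    alpha: float
    se_N: float
    se_S: float
    p_N: float
    p_S: float
    n_used: int
    n_excluded: int
    family: str
    converged: bool
    separation: bool


@dataclass(frozen=True)
class SelectionDecomposition:
    P: float
    C_I: float
    beta_N: float
    beta_S: float

    @property
    def term_nonsocial(self) -> float:
        return self.P * self.beta_N

    @property
    def term_social(self) -> float:
        return self.C_I * self.beta_S

    @property
    def s_total(self) -> float:
        return self.term_nonsocial + self.term_social


def standardize(values) -> StandardizedTrait:
    """Zero-mean, unit-variance rescaling with the population (1/n) sd.

    The population sd (not the n-1 sample sd) keeps the standardized
    phenotypic variance exactly 1, which the decomposition assumes.
    Raises on fewer than two distinct values.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if len(np.unique(finite)) < 2:
        raise ValueError("cannot standardize a constant trait")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=0))
    return StandardizedTrait(z=(x - mean) / sd, mean=mean, sd=sd)


def fit_gradients(
    fitness,
    z,
    zbar,
    family: str = "binomial",
    tol: float = 1e-8,
    maxiter: int = 100,
) -> SelectionGradients:
    """Estimate nonsocial and social selection gradients.

    Fits ``fitness ~ alpha + beta_N * z + beta_S * zbar`` by maximum
    likelihood: a logit-link binomial GLM for binary fitness (default),
    or an identity-link Gaussian fit on relative fitness (w / mean w)
    for the classical linear gradients. Rows with undefined ``zbar``
    (isolates) are dropped and counted in ``n_excluded``.
    """
    w = np.asarray(fitness, dtype=float)
    z = np.asarray(z, dtype=float)
    zb = np.asarray(zbar, dtype=float)
    if not (len(w) == len(z) == len(zb)):
        raise ValueError("fitness, z and zbar must be aligned")
    keep = np.isfinite(w) & np.isfinite(z) & np.isfinite(zb)
    n_excluded = int((~keep).sum())
    w, z, zb = w[keep], z[keep], zb[keep]
    if len(w) < 4:
        raise ValueError("too few usable observations to fit gradients")
    if family == "binomial" and not np.isin(w, [0.0, 1.0]).all():
        raise ValueError("binomial family requires binary (0/1) fitness")
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    r = np.corrcoef(z, zb)[0, 1]
    if np.isfinite(r) and abs(r) > 0.999:
        raise ValueError(
            f"own trait and social environment are collinear (|r| = {abs(r):.4f})"
        )

    X = sm.add_constant(np.column_stack([z, zb]))
    separation = False
    if family == "binomial":
        model = sm.GLM(w, X, family=sm.families.Binomial())
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(maxiter=maxiter, tol=tol)
        for c in caught:
            if "PerfectSeparation" in type(c.message).__name__ or "separat" in str(c.message).lower():
                separation = True
        mu = res.fittedvalues
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
            separation = True
        converged = bool(getattr(res, "converged", True))
    else:
        mean_w = w.mean()
        if mean_w == 0:
            raise ValueError("mean fitness is zero; relative fitness undefined")
        res = sm.OLS(w / mean_w, X).fit()
        converged = True

    params, bse, pvals = res.params, res.bse, res.pvalues
    return SelectionGradients(
        beta_N=float(params[1]),
        beta_S=float(params[2]),
        alpha=float(params[0]),
        se_N=float(bse[1]),
        se_S=float(bse[2]),
        p_N=float(pvals[1]),
        p_S=float(pvals[2]),
        n_used=int(len(w)),
        n_excluded=n_excluded,
        family=family,
        converged=converged,
        separation=separation,
    )


def decompose(
    P: float, C_I: float, beta_N: float, beta_S: float
) -> SelectionDecomposition:
    """Split total selection into nonsocial and social contributions.

    ``s = P * beta_N + C_I * beta_S`` holds as an exact identity of the
    returned object; on standardized traits P = 1 so the nonsocial term
    is the gradient itself.
    """
    for name, v in (("P", P), ("C_I", C_I), ("beta_N", beta_N), ("beta_S", beta_S)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    return SelectionDecomposition(P=float(P), C_I=float(C_I), beta_N=float(beta_N), beta_S=float(beta_S))
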