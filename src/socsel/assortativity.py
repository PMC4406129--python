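"""Weighted assortativity of a continuous trait and its permutation null.

The assortativity coefficient r-hat is the edge-weight-weighted Pearson
correlation between the trait values at the two ends of every network
edge. Each undirected edge contributes both orientations, so the two
endpoint marginals coincide and the coefficient is symmetric; with equal
weights it reduces to Newman's continuous assortativity. For a single
trait it equals the covariance of interacting phenotypes (C^I) used in
the selection decomposition.

Statistical significance is assessed against a data-stream permutation
null: individuals are repeatedly swapped between gathering events under
constraints that keep every event size and every individual's number of
observations fixed, and the statistic is recomputed along the chain.
This respects the non-independence of association indices, which node
-label shuffles do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .gathering import GroupByIndividual
from .network import AssociationNetwork, _align_trait

__all__ = [
    "AssortativityResult",
    "PermutationNull",
    "AssortativityUndefinedError",
    "DegenerateGBIError",
    "weighted_assortativity",
    "assortativity_se",
    "DataStreamPermutation",
    "permute_datastream",
]


class AssortativityUndefinedError(ValueError):
    """No edges, or no trait variance across edge endpoints."""


class DegenerateGBIError(ValueError):
    """No legal observation swap exists in the group-by-individual matrix."""


@dataclass(frozen=True)
class AssortativityResult:
    r_hat: float
    n_edges: int          # undirected positive edges
    se: Optional[float] = None


@dataclass(frozen=True)
class PermutationNull:
    statistic_values: np.ndarray
    n_perm: int
    n_swaps_per_perm: int
    observed: float
    p_value: float


def _directed_sums(i, j, w, z):
    """Weighted moment sums over the directed edge list (both orientations)."""
    zi, zj = z[i], z[j]
    W = 2.0 * w.sum()
    s1 = (w * (zi + zj)).sum()           # sum w*j over directed edges
    s2 = (w * (zi**2 + zj**2)).sum()
    s12 = 2.0 * (w * zi * zj).sum()
    return W, s1, s2, s12


def _r_from_sums(W, s1, s2, s12):
    mean = s1 / W
    var = s2 / W - mean**2
    if var <= 0:
        return np.nan
    cov = s12 / W - mean**2
    return cov / var


def weighted_assortativity(
    network: AssociationNetwork, trait, with_se: bool = False
) -> AssortativityResult:
    """Edge-weight-weighted correlation of endpoint trait values.

    Raises :class:`AssortativityUndefinedError` when the network has no
    positive edge or the trait is constant across edge endpoints. The
    value is invariant to affine transforms of the trait and to global
    positive rescaling of the weights.
    """
    z = _align_trait(network, trait)
    i, j, w = network.edges()
    if len(w) == 0:
        raise AssortativityUndefinedError("network has no positive edges")
    sums = _directed_sums(i, j, w, z)
    r = _r_from_sums(*sums)
    if not np.isfinite(r):
        raise AssortativityUndefinedError("zero trait variance over edge endpoints")
    r = float(min(1.0, max(-1.0, r)))
    se = assortativity_se(network, trait) if with_se else None
    return AssortativityResult(r_hat=r, n_edges=len(w), se=se)


def assortativity_se(network: AssociationNetwork, trait) -> float:
    """Delete-one-edge jackknife standard error of r-hat.

    Each undirected edge (both orientations) is removed in turn and the
    coefficient recomputed by downdating the weighted moment sums; the
    usual jackknife variance over the n leave-one-out replicates gives
    the SE. Requires at least two edges.
    """
    z = _align_trait(network, trait)
    i, j, w = network.edges()
    m = len(w)
    if m < 2:
        raise AssortativityUndefinedError("jackknife SE needs at least two edges")
    W, s1, s2, s12 = _directed_sums(i, j, w, z)
    zi, zj = z[i], z[j]
    Wd = W - 2.0 * w
    s1d = s1 - w * (zi + zj)
    s2d = s2 - w * (zi**2 + zj**2)
    s12d = s12 - 2.0 * w * zi * zj
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1d / Wd
        var = s2d / Wd - mean**2
        cov = s12d / Wd - mean**2
        r_loo = np.where(var > 0, cov / np.where(var > 0, var, 1.0), np.nan)
    r_loo = r_loo[np.isfinite(r_loo)]
    if len(r_loo) < 2:
        return 0.0
    n = len(r_loo)
    return float(np.sqrt((n - 1) / n * ((r_loo - r_loo.mean()) ** 2).sum()))


class DataStreamPermutation:
    """Serial chain of observation swaps on a group-by-individual matrix.

    One step picks two (event, individual) incidences (e1, i), (e2, j)
    with i absent from e2 and j absent from e1 (and, if strata are
    given, e1 and e2 in the same stratum) and exchanges them. Row sums
    (event sizes) and column sums (observation counts) are conserved by
    construction at every step.
    """

    def __init__(
        self,
        gbi: GroupByIndividual,
        strata: Optional[Sequence] = None,
        rng: Optional[np.random.Generator] = None,
        max_tries: int = 100_000,
    ):
        self.matrix = gbi.toarray().copy()
        self.event_ids = list(gbi.event_ids)
        self.individuals = list(gbi.individuals)
        rows, cols = np.nonzero(self.matrix)
        if len(rows) == 0:
            raise DegenerateGBIError("empty group-by-individual matrix")
        self._rows = rows.astype(np.int64)
        self._cols = cols.astype(np.int64)
        if strata is not None:
            strata = np.asarray(strata)
            if len(strata) != self.matrix.shape[0]:
                raise ValueError("strata must label every event (row)")
            codes = {s: k for k, s in enumerate(dict.fromkeys(strata.tolist()))}
            self._strata = np.array([codes[s] for s in strata.tolist()])
        else:
            self._strata = None
        self.rng = rng if rng is not None else np.random.default_rng()
        self.max_tries = max_tries
        self.n_swaps_done = 0

    def step(self) -> None:
        """Perform one accepted swap (rejection-sampling candidate pairs)."""
        m = self.matrix
        n_inc = len(self._rows)
        for _ in range(self.max_tries):
            k1, k2 = self.rng.integers(0, n_inc, size=2)
            e1, i = self._rows[k1], self._cols[k1]
            e2, j = self._rows[k2], self._cols[k2]
            if e1 == e2 or i == j:
                continue
            if self._strata is not None and self._strata[e1] != self._strata[e2]:
                continue
            if m[e1, j] or m[e2, i]:
                continue
            m[e1, i] = 0
            m[e2, i] = 1
            m[e2, j] = 0
            m[e1, j] = 1
            self._rows[k1] = e2
            self._rows[k2] = e1
            self.n_swaps_done += 1
            return
        raise DegenerateGBIError(
            f"no legal swap found in {self.max_tries} candidate draws"
        )

    def current(self) -> GroupByIndividual:
        # swaps preserve validity by construction; skip re-validation
        return GroupByIndividual(
            self.matrix, self.event_ids, self.individuals, validate=False
        )


def permute_datastream(
    gbi: GroupByIndividual,
    statistic: Callable[[GroupByIndividual], float],
    n_perm: int = 1000,
    n_swaps: int = 1,
    strata: Optional[Sequence] = None,
    seed: Optional[int] = None,
    burn_in: int = 1000,
    alternative: str = "greater",
) -> PermutationNull:
    """Data-stream permutation null distribution of a GBI statistic.

    After ``burn_in`` accepted swaps, the statistic is recorded every
    ``n_swaps`` further swaps until ``n_perm`` null values exist. The
    p-value uses the add-one correction,
    ``(#{null >= observed} + 1) / (n_perm + 1)`` for the upper tail
    (the default: the hypothesis is stronger-than-chance assortment).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(statistic(gbi))
    chain = DataStreamPermutation(gbi, strata=strata, rng=np.random.default_rng(seed))
    for _ in range(burn_in):
        chain.step()
    values = np.empty(n_perm)
    for p in range(n_perm):
        for _ in range(n_swaps):
            chain.step()
        values[p] = statistic(chain.current())
    if alternative == "greater":
        p_value = (np.sum(values >= observed) + 1) / (n_perm + 1)
    elif alternative == "less":
        p_value = (np.sum(values <= observed) + 1) / (n_perm + 1)
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return PermutationNull(
        statistic_values=values,
        n_perm=n_perm,
        n_swaps_per_perm=n_swaps,
        observed=observed,
        p_value=float(p_value),
    )
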