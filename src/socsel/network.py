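"""Weighted association networks from flock co-membership.

Edge weights are the simple ratio index: the fraction of gathering
events involving either of two individuals in which both were present.
It estimates the probability that the pair forage in the same flock and
runs from 0 (never together) to 1 (always together). The per-individual
social environment is the edge-weight-weighted mean trait of associates,
the covariate the social selection gradient is estimated on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import sparse

from .gathering import GroupByIndividual

__all__ = ["AssociationNetwork", "SocialEnvironment", "simple_ratio_index", "social_environment"]


class AssociationNetwork:
    """Symmetric weighted network over a roster of individuals.

    ``weights`` may be dense or scipy-sparse; entries must lie in
    [0, 1] with a zero diagonal and exact symmetry. Sparse storage is
    kept sparse so thousands of individuals stay cheap.
    """

    def __init__(self, weights, roster: Sequence[str]):
        roster = list(roster)
        if sparse.issparse(weights):
            W = weights.tocsr().astype(float)
            if (abs(W - W.T) > 1e-12).nnz:
                raise ValueError("association matrix must be symmetric")
            if W.diagonal().any():
                raise ValueError("association matrix must have a zero diagonal")
            if W.data.size and (W.data.min() < 0 or W.data.max() > 1 + 1e-12):
                raise ValueError("edge weights must lie in [0, 1]")
        else:
            W = np.asarray(weights, dtype=float)
            if W.ndim != 2 or W.shape[0] != W.shape[1]:
                raise ValueError("association matrix must be square")
            if not np.allclose(W, W.T, atol=1e-12):
                raise ValueError("association matrix must be symmetric")
            if np.diagonal(W).any():
                raise ValueError("association matrix must have a zero diagonal")
            if W.size and (W.min() < 0 or W.max() > 1 + 1e-12):
                raise ValueError("edge weights must lie in [0, 1]")
        if W.shape[0] != len(roster):
            raise ValueError("roster length does not match matrix size")
        self.weights = W
        self.roster = roster
        self._index = {ind: i for i, ind in enumerate(roster)}

    @property
    def n(self) -> int:
        return len(self.roster)

    def toarray(self) -> np.ndarray:
        W = self.weights
        return W.toarray() if sparse.issparse(W) else np.asarray(W)

    def edges(self):
        """Unordered positive edges as (i, j, w) arrays with i < j."""
        W = self.weights
        if sparse.issparse(W):
            coo = sparse.triu(W, k=1).tocoo()
            mask = coo.data > 0
            return coo.row[mask], coo.col[mask], coo.data[mask]
        iu, ju = np.triu_indices(self.n, k=1)
        w = W[iu, ju]
        mask = w > 0
        return iu[mask], ju[mask], w[mask]

    def weighted_degree(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()

    def density(self) -> float:
        i, _, _ = self.edges()
        possible = self.n * (self.n - 1) / 2
        return len(i) / possible if possible else 0.0

    def subgraph(self, individuals: Sequence[str]) -> "AssociationNetwork":
        idx = np.array([self._index[i] for i in individuals])
        W = self.weights
        sub = W[np.ix_(idx, idx)] if not sparse.issparse(W) else W[idx][:, idx]
        return AssociationNetwork(sub, [self.roster[i] for i in idx])

    def to_edge_list(self) -> pd.DataFrame:
        i, j, w = self.edges()
        return pd.DataFrame(
            {
                "id_a": [self.roster[a] for a in i],
                "id_b": [self.roster[b] for b in j],
                "weight": w,
            }
        )


@dataclass
class SocialEnvironment:
    """Weighted mean associate trait and weighted degree per individual.

    ``zbar`` is NaN for isolates (weighted degree zero), whose social
    environment is undefined; they are flagged in ``isolated``.
    """

    zbar: np.ndarray
    weighted_degree: np.ndarray
    isolated: np.ndarray
    roster: list


def simple_ratio_index(gbi: GroupByIndividual) -> AssociationNetwork:
    """Simple-ratio-index network from a group-by-individual matrix.

    For a pair (A, B), ``w = x / (x + y)`` with x the number of events
    containing both and y the number containing exactly one; pairs never
    observed in overlapping event sets get weight 0. The denominator
    counts gathering events, so an edge estimates the probability of
    co-membership per flock either bird joins.
    """
    X = gbi.matrix
    n_obs = gbi.observation_counts().astype(float)
    if sparse.issparse(X):
        Xf = X.astype(float)
        C = (Xf.T @ Xf).tocoo()
        mask = (C.row != C.col) & (C.data > 0)
        r, c, x = C.row[mask], C.col[mask], C.data[mask]
        denom = n_obs[r] + n_obs[c] - x
        W = sparse.coo_matrix((x / denom, (r, c)), shape=(gbi.n_individuals,) * 2).tocsr()
        return AssociationNetwork(W, gbi.individuals)
    Xf = gbi.toarray().astype(float)
    C = Xf.T @ Xf
    np.fill_diagonal(C, 0.0)
    denom = n_obs[:, None] + n_obs[None, :] - C
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(denom > 0, C / denom, 0.0)
    np.fill_diagonal(W, 0.0)
    return AssociationNetwork(W, gbi.individuals)


def social_environment(
    network: AssociationNetwork,
    trait: Union[np.ndarray, pd.Series, dict],
) -> SocialEnvironment:
    """Per-individual weighted mean associate trait.

    ``zbar_i = sum_k w_ik z_k / sum_k w_ik`` over associates k of i.
    The trait must be defined (finite) for every individual that is
    anyone's associate; isolates get NaN and are flagged.
    """
    z = _align_trait(network, trait)
    deg = network.weighted_degree()
    has_neighbours = deg > 0
    bad = has_neighbours & ~np.isfinite(z)
    # an individual with missing trait invalidates its associates' zbar
    if bad.any():
        name = network.roster[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"trait undefined for networked individual {name!r}")
    zz = np.where(np.isfinite(z), z, 0.0)
    W = network.weights
    num = np.asarray(W @ zz).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        zbar = np.where(has_neighbours, num / deg, np.nan)
    return SocialEnvironment(
        zbar=zbar, weighted_degree=deg, isolated=~has_neighbours, roster=list(network.roster)
    )


def _align_trait(network: AssociationNetwork, trait) -> np.ndarray:
    if isinstance(trait, dict):
        trait = pd.Series(trait)
    if isinstance(trait, pd.Series):
        missing = [r for r in network.roster if r not in trait.index]
        if missing:
            raise ValueError(f"trait undefined for networked individual {missing[0]!r}")
        return trait.reindex(network.roster).to_numpy(dtype=float)
    z = np.asarray(trait, dtype=float)
    if z.shape != (network.n,):
        raise ValueError("trait vector must align with the network roster")
    return z
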