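"""Linking winter associations to breeding geography and competition.

Three analyses connect the winter social network to the spring breeding
map: (1) do connected dyads breed closer together than non-connected
dyads; (2) does breeding distance fall with edge weight more steeply
than expected when nestboxes are randomly reallocated; (3) a
per-individual competition index, the time-weighted ratio of local
birds to local nestboxes over the feeders an individual used.

All coordinates are planar metres (a projected CRS); no geographic
lat/long handling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import AssociationNetwork

__all__ = [
    "SiteMap",
    "CompetitionIndex",
    "DyadDistanceResult",
    "WeightDistanceResult",
    "build_sitemap",
    "dyad_distance_test",
    "weight_distance_slope",
    "competition_index",
    "visit_proportions",
]


@dataclass(frozen=True)
class SiteMap:
    """Feeders, nestboxes, and the nearest-feeder assignment of boxes."""

    feeders: pd.DataFrame          # feeder_id, x, y (sorted by feeder_id)
    boxes: pd.DataFrame            # box_id, x, y
    box_to_feeder: pd.Series       # index box_id -> feeder_id


@dataclass(frozen=True)
class CompetitionIndex:
    local_population: pd.Series       # per-feeder expected bird count
    local_competition: pd.Series      # per-feeder birds per used box
    individual_competition: pd.Series # per-individual time-weighted average


@dataclass(frozen=True)
class DyadDistanceResult:
    mean_connected: float
    mean_nonconnected: float
    n_connected: int
    n_nonconnected: int
    t: float
    p: float


@dataclass(frozen=True)
class WeightDistanceResult:
    slope: float
    se: float
    t: float
    p_rand: float
    n_dyads: int
    n_rand: int
    null_slopes: np.ndarray


def build_sitemap(feeders: pd.DataFrame, boxes: pd.DataFrame) -> SiteMap:
    """Assign every nestbox to its nearest feeder (Euclidean metres).

    Exact distance ties go to the lowest feeder id, so the assignment
    is deterministic.
    """
    feeders = feeders.sort_values("feeder_id").reset_index(drop=True)
    boxes = boxes.sort_values("box_id").reset_index(drop=True)
    fxy = feeders[["x", "y"]].to_numpy(dtype=float)
    bxy = boxes[["x", "y"]].to_numpy(dtype=float)
    d = np.hypot(bxy[:, 0:1] - fxy[None, :, 0], bxy[:, 1:2] - fxy[None, :, 1])
    nearest = d.argmin(axis=1)  # first minimum = lowest feeder_id
    mapping = pd.Series(
        feeders["feeder_id"].to_numpy()[nearest],
        index=pd.Index(boxes["box_id"], name="box_id"),
        name="feeder_id",
    )
    return SiteMap(feeders=feeders, boxes=boxes, box_to_feeder=mapping)


def _breeding_dyads(
    network: AssociationNetwork,
    breeding_xy: pd.DataFrame,
    exclude_cohabiting: bool = True,
):
    """All unordered dyads in which both individuals bred.

    Returns (weights, distances) over those dyads. ``breeding_xy`` maps
    individual_id -> (x, y); individuals absent from it did not breed.
    Dyads breeding at identical coordinates (mates sharing a box) are
    excluded by default.
    """
    ids = [r for r in network.roster if r in breeding_xy.index]
    if len(ids) < 2:
        raise ValueError("fewer than two breeders overlap the network roster")
    idx = [network._index[r] for r in ids]
    W = network.toarray()[np.ix_(idx, idx)]
    xy = breeding_xy.loc[ids, ["x", "y"]].to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(ids), k=1)
    d = np.hypot(xy[iu, 0] - xy[ju, 0], xy[iu, 1] - xy[ju, 1])
    w = W[iu, ju]
    if exclude_cohabiting:
        keep = d > 0
        d, w = d[keep], w[keep]
    return w, d, np.array(ids), iu, ju


def dyad_distance_test(
    network: AssociationNetwork,
    breeding_xy: pd.DataFrame,
    exclude_cohabiting: bool = True,
    equal_var: bool = False,
) -> DyadDistanceResult:
    """Compare breeding distances of connected vs non-connected dyads.

    Over all breeder dyads, a two-sample t-test (Welch by default) of
    Euclidean breeding distance between dyads with positive edge weight
    and dyads never observed together. The dyads are not independent;
    the test is reported as-is, mirroring standard practice, and should
    be read descriptively.
    """
    w, d, _, _, _ = _breeding_dyads(network, breeding_xy, exclude_cohabiting)
    conn = w > 0
    if conn.all() or not conn.any():
        raise ValueError("need both connected and non-connected breeding dyads")
    dc, dn = d[conn], d[~conn]
    if len(dc) < 2 or len(dn) < 2:
        raise ValueError("need at least two dyads in each class")
    t, p = stats.ttest_ind(dc, dn, equal_var=equal_var)
    return DyadDistanceResult(
        mean_connected=float(dc.mean()),
        mean_nonconnected=float(dn.mean()),
        n_connected=int(conn.sum()),
        n_nonconnected=int((~conn).sum()),
        t=float(t),
        p=float(p),
    )


def weight_distance_slope(
    network: AssociationNetwork,
    breeding_xy: pd.DataFrame,
    boxes: pd.DataFrame,
    n_rand: int = 1000,
    seed: Optional[int] = None,
    exclusive: bool = False,
    exclude_cohabiting: bool = True,
) -> WeightDistanceResult:
    """OLS slope of breeding distance on edge weight, with a nestbox null.

    The observed slope comes from connected breeding dyads. The null
    reallocates each breeder a uniformly random box from the full box
    list (independently, with replacement across breeders by default;
    ``exclusive=True`` samples boxes without replacement) and recomputes
    the slope ``n_rand`` times; ``p_rand`` is the lower-tail add-one
    probability that a null slope is at least as negative as observed.
    """
    w_all, d_all, ids, iu, ju = _breeding_dyads(
        network, breeding_xy, exclude_cohabiting=False
    )
    conn = w_all > 0
    if exclude_cohabiting:
        conn &= d_all > 0
    if conn.sum() < 3:
        raise ValueError("need at least three connected breeding dyads")
    w = w_all[conn]
    if np.ptp(w) == 0:
        raise ValueError("edge weights are constant over connected dyads")
    d = d_all[conn]
    res = stats.linregress(w, d)
    slope, se, tval = float(res.slope), float(res.stderr), float(res.slope / res.stderr)

    rng = np.random.default_rng(seed)
    bxy = boxes[["x", "y"]].to_numpy(dtype=float)
    n_b, n_ids = len(bxy), len(ids)
    ii, jj = iu[conn], ju[conn]
    wc = w - w.mean()
    ssw = (wc**2).sum()
    null = np.empty(n_rand)
    for r in range(n_rand):
        if exclusive:
            pick = rng.choice(n_b, size=n_ids, replace=False)
        else:
            pick = rng.integers(0, n_b, size=n_ids)
        xy = bxy[pick]
        dr = np.hypot(xy[ii, 0] - xy[jj, 0], xy[ii, 1] - xy[jj, 1])
        null[r] = (wc * (dr - dr.mean())).sum() / ssw
    p_rand = (np.sum(null <= slope) + 1) / (n_rand + 1)
    return WeightDistanceResult(
        slope=slope,
        se=se,
        t=tval,
        p_rand=float(p_rand),
        n_dyads=int(conn.sum()),
        n_rand=n_rand,
        null_slopes=null,
    )


def visit_proportions(detections: pd.DataFrame) -> pd.DataFrame:
    """Per-individual fraction of detections at each feeder.

    Detections are the only proxy for time use, so the proportion of an
    individual's reads at a feeder estimates the proportion of time it
    spent there. Rows sum to 1.
    """
    counts = (
        detections.groupby(["individual_id", "location_id"], sort=True)
        .size()
        .unstack(fill_value=0)
        .astype(float)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def competition_index(
    proportions: pd.DataFrame,
    sitemap: SiteMap,
    boxes_used: Sequence[str],
) -> CompetitionIndex:
    """Time-weighted local breeding competition per individual.

    ``local_population_f`` sums the visit proportions of all birds at
    feeder f (expected bird count there); ``local_competition_f``
    divides it by the number of used nestboxes assigned to f; each
    bird's ``individual_competition`` averages local competition over
    the feeders it visited, weighted by its time there. A feeder with
    birds but no used box leaves competition undefined and is an error.
    """
    if proportions.empty:
        raise ValueError("empty visit-proportion table")
    rowsum = proportions.sum(axis=1)
    if not np.allclose(rowsum.to_numpy(), 1.0, atol=1e-8):
        raise ValueError("visit proportions must sum to 1 per individual")
    boxes_used = pd.Index(boxes_used)
    missing = boxes_used.difference(sitemap.box_to_feeder.index)
    if len(missing):
        raise KeyError(f"unknown nestbox ids: {list(missing[:5])}")
    used_per_feeder = (
        sitemap.box_to_feeder.loc[boxes_used].value_counts().astype(int)
    )
    local_population = proportions.sum(axis=0)
    local_population.index.name = "feeder_id"
    n_boxes = used_per_feeder.reindex(local_population.index, fill_value=0)
    orphaned = local_population.index[(local_population > 0) & (n_boxes == 0)]
    if len(orphaned):
        raise ValueError(
            "feeders with birds but no used nestbox assigned: "
            f"{list(orphaned)}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        local_competition = local_population / n_boxes.replace(0, np.nan)
    local_competition = local_competition.fillna(0.0)
    individual = proportions.to_numpy() @ local_competition.to_numpy()
    return CompetitionIndex(
        local_population=local_population,
        local_competition=local_competition,
        individual_competition=pd.Series(
            individual, index=proportions.index, name="competition"
        ),
    )
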