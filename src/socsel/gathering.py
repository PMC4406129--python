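"""From raw detections to gathering events and the group-by-individual matrix.

Feeder visits by tagged birds come in short, dense bursts as flocks
arrive and feed together. Under the gambit of the group, every bird
detected in the same burst is taken to be associating with every other,
so the unit of observation is the gathering event, not the single read.
Two burst detectors are provided: a deterministic inter-detection gap
rule (default) and a 1-D Gaussian mixture with BIC model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "GatheringEvent",
    "GroupByIndividual",
    "WeekCalendar",
    "detect_events",
    "build_gbi",
    "first_detection_week",
]


@dataclass(frozen=True)
class GatheringEvent:
    """One detected flock visit at a feeder."""

    event_id: str
    location_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    members: frozenset

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"event {self.event_id}: start after end")
        if not self.members:
            raise ValueError(f"event {self.event_id}: empty membership")


class GroupByIndividual:
    """Binary events x individuals occurrence matrix.

    The substrate for association indices and data-stream permutations.
    ``matrix`` may be a dense uint8 array or a scipy CSR matrix; row
    sums are event sizes and column sums per-individual observation
    counts.
    """

    def __init__(
        self,
        matrix,
        event_ids: Sequence[str],
        individuals: Sequence[str],
        validate: bool = True,
    ):
        if sparse.issparse(matrix):
            matrix = matrix.tocsr().astype(np.uint8)
        else:
            matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.shape != (len(event_ids), len(individuals)):
            raise ValueError("matrix shape does not match index maps")
        if validate:
            data = matrix.data if sparse.issparse(matrix) else matrix
            if data.size and not np.isin(np.unique(data), [0, 1]).all():
                raise ValueError("GBI entries must be binary")
            row_sums = np.asarray(matrix.sum(axis=1)).ravel()
            if matrix.shape[0] and (row_sums == 0).any():
                raise ValueError("GBI contains an all-zero row (empty event)")
        self.matrix = matrix
        self.event_ids = list(event_ids)
        self.individuals = list(individuals)

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[1]

    def event_sizes(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(int)

    def observation_counts(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel().astype(int)

    def toarray(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sparse.issparse(m) else np.asarray(m)

    def copy(self) -> "GroupByIndividual":
        return GroupByIndividual(self.toarray().copy(), self.event_ids, self.individuals)


@dataclass(frozen=True)
class WeekCalendar:
    """Maps timestamps to 1-based sampling-week indices."""

    start: pd.Timestamp
    n_weeks: Optional[int] = None

    def week_of(self, timestamps) -> np.ndarray:
        ts = pd.to_datetime(pd.Series(timestamps))
        weeks = ((ts - pd.Timestamp(self.start)).dt.days // 7 + 1).to_numpy()
        if (weeks < 1).any():
            raise ValueError("detection earlier than the calendar start")
        if self.n_weeks is not None and (weeks > self.n_weeks).any():
            raise ValueError("detection beyond the final sampling week")
        return weeks


def _gap_segments(seconds: np.ndarray, max_gap_s: float) -> np.ndarray:
    """Label sorted timestamps: new segment wherever the gap exceeds max_gap_s."""
    if seconds.size == 0:
        return np.empty(0, dtype=int)
    return np.concatenate([[0], np.cumsum(np.diff(seconds) > max_gap_s)])


def _gmm_segments(seconds: np.ndarray, max_gap_s: float, k_max: int) -> np.ndarray:
    """1-D Gaussian mixture burst labels, component count by minimum BIC.

    Components whose means lie within ``max_gap_s`` of each other are
    merged, then labels are renumbered in time order.
    """
    from sklearn.mixture import GaussianMixture

    n_unique = np.unique(seconds).size
    if n_unique <= 1:
        return np.zeros(seconds.size, dtype=int)
    X = seconds.reshape(-1, 1)
    best, best_bic = None, np.inf
    for k in range(1, min(k_max, n_unique) + 1):
        gm = GaussianMixture(n_components=k, random_state=0, n_init=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    labels = best.predict(X)
    means = best.means_.ravel()
    order = np.argsort(means)
    # merge adjacent components closer than max_gap_s
    merged = np.empty_like(order)
    group = 0
    merged[order[0]] = 0
    for a, b in zip(order[:-1], order[1:]):
        if means[b] - means[a] >= max_gap_s:
            group += 1
        merged[b] = group
    return merged[labels]


def detect_events(
    detections: pd.DataFrame,
    method: str = "gap",
    max_gap_s: float = 600.0,
    k_max: int = 15,
    return_labels: bool = False,
):
    """Segment a detection stream into gathering events.

    Detections must be sorted by (location_id, timestamp); each
    location-day is segmented independently (flocks do not span
    midnight). ``method='gap'`` opens a new event whenever the
    inter-detection gap exceeds ``max_gap_s``; ``method='gmm'`` fits a
    1-D Gaussian mixture per location-day with the component count
    chosen by minimum BIC over 1..k_max and merges components whose
    means differ by less than ``max_gap_s``.

    With ``return_labels=True`` also returns the assigned event id per
    detection row (useful for validating the detector against known
    event labels).
    """
    required = {"individual_id", "location_id", "timestamp"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detections must have columns {sorted(required)}")
    if method not in ("gap", "gmm"):
        raise ValueError(f"unknown method {method!r}")
    if detections.empty:
        return ([], np.empty(0, dtype=object)) if return_labels else []

    loc = detections["location_id"].to_numpy()
    ts = pd.to_datetime(detections["timestamp"]).reset_index(drop=True)
    ind = detections["individual_id"].to_numpy()
    boundaries = np.flatnonzero(loc[1:] != loc[:-1])
    blocks = np.split(np.arange(len(detections)), boundaries + 1)
    seen = set()
    for idx in blocks:
        l = loc[idx[0]]
        if l in seen or not ts.iloc[idx].is_monotonic_increasing:
            raise ValueError("detections must be sorted by (location_id, timestamp)")
        seen.add(l)

    events = []
    read_labels = np.empty(len(detections), dtype=object)
    counter: dict = {}
    for idx in blocks:
        locid = loc[idx[0]]
        block_ts = ts.iloc[idx]
        days = block_ts.dt.normalize().to_numpy()
        for d in pd.unique(days):
            daymask = days == d
            pos = idx[daymask]
            day_ts = block_ts[daymask]
            seconds = (day_ts - pd.Timestamp(d)).dt.total_seconds().to_numpy()
            if method == "gap":
                labels = _gap_segments(seconds, max_gap_s)
            else:
                labels = _gmm_segments(seconds, max_gap_s, k_max)
            for lab in np.unique(labels):
                mask = labels == lab
                k = counter.get(locid, 0)
                counter[locid] = k + 1
                eid = f"{locid}-{pd.Timestamp(d).date()}-{k:04d}"
                read_labels[pos[mask]] = eid
                events.append(
                    GatheringEvent(
                        event_id=eid,
                        location_id=locid,
                        start=day_ts.iloc[np.flatnonzero(mask)[0]],
                        end=day_ts.iloc[np.flatnonzero(mask)[-1]],
                        members=frozenset(ind[pos[mask]]),
                    )
                )
    return (events, read_labels) if return_labels else events


def build_gbi(
    events: Iterable, roster: Sequence[str], sparse_output: bool = False
) -> GroupByIndividual:
    """Stack gathering events into a group-by-individual matrix.

    ``events`` may be GatheringEvent objects or a truth table
    DataFrame with columns (event_id, individual_id). Every member must
    be in ``roster``; row order follows event order, column order the
    roster.
    """
    roster = list(roster)
    col = {ind: j for j, ind in enumerate(roster)}
    if isinstance(events, pd.DataFrame):
        pairs = events[["event_id", "individual_id"]]
        event_ids = list(pd.unique(pairs["event_id"]))
        row = {e: i for i, e in enumerate(event_ids)}
        rows, cols = [], []
        for e, ind in pairs.itertuples(index=False):
            if ind not in col:
                raise KeyError(f"individual {ind!r} not in roster")
            rows.append(row[e])
            cols.append(col[ind])
    else:
        events = list(events)
        event_ids = [ev.event_id for ev in events]
        rows, cols = [], []
        for i, ev in enumerate(events):
            for ind in ev.members:
                if ind not in col:
                    raise KeyError(f"individual {ind!r} not in roster")
                rows.append(i)
                cols.append(col[ind])
    m = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.uint8), (rows, cols)),
        shape=(len(event_ids), len(roster)),
    ).tocsr()
    m.data = np.minimum(m.data, 1).astype(np.uint8)
    if not sparse_output:
        m = m.toarray()
    return GroupByIndividual(m, event_ids, roster)


def first_detection_week(
    detections: pd.DataFrame, calendar: WeekCalendar
) -> pd.Series:
    """Arrival week per individual: the week index of its earliest read.

    Individuals with no detections are simply absent from the result;
    whether to treat them as missing or excluded is the caller's call.
    """
    if detections.empty:
        return pd.Series(dtype=int, name="arrival_week")
    first = detections.groupby("individual_id")["timestamp"].min()
    weeks = calendar.week_of(first)
    return pd.Series(weeks, index=first.index, name="arrival_week").astype(int)
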