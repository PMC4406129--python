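"""CSV/YAML/JSON round trips for the pipeline's external formats."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from .gathering import GroupByIndividual
from .network import AssociationNetwork
from .simulate import SimulationConfig

__all__ = [
    "write_detections",
    "read_detections",
    "write_events",
    "write_gbi",
    "read_gbi",
    "write_edge_list",
    "read_edge_list",
    "write_config",
    "read_config",
    "write_json",
    "file_digest",
]


def write_detections(detections: pd.DataFrame, path) -> None:
    out = detections[["individual_id", "location_id", "timestamp"]].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values(["location_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def write_events(events, path) -> None:
    rows = [
        {
            "event_id": ev.event_id,
            "location_id": ev.location_id,
            "start": pd.Timestamp(ev.start).isoformat(),
            "end": pd.Timestamp(ev.end).isoformat(),
            "member_ids": ";".join(sorted(ev.members)),
        }
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_gbi(gbi: GroupByIndividual, path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        pd.DataFrame(gbi.toarray(), index=gbi.event_ids, columns=gbi.individuals).to_csv(
            path, index_label="event_id"
        )
    elif fmt == "mtx":
        m = gbi.matrix if sparse.issparse(gbi.matrix) else sparse.csr_matrix(gbi.matrix)
        scipy_io.mmwrite(str(path), m)
        path.with_suffix(".rows.txt").write_text("\n".join(gbi.event_ids) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(gbi.individuals) + "\n")
    else:
        raise ValueError(f"unknown GBI format {fmt!r}")


def read_gbi(path) -> GroupByIndividual:
    df = pd.read_csv(path, index_col="event_id")
    return GroupByIndividual(df.to_numpy(), list(df.index), list(df.columns))


def write_edge_list(network: AssociationNetwork, path) -> None:
    network.to_edge_list().to_csv(path, index=False)


def read_edge_list(path, roster=None) -> AssociationNetwork:
    df = pd.read_csv(path)
    if roster is None:
        roster = sorted(set(df["id_a"]) | set(df["id_b"]))
    index = {r: k for k, r in enumerate(roster)}
    W = np.zeros((len(roster), len(roster)))
    for a, b, w in df[["id_a", "id_b", "weight"]].itertuples(index=False):
        W[index[a], index[b]] = w
        W[index[b], index[a]] = w
    return AssociationNetwork(W, roster)


def write_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig(**yaml.safe_load(fh))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
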