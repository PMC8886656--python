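"""Reading and writing the pipeline's delimited-text formats.

Formats (all plain text, pandas-backed):

* per-subject time series — tab-separated, first column ``parcel_id``,
  remaining columns ``t0, t1, ...`` (one per time point);
* phenotype table — CSV, one row per subject, ``subject_id`` column required;
* parcellation lookup — CSV with columns ``parcel_id, network_label``;
* connectivity — CSV with a two-row header (seed region, target region) and
  one row per subject indexed by ``subject_id``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .phase import BoldTimeSeries, ParcellationMap
from .stats import ConnectivityTable


def write_timeseries(ts: BoldTimeSeries, path) -> None:
    df = pd.DataFrame(
        ts.values,
        index=pd.Index(ts.region_ids, name="parcel_id"),
        columns=[f"t{k}" for k in range(ts.n_timepoints)],
    )
    df.to_csv(path, sep="\t")


def read_timeseries(path, tr: float) -> BoldTimeSeries:
    df = pd.read_csv(path, sep="\t", index_col="parcel_id")
    return BoldTimeSeries(
        values=df.to_numpy(dtype=float),
        tr=tr,
        region_ids=tuple(map(str, df.index)),
    )


def write_phenotype(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"phenotype table {path} lacks a subject_id column")
    return df


def write_parcellation(mapping, path) -> None:
    items = mapping.items() if hasattr(mapping, "items") else mapping
    pd.DataFrame(items, columns=["parcel_id", "network_label"]).to_csv(path, index=False)


def read_parcellation(path) -> ParcellationMap:
    df = pd.read_csv(path, dtype=str)
    expected = {"parcel_id", "network_label"}
    if not expected.issubset(df.columns):
        raise ValueError(f"parcellation file {path} must have columns {sorted(expected)}")
    if df["parcel_id"].duplicated().any():
        dupes = df.loc[df["parcel_id"].duplicated(), "parcel_id"].tolist()
        raise ValueError(f"duplicate parcel_id(s) in parcellation: {dupes[:5]}")
    return ParcellationMap(dict(zip(df["parcel_id"], df["network_label"])))


def write_connectivity(table: ConnectivityTable, path) -> None:
    cols = pd.MultiIndex.from_tuples(table.edge_labels, names=["seed", "target"])
    df = pd.DataFrame(table.matrix, index=pd.Index(table.subject_ids, name="subject_id"), columns=cols)
    df.to_csv(path)


def read_connectivity(path, normalized: bool = False) -> ConnectivityTable:
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    return ConnectivityTable(
        matrix=df.to_numpy(dtype=float),
        edge_labels=tuple((str(a), str(b)) for a, b in df.columns),
        subject_ids=tuple(map(str, df.index)),
        normalized=normalized,
    )


def write_metrics(records: list[dict], path) -> pd.DataFrame:
    """Write the tidy metrics table (subject_id, scope_label, synchronization, metastability)."""
    df = pd.DataFrame.from_records(
        records, columns=["subject_id", "scope_label", "synchronization", "metastability"]
    )
    df.to_csv(path, index=False)
    return df
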