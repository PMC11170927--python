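"""Readers and writers for the pipeline's on-disk formats.

All tables are plain text with explicit headers; missing values are
empty fields.  Readers validate schemas and report the offending
row/column on failure; every write/read round trip is an identity on
the table contents.

Formats
-------
ASV counts        TSV, rows = ASVs (index ``asv_id``), columns = samples
taxonomy          TSV: asv_id, lineage, confidences (semicolon-joined)
rrn lookup        TSV: taxon, rank, copy_number, parent
probe signals     TSV long: probe, sample, signal, cv, snr
forcing           CSV: date, temperature, moisture, gpp (daily, no gaps)
fluxes            CSV: year, month, r_h, r_s, r_a
parameters        YAML mapping of parameter name -> value
season partition  JSON: labels + boundary coordinates
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mend
from .seasons import SeasonPartition

__all__ = [
    "write_counts", "read_counts",
    "write_taxonomy", "read_taxonomy",
    "write_lookup", "read_lookup",
    "write_signals", "read_signals",
    "write_forcing", "read_forcing",
    "write_fluxes", "read_fluxes",
    "write_params", "read_params",
    "write_partition", "read_partition",
    "write_sample_meta", "read_sample_meta",
]


class SchemaError(ValueError):
    """A table violated its declared schema."""


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("asv_id").to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="asv_id")
    arr = df.to_numpy()
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise SchemaError(f"{path}: missing count at asv {df.index[r]!r}, "
                          f"sample {df.columns[c]!r}")
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise SchemaError(f"{path}: negative count at asv {df.index[r]!r}, "
                          f"sample {df.columns[c]!r}")
    if not np.allclose(arr, np.round(arr)):
        raise SchemaError(f"{path}: non-integer counts")
    return df.astype(int)


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["asv_id", "lineage", "confidences"], path)
    for i, row in df.iterrows():
        n_taxa = len(str(row["lineage"]).split(";"))
        n_conf = len(str(row["confidences"]).split(";"))
        if n_taxa != n_conf:
            raise SchemaError(f"{path}: row {i} ({row['asv_id']}): "
                              f"{n_taxa} taxa but {n_conf} confidences")
    return df


def write_lookup(lookup: pd.DataFrame, path) -> None:
    lookup.to_csv(path, sep="\t", index=False)


def read_lookup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["taxon", "rank", "copy_number", "parent"], path)
    bad = df.index[df["copy_number"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: non-positive copy number at row {bad[0]}")
    return df


def write_signals(signals: pd.DataFrame, path) -> None:
    signals.to_csv(path, sep="\t", index=False)


def read_signals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["probe", "sample", "signal"], path)
    bad = df.index[df["signal"] < 0]
    if len(bad):
        raise SchemaError(f"{path}: negative signal at row {bad[0]}")
    return df


def write_forcing(forcing: pd.DataFrame, path) -> None:
    forcing.rename_axis("date").to_csv(path)


def read_forcing(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"], index_col="date")
    _check_columns(df, ["temperature", "moisture", "gpp"], path)
    full = pd.date_range(df.index[0], df.index[-1], freq="D")
    missing = full.difference(df.index)
    if len(missing):
        raise SchemaError(f"{path}: missing day {missing[0].date()}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        day = df.index[df[col].isna()][0]
        raise SchemaError(f"{path}: missing {col} on {day.date()}")
    if ((df["moisture"] < 0) | (df["moisture"] > 100)).any():
        day = df.index[(df["moisture"] < 0) | (df["moisture"] > 100)][0]
        raise SchemaError(f"{path}: moisture out of [0, 100] on {day.date()}")
    return df


def write_fluxes(fluxes: pd.DataFrame, path) -> None:
    fluxes.to_csv(path, index=False)


def read_fluxes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["year", "month", "r_h"], path)
    if (df["r_h"].dropna() < 0).any():
        raise SchemaError(f"{path}: negative r_h")
    if {"r_s", "r_a"} <= set(df.columns):
        both = df.dropna(subset=["r_h", "r_s", "r_a"])
        if not np.allclose(both["r_a"], both["r_s"] - both["r_h"], atol=1e-9):
            raise SchemaError(f"{path}: r_a != r_s - r_h")
    return df


def write_params(params: mend.MendParams, path) -> None:
    d = dataclasses.asdict(params)
    d["kinetics"] = dataclasses.asdict(params.kinetics)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_params(path) -> mend.MendParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kin = mend.KineticConstants(**d.pop("kinetics", {}))
    return mend.MendParams(kinetics=kin, **d)


def write_partition(partition: SeasonPartition, path) -> None:
    doc = {"labels": {str(m): lab for m, lab in partition.labels.items()},
           "rise": partition.rise, "fall": partition.fall,
           "rise_interval": list(partition.rise_interval),
           "fall_interval": list(partition.fall_interval)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_partition(path) -> SeasonPartition:
    with open(path) as fh:
        doc = json.load(fh)
    return SeasonPartition(labels={int(m): lab for m, lab in doc["labels"].items()},
                           rise=doc["rise"], fall=doc["fall"],
                           rise_interval=tuple(doc["rise_interval"]),
                           fall_interval=tuple(doc["fall_interval"]))


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample").to_csv(path, sep="\t")


def read_sample_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    _check_columns(df, ["block", "month", "treatment"], path)
    return df


def sha256_of(path) -> str:
    import hashlib
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
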