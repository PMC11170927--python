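"""Functional-gene microarray (GeoChip-style) processing.

QC filtering of probe-level signals (spot coefficient of variance,
batch-specific signal-to-noise, minimum intensity, replicate-detection
fraction), two-step among-array normalization against universal-standard
and functional probes, warming/control response ratios with delta-method
95% confidence intervals at probe and sub-category level, and the
four-way probe classification (unique under warming / increased /
decreased / unique under control).

Signals travel in long format: one row per detected spot with columns
``probe``, ``sample``, ``signal`` plus per-spot QC fields ``cv`` and
``snr``; missing spots are simply absent rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "qc_filter",
    "normalize",
    "response_ratio",
    "classify_probes",
    "QcReport",
    "DEFAULT_SNR_BY_BATCH",
]

DEFAULT_SNR_BY_BATCH = {1: 7.0, 2: 3.5}

_Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class QcReport:
    """Removal counts per QC rule."""

    spots_cv: int
    spots_snr: int
    spots_intensity: int
    spots_detection: int
    probes_dropped: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{name} missing columns: {sorted(missing)}")


def qc_filter(signals: pd.DataFrame, sample_meta: pd.DataFrame,
              cv_max: float = 0.8,
              snr_by_batch: dict | None = None,
              min_intensity: float = 100.0,
              min_detection_fraction: float = 0.5,
              detection_scope: str = "treatment_month") -> tuple:
    """Apply the spot- and probe-level QC rules; returns (filtered, report).

    Spots with CV > ``cv_max``, SNR below the batch-specific threshold, or
    intensity < ``min_intensity`` are removed (set missing).  Probes then
    detected in fewer than ``min_detection_fraction`` of the replicate
    samples of a group are removed from that group; groups are
    treatment x month by default (``detection_scope='treatment'`` pools
    months, ``'global'`` uses all samples).  Filtering is idempotent.
    """
    _require_columns(signals, ["probe", "sample", "signal", "cv", "snr"], "signals")
    _require_columns(sample_meta, ["treatment", "block", "month", "batch"], "sample_meta")
    snr_by_batch = dict(DEFAULT_SNR_BY_BATCH if snr_by_batch is None else snr_by_batch)
    if cv_max <= 0 or min_intensity <= 0 or any(v <= 0 for v in snr_by_batch.values()):
        raise ValueError("QC thresholds must be positive")

    df = signals.copy()
    batch = sample_meta["batch"].to_dict()
    unknown = set(df["sample"]) - set(batch)
    if unknown:
        raise ValueError(f"samples with no batch label: {sorted(unknown)[:5]}")
    spot_batch = df["sample"].map(batch)
    bad_batches = set(spot_batch.unique()) - set(snr_by_batch)
    if bad_batches:
        raise ValueError(f"unknown batch label(s): {sorted(bad_batches)}")

    bad_cv = df["cv"] > cv_max
    snr_thresh = spot_batch.map(snr_by_batch)
    bad_snr = df["snr"] < snr_thresh
    bad_int = df["signal"] < min_intensity
    n_cv = int(bad_cv.sum())
    n_snr = int((bad_snr & ~bad_cv).sum())
    n_int = int((bad_int & ~bad_cv & ~bad_snr).sum())
    df = df.loc[~(bad_cv | bad_snr | bad_int)].copy()

    # replicate-detection rule
    if detection_scope == "treatment_month":
        group_cols = ["treatment", "month"]
    elif detection_scope == "treatment":
        group_cols = ["treatment"]
    elif detection_scope == "global":
        group_cols = []
    else:
        raise ValueError(f"unknown detection_scope {detection_scope!r}")

    meta = sample_meta.copy()
    meta.index.name = "sample"
    if group_cols:
        group_of = meta[group_cols].astype(str).agg("|".join, axis=1)
        group_sizes = group_of.value_counts()
        df["_group"] = df["sample"].map(group_of)
    else:
        df["_group"] = "all"
        group_sizes = pd.Series({"all": len(meta)})

    det = df.groupby(["probe", "_group"])["sample"].nunique()
    frac = det / det.index.get_level_values("_group").map(group_sizes)
    bad_pg = set(frac.index[frac < min_detection_fraction])
    keep = [
        (p, g) not in bad_pg
        for p, g in zip(df["probe"], df["_group"])
    ]
    n_det = int(len(df) - sum(keep))
    probes_before = df["probe"].nunique()
    df = df.loc[keep].drop(columns="_group")
    probes_dropped = probes_before - df["probe"].nunique()

    report = QcReport(spots_cv=n_cv, spots_snr=n_snr, spots_intensity=n_int,
                      spots_detection=n_det, probes_dropped=int(probes_dropped))
    return df.reset_index(drop=True), report


def normalize(filtered: pd.DataFrame, standard_probe_ids,
              return_factors: bool = False):
    """Two-step among-array normalization followed by a natural-log transform.

    Step 1 rescales each array (sample) so its mean universal-standard
    intensity equals the grand mean of standards across arrays; step 2
    rescales so each array's mean functional-probe intensity equals the
    across-array functional mean.  After step 1 the array standard means
    are exactly equal.  The returned table carries ``log_signal`` =
    ln(scaled signal) alongside the scaled linear ``signal``.
    """
    _require_columns(filtered, ["probe", "sample", "signal"], "signals")
    std_ids = set(standard_probe_ids)
    df = filtered.copy()
    is_std = df["probe"].isin(std_ids)
    samples = df["sample"].unique()
    std_means = df.loc[is_std].groupby("sample")["signal"].mean()
    missing = set(samples) - set(std_means.index)
    if missing:
        raise ValueError(f"arrays with no detected standards: {sorted(missing)[:5]}")
    grand_std = std_means.mean()
    factor1 = grand_std / std_means
    df["signal"] = df["signal"] * df["sample"].map(factor1).to_numpy()

    func_means = df.loc[~is_std].groupby("sample")["signal"].mean()
    grand_func = func_means.mean()
    factor2 = grand_func / func_means
    factor2 = factor2.reindex(pd.Index(samples)).fillna(1.0)
    df["signal"] = df["signal"] * df["sample"].map(factor2).to_numpy()
    df["log_signal"] = np.log(df["signal"])
    if return_factors:
        return df, factor1, factor2
    return df


def _rr_record(w: np.ndarray, c: np.ndarray, unit: str, scope: str,
               level: str) -> dict:
    n_w, n_c = len(w), len(c)
    mean_w, mean_c = float(np.mean(w)), float(np.mean(c))
    rec = {"unit": unit, "scope": scope, "level": level,
           "n_w": n_w, "n_c": n_c, "mean_w": mean_w, "mean_c": mean_c,
           "rr": math.nan, "se": math.nan, "ci_low": math.nan,
           "ci_high": math.nan, "significant": False, "flagged": False}
    if mean_w <= 0 or mean_c <= 0 or n_w < 2 or n_c < 2:
        rec["flagged"] = True
        return rec
    rr = math.log(mean_w / mean_c)
    s2_w = float(np.var(w, ddof=1))
    s2_c = float(np.var(c, ddof=1))
    var = s2_w / (n_w * mean_w ** 2) + s2_c / (n_c * mean_c ** 2)
    se = math.sqrt(var)
    rec.update(rr=rr, se=se, ci_low=rr - _Z95 * se, ci_high=rr + _Z95 * se)
    rec["significant"] = rec["ci_low"] > 0 or rec["ci_high"] < 0
    return rec


def response_ratio(normalized: pd.DataFrame, sample_meta: pd.DataFrame,
                   scope: str = "season",
                   season_of_month: dict | None = None,
                   level: str = "probe",
                   annotations: pd.DataFrame | None = None,
                   subcategory_mode: str = "sum") -> pd.DataFrame:
    """Warming/control response ratios with 95% confidence intervals.

    rr = ln(mean_w / mean_c) on linear-scale signals, with the
    delta-method variance s_w^2/(n_w mean_w^2) + s_c^2/(n_c mean_c^2)
    and a normal-approximation CI (Hedges' lnRR).  ``scope`` is
    ``'season'`` (requires ``season_of_month``), ``'month'`` or
    ``'all'``.  At ``level='subcategory'`` probe signals are summed per
    sample within each sub-category before the ratio
    (``subcategory_mode='mean_of_rr'`` instead averages probe-level rr).
    """
    _require_columns(normalized, ["probe", "sample", "signal"], "signals")
    df = normalized.merge(
        sample_meta[["treatment", "month"]], left_on="sample", right_index=True)
    if scope == "season":
        if season_of_month is None:
            raise ValueError("season scope requires season_of_month")
        df["_scope"] = df["month"].map(season_of_month)
    elif scope == "month":
        df["_scope"] = df["month"].astype(str)
    elif scope == "all":
        df["_scope"] = "all"
    else:
        raise ValueError(f"unknown scope {scope!r}")

    if level == "subcategory":
        if annotations is None:
            raise ValueError("subcategory level requires annotations")
        ann = annotations.set_index("probe")["subcategory"]
        df["_unit"] = df["probe"].map(ann)
        if subcategory_mode == "sum":
            df = (df.groupby(["_unit", "_scope", "sample", "treatment"], as_index=False)
                    ["signal"].sum())
        elif subcategory_mode != "mean_of_rr":
            raise ValueError(f"unknown subcategory_mode {subcategory_mode!r}")
    elif level == "probe":
        df["_unit"] = df["probe"]
    else:
        raise ValueError(f"unknown level {level!r}")

    records = []
    if level == "subcategory" and subcategory_mode == "mean_of_rr":
        probe_rr = response_ratio(normalized, sample_meta, scope=scope,
                                  season_of_month=season_of_month, level="probe")
        probe_rr["_unit"] = probe_rr["unit"].map(ann)
        for (unit, scp), grp in probe_rr.dropna(subset=["rr"]).groupby(["_unit", "scope"]):
            rr = float(grp["rr"].mean())
            se = float(np.sqrt((grp["se"] ** 2).sum()) / len(grp))
            records.append({"unit": unit, "scope": scp, "level": "subcategory",
                            "n_w": int(grp["n_w"].sum()), "n_c": int(grp["n_c"].sum()),
                            "mean_w": math.nan, "mean_c": math.nan, "rr": rr, "se": se,
                            "ci_low": rr - _Z95 * se, "ci_high": rr + _Z95 * se,
                            "significant": rr - _Z95 * se > 0 or rr + _Z95 * se < 0,
                            "flagged": False})
        return pd.DataFrame(records)

    for (unit, scp), grp in df.groupby(["_unit", "_scope"]):
        w = grp.loc[grp["treatment"] == "warmed", "signal"].to_numpy(dtype=float)
        c = grp.loc[grp["treatment"] == "control", "signal"].to_numpy(dtype=float)
        records.append(_rr_record(w, c, unit, scp, level))
    return pd.DataFrame(records)


def classify_probes(records: pd.DataFrame, detection: pd.DataFrame) -> pd.DataFrame:
    """Four-way probe classification within each scope.

    ``detection`` holds one row per probe x scope with boolean columns
    ``detected_warmed`` / ``detected_control``.  Probes detected only
    under warming (or only under control) are ``unique_warming``
    (``unique_control``); detected-in-both probes with a significant
    positive (negative) response ratio are ``increased`` (``decreased``);
    the rest are ``unchanged``.  Probes absent from both treatments are
    excluded.  Category sets are disjoint by construction.
    """
    _require_columns(detection, ["probe", "scope", "detected_warmed",
                                 "detected_control"], "detection")
    rr = records.set_index(["unit", "scope"]) if len(records) else None
    rows = []
    for row in detection.itertuples():
        dw, dc = bool(row.detected_warmed), bool(row.detected_control)
        if not dw and not dc:
            continue
        if dw and not dc:
            cat = "unique_warming"
        elif dc and not dw:
            cat = "unique_control"
        else:
            cat = "unchanged"
            if rr is not None and (row.probe, row.scope) in rr.index:
                rec = rr.loc[(row.probe, row.scope)]
                if bool(rec["significant"]):
                    cat = "increased" if rec["rr"] > 0 else "decreased"
        rows.append({"probe": row.probe, "scope": row.scope, "category": cat})
    out = pd.DataFrame(rows)
    return out


def category_percentages(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-scope percentage of probes in each category."""
    counts = classified.groupby(["scope", "category"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def detection_table(filtered: pd.DataFrame, sample_meta: pd.DataFrame,
                    scope: str = "season",
                    season_of_month: dict | None = None) -> pd.DataFrame:
    """Probe x scope detection flags per treatment from a filtered signal table."""
    df = filtered.merge(sample_meta[["treatment", "month"]],
                        left_on="sample", right_index=True)
    if scope == "season":
        df["_scope"] = df["month"].map(season_of_month)
    elif scope == "month":
        df["_scope"] = df["month"].astype(str)
    else:
        df["_scope"] = "all"
    det = (df.groupby(["probe", "_scope", "treatment"])["sample"].nunique() > 0)
    wide = det.unstack("treatment").fillna(False).reset_index()
    wide = wide.rename(columns={"_scope": "scope", "warmed": "detected_warmed",
                                "control": "detected_control"})
    for col in ("detected_warmed", "detected_control"):
        if col not in wide:
            wide[col] = False
    return wide[["probe", "scope", "detected_warmed", "detected_control"]]
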