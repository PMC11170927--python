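"""Community-level microbial trait computations.

Per-ASV rrn (ribosomal RNA operon) copy-number assignment from an
rrnDB-style lookup with rank-confidence fallback, the community average
rrn copy number

    community average rrn = sum_i S_i / sum_i (S_i / n_i),

(the abundance-weighted harmonic aggregate: total reads divided by the
implied number of organisms), paired warmed/control log-ratios, and the
microbial metabolic quotient (Rh per unit microbial biomass, with DNA
yield as the biomass proxy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RrnLookup",
    "assign_rrn",
    "assign_rrn_table",
    "community_rrn",
    "community_rrn_table",
    "paired_log_ratio",
    "paired_log_ratio_table",
    "metabolic_quotient",
    "seasonal_paired_tests",
    "RANKS",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class RrnLookup:
    """Taxon -> (rank, copy number, parent taxon) mapping with a child index.

    Copy numbers are real-valued (database entries are means over genomes);
    the parent pointers must form an acyclic hierarchy.
    """

    entries: dict = field(default_factory=dict)  # taxon -> (rank, copy_number, parent)
    _children: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        for taxon, (rank, copy, parent) in self.entries.items():
            if copy <= 0:
                raise ValueError(f"copy number for {taxon!r} must be > 0")
            self._children.setdefault(parent, []).append(taxon)
        # cycle guard
        for taxon in self.entries:
            seen = set()
            node = taxon
            while node in self.entries:
                if node in seen:
                    raise ValueError(f"cycle in lookup hierarchy at {node!r}")
                seen.add(node)
                node = self.entries[node][2]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RrnLookup":
        required = {"taxon", "rank", "copy_number", "parent"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"lookup table missing columns: {sorted(missing)}")
        entries = {
            str(r.taxon): (str(r.rank), float(r.copy_number), str(r.parent))
            for r in df.itertuples()
        }
        return cls(entries=entries)

    def children(self, taxon: str) -> list:
        return self._children.get(taxon, [])

    def value(self, taxon: str):
        """Copy number for a taxon: mean over child entries if any, else its own entry."""
        kids = self.children(taxon)
        if kids:
            return float(np.mean([self.entries[k][1] for k in kids]))
        if taxon in self.entries:
            return float(self.entries[taxon][1])
        return None


def assign_rrn(lineage, confidences, lookup: RrnLookup,
               confidence_floor: float = 0.5):
    """Estimate the rrn copy number for one ASV lineage.

    ``lineage`` is the ordered (root -> leaf) list of taxon names,
    ``confidences`` the per-rank classifier confidences.  The match starts
    at the lowest (deepest) rank whose confidence strictly exceeds
    ``confidence_floor``; a confidence exactly at the floor fails.  At the
    matched taxon the mean copy number of its child entries is used when
    children exist, otherwise its own entry; failing both, the search
    ascends the lineage.  Returns ``None`` when no ancestor resolves
    (callers exclude such ASVs from the community aggregate).
    """
    if not lineage:
        raise ValueError("empty lineage")
    if len(lineage) != len(confidences):
        raise ValueError("lineage and confidences length mismatch")
    if not 0.0 < confidence_floor < 1.0:
        raise ValueError("confidence_floor must be in (0, 1)")
    matched_idx = None
    for i in range(len(lineage) - 1, -1, -1):
        if confidences[i] > confidence_floor:
            matched_idx = i
            break
    if matched_idx is None:
        return None
    for i in range(matched_idx, -1, -1):
        v = lookup.value(lineage[i])
        if v is not None:
            return v
    return None


def assign_rrn_table(taxonomy: pd.DataFrame, lookup: RrnLookup,
                     confidence_floor: float = 0.5) -> pd.Series:
    """Vector assignment over a taxonomy table.

    Expects columns ``asv_id``, ``lineage`` (semicolon-joined taxa) and
    ``confidences`` (semicolon-joined floats).  Unassigned ASVs get NaN.
    """
    out = {}
    for row in taxonomy.itertuples():
        lineage = str(row.lineage).split(";")
        confs = [float(c) for c in str(row.confidences).split(";")]
        v = assign_rrn(lineage, confs, lookup, confidence_floor)
        out[row.asv_id] = math.nan if v is None else v
    return pd.Series(out, name="rrn_copy_number")


def community_rrn(abundances, copy_numbers) -> float:
    """Community average rrn copy number: sum(S) / sum(S / n).

    Equivalent to expanding each ASV into S_i organisms carrying n_i
    operon copies each and dividing total reads by total organisms; the
    result is bounded by min(n) and max(n) over ASVs with S_i > 0.
    """
    s = np.asarray(abundances, dtype=float)
    n = np.asarray(copy_numbers, dtype=float)
    if s.shape != n.shape:
        raise ValueError("abundances and copy numbers length mismatch")
    if (s < 0).any():
        raise ValueError("negative abundance")
    if (n <= 0).any():
        raise ValueError("copy numbers must be > 0")
    total = s.sum()
    if total <= 0:
        raise ValueError("all abundances are zero")
    return float(total / (s / n).sum())


def community_rrn_table(counts: pd.DataFrame, copy_numbers: pd.Series) -> pd.Series:
    """Per-sample community rrn over an ASV count table (rows = ASVs).

    ASVs with an unassigned (NaN) copy number are dropped from both the
    numerator and denominator; the dropped fraction is available via the
    returned series' ``attrs['n_unassigned']``.
    """
    n = copy_numbers.reindex(counts.index)
    keep = n.notna()
    kept_counts = counts.loc[keep]
    kept_n = n.loc[keep].to_numpy()
    result = {}
    for sample in counts.columns:
        result[sample] = community_rrn(kept_counts[sample].to_numpy(), kept_n)
    out = pd.Series(result, name="community_rrn")
    out.attrs["n_unassigned"] = int((~keep).sum())
    return out


def paired_log_ratio(value_warmed: float, value_control: float) -> float:
    """ln(warmed / control) for one matched block-month pair."""
    if value_warmed <= 0 or value_control <= 0:
        raise ValueError("paired log-ratio requires positive inputs")
    return math.log(value_warmed / value_control)


def paired_log_ratio_table(trait: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Block x month paired log-ratios of a per-sample trait.

    ``meta`` must be indexed by sample id with columns ``block``,
    ``month``, ``treatment`` (values ``warmed`` / ``control``); every
    warmed sample needs exactly one control partner in its block-month.
    """
    df = meta.copy()
    df["value"] = trait.reindex(df.index)
    wide = df.pivot_table(index=["block", "month"], columns="treatment",
                          values="value", aggfunc="first")
    if wide[["warmed", "control"]].isna().any().any():
        raise ValueError("unpaired block-month combination present")
    wide = wide.reset_index()
    wide["log_ratio"] = [
        paired_log_ratio(w, c) for w, c in zip(wide["warmed"], wide["control"])
    ]
    return wide[["block", "month", "warmed", "control", "log_ratio"]]


def metabolic_quotient(r_h, biomass_proxy):
    """Rh per unit microbial biomass (DNA yield as the biomass proxy)."""
    r = np.asarray(r_h, dtype=float)
    b = np.asarray(biomass_proxy, dtype=float)
    if (b <= 0).any():
        raise ValueError("biomass proxy must be > 0")
    return r / b


def seasonal_paired_tests(pairs: pd.DataFrame, season_of_month: dict) -> pd.DataFrame:
    """Paired t-tests of warmed vs control within each season.

    Thin delegation to :func:`scipy.stats.ttest_rel` over the block-month
    pairs produced by :func:`paired_log_ratio_table`.
    """
    rows = []
    df = pairs.copy()
    df["season"] = df["month"].map(season_of_month)
    for season, grp in df.groupby("season"):
        res = stats.ttest_rel(grp["warmed"], grp["control"])
        rows.append({
            "season": season,
            "n_pairs": len(grp),
            "mean_log_ratio": float(grp["log_ratio"].mean()),
            "t": float(res.statistic),
            "p": float(res.pvalue),
        })
    return pd.DataFrame(rows)
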