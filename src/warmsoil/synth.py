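"""Synthetic study generator.

Emulates the statistical structure of a paired warming experiment in a
temperate tallgrass prairie: 4 replicate blocks, each with one warmed
and one control plot, sampled monthly over one year (96 samples under
the default design).  Generates

* daily forcing (soil temperature, volumetric moisture, GPP) for both
  treatments, with season-specific warming offsets and cool-season
  moisture reduction;
* ASV count tables with taxonomy (per-rank confidences) and an
  rrnDB-style copy-number lookup, with a configurable cool-season shift
  of the warmed community toward high-rrn taxa;
* probe-level functional-gene signal matrices with batch-split
  hybridization structure and cool-season treatment effects;
* monthly heterotrophic-respiration (and enzyme gene-abundance)
  observations from forward runs of the microbial-enzyme model.

All randomness flows from a single master seed split per generator, so
identical configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import mend
from .seasons import EARLY_COOL, LATE_COOL, WARM

__all__ = [
    "StudyDesign",
    "ClimateCycle",
    "SITE_MONTHLY_AIR_T",
    "SEASON_OF_MONTH",
    "DEFAULT_WARMING_OFFSETS",
    "DEFAULT_MOISTURE_FACTORS",
    "control_cue_preset",
    "warmed_cue_preset",
    "gen_forcing",
    "gen_community",
    "tilt_proportions",
    "gen_probe_signals",
    "gen_rh_observations",
]

# Monthly mean air-temperature climatology (deg C) of the emulated site:
# a southern Great Plains prairie with the coldest month (January) near
# 3.5 C and the warmest (July) near 28.1 C, a rapid late-winter warm-up
# peaking between February and March and the steepest autumn cooling
# between September and October.
SITE_MONTHLY_AIR_T = np.array(
    [3.5, 7.4, 14.9, 20.3, 22.5, 26.7, 28.1, 27.2, 22.1, 13.0, 10.9, 6.2])

# Calendar partition implied by the site climatology.
SEASON_OF_MONTH = {1: EARLY_COOL, 2: EARLY_COOL,
                   **{m: WARM for m in range(3, 10)},
                   10: LATE_COOL, 11: LATE_COOL, 12: LATE_COOL}

# Season-specific soil warming offsets (deg C) of the emulated treatment.
DEFAULT_WARMING_OFFSETS = {EARLY_COOL: 3.6, WARM: 4.5, LATE_COOL: 4.1}

# Multiplicative cool-season soil-moisture reduction under warming
# (early cool 10.7 -> 5.9 %V, late cool 7.5 -> 5.3 %V; warm season unchanged).
DEFAULT_MOISTURE_FACTORS = {EARLY_COOL: 5.9 / 10.7, WARM: 1.0, LATE_COOL: 5.3 / 7.5}

# Monthly control-plot volumetric moisture normals (%V).
_MONTHLY_MOISTURE = np.array(
    [10.7, 10.7, 18.0, 22.0, 25.0, 22.0, 17.0, 14.0, 16.0, 7.5, 7.5, 7.5])


@dataclass(frozen=True)
class StudyDesign:
    """Paired-plot monthly sampling design (4 blocks x 12 months x 2 treatments)."""

    n_blocks: int = 4
    months: tuple = tuple(range(1, 13))
    year: int = 2012
    seed: int = 0

    def sample_ids(self) -> list:
        ids = []
        for b in range(1, self.n_blocks + 1):
            for m in self.months:
                for t in ("warmed", "control"):
                    ids.append(f"B{b}_M{m:02d}_{t[0].upper()}")
        return ids

    def sample_meta(self) -> pd.DataFrame:
        rows = []
        for b in range(1, self.n_blocks + 1):
            for m in self.months:
                for t in ("warmed", "control"):
                    rows.append({"sample": f"B{b}_M{m:02d}_{t[0].upper()}",
                                 "block": b, "month": m, "treatment": t,
                                 "season": SEASON_OF_MONTH[m]})
        return pd.DataFrame(rows).set_index("sample")


@dataclass(frozen=True)
class ClimateCycle:
    """Annual sinusoid for daily soil temperature with AR(1) noise."""

    mean: float = 15.8
    amplitude: float = 12.3
    coldest_doy: int = 15       # phase: day-of-year of the minimum
    noise_sd: float = 1.2
    noise_rho: float = 0.7


def control_cue_preset() -> mend.MendParams:
    """Control-treatment microbial parameter preset.

    Intrinsic CUE 0.43 at 15 C with slope -0.0025 per deg C spans
    roughly 0.39-0.47 over the 0-30 C soil temperature range.
    """
    return mend.MendParams(yg_ref=0.43, k_yg=-0.0025, t_ref=15.0)


def warmed_cue_preset() -> mend.MendParams:
    """Warmed-treatment preset: CUE temperature sensitivity reduced by
    28.7% relative to control, with the intercept set so the warmed and
    control CUE lines cross at 15.7 C."""
    k_c = -0.0025
    k_w = k_c * (1.0 - 0.287)
    t_star = 15.7
    yg_w = 0.43 + (k_c - k_w) * (t_star - 15.0)
    return mend.MendParams(yg_ref=yg_w, k_yg=k_w, t_ref=15.0)


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * math.sqrt(max(1e-12, 1.0 - rho ** 2)), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def gen_forcing(design: StudyDesign,
                climate: ClimateCycle | None = None,
                warming_offsets: dict | None = None,
                moisture_factors: dict | None = None,
                gpp_max: float = 8.0,
                gpp_peak_doy: int = 150,
                gpp_width: float = 70.0,
                moisture_noise_sd: float = 0.8,
                n_years: int = 1) -> tuple:
    """Generate the (warmed, control) daily forcing pair.

    Control temperature = annual sinusoid + AR(1) noise; the warmed
    series adds the season-specific offset of its calendar month.
    Moisture follows monthly normals with AR(1) noise, multiplied by the
    cool-season reduction factor under warming.  GPP is a Gaussian
    growing-season pulse (>= 0), identical between treatments.
    """
    climate = climate or ClimateCycle()
    if climate.amplitude <= 0:
        raise ValueError("temperature amplitude must be > 0")
    offsets = DEFAULT_WARMING_OFFSETS if warming_offsets is None else dict(warming_offsets)
    if set(offsets) != {EARLY_COOL, WARM, LATE_COOL}:
        raise ValueError("warming offsets must map exactly the three seasons")
    if not all(np.isfinite(v) for v in offsets.values()):
        raise ValueError("warming offsets must be finite")
    factors = DEFAULT_MOISTURE_FACTORS if moisture_factors is None else dict(moisture_factors)
    if set(factors) != {EARLY_COOL, WARM, LATE_COOL}:
        raise ValueError("moisture factors must map exactly the three seasons")

    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 101]))
    dates = pd.date_range(f"{design.year}-01-01",
                          f"{design.year + n_years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    n = len(dates)

    base_t = climate.mean - climate.amplitude * np.cos(
        2.0 * math.pi * (doy - climate.coldest_doy) / 365.25)
    t_control = base_t + _ar1(rng, n, climate.noise_sd, climate.noise_rho)
    season = np.array([SEASON_OF_MONTH[m] for m in month])
    offset = np.array([offsets[s] for s in season])
    t_warmed = t_control + offset

    w_base = _MONTHLY_MOISTURE[month - 1]
    w_control = np.clip(w_base + _ar1(rng, n, moisture_noise_sd, 0.6), 0.5, 100.0)
    w_factor = np.array([factors[s] for s in season])
    w_warmed = np.clip(w_control * w_factor, 0.5, 100.0)

    gpp_noise = _ar1(rng, n, 0.05 * gpp_max, 0.5)
    gpp = np.maximum(
        0.0, gpp_max * np.exp(-(((doy - gpp_peak_doy) / gpp_width) ** 2)) + gpp_noise)

    control = pd.DataFrame({"temperature": t_control, "moisture": w_control,
                            "gpp": gpp}, index=dates)
    warmed = pd.DataFrame({"temperature": t_warmed, "moisture": w_warmed,
                           "gpp": gpp}, index=dates)
    return warmed, control


# ---------------------------------------------------------------------------
# community / taxonomy / rrn lookup
# ---------------------------------------------------------------------------

_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class CommunitySim:
    """Counts, taxonomy, lookup and ground truth from :func:`gen_community`."""

    counts: pd.DataFrame         # ASVs x samples
    taxonomy: pd.DataFrame       # asv_id, lineage, confidences
    lookup: pd.DataFrame         # taxon, rank, copy_number, parent
    sample_meta: pd.DataFrame
    true_copy: pd.Series         # per-ASV true rrn copy number
    true_community_rrn: pd.Series  # per-sample (from exact proportions)
    effect: float
    degenerate_trait: bool = False


def _community_rrn_from_props(p: np.ndarray, n: np.ndarray) -> float:
    return 1.0 / float(np.sum(p / n))


def tilt_proportions(p: np.ndarray, n: np.ndarray, effect: float) -> np.ndarray:
    """Tilt a composition toward high-rrn taxa so that the community
    average rrn log-ratio against the untilted composition equals
    ``effect`` exactly (solved for the exponential tilt parameter)."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if effect == 0.0:
        return p.copy()
    if np.ptp(n) == 0.0:
        raise ValueError("degenerate trait distribution (single support point) "
                         "cannot be tilted to a nonzero effect")
    base = math.log(_community_rrn_from_props(p, n))

    def gap(theta: float) -> float:
        q = p * np.power(n, theta)
        q = q / q.sum()
        return math.log(_community_rrn_from_props(q, n)) - base - effect

    theta = brentq(gap, -50.0, 50.0, xtol=1e-12)
    q = p * np.power(n, theta)
    return q / q.sum()


def gen_community(design: StudyDesign,
                  n_asvs: int = 300,
                  rrn_lognormal: tuple = (0.9, 0.55),
                  warming_trait_effect: float = 0.10,
                  depth: int = 21567,
                  dirichlet_alpha: float = 0.3) -> CommunitySim:
    """ASV counts + taxonomy + rrn lookup with a cool-season trait shift.

    Counts are Dirichlet-multinomial at fixed depth (the rarefaction
    depth): a Dirichlet base composition per block-month shared between
    treatments, multinomially resampled.  In cool months the warmed
    composition is tilted toward high-rrn ASVs so the true community rrn
    log-ratio equals ``warming_trait_effect``; warm months carry no
    effect.  The taxonomy/lookup pair is built so the rank-fallback
    assignment recovers each ASV's true copy number.
    """
    if n_asvs < 2:
        raise ValueError("need at least 2 ASVs")
    if not np.isfinite(warming_trait_effect):
        raise ValueError("effect size must be finite")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 202]))

    mu, sigma = rrn_lognormal
    copies = np.clip(rng.lognormal(mu, sigma, n_asvs), 1.0, 15.0)
    degenerate = bool(np.ptp(copies) < 1e-12)

    n_gen = max(2, n_asvs // 6)
    n_fam = max(2, n_gen // 4)
    genus_of_asv = rng.integers(0, n_gen, n_asvs)
    family_of_genus = np.arange(n_gen) % n_fam
    cat_draw = rng.random(n_asvs)
    category = np.where(cat_draw < 0.80, "direct",
                        np.where(cat_draw < 0.95, "genus_fb", "family_fb"))

    genus_entry_copy = np.clip(rng.lognormal(mu, sigma, n_gen), 1.0, 15.0)
    lookup_rows = []
    for g in range(n_gen):
        lookup_rows.append({"taxon": f"Genus_{g}", "rank": "genus",
                            "copy_number": genus_entry_copy[g],
                            "parent": f"Family_{family_of_genus[g]}"})
    species_under_genus: dict = {g: [] for g in range(n_gen)}
    for i in range(n_asvs):
        if category[i] == "direct":
            g = genus_of_asv[i]
            lookup_rows.append({"taxon": f"Species_{i}", "rank": "species",
                                "copy_number": copies[i], "parent": f"Genus_{g}"})
            species_under_genus[g].append(copies[i])

    # ground-truth copy numbers implied by the fallback rule
    true_copy = np.empty(n_asvs)
    genus_value = {
        g: (float(np.mean(species_under_genus[g])) if species_under_genus[g]
            else float(genus_entry_copy[g]))
        for g in range(n_gen)
    }
    family_value = {
        f: float(np.mean([genus_entry_copy[g] for g in range(n_gen)
                          if family_of_genus[g] == f]))
        for f in range(n_fam)
    }
    tax_rows = []
    for i in range(n_asvs):
        g = genus_of_asv[i]
        f = family_of_genus[g]
        lineage = ["Bacteria", f"Phylum_{f % 3}", f"Class_{f % 5}",
                   f"Order_{f}", f"Family_{f}", f"Genus_{g}", f"Species_{i}"]
        if category[i] == "direct":
            confs = [1.0, 0.99, 0.99, 0.98, 0.97, 0.96, 0.95]
            true_copy[i] = copies[i]
        elif category[i] == "genus_fb":
            confs = [1.0, 0.99, 0.99, 0.98, 0.97, 0.96, 0.30]
            true_copy[i] = genus_value[g]
        else:
            confs = [1.0, 0.99, 0.99, 0.98, 0.97, 0.35, 0.30]
            true_copy[i] = family_value[f]
        tax_rows.append({"asv_id": f"ASV_{i:05d}",
                         "lineage": ";".join(lineage),
                         "confidences": ";".join(f"{c:.2f}" for c in confs)})

    meta = design.sample_meta()
    asv_ids = [f"ASV_{i:05d}" for i in range(n_asvs)]
    counts = {}
    true_crrn = {}
    for (b, m), grp in meta.groupby(["block", "month"]):
        base = rng.dirichlet(np.full(n_asvs, dirichlet_alpha))
        base = np.maximum(base, 1e-12)
        base = base / base.sum()
        cool = SEASON_OF_MONTH[m] != WARM
        for sample, row in grp.iterrows():
            if (row["treatment"] == "warmed" and cool
                    and warming_trait_effect != 0.0 and not degenerate):
                p = tilt_proportions(base, true_copy, warming_trait_effect)
            else:
                p = base
            counts[sample] = rng.multinomial(depth, p)
            true_crrn[sample] = _community_rrn_from_props(p, true_copy)

    counts_df = pd.DataFrame(counts, index=pd.Index(asv_ids, name="asv_id"))
    return CommunitySim(
        counts=counts_df,
        taxonomy=pd.DataFrame(tax_rows),
        lookup=pd.DataFrame(lookup_rows),
        sample_meta=meta,
        true_copy=pd.Series(true_copy, index=asv_ids, name="true_copy"),
        true_community_rrn=pd.Series(true_crrn, name="true_community_rrn"),
        effect=warming_trait_effect,
        degenerate_trait=degenerate,
    )


# ---------------------------------------------------------------------------
# probe-level functional-gene signals
# ---------------------------------------------------------------------------

_GENES = [  # C-decomposition probes: (gene, subcategory, substrate labile -> recalcitrant)
    ("amyA", "starch", "starch"),
    ("xylanase", "hemicellulose", "hemicellulose"),
    ("cellobiase", "cellulose", "cellulose"),
    ("chitinase", "chitin", "chitin"),
    ("pectinase", "pectin", "pectin"),
    ("cutinase", "cutin", "cutin"),
    ("glx", "lignin", "lignin"),
    ("mnp", "lignin", "lignin"),
]

_BACKGROUND_GENES = [  # non-target gene families filling out the array
    ("nirS", "denitrification", "none"),
    ("amoA", "nitrification", "none"),
    ("nifH", "n_fixation", "none"),
    ("ppx", "p_cycling", "none"),
    ("dsrA", "s_cycling", "none"),
    ("mcrA", "methanogenesis", "none"),
]

DEFAULT_BATCH_OF_MONTH = {**{m: 1 for m in range(1, 7)}, **{m: 2 for m in range(7, 13)}}


@dataclass
class ProbeSim:
    """Signals, metadata, annotations and ground truth from :func:`gen_probe_signals`."""

    signals: pd.DataFrame        # long: probe, sample, signal, cv, snr
    sample_meta: pd.DataFrame    # adds batch column
    annotations: pd.DataFrame    # probe, gene, subcategory, substrate_class, is_standard
    affected_probes: set
    effect: float


def gen_probe_signals(design: StudyDesign,
                      n_probes: int = 400,
                      n_standards: int = 20,
                      batch_of_month: dict | None = None,
                      c_decomp_fraction: float = 0.15,
                      effect_fraction: float = 0.85,
                      effect_size: float = math.log(2.0),
                      noise_sd: float = 0.45,
                      batch_log_offsets: dict | None = None,
                      block_sd: float = 0.10) -> ProbeSim:
    """Lognormal probe signals with batch structure and cool-season effects.

    ``c_decomp_fraction`` of the probes target C-decomposition genes and
    ``effect_fraction`` of those carry the warming effect (added to warmed
    samples on the log scale, cool months only); the remainder are
    background gene families with no treatment effect, mirroring a
    functional array where the responsive category is a minority of
    probes.  Universal-standard probes are unaffected by treatment.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    batch_of_month = dict(DEFAULT_BATCH_OF_MONTH if batch_of_month is None
                          else batch_of_month)
    missing = set(design.months) - set(batch_of_month)
    if missing:
        raise ValueError(f"months with no batch: {sorted(missing)}")
    offsets = {1: 0.25, 2: -0.25} if batch_log_offsets is None else dict(batch_log_offsets)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 303]))

    meta = design.sample_meta()
    meta = meta.assign(batch=meta["month"].map(batch_of_month))

    n_cdec = int(round(c_decomp_fraction * n_probes))
    ann_rows = []
    for i in range(n_probes):
        if i < n_cdec:
            gene, sub, substrate = _GENES[i % len(_GENES)]
        else:
            gene, sub, substrate = _BACKGROUND_GENES[i % len(_BACKGROUND_GENES)]
        ann_rows.append({"probe": f"P{i:05d}", "gene": gene, "subcategory": sub,
                         "substrate_class": substrate, "is_standard": False})
    for i in range(n_standards):
        ann_rows.append({"probe": f"STD{i:03d}", "gene": "standard",
                         "subcategory": "standard", "substrate_class": "standard",
                         "is_standard": True})
    annotations = pd.DataFrame(ann_rows)

    n_aff = int(round(effect_fraction * n_cdec))
    affected = (set(f"P{i:05d}" for i in rng.choice(n_cdec, n_aff, replace=False))
                if n_aff > 0 else set())

    mu = rng.normal(math.log(800.0), 0.5, n_probes)
    block_eff = rng.normal(0.0, block_sd, (n_probes, design.n_blocks + 1))

    rows = []
    for sample, srow in meta.iterrows():
        b, m, t = srow["block"], srow["month"], srow["treatment"]
        batch = srow["batch"]
        cool = SEASON_OF_MONTH[m] != WARM
        noise = rng.normal(0.0, noise_sd, n_probes) if noise_sd > 0 else np.zeros(n_probes)
        for i in range(n_probes):
            pid = f"P{i:05d}"
            ln_sig = mu[i] + offsets.get(batch, 0.0) + block_eff[i, b] + noise[i]
            if t == "warmed" and cool and pid in affected:
                ln_sig += effect_size
            snr_lo, snr_hi = (8.0, 20.0) if batch == 1 else (4.0, 12.0)
            rows.append({"probe": pid, "sample": sample,
                         "signal": math.exp(ln_sig),
                         "cv": rng.uniform(0.1, 0.6),
                         "snr": rng.uniform(snr_lo, snr_hi)})
        for i in range(n_standards):
            rows.append({"probe": f"STD{i:03d}", "sample": sample,
                         "signal": 1500.0 * math.exp(offsets.get(batch, 0.0)
                                                     + (noise[i % n_probes] * 0.1
                                                        if noise_sd > 0 else 0.0)),
                         "cv": 0.2, "snr": 15.0})
    signals = pd.DataFrame(rows)
    return ProbeSim(signals=signals, sample_meta=meta, annotations=annotations,
                    affected_probes=affected, effect=effect_size)


# ---------------------------------------------------------------------------
# respiration observations
# ---------------------------------------------------------------------------

@dataclass
class FluxObs:
    """Monthly flux observations plus calibration-ready series."""

    fluxes: pd.DataFrame          # year, month, r_h, r_s, r_a
    observations: dict            # {"rh": array, "enz_co": array, "enz_ch": array}
    sim: mend.SimulationOutput    # the noiseless forward run


def gen_rh_observations(params: mend.MendParams, forcing: pd.DataFrame,
                        noise_sd: float = 0.05, seed: int = 0,
                        enzyme_scale: float = 1e4,
                        enzyme_noise_sd: float = 0.10,
                        rs_factor: float = 1.6,
                        initial: mend.MendPools | None = None) -> FluxObs:
    """Monthly Rh observations from a forward model run plus noise.

    ``noise_sd`` is the relative (multiplicative-scale) Gaussian noise on
    monthly Rh, truncated at zero.  Companion monthly enzyme
    "gene-abundance" series are the simulated enzyme pools rescaled by an
    arbitrary factor with lognormal noise (they are compared by
    correlation of logs, so the scale is irrelevant).  Rs is emulated as
    a fixed multiple of Rh so that Ra = Rs - Rh holds exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    out = mend.simulate(params, forcing, initial=initial or mend.MendPools())
    rh_m = out.monthly_rh()
    noise = rng.normal(0.0, 1.0, len(rh_m))
    rh_obs = np.maximum(0.0, rh_m.to_numpy() * (1.0 + noise_sd * noise))
    monthly = out.pools.groupby(
        [out.pools.index.year, out.pools.index.month]).mean()
    enz_noise = rng.normal(0.0, 1.0, (2, len(rh_m)))
    enz_co = monthly["ep_o"].to_numpy() * enzyme_scale * np.exp(
        enzyme_noise_sd * enz_noise[0])
    enz_ch = monthly["ep_h"].to_numpy() * enzyme_scale * np.exp(
        enzyme_noise_sd * enz_noise[1])
    years = [y for (y, m) in rh_m.index]
    months = [m for (y, m) in rh_m.index]
    r_s = rh_obs * rs_factor
    fluxes = pd.DataFrame({"year": years, "month": months, "r_h": rh_obs,
                           "r_s": r_s, "r_a": r_s - rh_obs})
    return FluxObs(fluxes=fluxes,
                   observations={"rh": rh_obs, "enz_co": enz_co, "enz_ch": enz_ch},
                   sim=out)
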