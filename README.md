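# warmsoil

Quantitative chain linking experimental soil warming to soil microbial
traits and heterotrophic respiration (Rh) in a temperate grassland:
community-level rRNA operon (*rrn*) copy-number aggregation, calendar
season segmentation, functional-gene response-ratio analysis, a
microbial-enzyme decomposition soil-carbon model assimilated against
respiration and gene-abundance series, a first-order (CENTURY-type)
baseline model, and derived carbon-use-efficiency (CUE) temperature
sensitivity analytics.

The package is written for soil microbial ecologists and ecosystem
modelers who want the full analysis — from an ASV count table and
probe-level functional-gene signals to calibrated model parameters and
CUE diagnostics — as reusable, tested library code. A synthetic-data
generator reproduces the statistical structure of a paired warming
experiment (4 replicate blocks × 12 months × warmed/control plots), so
the whole chain runs end to end without any external downloads.

## The quantities at the core

**Community average rrn copy number.** With `S_i` the read count of
ASV `i` and `n_i` its estimated *rrn* copy number,

    community average rrn = ( Σ_i S_i ) / ( Σ_i S_i / n_i ),

i.e. total reads divided by the implied number of organisms. Copy
numbers come from an rrnDB-style lookup through the lowest taxonomic
rank whose classifier confidence exceeds 50%, using the mean of child
taxa when available and ascending to the parent-taxa mean otherwise.
Warming effects are summarized as paired log-ratios ln(warmed/control)
within block-month pairs.

**Response ratios.** Warming effects on probe-level gene signals are
measured as RR = ln(x̄_w / x̄_c) with the delta-method standard error
SE² = s²_w/(n_w x̄²_w) + s²_c/(n_c x̄²_c) and normal 95% confidence
intervals, after CV / signal-to-noise / intensity / detection filtering
and two-step normalization against universal-standard and functional
probe intensities.

**Microbial-enzyme model.** Ten carbon pools (particulate oxidative and
hydrolytic substrates, mineral-associated C, adsorbed and dissolved C,
active and dormant biomass, three enzyme classes) with Michaelis–Menten
enzymatic decomposition, dissolved-C uptake split between growth and
respiration by a temperature-dependent intrinsic CUE

    Yg(T) = Yg(T_ref) + kYg · (T − T_ref),

maintenance respiration, enzyme production/turnover and
moisture-threshold dormancy. Eleven process parameters (fINP, rE, pEP,
fpEM, fD, gD, Vg, α, KD, β, ψA2D) plus Yg(T_ref) and kYg are exposed for
calibration. Parameters are estimated by minimizing the weighted
multiobjective

    J = w₁ (1 − R²_Rh) + w₂ (1 − r_EnzCo) + w₃ (1 − r_EnzCh),
    w = (3/5, 1/5, 1/5),

with the Shuffled Complex Evolution (SCE-UA) global optimizer;
uncertainty uses the Critical Objective Function Index

    J_cr = J_opt · (1 + p/(n−p) · F_{α,p,n−p}),

whose feasible region is every evaluated parameter vector with
J ≤ J_cr. A first-order multi-pool baseline (dX/dt = B u + ξ(T,W) A K X,
Q10 temperature scalar) calibrated by Metropolis–Hastings MCMC provides
the non-microbial comparison.

## Worked example

```bash
python analysis/01_generate_data.py
python analysis/02_community_traits.py
python analysis/03_segment_seasons.py
python analysis/04_gene_response_ratios.py
python analysis/05_calibrate_models.py
python analysis/06_cue_sensitivity.py
```

Abridged output of a run with the default seed:

```
assigned rrn copies for 300/300 ASVs (0 unassigned, dropped from the aggregate)
   early_cool: mean log-ratio +0.0971 (n=8 pairs)
    late_cool: mean log-ratio +0.1000 (n=12 pairs)
         warm: mean log-ratio -0.0004 (n=28 pairs)
fastest temperature rise at month 2.91 (between months 2 and 3)
fastest fall at month 9.98 (between months 9 and 10)
   early_cool:  60.0% of C-decomposition probes significantly stimulated by warming (n=90)
         warm:   4.4% of C-decomposition probes significantly stimulated by warming (n=90)
    late_cool:  73.3% of C-decomposition probes significantly stimulated by warming (n=90)
control: R2(Rh) = 0.994, J_opt = 0.0034, J_cr = 0.0054, feasible set 1045
baseline R2 = 0.696; microbial-model R2 = 0.994; relative improvement 42.9%
sensitivity slopes: control -0.00330, warmed -0.00181 per deg C (-45.1% change in magnitude)
```

Reading the numbers: the community *rrn* aggregate shifts toward
high-copy (fast-growth) taxa under warming only in the cool months
(log-ratios ≈ +0.10 vs ≈ 0 in the warm season) — the generator's
configured trait effect, recovered through the full count → assignment →
aggregation chain. The quintic temperature fit places the season
boundaries between February/March and September/October, giving the
Jan–Feb / Mar–Sep / Oct–Dec partition. Warming stimulation of
C-decomposition genes concentrates in the cool seasons. The microbial
model fits the synthetic Rh series far better than the first-order
baseline, and the calibrated CUE temperature slope is weaker under
warming — the trait signature that makes cool-season respiration more
responsive to warming.

## Layout

```
src/warmsoil/       library: synth, traits, seasons, geochip, mend,
                    calibration, teco, cue, io, pipeline
analysis/           numbered narrative drivers (the worked example)
scripts/            acceptance.py
tests/              pytest suite (unit, property and end-to-end checks)
docs/methods.md     model equations, generator design, numerical choices
```

`warmsoil.pipeline.run_pipeline` executes the whole chain in one call
and writes a manifest (config hash, seed, per-file checksums) for
reproducibility.
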