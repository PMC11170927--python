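#!/usr/bin/env python
"""Generate the synthetic study: paired-plot forcing, ASV community with
taxonomy and rrn lookup, probe-level gene signals, and monthly flux
observations, written under results/data/."""

from pathlib import Path

from warmsoil import io, synth

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = synth.StudyDesign(seed=SEED)
    warmed_f, control_f = synth.gen_forcing(design, n_years=2)
    comm = synth.gen_community(design, n_asvs=300)
    probes = synth.gen_probe_signals(design, n_probes=600)

    io.write_forcing(control_f, OUT / "forcing_control.csv")
    io.write_forcing(warmed_f, OUT / "forcing_warmed.csv")
    io.write_counts(comm.counts, OUT / "asv_counts.tsv")
    io.write_taxonomy(comm.taxonomy, OUT / "taxonomy.tsv")
    io.write_lookup(comm.lookup, OUT / "rrn_lookup.tsv")
    io.write_signals(probes.signals, OUT / "probe_signals.tsv")
    io.write_sample_meta(probes.sample_meta, OUT / "sample_meta.tsv")
    probes.annotations.to_csv(OUT / "probe_annotations.tsv", sep="\t", index=False)

    for label, p, f, s in (("control", synth.control_cue_preset(), control_f, SEED),
                           ("warmed", synth.warmed_cue_preset(), warmed_f, SEED + 1)):
        obs = synth.gen_rh_observations(p, f, noise_sd=0.05, seed=s)
        io.write_fluxes(obs.fluxes, OUT / f"fluxes_{label}.csv")

    n_samples = comm.counts.shape[1]
    print(f"wrote {n_samples} samples ({design.n_blocks} blocks x 12 months x 2 "
          f"treatments), {comm.counts.shape[0]} ASVs, "
          f"{probes.signals['probe'].nunique()} probes, 2 years of daily forcing "
          f"-> {OUT}")


if __name__ == "__main__":
    main()
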