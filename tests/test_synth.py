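"""Synthetic-data generator: determinism, pairing, configured effects and
their recoverability by the downstream estimators."""

import math

import numpy as np
import pandas as pd
import pytest

from warmsoil import geochip, mend, synth, traits
from warmsoil.seasons import EARLY_COOL, LATE_COOL, WARM

COOL_MONTHS = [m for m, s in synth.SEASON_OF_MONTH.items() if s != WARM]


class TestDesign:
    def test_perfect_pairing_96_samples(self, design):
        meta = design.sample_meta()
        assert len(meta) == 96
        pair_counts = meta.groupby(["block", "month"])["treatment"].agg(
            lambda s: sorted(s))
        assert all(v == ["control", "warmed"] for v in pair_counts)


class TestGenForcing:
    def test_determinism(self, design):
        a_w, a_c = synth.gen_forcing(design)
        b_w, b_c = synth.gen_forcing(design)
        pd.testing.assert_frame_equal(a_w, b_w)
        pd.testing.assert_frame_equal(a_c, b_c)

    def test_zero_offsets_identical_series(self, design):
        null = {EARLY_COOL: 0.0, WARM: 0.0, LATE_COOL: 0.0}
        unity = {EARLY_COOL: 1.0, WARM: 1.0, LATE_COOL: 1.0}
        w, c = synth.gen_forcing(design, warming_offsets=null,
                                 moisture_factors=unity)
        pd.testing.assert_frame_equal(w, c)

    def test_monthly_means_span_site_range(self, design):
        _, c = synth.gen_forcing(design)
        monthly = c["temperature"].groupby(c.index.month).mean()
        assert monthly.idxmin() == 1 and monthly.idxmax() == 7
        assert monthly.min() == pytest.approx(3.5, abs=1.5)
        assert monthly.max() == pytest.approx(28.1, abs=1.5)

    def test_annual_offset_is_calendar_weighted_mean(self, design):
        """The annual warmed-minus-control difference equals the
        season-length weighted mean of the offsets (closed form over the
        2012 calendar: 60 early-cool, 214 warm, 92 late-cool days)."""
        w, c = synth.gen_forcing(design)
        diff = (w["temperature"] - c["temperature"]).mean()
        expected = (60 * 3.6 + 214 * 4.5 + 92 * 4.1) / 366.0
        assert diff == pytest.approx(expected, abs=1e-9)

    def test_moisture_reduced_only_in_cool_seasons(self, design):
        w, c = synth.gen_forcing(design)
        cool = w.index.month.isin(COOL_MONTHS)
        assert (w.loc[cool, "moisture"] < c.loc[cool, "moisture"]).all()
        assert np.allclose(w.loc[~cool, "moisture"], c.loc[~cool, "moisture"])

    def test_moisture_bounds_and_gpp_nonnegative(self, forcing_pair):
        for f in forcing_pair:
            assert f["moisture"].between(0, 100).all()
            assert (f["gpp"] >= 0).all()

    def test_bad_offset_map_rejected(self, design):
        with pytest.raises(ValueError):
            synth.gen_forcing(design, warming_offsets={WARM: 1.0})

    def test_nonpositive_amplitude_rejected(self, design):
        with pytest.raises(ValueError):
            synth.gen_forcing(design, climate=synth.ClimateCycle(amplitude=0.0))


class TestGenCommunity:
    def test_determinism(self, design):
        a = synth.gen_community(design, n_asvs=50)
        b = synth.gen_community(design, n_asvs=50)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_counts_nonnegative_fixed_depth(self, community):
        assert (community.counts.to_numpy() >= 0).all()
        assert (community.counts.sum(axis=0) == 21567).all()

    def test_null_effect_equal_true_traits(self, design):
        sim = synth.gen_community(design, n_asvs=60, warming_trait_effect=0.0)
        meta = sim.sample_meta
        crrn = sim.true_community_rrn
        for (b, m), grp in meta.groupby(["block", "month"]):
            w = grp.index[grp["treatment"] == "warmed"][0]
            c = grp.index[grp["treatment"] == "control"][0]
            assert crrn[w] == pytest.approx(crrn[c])

    def test_configured_effect_exact_on_true_proportions(self, community):
        meta = community.sample_meta
        crrn = community.true_community_rrn
        for (b, m), grp in meta.groupby(["block", "month"]):
            w = grp.index[grp["treatment"] == "warmed"][0]
            c = grp.index[grp["treatment"] == "control"][0]
            lr = math.log(crrn[w] / crrn[c])
            expected = community.effect if m in COOL_MONTHS else 0.0
            assert lr == pytest.approx(expected, abs=1e-9)

    def test_effect_recovered_over_replicates(self):
        """Monte-Carlo oracle: the mean estimated log-ratio over 1000
        multinomial replicate pairs recovers the configured tilt."""
        rng = np.random.default_rng(7)
        n_asvs, depth, effect = 40, 5000, 0.5
        copies = np.clip(rng.lognormal(0.9, 0.55, n_asvs), 1, 15)
        base = rng.dirichlet(np.full(n_asvs, 0.3))
        base = np.maximum(base, 1e-9)
        base /= base.sum()
        tilted = synth.tilt_proportions(base, copies, effect)
        lrs = np.empty(1000)
        for i in range(1000):
            sw = rng.multinomial(depth, tilted)
            sc = rng.multinomial(depth, base)
            kw = sw > 0
            kc = sc > 0
            lrs[i] = math.log(traits.community_rrn(sw[kw], copies[kw])
                              / traits.community_rrn(sc[kc], copies[kc]))
        assert lrs.mean() == pytest.approx(effect, abs=3 * lrs.std() / math.sqrt(1000))

    def test_constant_trait_lookup_forces_constant_aggregate(self, design):
        """All ASVs at copy number 3: any downstream aggregate equals 3."""
        sim = synth.gen_community(design, n_asvs=30,
                                  rrn_lognormal=(math.log(3.0), 0.0))
        assert sim.degenerate_trait
        lookup = traits.RrnLookup.from_frame(sim.lookup)
        copy = traits.assign_rrn_table(sim.taxonomy, lookup)
        crrn = traits.community_rrn_table(sim.counts, copy)
        assert np.allclose(crrn.to_numpy(), 3.0)

    def test_assignment_recovers_generator_truth(self, community):
        lookup = traits.RrnLookup.from_frame(community.lookup)
        copy = traits.assign_rrn_table(community.taxonomy, lookup)
        assert np.allclose(copy.reindex(community.true_copy.index).to_numpy(),
                           community.true_copy.to_numpy())

    def test_too_few_asvs_rejected(self, design):
        with pytest.raises(ValueError):
            synth.gen_community(design, n_asvs=1)


class TestGenProbeSignals:
    def test_determinism(self, design):
        a = synth.gen_probe_signals(design, n_probes=20)
        b = synth.gen_probe_signals(design, n_probes=20)
        pd.testing.assert_frame_equal(a.signals, b.signals)

    def test_zero_effect_zero_noise_null_rrs(self, design):
        sim = synth.gen_probe_signals(design, n_probes=30, effect_fraction=0.0,
                                      noise_sd=0.0)
        rr = geochip.response_ratio(sim.signals, sim.sample_meta, scope="month")
        assert np.allclose(rr["rr"], 0.0)

    def test_configured_effect_plug_in_limit(self, design):
        """With noise -> 0 and a small affected set, probe response
        ratios converge to the configured log effect (up to the
        compositional bias of mean normalization, < 0.03 here)."""
        sim = synth.gen_probe_signals(design, n_probes=300,
                                      c_decomp_fraction=0.02,
                                      effect_fraction=1.0,
                                      effect_size=math.log(2.0),
                                      noise_sd=1e-5, block_sd=0.05)
        filt, _ = geochip.qc_filter(sim.signals, sim.sample_meta)
        std = set(sim.annotations.loc[sim.annotations["is_standard"], "probe"])
        norm = geochip.normalize(filt, std)
        func = norm[~norm["probe"].isin(std)]
        rr = geochip.response_ratio(func, sim.sample_meta, scope="season",
                                    season_of_month=synth.SEASON_OF_MONTH)
        aff = rr[rr["unit"].isin(sim.affected_probes) & (rr["scope"] != "warm")]
        assert aff["rr"].mean() == pytest.approx(math.log(2.0), abs=0.05)

    def test_month_batch_map_must_cover(self, design):
        with pytest.raises(ValueError):
            synth.gen_probe_signals(design, n_probes=5, batch_of_month={1: 1})

    def test_batch_offsets_removed_by_normalization(self, probe_sim):
        """Raw standards carry the batch scale gap; after the
        standard-probe rescale (step 1) the array standard means are
        exactly equal."""
        filt, _ = geochip.qc_filter(probe_sim.signals, probe_sim.sample_meta)
        std = set(probe_sim.annotations.loc[probe_sim.annotations["is_standard"],
                                            "probe"])
        raw_means = (filt[filt["probe"].isin(std)]
                     .groupby("sample")["signal"].mean())
        assert raw_means.max() / raw_means.min() > 1.3  # e^0.5 batch gap
        _, f1, _ = geochip.normalize(filt, std, return_factors=True)
        step1 = raw_means * f1
        assert np.allclose(step1, step1.iloc[0])


class TestGenRhObservations:
    def test_noiseless_identity(self, default_params, control_forcing):
        obs = synth.gen_rh_observations(default_params, control_forcing,
                                        noise_sd=0.0, seed=1)
        assert np.allclose(obs.observations["rh"],
                           obs.sim.monthly_rh().to_numpy())

    def test_ra_is_rs_minus_rh(self, default_params, control_forcing):
        obs = synth.gen_rh_observations(default_params, control_forcing, seed=2)
        f = obs.fluxes
        assert np.allclose(f["r_a"], f["r_s"] - f["r_h"])
        assert (f["r_h"] >= 0).all()

    def test_doubling_vg_does_not_decrease_rh(self, default_params, control_forcing):
        lo = synth.gen_rh_observations(default_params, control_forcing,
                                       noise_sd=0.0, seed=1)
        hi_params = default_params.with_values(v_g=default_params.v_g * 2)
        hi = synth.gen_rh_observations(hi_params, control_forcing,
                                       noise_sd=0.0, seed=1)
        assert hi.observations["rh"].mean() >= lo.observations["rh"].mean()

    def test_seeding_contract(self, default_params, control_forcing):
        a = synth.gen_rh_observations(default_params, control_forcing, seed=1)
        b = synth.gen_rh_observations(default_params, control_forcing, seed=2)
        c = synth.gen_rh_observations(default_params, control_forcing, seed=1)
        assert not np.array_equal(a.observations["rh"], b.observations["rh"])
        assert np.array_equal(a.observations["rh"], c.observations["rh"])

    def test_negative_noise_rejected(self, default_params, control_forcing):
        with pytest.raises(ValueError):
            synth.gen_rh_observations(default_params, control_forcing,
                                      noise_sd=-0.1)
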