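"""GeoChip-style QC filtering, normalization, response ratios and probe
classification."""

import math

import numpy as np
import pandas as pd
import pytest

from warmsoil import geochip


def toy_meta():
    rows = []
    for b in (1, 2, 3, 4):
        for m in (1, 7):
            for t in ("warmed", "control"):
                rows.append({"sample": f"B{b}_M{m:02d}_{t[0].upper()}",
                             "block": b, "month": m, "treatment": t,
                             "batch": 1 if m <= 6 else 2})
    return pd.DataFrame(rows).set_index("sample")


def passing_row(probe, sample, signal=500.0):
    return {"probe": probe, "sample": sample, "signal": signal,
            "cv": 0.2, "snr": 10.0}


class TestQcFilter:
    def test_one_violation_per_rule(self):
        """Toy fixture with exactly one CV, one SNR and one intensity
        violation plus one probe detected in under half of its group:
        removals match a brute-force application of each rule."""
        meta = toy_meta()
        rows = []
        for s in meta.index:
            for p in ("pA", "pB", "pC"):
                rows.append(passing_row(p, s))
        df = pd.DataFrame(rows)
        df.loc[(df["probe"] == "pA") & (df["sample"] == "B1_M01_W"), "cv"] = 0.9
        df.loc[(df["probe"] == "pB") & (df["sample"] == "B1_M01_C"), "snr"] = 5.0
        df.loc[(df["probe"] == "pC") & (df["sample"] == "B1_M07_W"), "signal"] = 50.0
        # probe pD present in only 1 of the 4 replicates of one group
        df = pd.concat([df, pd.DataFrame([passing_row("pD", "B1_M01_W")])],
                       ignore_index=True)
        out, report = geochip.qc_filter(df, meta)
        assert report.spots_cv == 1
        assert report.spots_snr == 1
        assert report.spots_intensity == 1
        assert report.probes_dropped == 1       # pD vanishes entirely
        assert "pD" not in set(out["probe"])
        # pA keeps the other 3 replicates of its masked group (3/4 >= 50%)
        assert len(out[(out["probe"] == "pA")
                       & (out["sample"].str.contains("M01_W"))]) == 3

    def test_all_passing_identity_and_idempotence(self):
        meta = toy_meta()
        df = pd.DataFrame([passing_row(p, s) for s in meta.index
                           for p in ("pA", "pB")])
        once, rep = geochip.qc_filter(df, meta)
        assert rep.as_dict() == {"spots_cv": 0, "spots_snr": 0,
                                 "spots_intensity": 0, "spots_detection": 0,
                                 "probes_dropped": 0}
        assert len(once) == len(df)
        twice, rep2 = geochip.qc_filter(once, meta)
        assert len(twice) == len(once)
        assert rep2.spots_detection == 0

    def test_batch_specific_snr(self):
        """SNR 5 passes in batch 2 (threshold 3.5) but fails in batch 1
        (threshold 7)."""
        meta = toy_meta()
        rows = [passing_row("pA", s) for s in meta.index]
        df = pd.DataFrame(rows)
        df["snr"] = 5.0
        out, report = geochip.qc_filter(df, meta, min_detection_fraction=0.0)
        kept_months = set(out.merge(meta, left_on="sample",
                                    right_index=True)["month"])
        assert kept_months == {7}
        assert report.spots_snr == len(meta) // 2

    def test_unknown_batch_rejected(self):
        meta = toy_meta()
        meta["batch"] = 9
        df = pd.DataFrame([passing_row("pA", s) for s in meta.index])
        with pytest.raises(ValueError):
            geochip.qc_filter(df, meta)


class TestNormalize:
    def make_signals(self):
        rows = []
        for s, scale in (("a1", 1.0), ("a2", 2.0)):
            rows += [{"probe": "STD1", "sample": s, "signal": 1000.0 * scale},
                     {"probe": "STD2", "sample": s, "signal": 1200.0 * scale},
                     {"probe": "f1", "sample": s, "signal": 400.0 * scale},
                     {"probe": "f2", "sample": s, "signal": 600.0 * scale}]
        return pd.DataFrame(rows)

    def test_doubled_array_scale_factor_half(self):
        df = self.make_signals()
        out, f1, _ = geochip.normalize(df, {"STD1", "STD2"}, return_factors=True)
        assert f1["a2"] == pytest.approx(f1["a1"] / 2.0)
        # standard means equalized after step 1 (factors applied)
        std = out[out["probe"].isin({"STD1", "STD2"})]
        means = std.groupby("sample")["signal"].mean()
        assert means["a1"] == pytest.approx(means["a2"])

    def test_equal_arrays_identity_factors(self):
        df = self.make_signals()
        df.loc[df["sample"] == "a2", "signal"] = \
            df.loc[df["sample"] == "a1", "signal"].to_numpy()
        _, f1, f2 = geochip.normalize(df, {"STD1", "STD2"}, return_factors=True)
        assert np.allclose(f1, 1.0) and np.allclose(f2, 1.0)

    def test_log_transform_definition(self):
        df = self.make_signals()
        out = geochip.normalize(df, {"STD1", "STD2"})
        assert np.allclose(out["log_signal"], np.log(out["signal"]))

    def test_array_without_standards_rejected(self):
        df = self.make_signals()
        df = df[~((df["sample"] == "a2") & df["probe"].str.startswith("STD"))]
        with pytest.raises(ValueError):
            geochip.normalize(df, {"STD1", "STD2"})


class TestResponseRatio:
    def make_group(self, w_vals, c_vals):
        meta = toy_meta()
        rows = []
        samples_w = [s for s in meta.index if s.endswith("W")]
        samples_c = [s for s in meta.index if s.endswith("C")]
        for s, v in zip(samples_w, w_vals):
            rows.append({"probe": "p1", "sample": s, "signal": v})
        for s, v in zip(samples_c, c_vals):
            rows.append({"probe": "p1", "sample": s, "signal": v})
        return pd.DataFrame(rows), meta

    def test_identical_groups_null(self):
        df, meta = self.make_group([3.0] * 4, [3.0] * 4)
        rr = geochip.response_ratio(df, meta, scope="all")
        assert rr.loc[0, "rr"] == 0.0
        assert rr.loc[0, "ci_low"] <= 0.0 <= rr.loc[0, "ci_high"]
        assert not rr.loc[0, "significant"]

    def test_ln2_with_zero_variance(self):
        df, meta = self.make_group([4.0] * 4, [2.0] * 4)
        rr = geochip.response_ratio(df, meta, scope="all")
        assert rr.loc[0, "rr"] == pytest.approx(math.log(2.0))
        assert rr.loc[0, "se"] == 0.0
        assert rr.loc[0, "ci_low"] == rr.loc[0, "ci_high"] == rr.loc[0, "rr"]

    def test_swap_antisymmetry(self):
        df, meta = self.make_group([4.0, 5.0, 6.0, 7.0], [2.0, 2.5, 3.0, 3.5])
        fwd = geochip.response_ratio(df, meta, scope="all")
        swapped = meta.copy()
        swapped["treatment"] = swapped["treatment"].map(
            {"warmed": "control", "control": "warmed"})
        rev = geochip.response_ratio(df, swapped, scope="all")
        assert rev.loc[0, "rr"] == pytest.approx(-fwd.loc[0, "rr"])
        assert rev.loc[0, "ci_low"] == pytest.approx(-fwd.loc[0, "ci_high"])

    def test_delta_method_se(self):
        w = np.array([4.0, 5.0, 6.0, 7.0])
        c = np.array([2.0, 2.5, 3.0, 3.5])
        df, meta = self.make_group(list(w), list(c))
        rr = geochip.response_ratio(df, meta, scope="all")
        expected = math.sqrt(w.var(ddof=1) / (4 * w.mean() ** 2)
                             + c.var(ddof=1) / (4 * c.mean() ** 2))
        assert rr.loc[0, "se"] == pytest.approx(expected)

    def test_zero_group_mean_flagged(self):
        df, meta = self.make_group([0.0] * 4, [2.0] * 4)
        rr = geochip.response_ratio(df, meta, scope="all")
        assert bool(rr.loc[0, "flagged"])
        assert math.isnan(rr.loc[0, "rr"])

    def test_subcategory_sums_before_ratio(self):
        meta = toy_meta()
        rows = []
        for s in meta.index:
            warmed = s.endswith("W")
            rows.append({"probe": "p1", "sample": s, "signal": 4.0 if warmed else 2.0})
            rows.append({"probe": "p2", "sample": s, "signal": 8.0 if warmed else 4.0})
        df = pd.DataFrame(rows)
        ann = pd.DataFrame({"probe": ["p1", "p2"], "subcategory": ["sc", "sc"]})
        rr = geochip.response_ratio(df, meta, scope="all", level="subcategory",
                                    annotations=ann)
        assert len(rr) == 1
        assert rr.loc[0, "rr"] == pytest.approx(math.log(2.0))


class TestClassifyProbes:
    def test_four_categories(self):
        records = pd.DataFrame([
            {"unit": "p_up", "scope": "s", "rr": 0.5, "significant": True},
            {"unit": "p_dn", "scope": "s", "rr": -0.5, "significant": True},
            {"unit": "p_ns", "scope": "s", "rr": 0.2, "significant": False},
        ])
        detection = pd.DataFrame([
            {"probe": "p_w", "scope": "s", "detected_warmed": True,
             "detected_control": False},
            {"probe": "p_c", "scope": "s", "detected_warmed": False,
             "detected_control": True},
            {"probe": "p_up", "scope": "s", "detected_warmed": True,
             "detected_control": True},
            {"probe": "p_dn", "scope": "s", "detected_warmed": True,
             "detected_control": True},
            {"probe": "p_ns", "scope": "s", "detected_warmed": True,
             "detected_control": True},
            {"probe": "p_absent", "scope": "s", "detected_warmed": False,
             "detected_control": False},
        ])
        out = geochip.classify_probes(records, detection)
        cat = dict(zip(out["probe"], out["category"]))
        assert cat == {"p_w": "unique_warming", "p_c": "unique_control",
                       "p_up": "increased", "p_dn": "decreased",
                       "p_ns": "unchanged"}
        assert "p_absent" not in cat

    def test_categories_disjoint_on_generator(self, probe_sim):
        from warmsoil import synth
        filt, _ = geochip.qc_filter(probe_sim.signals, probe_sim.sample_meta)
        std = set(probe_sim.annotations.loc[probe_sim.annotations["is_standard"],
                                            "probe"])
        norm = geochip.normalize(filt, std)
        func = norm[~norm["probe"].isin(std)]
        rr = geochip.response_ratio(func, probe_sim.sample_meta, scope="season",
                                    season_of_month=synth.SEASON_OF_MONTH)
        det = geochip.detection_table(func, probe_sim.sample_meta, scope="season",
                                      season_of_month=synth.SEASON_OF_MONTH)
        out = geochip.classify_probes(rr, det)
        assert not out.duplicated(subset=["probe", "scope"]).any()
        assert set(out["probe"]) <= set(func["probe"])

    def test_cool_season_effects_recovered(self, probe_sim):
        """Most affected C-decomposition probes classify as increased in
        cool seasons (generator ground truth)."""
        from warmsoil import synth
        filt, _ = geochip.qc_filter(probe_sim.signals, probe_sim.sample_meta)
        std = set(probe_sim.annotations.loc[probe_sim.annotations["is_standard"],
                                            "probe"])
        norm = geochip.normalize(filt, std)
        func = norm[~norm["probe"].isin(std)]
        rr = geochip.response_ratio(func, probe_sim.sample_meta, scope="season",
                                    season_of_month=synth.SEASON_OF_MONTH)
        det = geochip.detection_table(func, probe_sim.sample_meta, scope="season",
                                      season_of_month=synth.SEASON_OF_MONTH)
        out = geochip.classify_probes(rr, det)
        cool = out[(out["scope"] != "warm")
                   & out["probe"].isin(probe_sim.affected_probes)]
        frac_up = (cool["category"] == "increased").mean()
        assert frac_up > 0.5
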