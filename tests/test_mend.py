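"""Microbial-enzyme model: CUE function, flux arithmetic, integrator
conservation and qualitative dynamics."""

import math

import numpy as np
import pandas as pd
import pytest

from warmsoil import mend


class TestCueAt:
    def test_reference_identity(self, default_params):
        assert mend.cue_at(default_params.t_ref, default_params) == default_params.yg_ref

    def test_linear_evaluation(self):
        p = mend.MendParams(yg_ref=0.45, k_yg=-0.01, t_ref=20.0)
        assert mend.cue_at(30.0, p) == pytest.approx(0.35)

    def test_clamped_at_extremes(self):
        p = mend.MendParams(yg_ref=0.45, k_yg=-0.01, t_ref=20.0)
        assert mend.cue_at(1000.0, p) == 0.01
        assert mend.cue_at(-1000.0, p) == 0.99


class TestFluxes:
    def test_empty_system_all_zero(self, default_params):
        state = mend.MendPools(**{f: 0.0 for f in
                                  ("p_o", "p_h", "m", "q", "d", "b_a", "b_d",
                                   "ep_o", "ep_h", "em")})
        fx = mend.fluxes(state, default_params, 15.0, 25.0, c_input=0.0)
        assert all(v == 0.0 for v in fx.values())

    def test_growth_respiration_complement(self, default_params):
        """Growth + growth respiration always equals uptake; at the upper
        CUE clamp the respired share is the 1% complement."""
        state = mend.MendPools()
        fx = mend.fluxes(state, default_params, 15.0, 25.0)
        assert fx["growth"] + fx["growth_resp"] == pytest.approx(fx["uptake"])
        hot = mend.MendParams(yg_ref=0.45, k_yg=0.1, t_ref=15.0)  # clamps to 0.99
        fx2 = mend.fluxes(state, hot, 40.0, 25.0)
        assert fx2["growth_resp"] == pytest.approx(0.01 * fx2["uptake"])

    def test_hand_computed_oracle(self):
        """Every flux matches an independent evaluation of its formula at
        a small reference state and 15 C / 25 %V (so the temperature and
        moisture scalars are closed-form)."""
        p = mend.MendParams()
        k = p.kinetics
        st = mend.MendPools(p_o=1.0, p_h=2.0, m=10.0, q=0.2, d=0.1,
                            b_a=0.3, b_d=0.1, ep_o=0.004, ep_h=0.006, em=0.002)
        f_t = 1.0  # T = t_ref
        f_w = math.sqrt(25.0 / 30.0)
        fx = mend.fluxes(st, p, 15.0, 25.0, c_input=0.01)
        yg = 0.43
        assert fx["dec_po"] == pytest.approx(2.5 * 0.004 * 1.0 / 51.0 * f_t * f_w)
        assert fx["dec_ph"] == pytest.approx(2.5 * 0.006 * 2.0 / 52.0 * f_t * f_w)
        assert fx["dec_m"] == pytest.approx(1.0 * 0.002 * 10.0 / 260.0 * f_t * f_w)
        assert fx["ads"] == pytest.approx(0.006 * 0.1 * (1 - 0.2 / 1.7))
        assert fx["des"] == pytest.approx(0.001 * 0.2)
        up = 0.06 * 0.3 * 0.1 / 0.36 * f_w
        assert fx["uptake"] == pytest.approx(up)
        assert fx["growth"] == pytest.approx(yg * up)
        assert fx["maint"] == pytest.approx(0.2 * 0.06 * 0.3 * f_w)
        assert fx["enz_prod_o"] == pytest.approx(0.5 * 0.01 * 0.06 * 0.3)
        assert fx["enz_prod_m"] == pytest.approx(0.5 * 0.01 * 0.06 * 0.3)
        assert fx["turn_o"] == pytest.approx(0.005 * 0.004)
        assert fx["input_p"] == pytest.approx(0.7 * 0.01)
        assert fx["input_d"] == pytest.approx(0.3 * 0.01)
        assert fx["d2a"] == pytest.approx(0.01 * 0.1)   # W above psi_a2d
        assert fx["a2d"] == 0.0
        assert fx["rh"] == pytest.approx((1 - yg) * up + fx["maint"] + fx["maint_dorm"])

    def test_negative_pool_rejected(self, default_params):
        bad = mend.MendPools(d=-0.1)
        with pytest.raises(ValueError):
            mend.fluxes(bad, default_params, 15.0, 25.0)


class TestSimulate:
    def test_null_run(self, default_params):
        dates = pd.date_range("2012-01-01", periods=60, freq="D")
        forcing = pd.DataFrame({"temperature": 15.0, "moisture": 25.0, "gpp": 0.0},
                               index=dates)
        zero = mend.MendPools(**{f: 0.0 for f in
                                 ("p_o", "p_h", "m", "q", "d", "b_a", "b_d",
                                  "ep_o", "ep_h", "em")})
        out = mend.simulate(default_params, forcing, initial=zero)
        assert np.all(out.rh == 0.0)

    def test_mass_balance(self, default_params, control_forcing):
        out = mend.simulate(default_params, control_forcing)
        err = out.mass_balance_error(mend.MendPools().total)
        assert err <= 1e-6 * (out.inputs_total + out.rh_total)

    def test_pools_nonnegative(self, default_params, control_forcing):
        out = mend.simulate(default_params, control_forcing)
        assert (out.pools.to_numpy() >= 0.0).all()

    def test_steady_state_balance(self, default_params):
        """Constant forcing: the long-run respiration rate approaches the
        input rate (multi-decade spin-up; slow mineral pool dominates the
        residual gap)."""
        dates = pd.date_range("2000-01-01", periods=365 * 200, freq="D")
        forcing = pd.DataFrame({"temperature": 15.0, "moisture": 25.0, "gpp": 3.0},
                               index=dates)
        out = mend.simulate(default_params, forcing)
        inp = 3.0 * default_params.gpp_to_soil * 1e3 / mend.SOIL_MASS_G_M2
        assert out.rh_mg[-365:].mean() == pytest.approx(inp, rel=0.05)

    def test_gpp_monotonicity(self, default_params, control_forcing):
        doubled = control_forcing.copy()
        doubled["gpp"] = doubled["gpp"] * 2.0
        base = mend.simulate(default_params, control_forcing)
        more = mend.simulate(default_params, doubled)
        assert more.rh_total >= base.rh_total

    def test_substep_halving_insensitive(self, default_params, control_forcing):
        o1 = mend.simulate(default_params, control_forcing, dt=1.0)
        o2 = mend.simulate(default_params, control_forcing, dt=0.5)
        assert abs(o1.rh_total - o2.rh_total) / o1.rh_total < 0.005

    def test_realized_cue_equals_intrinsic_without_maintenance(self, control_forcing):
        p = mend.MendParams(alpha_maint=0.0)
        out = mend.simulate(p, control_forcing)
        temps = control_forcing["temperature"].to_numpy()
        expected = np.array([mend.cue_at(t, p) for t in temps])
        ok = ~np.isnan(out.cue)
        assert np.allclose(out.cue[ok], expected[ok], atol=1e-9)

    def test_missing_forcing_rejected(self, default_params, control_forcing):
        broken = control_forcing.copy()
        broken.iloc[5, 0] = np.nan
        with pytest.raises(ValueError):
            mend.simulate(default_params, broken)


class TestParams:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            mend.MendParams(f_inp=1.2).validate()

    def test_build_params_roundtrip(self, default_params):
        p = mend.build_params(default_params, ["v_g", "yg_ref"], [0.1, 0.5])
        assert p.v_g == 0.1 and p.yg_ref == 0.5

    def test_build_params_unknown_name(self, default_params):
        with pytest.raises(KeyError):
            mend.build_params(default_params, ["nope"], [1.0])
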