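"""Microbial-ENzyme Decomposition (MEND-type) soil carbon model.

Forward-simulates daily heterotrophic respiration (Rh), carbon pools and
enzyme concentrations from daily forcing (soil temperature, moisture,
GPP-derived carbon input), with a temperature-dependent intrinsic
microbial carbon use efficiency (CUE, the ``Yg`` parameter).

Pools (all mg C per g soil):

========  =====================================================
``p_o``   particulate organic C decomposed oxidatively
``p_h``   particulate organic C decomposed hydrolytically
``m``     mineral-associated organic C
``q``     adsorbed (protected) dissolved C
``d``     dissolved organic C
``b_a``   active microbial biomass
``b_d``   dormant microbial biomass
``ep_o``  oxidative exo-enzymes (EnzCo)
``ep_h``  hydrolytic exo-enzymes (EnzCh)
``em``    enzymes acting on the mineral-associated pool
========  =====================================================

Process structure: Michaelis–Menten decomposition of each substrate pool
by its enzyme class; microbial uptake of dissolved C with a fraction
Yg(T) assimilated to growth and 1 − Yg(T) respired; maintenance
respiration scaled by the ``alpha_maint`` coefficient; enzyme production
(``p_ep``, with mineral-enzyme share ``fp_em``) and first-order enzyme
turnover (``r_e``); moisture-threshold dormancy switching (``beta_dorm``,
``psi_a2d``); adsorption/desorption exchange between dissolved and
protected C.  All biological rates carry an Arrhenius temperature scalar
and a saturating moisture scalar.  Rh = growth respiration + maintenance
respiration (active + residual dormant).

The integrator is explicit Euler with adaptive halving of the daily step
whenever a pool would go negative, which keeps the scheme deterministic
and exactly mass conservative: the change in total C over any window
equals inputs minus cumulative Rh to floating-point round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

__all__ = [
    "KineticConstants",
    "MendParams",
    "MendPools",
    "SimulationOutput",
    "cue_at",
    "fluxes",
    "simulate",
    "MGC_TO_UMOL",
    "SOIL_MASS_G_M2",
]

# Topsoil mass per unit area used to convert between the model's internal
# mg C g^-1 soil d^-1 and chamber-flux units: 0-15 cm at bulk density
# 1.3 g cm^-3.
SOIL_MASS_G_M2 = 1.95e5
_GC_PER_MOL = 12.011
# mg C g^-1 soil d^-1  ->  umol CO2 m^-2 s^-1
MGC_TO_UMOL = SOIL_MASS_G_M2 / _GC_PER_MOL * 1e3 / 86400.0

_R_KJ = 8.314e-3  # kJ mol^-1 K^-1


@dataclass(frozen=True)
class KineticConstants:
    """Fixed (non-calibrated) kinetic constants.

    Activation energies are held fixed because the calibrated-parameter
    set contains no Ea terms; adsorption/desorption and mortality are
    slow background processes.
    """

    ea_kj: float = 47.0            # activation energy, kJ mol^-1 (Q10 ~ 1.9 at 15 C)
    v_p: float = 2.5               # max specific P decomposition, mg C (mg enzyme C)^-1 d^-1
    k_p: float = 50.0              # half-saturation for P pools, mg C g^-1
    v_m: float = 1.0               # max specific M decomposition
    k_m: float = 250.0             # half-saturation for M pool, mg C g^-1
    q_max: float = 1.7             # adsorption capacity, mg C g^-1
    k_ads: float = 0.006           # adsorption rate, d^-1
    k_des: float = 0.001           # desorption rate, d^-1
    k_death: float = 5e-4          # active-biomass mortality, d^-1
    dormant_death_frac: float = 0.1    # dormant mortality relative to active
    dormant_maint_frac: float = 0.01   # dormant maintenance relative to active
    w_opt: float = 30.0            # volumetric moisture (%) at which rates saturate


@dataclass(frozen=True)
class MendParams:
    """Calibratable MEND parameters plus frozen kinetic constants.

    The eleven process parameters (``f_inp`` … ``psi_a2d``) regulate soil
    C input partitioning, enzyme production/turnover, C flow to dissolved
    organic C, and microbial growth, maintenance and dormancy; ``yg_ref``
    and ``k_yg`` define the temperature-dependent intrinsic CUE
    Yg(T) = yg_ref + k_yg * (T - t_ref).
    """

    f_inp: float = 0.70        # fraction of soil C input entering particulate pools
    r_e: float = 0.005         # enzyme turnover rate, d^-1
    p_ep: float = 0.010        # enzyme production fraction of potential uptake
    fp_em: float = 0.50        # mineral-enzyme production relative to exo-enzymes
    f_d: float = 0.50          # fraction of decomposed P routed to dissolved C
    g_d: float = 0.50          # fraction of dead biomass/enzyme C routed to dissolved C
    v_g: float = 0.060         # max specific uptake rate, d^-1
    alpha_maint: float = 0.20  # maintenance coefficient (scales v_g)
    k_d: float = 0.26          # half-saturation for D uptake, mg C g^-1
    beta_dorm: float = 0.010   # active<->dormant exchange rate, d^-1
    psi_a2d: float = 6.0       # volumetric moisture (%) below which biomass goes dormant
    yg_ref: float = 0.43       # intrinsic CUE at the reference temperature
    k_yg: float = -0.0025      # CUE temperature slope, per deg C
    t_ref: float = 15.0        # reference temperature, deg C
    gpp_to_soil: float = 0.30  # fraction of GPP entering the soil as C input
    kinetics: KineticConstants = field(default_factory=KineticConstants)

    def validate(self) -> None:
        for name in ("f_inp", "p_ep", "fp_em", "f_d", "g_d", "alpha_maint"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("r_e", "v_g", "k_d", "beta_dorm", "psi_a2d", "gpp_to_soil"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.yg_ref < 1.0:
            raise ValueError(f"yg_ref={self.yg_ref} outside (0, 1)")

    def with_values(self, **kwargs: float) -> "MendParams":
        return replace(self, **kwargs)


_POOL_NAMES = ("p_o", "p_h", "m", "q", "d", "b_a", "b_d", "ep_o", "ep_h", "em")


@dataclass
class MendPools:
    """Carbon-pool state, mg C per g soil; all pools must be >= 0."""

    p_o: float = 1.5
    p_h: float = 3.0
    m: float = 15.0
    q: float = 0.4
    d: float = 0.05
    b_a: float = 0.40
    b_d: float = 0.40
    ep_o: float = 2e-3
    ep_h: float = 2e-3
    em: float = 1e-3

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, n) for n in _POOL_NAMES)

    def validate(self) -> None:
        for n in _POOL_NAMES:
            if getattr(self, n) < 0.0:
                raise ValueError(f"pool {n} is negative")

    @property
    def total(self) -> float:
        return sum(self.as_tuple())


@dataclass
class SimulationOutput:
    """Daily model output aligned with the forcing index."""

    dates: pd.Index
    rh: np.ndarray            # umol CO2 m^-2 s^-1
    rh_mg: np.ndarray         # mg C g^-1 soil d^-1
    pools: pd.DataFrame       # one column per pool
    enz_co: np.ndarray        # oxidative enzyme pool (= pools.ep_o)
    enz_ch: np.ndarray        # hydrolytic enzyme pool (= pools.ep_h)
    cue: np.ndarray           # realized daily CUE (nan when no uptake)
    inputs_total: float       # cumulative C input, mg C g^-1
    rh_total: float           # cumulative Rh, mg C g^-1
    clamp_events: int         # days on which Yg(T) hit its clamp

    def mass_balance_error(self, initial_total: float) -> float:
        """|delta total C - (inputs - cumulative Rh)|, mg C g^-1."""
        final_total = float(self.pools.iloc[-1].sum())
        return abs((final_total - initial_total) - (self.inputs_total - self.rh_total))

    def monthly_rh(self) -> pd.Series:
        """Calendar-month mean Rh in umol CO2 m^-2 s^-1."""
        s = pd.Series(self.rh, index=self.dates)
        return s.groupby([s.index.year, s.index.month]).mean()


def cue_at(t_c: float, params: MendParams) -> float:
    """Intrinsic CUE at temperature ``t_c``: linear in T, clamped to [0.01, 0.99]."""
    yg = params.yg_ref + params.k_yg * (t_c - params.t_ref)
    return min(0.99, max(0.01, yg))


def _cue_clamped(t_c: float, params: MendParams) -> tuple:
    yg = params.yg_ref + params.k_yg * (t_c - params.t_ref)
    clamped = yg < 0.01 or yg > 0.99
    return min(0.99, max(0.01, yg)), clamped


def temperature_scalar(t_c: float, params: MendParams) -> float:
    """Arrhenius factor relative to the reference temperature."""
    k = params.kinetics
    return math.exp(-k.ea_kj / _R_KJ * (1.0 / (t_c + 273.15) - 1.0 / (params.t_ref + 273.15)))


def moisture_scalar(w_pct: float, params: MendParams) -> float:
    """Saturating moisture limitation: sqrt ramp up to ``w_opt``, 1 above."""
    if w_pct <= 0.0:
        return 0.0
    return min(1.0, w_pct / params.kinetics.w_opt) ** 0.5


def fluxes(state: MendPools, params: MendParams, t_c: float, w_pct: float,
           c_input: float = 0.0) -> dict:
    """Evaluate every model flux (mg C g^-1 d^-1) at a given state and forcing.

    ``c_input`` is the external soil C input rate.  Returns a dict of named
    fluxes plus the derived respiration terms; :func:`simulate` consumes the
    same arithmetic through the fast scalar path.
    """
    state.validate()
    if not 0.0 <= w_pct <= 100.0:
        raise ValueError(f"moisture {w_pct} outside [0, 100]")
    k = params.kinetics
    f_t = temperature_scalar(t_c, params)
    f_w = moisture_scalar(w_pct, params)
    yg, _ = _cue_clamped(t_c, params)

    dec_po = k.v_p * state.ep_o * state.p_o / (k.k_p + state.p_o) * f_t * f_w
    dec_ph = k.v_p * state.ep_h * state.p_h / (k.k_p + state.p_h) * f_t * f_w
    dec_m = k.v_m * state.em * state.m / (k.k_m + state.m) * f_t * f_w
    ads = k.k_ads * state.d * max(0.0, 1.0 - state.q / k.q_max)
    des = k.k_des * state.q
    uptake = params.v_g * state.b_a * state.d / (params.k_d + state.d) * f_t * f_w
    growth = yg * uptake
    growth_resp = (1.0 - yg) * uptake
    maint = params.alpha_maint * params.v_g * state.b_a * f_t * f_w
    maint_dorm = k.dormant_maint_frac * params.alpha_maint * params.v_g * state.b_d * f_t * f_w
    enz_prod_o = 0.5 * params.p_ep * params.v_g * state.b_a * f_t
    enz_prod_h = enz_prod_o
    enz_prod_m = params.fp_em * params.p_ep * params.v_g * state.b_a * f_t
    turn_o = params.r_e * state.ep_o
    turn_h = params.r_e * state.ep_h
    turn_m = params.r_e * state.em
    death_a = k.k_death * state.b_a
    death_d = k.dormant_death_frac * k.k_death * state.b_d
    if w_pct < params.psi_a2d:
        a2d, d2a = params.beta_dorm * state.b_a, 0.0
    else:
        a2d, d2a = 0.0, params.beta_dorm * state.b_d
    return {
        "input_p": params.f_inp * c_input,
        "input_d": (1.0 - params.f_inp) * c_input,
        "dec_po": dec_po, "dec_ph": dec_ph, "dec_m": dec_m,
        "ads": ads, "des": des,
        "uptake": uptake, "growth": growth,
        "growth_resp": growth_resp, "maint": maint, "maint_dorm": maint_dorm,
        "enz_prod_o": enz_prod_o, "enz_prod_h": enz_prod_h, "enz_prod_m": enz_prod_m,
        "turn_o": turn_o, "turn_h": turn_h, "turn_m": turn_m,
        "death_a": death_a, "death_d": death_d,
        "a2d": a2d, "d2a": d2a,
        "rh": growth_resp + maint + maint_dorm,
    }


def _derivs(s: tuple, params: MendParams, f_t: float, f_w: float, yg: float,
            c_input: float, dormant: bool) -> tuple:
    """Scalar-path derivative evaluation; returns (derivs tuple, rh, uptake)."""
    p_o, p_h, m, q, d, b_a, b_d, ep_o, ep_h, em = s
    k = params.kinetics
    dec_po = k.v_p * ep_o * p_o / (k.k_p + p_o) * f_t * f_w
    dec_ph = k.v_p * ep_h * p_h / (k.k_p + p_h) * f_t * f_w
    dec_m = k.v_m * em * m / (k.k_m + m) * f_t * f_w
    ads = k.k_ads * d * (1.0 - q / k.q_max if q < k.q_max else 0.0)
    des = k.k_des * q
    uptake = params.v_g * b_a * d / (params.k_d + d) * f_t * f_w
    growth = yg * uptake
    maint = params.alpha_maint * params.v_g * b_a * f_t * f_w
    maint_dorm = k.dormant_maint_frac * params.alpha_maint * params.v_g * b_d * f_t * f_w
    e_half = 0.5 * params.p_ep * params.v_g * b_a * f_t
    e_m = params.fp_em * params.p_ep * params.v_g * b_a * f_t
    turn_o = params.r_e * ep_o
    turn_h = params.r_e * ep_h
    turn_m = params.r_e * em
    death_a = k.k_death * b_a
    death_d = k.dormant_death_frac * k.k_death * b_d
    if dormant:
        a2d, d2a = params.beta_dorm * b_a, 0.0
    else:
        a2d, d2a = 0.0, params.beta_dorm * b_d
    dec_p = dec_po + dec_ph
    dead = death_a + death_d
    d_po = 0.5 * params.f_inp * c_input - dec_po
    d_ph = 0.5 * params.f_inp * c_input + (1.0 - params.g_d) * (turn_o + turn_h + dead) - dec_ph
    d_m = (1.0 - params.f_d) * dec_p + (1.0 - params.g_d) * turn_m - dec_m
    d_q = ads - des
    d_d = ((1.0 - params.f_inp) * c_input + params.f_d * dec_p + dec_m
           + params.g_d * (turn_o + turn_h + turn_m + dead) + des - ads - uptake)
    d_ba = growth - maint - 2.0 * e_half - e_m - death_a - a2d + d2a
    d_bd = a2d - d2a - maint_dorm - death_d
    d_epo = e_half - turn_o
    d_eph = e_half - turn_h
    d_em = e_m - turn_m
    rh = (1.0 - yg) * uptake + maint + maint_dorm
    return ((d_po, d_ph, d_m, d_q, d_d, d_ba, d_bd, d_epo, d_eph, d_em), rh, uptake)


class MendInstabilityError(RuntimeError):
    """Raised when the integrator cannot keep pools non-negative."""


def simulate(params: MendParams, forcing: pd.DataFrame, initial: MendPools | None = None,
             dt: float = 1.0, max_halvings: int = 20) -> SimulationOutput:
    """Forward-simulate the model over daily forcing.

    ``forcing`` must have a DatetimeIndex (or RangeIndex) with columns
    ``temperature`` (deg C), ``moisture`` (volumetric %), ``gpp``
    (g C m^-2 d^-1); one row per day, no gaps.  Daily Rh is the
    growth + maintenance respiration summed over the day's substeps.
    """
    params.validate()
    if initial is None:
        initial = MendPools()
    initial.validate()
    temp = forcing["temperature"].to_numpy(dtype=float)
    wet = forcing["moisture"].to_numpy(dtype=float)
    gpp = forcing["gpp"].to_numpy(dtype=float)
    if np.isnan(temp).any() or np.isnan(wet).any() or np.isnan(gpp).any():
        raise ValueError("forcing contains missing values")
    if (wet < 0).any() or (wet > 100).any():
        raise ValueError("moisture outside [0, 100]")
    n = len(temp)
    input_scale = params.gpp_to_soil * 1e3 / SOIL_MASS_G_M2  # gC m-2 d-1 -> mg C g-1 d-1

    s = initial.as_tuple()
    rh_daily = np.empty(n)
    cue_daily = np.empty(n)
    pool_tracks = np.empty((n, 10))
    inputs_total = 0.0
    rh_total = 0.0
    clamp_events = 0

    for i in range(n):
        t_c = temp[i]
        w = wet[i]
        c_in = gpp[i] * input_scale
        f_t = temperature_scalar(t_c, params)
        f_w = moisture_scalar(w, params)
        yg, clamped = _cue_clamped(t_c, params)
        if clamped:
            clamp_events += 1
        dormant = w < params.psi_a2d
        remaining = 1.0  # each forcing row is one day, split into dt-substeps
        day_rh = 0.0
        day_up = 0.0
        day_growth = 0.0
        while remaining > 1e-12:
            h = min(dt, remaining)
            halvings = 0
            while True:
                der, rh_rate, up_rate = _derivs(s, params, f_t, f_w, yg, c_in, dormant)
                new = tuple(s[j] + h * der[j] for j in range(10))
                if min(new) >= 0.0 or halvings >= max_halvings:
                    break
                h *= 0.5
                halvings += 1
            if min(new) < -1e-9:
                raise MendInstabilityError(
                    f"pool went negative at step {i} despite {max_halvings} halvings")
            s = tuple(v if v > 0.0 else 0.0 for v in new)
            day_rh += rh_rate * h
            day_up += up_rate * h
            day_growth += yg * up_rate * h
            remaining -= h
        rh_daily[i] = day_rh
        cue_daily[i] = (day_growth / day_up) if day_up > 0 else math.nan
        pool_tracks[i] = s
        inputs_total += c_in
        rh_total += day_rh

    pools = pd.DataFrame(pool_tracks, columns=list(_POOL_NAMES), index=forcing.index)
    return SimulationOutput(
        dates=forcing.index,
        rh=rh_daily * MGC_TO_UMOL,
        rh_mg=rh_daily,
        pools=pools,
        enz_co=pool_tracks[:, 7],
        enz_ch=pool_tracks[:, 8],
        cue=cue_daily,
        inputs_total=inputs_total,
        rh_total=rh_total,
        clamp_events=clamp_events,
    )


def param_bounds(names: list[str]) -> np.ndarray:
    """Default calibration bounds for a named subset of parameters."""
    table = {
        "f_inp": (0.05, 0.95),
        "r_e": (5e-4, 0.05),
        "p_ep": (1e-3, 0.1),
        "fp_em": (0.01, 1.0),
        "f_d": (0.05, 0.95),
        "g_d": (0.05, 0.95),
        "v_g": (0.005, 0.5),
        "alpha_maint": (0.01, 1.0),
        "k_d": (0.02, 2.0),
        "beta_dorm": (1e-4, 0.1),
        "psi_a2d": (0.5, 20.0),
        "yg_ref": (0.10, 0.80),
        "k_yg": (-0.02, 0.02),
    }
    return np.array([table[n] for n in names], dtype=float)


_PARAM_FIELD_NAMES = {f.name for f in fields(MendParams)}


def build_params(base: MendParams, names: list[str], values) -> MendParams:
    """Return ``base`` with the named parameters replaced by ``values``."""
    unknown = set(names) - _PARAM_FIELD_NAMES
    if unknown:
        raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
    return base.with_values(**dict(zip(names, (float(v) for v in values))))
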