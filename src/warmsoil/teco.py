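"""First-order (CENTURY-type) multi-pool carbon model baseline with MCMC.

The TECO-style baseline represents soil carbon as a small set of pools
with first-order turnover modulated by temperature and moisture scalars:

    dX/dt = B u(t) + xi(T, W) (A - I) K X,

where u(t) is the carbon input (from GPP), B allocates input among
pools, K is the diagonal of turnover rates, A holds the transfer
fractions between pools and xi = xi_T * xi_W is the environmental
scalar (Q10 temperature response times a saturating moisture ramp).
The respired fraction of each pool's outflow (1 minus its column sum of
transfers) yields heterotrophic respiration.  Parameters are calibrated
against observed Rh with a Metropolis-Hastings random-walk sampler
whose Gaussian-residual variance is marginalized analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import fit_r2
from .mend import MGC_TO_UMOL, SOIL_MASS_G_M2

__all__ = [
    "TecoParams",
    "PosteriorSample",
    "teco_simulate",
    "instantaneous_rh",
    "mh_calibrate",
    "compare_models",
]


@dataclass
class TecoParams:
    """Turnover, transfer and environmental-scalar parameters.

    Default structure: three heterotrophic pools (litter, fast SOM,
    slow SOM) in a serial cascade; ``transfers[i, j]`` is the fraction
    of pool ``j``'s outflow entering pool ``i``; each column sum must be
    <= 1, the remainder being respired.
    """

    turnover: np.ndarray = field(
        default_factory=lambda: np.array([8e-3, 8e-4, 5e-5]))  # d^-1
    transfers: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0, 0.0],
                                          [0.45, 0.0, 0.0],
                                          [0.0, 0.30, 0.0]]))
    input_allocation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    q10: float = 2.0
    t_ref: float = 15.0
    w_opt: float = 30.0          # moisture (%) above which xi_W = 1
    gpp_to_soil: float = 0.30    # fraction of GPP entering the litter input

    def validate(self) -> None:
        k = np.asarray(self.turnover, dtype=float)
        a = np.asarray(self.transfers, dtype=float)
        b = np.asarray(self.input_allocation, dtype=float)
        n = len(k)
        if (k < 0).any():
            raise ValueError("turnover rates must be >= 0")
        if a.shape != (n, n) or (a < 0).any() or (a > 1).any():
            raise ValueError("transfer matrix must be (n, n) with entries in [0, 1]")
        if (a.sum(axis=0) > 1.0 + 1e-12).any():
            raise ValueError("transfer-column sums must be <= 1 "
                             "(respired fraction would be negative)")
        if b.shape != (n,) or (b < 0).any() or abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("input allocation must be a length-n simplex vector")
        if self.q10 <= 0:
            raise ValueError("q10 must be > 0")

    @property
    def respired_fraction(self) -> np.ndarray:
        return 1.0 - np.asarray(self.transfers).sum(axis=0)


def environmental_scalar(t_c, w_pct, params: TecoParams):
    """xi(T, W) = Q10^((T - T_ref)/10) * min(1, W / w_opt)."""
    xi_t = params.q10 ** ((np.asarray(t_c, dtype=float) - params.t_ref) / 10.0)
    xi_w = np.clip(np.asarray(w_pct, dtype=float) / params.w_opt, 0.0, 1.0)
    return xi_t * xi_w


@dataclass
class TecoOutput:
    dates: pd.Index
    rh: np.ndarray          # umol CO2 m^-2 s^-1
    rh_mg: np.ndarray       # mg C g^-1 d^-1
    pools: np.ndarray       # (n_days, n_pools)
    inputs_total: float
    rh_total: float

    def monthly_rh(self) -> pd.Series:
        s = pd.Series(self.rh, index=self.dates)
        return s.groupby([s.index.year, s.index.month]).mean()


def teco_simulate(params: TecoParams, forcing: pd.DataFrame,
                  initial_pools) -> TecoOutput:
    """Daily explicit integration of the linear pool system.

    ``forcing`` as for the microbial model: ``temperature``, ``moisture``,
    ``gpp`` columns, one row per day.  Pools in mg C g^-1 soil.
    """
    params.validate()
    x = np.asarray(initial_pools, dtype=float).copy()
    if (x < 0).any():
        raise ValueError("initial pools must be >= 0")
    k = np.asarray(params.turnover, dtype=float)
    a = np.asarray(params.transfers, dtype=float)
    b = np.asarray(params.input_allocation, dtype=float)
    resp_frac = params.respired_fraction
    temp = forcing["temperature"].to_numpy(dtype=float)
    wet = forcing["moisture"].to_numpy(dtype=float)
    gpp = forcing["gpp"].to_numpy(dtype=float)
    xi = environmental_scalar(temp, wet, params)
    input_scale = params.gpp_to_soil * 1e3 / SOIL_MASS_G_M2
    n = len(temp)
    n_pools = len(k)
    pools = np.empty((n, n_pools))
    rh = np.empty(n)
    inputs_total = 0.0
    rh_total = 0.0
    for i in range(n):
        u = gpp[i] * input_scale
        # exponential outflow propagator: exact for first-order decay
        # over the daily step, unconditionally stable
        out = -np.expm1(-xi[i] * k) * x
        rh[i] = float(resp_frac @ out)
        x = x + b * u + a @ out - out
        pools[i] = x
        inputs_total += u
        rh_total += rh[i]
    return TecoOutput(dates=forcing.index, rh=rh * MGC_TO_UMOL, rh_mg=rh,
                      pools=pools, inputs_total=inputs_total, rh_total=rh_total)


def instantaneous_rh(params: TecoParams, pools, t_c: float, w_pct: float) -> float:
    """Instantaneous respiration rate (mg C g^-1 d^-1) at a given state;
    exactly linear in the environmental scalar."""
    xi = float(environmental_scalar(t_c, w_pct, params))
    out = xi * np.asarray(params.turnover, dtype=float) * np.asarray(pools, dtype=float)
    return float(params.respired_fraction @ out)


@dataclass
class PosteriorSample:
    """Thinned M-H chain with acceptance diagnostics."""

    chain: np.ndarray          # (n_kept, p)
    log_posterior: np.ndarray  # (n_kept,)
    acceptance_rate: float
    param_names: list

    def summary(self) -> pd.DataFrame:
        q = np.percentile(self.chain, [2.5, 50, 97.5], axis=0)
        return pd.DataFrame({
            "name": self.param_names,
            "mean": self.chain.mean(axis=0),
            "sd": self.chain.std(axis=0, ddof=1),
            "q2.5": q[0], "median": q[1], "q97.5": q[2],
        })


def _marginal_loglik(residuals: np.ndarray) -> float:
    """Gaussian log-likelihood with the noise variance marginalized
    (Jeffreys prior on sigma): -n/2 * log(SSR)."""
    ssr = float(np.sum(residuals ** 2))
    if ssr <= 0:
        ssr = 1e-300
    return -0.5 * len(residuals) * math.log(ssr)


def mh_calibrate(observed_rh, simulator, priors, chain_length: int = 5000,
                 proposal_scale: float = 0.1, seed: int = 0,
                 burn_fraction: float = 0.2, thin: int = 1,
                 param_names=None) -> PosteriorSample:
    """Metropolis-Hastings random-walk calibration against observed Rh.

    ``simulator(theta)`` must return the simulated series aligned with
    ``observed_rh``.  ``priors`` is a (p, 2) array of uniform bounds;
    proposals are Gaussian with per-parameter step
    ``proposal_scale * (hi - lo)``, reflected at the bounds.  The
    Gaussian residual variance is marginalized analytically, so the
    posterior involves only the parameters of interest.  Deterministic
    for a given seed.
    """
    if chain_length < 1000:
        raise ValueError("chain_length must be >= 1000")
    obs = np.asarray(observed_rh, dtype=float)
    priors = np.asarray(priors, dtype=float)
    p = priors.shape[0]
    if not np.isfinite(priors).all():
        raise ValueError("priors must be finite")
    lo, hi = priors[:, 0], priors[:, 1]
    span = hi - lo
    step = proposal_scale * span
    rng = np.random.default_rng(seed)

    def logpost(theta):
        sim = np.asarray(simulator(theta), dtype=float)
        return _marginal_loglik(sim - obs)

    theta = lo + rng.random(p) * span
    lp = logpost(theta)
    kept, kept_lp = [], []
    accepted = 0
    adapt_window = min(500, chain_length // 4)
    for it in range(chain_length):
        prop = theta + rng.normal(0.0, step)
        # reflect at the prior bounds
        for j in range(p):
            while prop[j] < lo[j] or prop[j] > hi[j]:
                if prop[j] < lo[j]:
                    prop[j] = 2 * lo[j] - prop[j]
                if prop[j] > hi[j]:
                    prop[j] = 2 * hi[j] - prop[j]
        lp_prop = logpost(prop)
        if lp_prop - lp > math.log(rng.random() + 1e-300):
            theta, lp = prop, lp_prop
            accepted += 1
        if it == adapt_window - 1 and accepted == 0:
            raise RuntimeError("no acceptance within the adaptation window; "
                               "reduce proposal_scale")
        kept.append(theta.copy())
        kept_lp.append(lp)
    burn = int(burn_fraction * chain_length)
    chain = np.asarray(kept)[burn::thin]
    lps = np.asarray(kept_lp)[burn::thin]
    names = list(param_names) if param_names is not None else [f"p{i}" for i in range(p)]
    return PosteriorSample(chain=chain, log_posterior=lps,
                           acceptance_rate=accepted / chain_length,
                           param_names=names)


def compare_models(observed_rh, teco_rh, mend_rh) -> dict:
    """Paired R^2 report: per-model fit and relative improvement of the
    microbial model over the first-order baseline."""
    obs = np.asarray(observed_rh, dtype=float)
    if len(teco_rh) != len(obs) or len(mend_rh) != len(obs):
        raise ValueError("simulated series misaligned with observations")
    r2_teco = fit_r2(obs, np.asarray(teco_rh, dtype=float))
    r2_mend = fit_r2(obs, np.asarray(mend_rh, dtype=float))
    improvement = (r2_mend - r2_teco) / r2_teco if r2_teco != 0 else math.inf
    return {"r2_teco": r2_teco, "r2_mend": r2_mend,
            "relative_improvement": improvement}
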