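"""Multiobjective calibration of the microbial-enzyme model.

The overall objective J = sum_i w_i J_i is a weighted average of
per-variable misfits: J_1 = 1 - R^2 on heterotrophic respiration,
J_2 = 1 - r on log oxidative-enzyme (gene-abundance) series and
J_3 = 1 - r on log hydrolytic-enzyme series, with default weights
(3/5, 1/5, 1/5).  The global search is the Shuffled Complex Evolution
(SCE-UA) scheme; parameter uncertainty comes from the Critical Objective
Function Index (COFI): J_cr = J_opt * (1 + p/(n-p) * F_{alpha,p,n-p}),
with the feasible parameter region defined by all evaluated parameter
vectors whose objective does not exceed J_cr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import mend

__all__ = [
    "ObjectiveSpec",
    "CofiResult",
    "SceResult",
    "fit_r2",
    "fit_r",
    "total_objective",
    "mend_objective",
    "sce_optimize",
    "cofi",
    "calibrate_mend",
]


def fit_r2(observed, simulated) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (can be negative)."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    if len(obs) < 3:
        raise ValueError("need at least 3 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("observed series has zero variance")
    ss_res = float(np.sum((sim - obs) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_r(observed_log, simulated_log) -> float:
    """Pearson correlation between (log-scale) observed and simulated series."""
    obs = np.asarray(observed_log, dtype=float)
    sim = np.asarray(simulated_log, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    if len(obs) < 3:
        raise ValueError("need at least 3 points")
    do = obs - obs.mean()
    ds = sim - sim.mean()
    denom = math.sqrt(float(np.sum(do ** 2)) * float(np.sum(ds ** 2)))
    if denom <= 0:
        raise ValueError("zero variance in a series")
    return float(np.sum(do * ds) / denom)


@dataclass
class ObjectiveSpec:
    """Weights for the (Rh, EnzCo, EnzCh) objectives; normalized to sum 1."""

    weights: tuple = (0.6, 0.2, 0.2)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        self.weights = tuple(w / w.sum())


def total_objective(components, spec: ObjectiveSpec | None = None) -> float:
    """J = sum_i w_i J_i over per-variable misfit components."""
    spec = spec or ObjectiveSpec()
    comps = np.asarray(components, dtype=float)
    if comps.shape != (len(spec.weights),):
        raise ValueError("component count does not match weights")
    return float(np.dot(spec.weights, comps))


def mend_objective(values, names, base_params: mend.MendParams,
                   forcing: pd.DataFrame, observations: dict,
                   spec: ObjectiveSpec | None = None,
                   initial: mend.MendPools | None = None,
                   penalty: float = 1e6) -> float:
    """Objective for one candidate parameter vector.

    ``observations`` maps ``rh`` to a monthly Rh series and optionally
    ``enz_co`` / ``enz_ch`` to monthly gene-abundance series (arbitrary
    units; compared by correlation of logs).  A failed simulation returns
    ``penalty``.
    """
    spec = spec or ObjectiveSpec()
    try:
        params = mend.build_params(base_params, names, values)
        params.validate()
        out = mend.simulate(params, forcing, initial=initial or mend.MendPools())
    except (ValueError, mend.MendInstabilityError):
        return penalty
    sim_rh = out.monthly_rh()
    obs_rh = observations["rh"]
    sim_rh = sim_rh.to_numpy()[: len(obs_rh)]
    comps = [1.0 - fit_r2(np.asarray(obs_rh, dtype=float), sim_rh)]
    monthly = out.pools.groupby(
        [out.pools.index.year, out.pools.index.month]).mean()
    for key, col in (("enz_co", "ep_o"), ("enz_ch", "ep_h")):
        obs = observations.get(key)
        if obs is None:
            comps.append(0.0)
            continue
        sim = monthly[col].to_numpy()[: len(obs)]
        if (sim <= 0).any() or (np.asarray(obs, dtype=float) <= 0).any():
            return penalty
        try:
            r = fit_r(np.log(np.asarray(obs, dtype=float)), np.log(sim))
        except ValueError:
            return penalty
        comps.append(1.0 - r)
    return total_objective(comps, spec)


@dataclass
class SceResult:
    """Best point plus the full evaluation trace (for COFI)."""

    best_params: np.ndarray
    best_objective: float
    trace_params: np.ndarray    # (n_eval, p)
    trace_objective: np.ndarray  # (n_eval,)
    n_evaluations: int
    converged: bool


def sce_optimize(objective, bounds, n_complexes: int | None = None,
                 budget: int = 5000, seed: int = 0,
                 tol: float = 1e-8, max_loops: int = 200) -> SceResult:
    """Shuffled Complex Evolution (SCE-UA) global minimization.

    The population (``n_complexes`` x (2p+1) points sampled uniformly in
    ``bounds``) is partitioned into complexes; each complex evolves by
    p+1 competitive simplex (reflection/contraction/random-replacement)
    steps per shuffling loop.  Defaults: 2*ceil(sqrt(p)) complexes.
    Deterministic for a given seed.  Convergence is certified when the
    population objective spread falls below ``tol``.
    """
    bounds = np.asarray(bounds, dtype=float)
    p = bounds.shape[0]
    if bounds.shape != (p, 2) or not np.isfinite(bounds).all():
        raise ValueError("bounds must be a finite (p, 2) array")
    if (bounds[:, 0] >= bounds[:, 1]).any():
        raise ValueError("each lower bound must be below its upper bound")
    if n_complexes is None:
        n_complexes = 2 * math.ceil(math.sqrt(p))
    m = 2 * p + 1                 # points per complex
    q = p + 1                     # simplex size
    n_steps = p + 1               # evolution steps per complex per loop
    pop_size = n_complexes * m
    if budget < pop_size:
        raise ValueError(f"budget {budget} below population size {pop_size}")

    rng = np.random.default_rng(seed)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo

    trace_x: list = []
    trace_j: list = []

    def evaluate(x: np.ndarray) -> float:
        j = float(objective(x))
        trace_x.append(x.copy())
        trace_j.append(j)
        return j

    pop = lo + rng.random((pop_size, p)) * span
    obj = np.array([evaluate(x) for x in pop])

    # selection weights within a complex: triangular, best most likely
    sel_w = 2.0 * (m - np.arange(m)) / (m * (m + 1))
    converged = False

    for _ in range(max_loops):
        order = np.argsort(obj, kind="stable")
        pop, obj = pop[order], obj[order]
        if obj[-1] - obj[0] < tol:
            converged = True
            break
        if len(trace_j) >= budget:
            break
        for c in range(n_complexes):
            idx = np.arange(c, pop_size, n_complexes)  # systematic assignment
            cx, cj = pop[idx], obj[idx]
            for _step in range(n_steps):
                if len(trace_j) >= budget:
                    break
                csort = np.argsort(cj, kind="stable")
                cx, cj = cx[csort], cj[csort]
                chosen = rng.choice(m, size=q, replace=False, p=sel_w)
                chosen.sort()
                worst = chosen[-1]
                centroid = cx[chosen[:-1]].mean(axis=0)
                cand = 2.0 * centroid - cx[worst]          # reflection
                if ((cand < lo) | (cand > hi)).any():
                    cand = lo + rng.random(p) * span       # mutation when outside
                jc = evaluate(cand)
                if jc >= cj[worst]:
                    cand = 0.5 * (centroid + cx[worst])    # contraction
                    jc = evaluate(cand)
                    if jc >= cj[worst]:
                        cand = lo + rng.random(p) * span   # random replacement
                        jc = evaluate(cand)
                cx[worst], cj[worst] = cand, jc
            pop[idx], obj[idx] = cx, cj
        if len(trace_j) >= budget:
            break

    order = np.argsort(obj, kind="stable")
    pop, obj = pop[order], obj[order]
    tj = np.asarray(trace_j)
    tx = np.asarray(trace_x)
    best_i = int(np.argmin(tj))
    return SceResult(best_params=tx[best_i].copy(), best_objective=float(tj[best_i]),
                     trace_params=tx, trace_objective=tj,
                     n_evaluations=len(tj), converged=converged)


@dataclass
class CofiResult:
    """Critical Objective Function Index uncertainty summary."""

    j_opt: float
    j_cr: float
    p: int
    n: int
    alpha_sig: float
    feasible_params: np.ndarray
    feasible_objectives: np.ndarray
    parameter_cv: np.ndarray
    f_quantile: float

    @property
    def n_feasible(self) -> int:
        return len(self.feasible_objectives)


def cofi(trace_params, trace_objective, p: int, n: int,
         alpha_sig: float = 0.05, penalty_threshold: float = 1e5) -> CofiResult:
    """COFI feasible-region computation from an optimization trace.

    J_cr = J_opt * (1 + p/(n-p) * F_{alpha,p,n-p}) with the upper-alpha
    F quantile; the feasible set collects every evaluated parameter
    vector with J <= J_cr (penalty evaluations above
    ``penalty_threshold`` are excluded).  Per-parameter coefficients of
    variation are computed over the feasible set.
    """
    if not n > p >= 1:
        raise ValueError("need n > p >= 1")
    tj = np.asarray(trace_objective, dtype=float)
    tx = np.asarray(trace_params, dtype=float)
    if len(tj) == 0:
        raise ValueError("empty trace")
    ok = tj < penalty_threshold
    tj, tx = tj[ok], tx[ok]
    j_opt = float(tj.min())
    fq = float(stats.f.ppf(1.0 - alpha_sig, p, n - p))
    j_cr = j_opt * (1.0 + p / (n - p) * fq)
    feas = tj <= j_cr
    fx, fj = tx[feas], tj[feas]
    mean = fx.mean(axis=0)
    sd = fx.std(axis=0, ddof=1) if len(fx) > 1 else np.zeros(tx.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.nan)
    return CofiResult(j_opt=j_opt, j_cr=float(j_cr), p=p, n=n, alpha_sig=alpha_sig,
                      feasible_params=fx, feasible_objectives=fj,
                      parameter_cv=cv, f_quantile=fq)


@dataclass
class MendCalibration:
    """Bundle returned by :func:`calibrate_mend`."""

    names: list
    sce: SceResult
    params: mend.MendParams
    cofi: CofiResult
    objective_spec: ObjectiveSpec = field(default_factory=ObjectiveSpec)


def calibrate_mend(forcing: pd.DataFrame, observations: dict,
                   names: list | None = None,
                   base_params: mend.MendParams | None = None,
                   bounds=None, budget: int = 5000, seed: int = 0,
                   spec: ObjectiveSpec | None = None,
                   initial: mend.MendPools | None = None,
                   n_obs: int | None = None) -> MendCalibration:
    """SCE calibration of a named MEND parameter subset with COFI uncertainty.

    ``n_obs`` (observation count for COFI) defaults to the number of Rh
    observations plus any enzyme observations.
    """
    names = names or ["v_g", "k_d", "yg_ref", "k_yg"]
    base_params = base_params or mend.MendParams()
    spec = spec or ObjectiveSpec()
    if bounds is None:
        bounds = mend.param_bounds(names)

    def objective(x):
        return mend_objective(x, names, base_params, forcing, observations,
                              spec=spec, initial=initial)

    sce = sce_optimize(objective, bounds, budget=budget, seed=seed)
    if n_obs is None:
        n_obs = sum(len(v) for v in observations.values() if v is not None)
    unc = cofi(sce.trace_params, sce.trace_objective, p=len(names), n=n_obs)
    params = mend.build_params(base_params, names, sce.best_params)
    return MendCalibration(names=list(names), sce=sce, params=params,
                           cofi=unc, objective_spec=spec)
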