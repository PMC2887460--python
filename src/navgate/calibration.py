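"""Calibration of the 18 channel parameters against behavioral targets.

The gating cube is constrained by a small set of published-style
behavioral observables rather than raw current traces: recovery time
constants, inactivated-state fractions after defined conditioning steps,
and the stability of the availability midpoint under pre-pulse
prolongation.  All observables are computed by running the actual
protocol engine and fitting with the metrics module, so a parameter set
that passes calibration passes the same machinery the simulations use.

Targets (drug-free channel):

* biexponential recovery at -150 mV after 5 s at -20 mV with
  tau_fast = 2.21 ms and tau_slow = 58.25 ms;
* about 45% fast- and 55% slow-inactivated channels at the end of that
  5 s conditioning step;
* >= 95% recovery from fast inactivation within a 10 ms step to -150 mV;
* slow-inactivated fraction ~5% after a 0.1 s pre-pulse and ~40% after a
  2 s pre-pulse at the depolarized end of the availability protocol;
* a V1/2 shift below 4 mV of the availability curve when the pre-pulse is
  extended from 0.1 s to 2 s;
* the equilibrium midpoint of fast inactivation more negative than that
  of slow inactivation.

Printed "~" targets carry generous tolerances (20% relative on time
constants and fractions, 2 percentage points on the smallest fraction);
the inequality targets are hard hinges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import engine, metrics
from .model import GateSpec
from .protocols import standard_protocol, run_sweep
from .tetracube import build_free_model, state_name, gate_is_open

__all__ = ["Constraint", "default_constraints", "compute_observables",
           "constraint_report", "objective", "calibrate", "CalibrationResult",
           "PARAM_ORDER"]

PARAM_ORDER = tuple(
    f"{field_}_{gate}_{direction}"
    for gate in ("act", "fast", "slow")
    for direction in ("open", "close")
    for field_ in ("A", "Vhalf", "r"))

_LOG_SCALED = tuple(p for p in PARAM_ORDER if p.startswith(("A_", "r_")))


@dataclass(frozen=True)
class Constraint:
    """One behavioral target.

    ``kind``: ``eq_rel`` (two-sided, relative tolerance), ``eq_abs``
    (two-sided, absolute tolerance), ``ge``/``le`` (one-sided hinges).
    The residual is zero inside the tolerance band and grows linearly
    outside it, in units of the tolerance, so the total objective is zero
    iff every constraint is satisfied.
    """

    name: str
    observable: str
    target: float
    tol: float
    kind: str = "eq_rel"
    weight: float = 1.0

    def residual(self, value: float) -> float:
        if not math.isfinite(value):
            return 100.0
        if self.kind == "eq_rel":
            band = self.tol * abs(self.target)
            return max(0.0, abs(value - self.target) - band) / band
        if self.kind == "eq_abs":
            return max(0.0, abs(value - self.target) - self.tol) / self.tol
        if self.kind == "ge":
            return max(0.0, self.target - value) / self.tol
        if self.kind == "le":
            return max(0.0, value - self.target) / self.tol
        raise ValueError(f"unknown constraint kind {self.kind!r}")

    def passes(self, value: float) -> bool:
        return self.residual(value) == 0.0


def default_constraints() -> list[Constraint]:
    """The eight behavioral targets for the drug-free gating cube."""
    return [
        Constraint("recovery_tau_fast_ms", "rec_tau_fast_ms", 2.21, 0.20),
        Constraint("recovery_tau_slow_ms", "rec_tau_slow_ms", 58.25, 0.20),
        Constraint("fast_slow_split_after_5s", "split_deviation_pct", 10.0,
                   10.0, kind="le"),
        Constraint("gap_recovery_pct", "gap_recovery_pct", 95.0, 1.0,
                   kind="ge"),
        Constraint("slow_fraction_100ms_pct", "slow_frac_100ms_pct", 5.0, 2.0,
                   kind="eq_abs"),
        Constraint("slow_fraction_2s_pct", "slow_frac_2s_pct", 40.0, 0.20),
        Constraint("finact_vhalf_shift_mV", "dv_finact_mV", 4.0, 1.0,
                   kind="le"),
        Constraint("fast_vhalf_below_slow", "v12_slow_minus_fast_mV", 0.0,
                   1.0, kind="ge"),
    ]


def _marginal(p: np.ndarray, states, predicate) -> float:
    return float(sum(p[i] for i, s in enumerate(states) if predicate(s)))


def compute_observables(gates: dict[str, GateSpec]) -> dict[str, float]:
    """All calibration observables for one parameter set, via the protocol
    engine and the curve-fitting metrics."""
    model = build_free_model(gates)
    obs: dict[str, float] = {}

    def Q(v):
        return engine.assemble_rate_matrix(model, None, v)

    p_hold = engine.equilibrium(Q(-150.0))

    # --- recovery time constants: drug-free Rec_t + biexponential fit
    rec = run_sweep(model, None, standard_protocol("Rec_t"))
    fit = metrics.fit_biexponential(rec)
    obs["rec_tau_fast_ms"] = fit.tau_fast * 1e3
    obs["rec_tau_slow_ms"] = fit.tau_slow * 1e3

    # --- state split at the end of the 5 s / -20 mV conditioning step
    p5 = engine.propagate(Q(-20.0), p_hold, 5.0)
    slow = _marginal(p5, model.states,
                     lambda s: not gate_is_open(s, "slow_inactivation"))
    fast = _marginal(p5, model.states,
                     lambda s: (not gate_is_open(s, "fast_inactivation"))
                     and gate_is_open(s, "slow_inactivation"))
    obs["fast_frac_5s_pct"] = fast * 100.0
    obs["slow_frac_5s_pct"] = slow * 100.0
    obs["split_deviation_pct"] = max(abs(fast * 100.0 - 45.0),
                                     abs(slow * 100.0 - 55.0))

    # --- fast-inactivation recovery within the 10 ms / -150 mV gap
    p_cond = engine.propagate(Q(-20.0), p_hold, 0.1)
    m0 = _marginal(p_cond, model.states,
                   lambda s: not gate_is_open(s, "fast_inactivation"))
    p_gap = engine.propagate(Q(-150.0), p_cond, 0.010)
    m1 = _marginal(p_gap, model.states,
                   lambda s: not gate_is_open(s, "fast_inactivation"))
    obs["gap_recovery_pct"] = (m0 - m1) / m0 * 100.0

    # --- slow-inactivated fraction at the depolarized end of FInact_V
    for label, dur in (("100ms", 0.1), ("2s", 2.0)):
        p_end = engine.propagate(Q(-30.0), p_hold, dur)
        obs[f"slow_frac_{label}_pct"] = _marginal(
            p_end, model.states,
            lambda s: not gate_is_open(s, "slow_inactivation")) * 100.0

    # --- availability midpoint shift with pre-pulse prolongation
    fits = []
    for dur in (0.1, 2.0):
        sweep = run_sweep(model, None,
                          standard_protocol("FInact_V", prepulse_duration=dur))
        fits.append(metrics.fit_boltzmann(sweep))
    if fits[0].defined and fits[1].defined:
        obs["dv_finact_mV"] = abs(fits[0].Vhalf - fits[1].Vhalf)
    else:
        obs["dv_finact_mV"] = float("nan")

    # --- equilibrium midpoints of the two inactivation gates
    gf, gs = gates["fast_inactivation"], gates["slow_inactivation"]
    v_fast = metrics.equilibrium_vhalf(gf.opening, gf.closing)
    v_slow = metrics.equilibrium_vhalf(gs.opening, gs.closing)
    obs["v12_fast_mV"] = v_fast
    obs["v12_slow_mV"] = v_slow
    obs["v12_slow_minus_fast_mV"] = v_slow - v_fast
    return obs


def constraint_report(constraints: list[Constraint],
                      obs: dict[str, float]) -> dict[str, dict]:
    return {c.name: {"value": obs[c.observable], "target": c.target,
                     "residual": c.residual(obs[c.observable]),
                     "passes": c.passes(obs[c.observable])}
            for c in constraints}


def objective(constraints: list[Constraint], obs: dict[str, float]) -> float:
    """Weighted sum of squared hinge residuals; zero iff all pass."""
    return float(sum(c.weight * c.residual(obs[c.observable]) ** 2
                     for c in constraints))


# ---------------------------------------------------------------------------
# parameter vector mapping and the optimizer


def params_to_vector(params: dict[str, float]) -> np.ndarray:
    """18-vector in optimizer coordinates (log for A and r, linear Vhalf)."""
    return np.array([np.log(params[k]) if k in _LOG_SCALED else params[k]
                     for k in PARAM_ORDER])


def vector_to_params(x: np.ndarray) -> dict[str, float]:
    return {k: float(np.exp(v)) if k in _LOG_SCALED else float(v)
            for k, v in zip(PARAM_ORDER, x)}


def default_bounds(params: dict[str, float],
                   v_width: float = 30.0, factor: float = 30.0) -> dict:
    """Search box bracketing a reference set: +/- 30 mV on midpoints,
    x/÷ 30 on limiting rates and slope factors."""
    bounds = {}
    for k, v in params.items():
        if k in _LOG_SCALED:
            bounds[k] = (v / factor, v * factor)
        else:
            bounds[k] = (v - v_width, v + v_width)
    return bounds


@dataclass
class CalibrationResult:
    gates: dict[str, GateSpec]
    params: dict[str, float]
    objective: float
    report: dict[str, dict]
    feasible: bool
    n_evaluations: int = 0


def calibrate(
    constraints: list[Constraint] | None = None,
    x0: dict[str, float] | None = None,
    bounds: dict | None = None,
    seed: int = 0,
    max_evaluations: int = 400,
    n_starts: int = 3,
    free_params: list[str] | None = None,
) -> CalibrationResult:
    """Find an 18-parameter set satisfying the behavioral constraints.

    The objective is a weighted least-squares hinge over constraint
    deviations, evaluated through the full protocol pipeline.  A seed set
    that already satisfies every constraint is returned unchanged (the
    objective is exactly zero there).  Otherwise a deterministic
    multi-start Nelder-Mead search runs in transformed coordinates
    (log for rates and slopes, linear for midpoints) inside the bounds
    box; if no start reaches feasibility within the evaluation budget the
    best set found is returned flagged infeasible.  ``free_params``
    restricts the search to a subset of the 18 parameters, holding the
    rest at their ``x0`` values (useful when part of the gating scheme is
    known).
    """
    from .io import default_channel_params, gates_to_dict, gates_from_dict

    constraints = constraints if constraints is not None else default_constraints()
    if x0 is None:
        x0 = gates_to_dict(default_channel_params())
    bounds = bounds if bounds is not None else default_bounds(x0)

    n_eval = 0

    def evaluate(params: dict[str, float]) -> tuple[float, dict]:
        nonlocal n_eval
        n_eval += 1
        try:
            obs = compute_observables(gates_from_dict(params))
        except Exception:
            return 1e6, {}
        return objective(constraints, obs), obs

    f0, obs0 = evaluate(x0)
    if f0 == 0.0:
        return CalibrationResult(
            gates=gates_from_dict(x0), params=dict(x0), objective=0.0,
            report=constraint_report(constraints, obs0), feasible=True,
            n_evaluations=n_eval)

    free = list(free_params) if free_params is not None else list(PARAM_ORDER)
    unknown = set(free) - set(PARAM_ORDER)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    free_idx = [PARAM_ORDER.index(k) for k in free]

    lo_full = params_to_vector({k: bounds[k][0] for k in PARAM_ORDER})
    hi_full = params_to_vector({k: bounds[k][1] for k in PARAM_ORDER})
    x_full = params_to_vector(x0)
    lo, hi = lo_full[free_idx], hi_full[free_idx]

    def expand(x: np.ndarray) -> np.ndarray:
        full = x_full.copy()
        full[free_idx] = x
        return full

    def penalized(x: np.ndarray) -> float:
        xc = np.clip(x, lo, hi)
        f, _ = evaluate(vector_to_params(expand(xc)))
        return f + 10.0 * float(np.abs(x - xc).sum())

    rng = np.random.default_rng(seed)
    best_x, best_f = x_full[free_idx].copy(), f0
    budget = max(max_evaluations // max(n_starts, 1), 20)
    for start in range(n_starts):
        if start == 0:
            xs = x_full[free_idx].copy()
        else:
            jitter = rng.normal(scale=0.05, size=len(free))
            xs = np.clip(best_x + jitter * (hi - lo) / 4.0, lo, hi)
        res = minimize(penalized, xs, method="Nelder-Mead",
                       options={"maxfev": budget, "xatol": 1e-4,
                                "fatol": 1e-10})
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
        if best_f == 0.0:
            break

    params = vector_to_params(expand(np.clip(best_x, lo, hi)))
    f_best, obs_best = evaluate(params)
    report = constraint_report(constraints, obs_best) if obs_best else {}
    return CalibrationResult(
        gates=gates_from_dict(params), params=params, objective=f_best,
        report=report, feasible=(f_best == 0.0), n_evaluations=n_eval)
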