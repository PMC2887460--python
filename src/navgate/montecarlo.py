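"""Monte Carlo robustness study: random channel parameters, fixed drugs.

All 18 gating parameters are drawn independently and uniformly between
per-parameter bounds — on a linear scale for midpoint voltages and on a
logarithmic scale for limiting rates and slope factors — and the four
prototypical drugs are re-tested on every random channel.  Randomly
combined rate laws frequently produce channels with unphysiological
gating even when each parameter is individually reasonable, so records
carry validity flags instead of being silently dropped.

Randomness uses the counter-based Philox generator keyed per record from
the single study seed, so any record can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine, metrics
from .io import prototype_drugs
from .model import DrugSpec, GateSpec
from .protocols import run_control_and_drug, run_sweep, standard_protocol
from .tetracube import build_free_model, gate_is_open

__all__ = ["ParameterConstraints", "MCRecord", "default_parameter_constraints",
           "random_params", "random_model", "run_mc_study", "MCSummary"]


@dataclass(frozen=True)
class ParameterConstraints:
    """Per-parameter (low, high) bounds plus the sampling scale."""

    bounds: dict[str, tuple[float, float]]
    scales: dict[str, str]  # "linear" or "log"

    def __post_init__(self) -> None:
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {k} must satisfy low < high")
            if self.scales[k] == "log" and lo <= 0:
                raise ValueError(f"log-scaled parameter {k} needs positive bounds")


def default_parameter_constraints(
    reference: dict[str, float] | None = None,
    v_width: float = 30.0,
    factor: float = 30.0,
) -> ParameterConstraints:
    """Bounds bracketing the calibrated set: midpoints +/- 30 mV (linear
    sampling), limiting rates and slope factors x/÷ 30 (log sampling).

    This bracket is a reconstruction — wide enough to produce a majority
    of ill-behaved gating combinations, which is the point of the study —
    and is adjustable for sensitivity analyses.
    """
    if reference is None:
        from .io import default_channel_params, gates_to_dict
        reference = gates_to_dict(default_channel_params())
    bounds, scales = {}, {}
    for k, v in reference.items():
        if k.startswith("Vhalf"):
            bounds[k] = (v - v_width, v + v_width)
            scales[k] = "linear"
        else:
            bounds[k] = (v / factor, v * factor)
            scales[k] = "log"
    return ParameterConstraints(bounds=bounds, scales=scales)


def _record_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=(int(seed) << 32) + index))


def random_params(constraints: ParameterConstraints,
                  rng: np.random.Generator) -> dict[str, float]:
    """Uniform draws in [0, 1] mapped linearly or logarithmically onto the
    per-parameter bounds (iteration order is fixed by the bounds dict)."""
    out = {}
    for k, (lo, hi) in constraints.bounds.items():
        u = rng.uniform()
        if constraints.scales[k] == "log":
            out[k] = float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        else:
            out[k] = float(lo + u * (hi - lo))
    return out


def random_model(constraints: ParameterConstraints, seed: int,
                 index: int = 0) -> dict[str, float]:
    """Reproducible parameter draw for one record of a study."""
    return random_params(constraints, _record_rng(seed, index))


@dataclass
class MCRecord:
    index: int
    params: dict[str, float]
    gating_ok: bool = False
    slow_inactivation_ok: bool = False
    failed: bool = False
    dv12_slow_minus_fast: float = float("nan")
    sinact_v_shift_fi_sb: float = float("nan")
    nsod_sinact_t: dict[str, float] = field(default_factory=dict)
    nsod_rec_t: dict[str, float] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return self.gating_ok and not self.failed


@dataclass
class MCSummary:
    n_sets: int
    n_valid: int
    n_no_slow_inactivation: int
    most_effective_onset: dict[str, int]
    most_effective_recovery: dict[str, int]
    fraction_fi_best_onset: float
    fraction_fi_sb_best_recovery: float
    n_sinact_v_shift_gt_5mV: int
    n_sinact_v_determined: int


def _gate_from(params: dict, gates: dict[str, GateSpec], name: str) -> GateSpec:
    return gates[name]


def _availability(gates: dict[str, GateSpec], voltage: float) -> float:
    """Equilibrium availability (product of the two inactivation-gate
    open probabilities; the activation gate recovers on the test pulse)."""
    return (gates["fast_inactivation"].open_probability(voltage)
            * gates["slow_inactivation"].open_probability(voltage))


def _slow_fraction_10s(gates: dict[str, GateSpec], voltage: float = -20.0,
                       holding: float = -150.0) -> float:
    """Slow-inactivated fraction after 10 s conditioning (two-state gate
    relaxation from the holding equilibrium; gates are independent)."""
    g = gates["slow_inactivation"]
    s_inf = 1.0 - g.open_probability(voltage)
    s0 = 1.0 - g.open_probability(holding)
    tau = g.time_constant(voltage)
    return s_inf - (s_inf - s0) * float(np.exp(-10.0 / tau))


def evaluate_record(index: int, params: dict, drugs: dict[str, DrugSpec],
                    per_decade: int = 6) -> MCRecord:
    """All protocol statistics for one random parameter set.

    Individual failures (stiff systems, undefined fits) are recorded in
    the flags; they never abort the batch.
    """
    from .io import gates_from_dict

    rec = MCRecord(index=index, params=params)
    try:
        gates = gates_from_dict(params)
        rec.gating_ok = _availability(gates, -120.0) >= 0.5
        rec.slow_inactivation_ok = _slow_fraction_10s(gates) >= 0.05
        gf, gs = gates["fast_inactivation"], gates["slow_inactivation"]
        try:
            rec.dv12_slow_minus_fast = (
                metrics.equilibrium_vhalf(gs.opening, gs.closing)
                - metrics.equilibrium_vhalf(gf.opening, gf.closing))
        except ValueError:
            pass  # no midpoint crossing in range: abnormal voltage dependence
        if not rec.gating_ok:
            return rec

        model = build_free_model(gates)

        if rec.slow_inactivation_ok:
            proto_sv = standard_protocol("SInact_V")
            control, drugged = run_control_and_drug(model, drugs["FI_sb"], proto_sv)
            fit_c = metrics.fit_boltzmann(control)
            fit_d = metrics.fit_boltzmann(
                (drugged.x, drugged.current / max(drugged.current.max(), 1e-12)))
            if fit_c.defined and fit_d.defined:
                rec.sinact_v_shift_fi_sb = fit_c.Vhalf - fit_d.Vhalf  # leftward > 0

        proto_on = standard_protocol("SInact_t", per_decade=per_decade)
        proto_rec = standard_protocol("Rec_t", per_decade=per_decade)
        c_on = run_sweep(model, None, proto_on)
        c_rec = run_sweep(model, None, proto_rec)
        for name, drug in drugs.items():
            _, d_on = run_control_and_drug(model, drug, proto_on, control=c_on)
            _, d_rec = run_control_and_drug(model, drug, proto_rec, control=c_rec)
            rec.nsod_sinact_t[name] = metrics.nsod(c_on, d_on)
            rec.nsod_rec_t[name] = metrics.nsod(c_rec, d_rec)
    except (engine.StabilityError, np.linalg.LinAlgError, ValueError,
            RuntimeError):
        rec.failed = True
    return rec


def summarize(records: list[MCRecord]) -> MCSummary:
    valid = [r for r in records if r.valid and r.nsod_sinact_t]
    on_counts: dict[str, int] = {}
    rec_counts: dict[str, int] = {}
    for r in valid:
        on_counts[max(r.nsod_sinact_t, key=r.nsod_sinact_t.get)] = \
            on_counts.get(max(r.nsod_sinact_t, key=r.nsod_sinact_t.get), 0) + 1
        rec_counts[max(r.nsod_rec_t, key=r.nsod_rec_t.get)] = \
            rec_counts.get(max(r.nsod_rec_t, key=r.nsod_rec_t.get), 0) + 1
    n_valid = len(valid)
    fi_on = sum(v for k, v in on_counts.items() if k.startswith("FI"))
    shifts = [r.sinact_v_shift_fi_sb for r in valid
              if np.isfinite(r.sinact_v_shift_fi_sb)]
    return MCSummary(
        n_sets=len(records),
        n_valid=n_valid,
        n_no_slow_inactivation=sum(1 for r in records if r.valid
                                   and not r.slow_inactivation_ok),
        most_effective_onset=on_counts,
        most_effective_recovery=rec_counts,
        fraction_fi_best_onset=fi_on / n_valid if n_valid else float("nan"),
        fraction_fi_sb_best_recovery=(
            rec_counts.get("FI_sb", 0) / n_valid if n_valid else float("nan")),
        n_sinact_v_shift_gt_5mV=sum(1 for s in shifts if s > 5.0),
        n_sinact_v_determined=len(shifts),
    )


def run_mc_study(
    n_sets: int,
    seed: int,
    drugs: dict[str, DrugSpec] | None = None,
    constraints: ParameterConstraints | None = None,
    per_decade: int = 6,
) -> tuple[list[MCRecord], MCSummary]:
    """Random-parameter study: ``n_sets`` channels x four drugs.

    Deterministic for a given (seed, constraints): record ``i`` uses the
    Philox stream keyed by ``(seed, i)`` regardless of batch size.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    drugs = drugs or prototype_drugs()
    constraints = constraints or default_parameter_constraints()
    records = [
        evaluate_record(i, random_model(constraints, seed, i), drugs,
                        per_decade=per_decade)
        for i in range(n_sets)
    ]
    return records, summarize(records)
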