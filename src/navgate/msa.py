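"""Multi-step-activation (MSA) Markov model with fast and slow
inactivation tiers, used to test whether conclusions drawn with the
phenomenological gating cube survive a change of model architecture.

Activation proceeds through five voltage-sensor states C0..C4 (0-4
sensors in the depolarized position) and a final concerted opening step
C4 <-> O.  The four sensors are identical and independent, so sensor
edges carry binomial multiplicities (4,3,2,1 forward; 1,2,3,4 backward).
Fast and slow inactivation are voltage-independent in themselves; they
borrow voltage dependence allosterically from sensor position: after n
sensor steps the inactivation on-rate is multiplied by ``a**n`` and the
off-rate divided by ``a**n`` (one coupling constant per tier), and inside
an inactivated tier sensors move more easily by the same factor per step.
That single-parameter-per-tier scheme couples inactivation equally to all
four sensors and preserves detailed balance on every loop by
construction.

Drug-free: 24 states.  Drug extension doubles them to 48 (224 directed
transitions) with the same modulated-receptor algebra as the tetracube:
CF acts on the fast tier, CS on the slow tier.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (ChannelModel, DrugSpec, ParameterError, RateLaw,
                    Transition)
from .tetracube import BOUND_SUFFIX, _BindingRate

__all__ = ["MSAParams", "build_msa_model", "msa_state_name",
           "verify_architecture_independence"]


@dataclass(frozen=True)
class MSAParams:
    """Parameters of the MSA model.

    Sensor movement uses the three-parameter saturating rate law; the
    concerted opening step and both inactivation tiers are voltage-
    independent.  ``a_fast``/``a_slow`` are the allosteric coupling
    factors per sensor step (> 1: inactivation is favored as sensors
    activate).
    """

    sensor_fwd: RateLaw
    sensor_bwd: RateLaw
    open_rate: float  # C4 -> O, 1/s
    close_rate: float  # O -> C4, 1/s
    kon_fast: float  # fast-inactivation on-rate at 0 sensors up, 1/s
    koff_fast: float
    a_fast: float
    kon_slow: float
    koff_slow: float
    a_slow: float

    def __post_init__(self) -> None:
        for attr in ("open_rate", "close_rate", "kon_fast", "koff_fast",
                     "a_fast", "kon_slow", "koff_slow", "a_slow"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"{attr} must be > 0")


def msa_state_name(pos: str, fi: bool, si: bool, bound: bool = False) -> str:
    """``pos`` is 'C0'..'C4' or 'O'; suffixes mark inactivation/binding."""
    s = pos + ("F" if fi else "") + ("S" if si else "")
    return s + BOUND_SUFFIX if bound else s


class _Const:
    __slots__ = ("value",)

    def __init__(self, value: float):
        self.value = value

    def __call__(self, voltage: float) -> float:
        return self.value


class _SensorRate:
    """Multiplicity-weighted sensor rate, allosterically scaled in
    inactivated tiers."""

    __slots__ = ("law", "mult", "scale")

    def __init__(self, law: RateLaw, mult: int, scale: float):
        self.law = law
        self.mult = mult
        self.scale = scale

    def __call__(self, voltage: float) -> float:
        return self.mult * self.scale * self.law(voltage)


def _positions():
    return ["C0", "C1", "C2", "C3", "C4", "O"]


def _sensors_up(pos: str) -> int:
    return 4 if pos == "O" else int(pos[1])


def build_msa_model(params: MSAParams, drug: DrugSpec | None = None) -> ChannelModel:
    """Build the 24-state MSA model, optionally drug-extended to 48 states.

    With both allosteric factors equal to 1 the inactivation rates are
    identical in every sensor position (degenerate limit).
    """
    states: list[str] = []
    transitions: list[Transition] = []

    for fi in (False, True):
        for si in (False, True):
            for pos in _positions():
                states.append(msa_state_name(pos, fi, si))

    def tier_scale(fi: bool, si: bool) -> float:
        return (params.a_fast if fi else 1.0) * (params.a_slow if si else 1.0)

    for fi in (False, True):
        for si in (False, True):
            ts = tier_scale(fi, si)
            # sensor steps with binomial multiplicities
            for k in range(4):
                frm = msa_state_name(f"C{k}", fi, si)
                to = msa_state_name(f"C{k + 1}", fi, si)
                transitions.append(Transition(
                    frm, to, _SensorRate(params.sensor_fwd, 4 - k, ts)))
                transitions.append(Transition(
                    to, frm, _SensorRate(params.sensor_bwd, k + 1, 1.0 / ts)))
            # concerted opening step (voltage-independent)
            transitions.append(Transition(
                msa_state_name("C4", fi, si), msa_state_name("O", fi, si),
                _Const(params.open_rate)))
            transitions.append(Transition(
                msa_state_name("O", fi, si), msa_state_name("C4", fi, si),
                _Const(params.close_rate)))

    # inactivation steps, allosterically scaled by sensor position
    for pos in _positions():
        n = _sensors_up(pos)
        for si in (False, True):
            transitions.append(Transition(
                msa_state_name(pos, False, si), msa_state_name(pos, True, si),
                _Const(params.kon_fast * params.a_fast ** n)))
            transitions.append(Transition(
                msa_state_name(pos, True, si), msa_state_name(pos, False, si),
                _Const(params.koff_fast / params.a_fast ** n)))
        for fi in (False, True):
            transitions.append(Transition(
                msa_state_name(pos, fi, False), msa_state_name(pos, fi, True),
                _Const(params.kon_slow * params.a_slow ** n)))
            transitions.append(Transition(
                msa_state_name(pos, fi, True), msa_state_name(pos, fi, False),
                _Const(params.koff_slow / params.a_slow ** n)))

    model = ChannelModel(
        name="msa",
        states=tuple(states),
        transitions=tuple(transitions),
        conducting=frozenset({msa_state_name("O", False, False)}),
        extender=_extend_msa_with_drug,
        meta={"params": params},
    )
    return model.with_drug(drug) if drug is not None else model


def _state_tag(state: str) -> str:
    """Inactivation suffix of an MSA state name ('', 'F', 'S' or 'FS')."""
    s = state.removesuffix(BOUND_SUFFIX)
    return s[2:] if s[0] == "C" else s[1:]


def _inactivation_factor(drug: DrugSpec, state: str) -> float:
    tag = _state_tag(state)
    return (drug.CF if "F" in tag else 1.0) * (drug.CS if "S" in tag else 1.0)


class _ScaledRate:
    __slots__ = ("inner", "factor")

    def __init__(self, inner, factor: float):
        self.inner = inner
        self.factor = factor

    def __call__(self, voltage: float) -> float:
        return self.factor * self.inner(voltage)


def _extend_msa_with_drug(model: ChannelModel, drug: DrugSpec) -> ChannelModel:
    """Add a bound copy of every MSA state (modulated-receptor algebra).

    CF slows recovery from fast inactivation of bound channels (and
    raises the affinity for fast-inactivated configurations); CS does the
    same for the slow tier.  Sensor and opening rates are unchanged in the bound
    layer, so every added face of the graph satisfies the cycle condition.
    Activation-state preference is out of scope here: CA must be 1.
    """
    if drug.CA != 1.0:
        raise ParameterError("MSA drug extension supports CA = 1 only")

    free_states = model.states
    bound_states = tuple(s + BOUND_SUFFIX for s in free_states)
    transitions = list(model.transitions)

    for t in model.transitions:
        frm_tag = _state_tag(t.frm)
        to_tag = _state_tag(t.to)
        factor = 1.0
        if "F" in frm_tag and "F" not in to_tag:
            factor = 1.0 / drug.CF
        elif "S" in frm_tag and "S" not in to_tag:
            factor = 1.0 / drug.CS
        rate = _ScaledRate(t.rate, factor) if factor != 1.0 else t.rate
        transitions.append(Transition(t.frm + BOUND_SUFFIX, t.to + BOUND_SUFFIX, rate))

    for s in free_states:
        transitions.append(Transition(
            s, s + BOUND_SUFFIX,
            _BindingRate(drug.ka, drug.concentration, _inactivation_factor(drug, s))))
        transitions.append(Transition(s + BOUND_SUFFIX, s, _BindingRate(drug.kd)))

    return ChannelModel(
        name=f"{model.name}+{drug.name}",
        states=free_states + bound_states,
        transitions=tuple(transitions),
        conducting=model.conducting,
        extender=None,
        meta={"params": model.meta["params"], "drug": drug},
    )


def protocol_report(model: ChannelModel, drugs: dict | None = None,
                    per_decade: int = 5) -> dict:
    """Protocol statistics needed for the architecture comparison:
    FI_sb's midpoint shift of the 10-s "slow inactivation" curve plus the
    nSOD of every prototypical drug in the onset and recovery protocols.
    Works for any channel model (gating cube or MSA)."""
    from . import metrics
    from .io import prototype_drugs
    from .protocols import run_control_and_drug, run_sweep, standard_protocol

    drugs = drugs or prototype_drugs()
    proto_sv = standard_protocol("SInact_V")
    control = run_sweep(model, None, proto_sv)
    _, drugged = run_control_and_drug(model, drugs["FI_sb"], proto_sv,
                                      control=control)
    fit_c = metrics.fit_boltzmann(control)
    fit_d = metrics.fit_boltzmann(
        (drugged.x, drugged.current / max(drugged.current.max(), 1e-12)))
    shift = (fit_c.Vhalf - fit_d.Vhalf
             if fit_c.defined and fit_d.defined else float("nan"))
    report = {"sinact_v_shift_fi_sb": shift,
              "nsod_sinact_t": {}, "nsod_rec_t": {}}
    for pname, key in (("SInact_t", "nsod_sinact_t"), ("Rec_t", "nsod_rec_t")):
        proto = standard_protocol(pname, per_decade=per_decade)
        c = run_sweep(model, None, proto)
        for name, drug in drugs.items():
            _, d = run_control_and_drug(model, drug, proto, control=c)
            report[key][name] = metrics.nsod(c, d)
    return report


def verify_architecture_independence(tetracube_report: dict,
                                     msa_report: dict) -> dict:
    """Compare the three headline observations across the two architectures.

    Each input is a dict with keys ``sinact_v_shift_fi_sb`` (mV, leftward
    positive), ``nsod_sinact_t`` and ``nsod_rec_t`` (dicts keyed by drug
    name).  Returns per-observation booleans for each model plus an
    overall flag.  The observations:

    1. a fast-inactivated-state-preferring, slowly binding drug shifts the
       10-s "slow inactivation" availability curve (> 5 mV);
    2. the fast-binding fast-inactivated-state drug beats the fast-binding
       slow-inactivated-state drug on the onset (SInact_t) statistic;
    3. the slowly binding fast-inactivated-state drug is at least as
       effective as the slow-state-preferring drugs in delaying recovery.
    """
    def observations(rep: dict) -> dict:
        on = rep["nsod_sinact_t"]
        rec = rep["nsod_rec_t"]
        return {
            "sinact_v_shifted_by_fi_sb": rep["sinact_v_shift_fi_sb"] > 5.0,
            "fi_fb_beats_si_fb_on_onset": on["FI_fb"] > on["SI_fb"],
            "fi_sb_matches_si_on_recovery":
                rec["FI_sb"] >= max(rec["SI_fb"], rec["SI_sb"]) - 0.05,
        }

    tet = observations(tetracube_report)
    msa = observations(msa_report)
    return {
        "tetracube": tet,
        "msa": msa,
        "confirmed_in_both": {k: tet[k] and msa[k] for k in tet},
        "all_confirmed": all(tet.values()) and all(msa.values()),
    }
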