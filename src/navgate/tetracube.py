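"""Eight-state Hodgkin-Huxley-like gating cube and its 16-state drug
extension (the "tetracube", a tesseract).

Three independent two-state gates — activation (A), fast inactivation (F)
and slow inactivation (S) — give 2**3 = 8 gating configurations arranged
on a cube whose edges are single-gate moves.  A state is written e.g.
``AoFcSo``: activation gate open, fast-inactivation gate closed,
slow-inactivation gate open.  The single conducting state is ``AoFoSo``.

Drug binding adds a bound copy of every vertex, turning the cube into a
tesseract: 16 states, 32 undirected edges.  The modulated-receptor algebra
lives in :func:`extend_with_drug`; see its docstring for the exact rate
split that keeps every reaction cycle microscopically reversible.
"""

from __future__ import annotations

from .model import (ChannelModel, DrugSpec, GateSpec, ParameterError, RateLaw,
                    Transition)

__all__ = [
    "GATE_ORDER",
    "rate_law_eval",
    "build_free_model",
    "extend_with_drug",
    "stabilization_shift",
    "state_name",
    "gate_is_open",
    "is_bound",
]

GATE_ORDER = ("activation", "fast_inactivation", "slow_inactivation")
_LETTER = {"activation": "A", "fast_inactivation": "F", "slow_inactivation": "S"}
BOUND_SUFFIX = "*D"


def rate_law_eval(law: RateLaw, voltage: float) -> float:
    """Evaluate a saturating sigmoid rate law at a voltage (1/s)."""
    return law(voltage)


def state_name(config: tuple[bool, bool, bool], bound: bool = False) -> str:
    """Canonical state label from gate-open flags (A, F, S)."""
    s = "".join(_LETTER[g] + ("o" if open_ else "c")
                for g, open_ in zip(GATE_ORDER, config))
    return s + BOUND_SUFFIX if bound else s


def gate_is_open(state: str, gate: str) -> bool:
    i = GATE_ORDER.index(gate)
    return state[2 * i + 1] == "o"


def is_bound(state: str) -> bool:
    return state.endswith(BOUND_SUFFIX)


def _configs():
    for a in (True, False):
        for f in (True, False):
            for s in (True, False):
                yield (a, f, s)


def build_free_model(gates: dict[str, GateSpec] | list[GateSpec]) -> ChannelModel:
    """Drug-free 8-state cube from three independent gates.

    Every edge flips exactly one gate and carries that gate's opening or
    closing rate law, identical in all configurations of the other gates —
    the gates move independently.  Conducting state: all gates open.
    """
    if not isinstance(gates, dict):
        gates = {g.name: g for g in gates}
    missing = set(GATE_ORDER) - set(gates)
    if missing:
        raise ParameterError(f"missing gate specs: {sorted(missing)}")

    states = tuple(state_name(c) for c in _configs())
    transitions: list[Transition] = []
    for config in _configs():
        frm = state_name(config)
        for i, gate in enumerate(GATE_ORDER):
            flipped = list(config)
            flipped[i] = not config[i]
            to = state_name(tuple(flipped))
            law = gates[gate].closing if config[i] else gates[gate].opening
            transitions.append(Transition(frm, to, law))

    return ChannelModel(
        name="tetracube",
        states=states,
        transitions=tuple(transitions),
        conducting=frozenset({state_name((True, True, True))}),
        extender=extend_with_drug,
        meta={"gates": dict(gates)},
    )


class _ScaledLaw:
    """Rate law times a voltage-independent factor (picklable callable)."""

    __slots__ = ("law", "factor")

    def __init__(self, law, factor: float):
        self.law = law
        self.factor = factor

    def __call__(self, voltage: float) -> float:
        return self.factor * self.law(voltage)


class _BindingRate:
    """Concentration-scaled association (or plain dissociation) rate."""

    __slots__ = ("base", "concentration", "factor")

    def __init__(self, base: float, concentration: float = 1.0, factor: float = 1.0):
        self.base = base
        self.concentration = concentration
        self.factor = factor

    def __call__(self, voltage: float) -> float:
        return self.base * self.concentration * self.factor


def closed_gate_factor(drug: DrugSpec, state: str) -> float:
    """Product of stabilizing factors over the gates closed in ``state``."""
    prod = 1.0
    for gate in GATE_ORDER:
        if not gate_is_open(state, gate):
            prod *= drug.factor(gate)
    return prod


def extend_with_drug(model: ChannelModel, drug: DrugSpec) -> ChannelModel:
    """Graft a drug-bound copy onto every vertex of the free cube.

    Rate assignment (one place, so alternative splits are a one-line edit):

    * binding: association into the bound copy of a configuration whose
      closed-gate set is G runs at ``ka * c * prod_{g in G} C_g``;
      dissociation is ``kd`` everywhere.  State preference therefore shows
      up in the association limb, i.e. the binding site of an inactivated
      channel is also more accessible, not only stickier.
    * gating in the bound layer: the rate away from the conformation the
      drug stabilizes (gate opening, i.e. recovery, for ``C_g > 1``) is
      divided by ``C_g``; the rate toward it is unchanged.  State
      stabilization therefore acts by delaying recovery of the drug-bound
      gate, not by accelerating its entry — which is how inactivated-state
      stabilization manifests in voltage-clamp data.  Only the ratio is
      fixed by microscopic reversibility; this assignment is the one place
      to edit for alternative splits.

    With this split the clockwise and counter-clockwise rate products agree
    on every square face of the tesseract at every voltage, so microscopic
    reversibility holds by construction.
    """
    if model.meta.get("drug") is not None:
        raise ParameterError("model already carries a drug extension")
    gates: dict[str, GateSpec] = model.meta["gates"]

    free_states = model.states
    bound_states = tuple(s + BOUND_SUFFIX for s in free_states)
    transitions = list(model.transitions)

    # bound-layer gating: opening (recovery) rates slowed by the gate factor
    for t in model.transitions:
        gate = next(g for g in GATE_ORDER
                    if gate_is_open(t.frm, g) != gate_is_open(t.to, g))
        opening = (not gate_is_open(t.frm, gate)) and gate_is_open(t.to, gate)
        factor = 1.0 / drug.factor(gate) if opening else 1.0
        rate = _ScaledLaw(t.rate, factor) if factor != 1.0 else t.rate
        transitions.append(Transition(t.frm + BOUND_SUFFIX, t.to + BOUND_SUFFIX, rate))

    # binding edges
    for s in free_states:
        g = closed_gate_factor(drug, s)
        transitions.append(Transition(
            s, s + BOUND_SUFFIX,
            _BindingRate(drug.ka, drug.concentration, g)))
        transitions.append(Transition(
            s + BOUND_SUFFIX, s, _BindingRate(drug.kd)))

    return ChannelModel(
        name=f"{model.name}+{drug.name}",
        states=free_states + bound_states,
        transitions=tuple(transitions),
        conducting=model.conducting,  # bound states never conduct
        extender=None,
        meta={"gates": gates, "drug": drug},
    )


def stabilization_shift(drug: DrugSpec, gate: str) -> float:
    """Multiplicative shift of the closed/open equilibrium constant of a
    gate in the drug-bound layer (equal to the gate's C factor)."""
    return drug.factor(gate)
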