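"""Shared domain types for Markov channel models.

A channel model is a labelled directed graph: states are identifiers,
each directed edge carries a voltage-dependent rate function (1/s).
Model builders (:mod:`navgate.tetracube`, :mod:`navgate.msa`) construct
instances; the generic solver (:mod:`navgate.engine`) consumes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

__all__ = [
    "RateLaw",
    "GateSpec",
    "DrugSpec",
    "Transition",
    "ChannelModel",
    "ModelError",
    "ParameterError",
]


class ModelError(ValueError):
    """Structural problem in a channel model graph."""


class ParameterError(ValueError):
    """Invalid parameter value for a model or drug."""


@dataclass(frozen=True)
class RateLaw:
    """Saturating three-parameter voltage dependence of a rate constant.

    ``rate(V) = A / (1 + exp(-s * (V - Vhalf) / r))`` where ``s = +1`` for a
    rate that saturates at its limiting value ``A`` on depolarization
    (``sense="depolarized"``) and ``s = -1`` for one that saturates on
    hyperpolarization.  On a log-rate vs. voltage plot the curve is sigmoid
    with inflection at ``Vhalf`` and maximal slope set by ``r`` (mV per
    e-fold in the exponential limb).

    The two-parameter pure exponential has no limiting value and diverges at
    extreme potentials; the saturating form keeps stiff systems integrable.
    """

    A: float  # limiting rate, 1/s
    Vhalf: float  # inflection voltage, mV
    r: float  # slope factor, mV
    sense: str = "depolarized"  # direction of saturation

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ParameterError(f"limiting rate A must be > 0, got {self.A}")
        if self.r <= 0:
            raise ParameterError(f"slope factor r must be > 0, got {self.r}")
        if self.sense not in ("depolarized", "hyperpolarized"):
            raise ParameterError(f"unknown sense {self.sense!r}")

    def __call__(self, voltage: float) -> float:
        if not math.isfinite(voltage):
            raise ParameterError(f"voltage must be finite, got {voltage}")
        s = 1.0 if self.sense == "depolarized" else -1.0
        x = -s * (voltage - self.Vhalf) / self.r
        # guard overflow in the vanishing limb
        if x > 700.0:
            return self.A * math.exp(-x) if x < 745.0 else 0.0
        return self.A / (1.0 + math.exp(x))


@dataclass(frozen=True)
class GateSpec:
    """One two-state gate: an opening and a closing rate law.

    ``name`` is one of ``activation``, ``fast_inactivation``,
    ``slow_inactivation``.  "Open" always means the permissive conformation
    (available / not inactivated); a channel conducts only when every gate
    is open.
    """

    name: str
    opening: RateLaw
    closing: RateLaw

    GATE_NAMES = ("activation", "fast_inactivation", "slow_inactivation")

    def __post_init__(self) -> None:
        if self.name not in self.GATE_NAMES:
            raise ParameterError(f"unknown gate name {self.name!r}")

    def open_probability(self, voltage: float) -> float:
        """Equilibrium open probability of the isolated gate."""
        a, b = self.opening(voltage), self.closing(voltage)
        return a / (a + b)

    def time_constant(self, voltage: float) -> float:
        """Equilibration time constant of the isolated gate (s)."""
        return 1.0 / (self.opening(voltage) + self.closing(voltage))


@dataclass(frozen=True)
class DrugSpec:
    """State-dependent inhibitor under the modulated-receptor scheme.

    ``ka`` (1/(s*uM)) and ``kd`` (1/s) set association and dissociation to
    the resting channel, so the resting dissociation constant is ``kd/ka``.
    ``CA``, ``CF``, ``CS`` are the gate-stabilizing factors for the
    activation, fast-inactivation and slow-inactivation gates: a factor of 1
    means no preference, a factor > 1 stabilizes the closed (inactivated)
    conformation of that gate in the drug-bound channel and raises the
    binding affinity to configurations with that gate closed by the same
    factor, which is what keeps every reaction cycle microscopically
    reversible.
    """

    name: str
    ka: float
    kd: float
    CA: float = 1.0
    CF: float = 1.0
    CS: float = 1.0
    concentration: float = 0.0  # uM

    def __post_init__(self) -> None:
        for attr in ("ka", "kd", "CA", "CF", "CS"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"{attr} must be > 0, got {getattr(self, attr)}")
        if self.concentration < 0:
            raise ParameterError("concentration must be >= 0")

    @property
    def Kd_resting(self) -> float:
        """Dissociation constant from the resting state (uM)."""
        return self.kd / self.ka

    def factor(self, gate: str) -> float:
        """Stabilizing factor for a gate by name."""
        try:
            return {"activation": self.CA,
                    "fast_inactivation": self.CF,
                    "slow_inactivation": self.CS}[gate]
        except KeyError:
            raise ParameterError(f"unknown gate name {gate!r}") from None

    def at(self, concentration: float) -> "DrugSpec":
        """Copy of this drug at a different concentration."""
        return replace(self, concentration=concentration)


@dataclass(frozen=True)
class Transition:
    """Directed edge ``frm -> to`` with rate ``rate(V)`` in 1/s."""

    frm: str
    to: str
    rate: Callable[[float], float]


@dataclass(frozen=True)
class ChannelModel:
    """State graph with per-transition rate functions.

    ``conducting`` lists the states that carry current.  ``extender``
    is the builder-supplied function that grafts drug-bound states onto
    the free model (used by :func:`navgate.engine.assemble_rate_matrix`
    when a drug is present).
    """

    name: str
    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    conducting: frozenset[str]
    extender: Callable[["ChannelModel", DrugSpec], "ChannelModel"] | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        known = set(self.states)
        if len(known) != len(self.states):
            raise ModelError("duplicate state identifiers")
        for t in self.transitions:
            if t.frm not in known or t.to not in known:
                raise ModelError(
                    f"transition {t.frm!r} -> {t.to!r} references unknown state")
        if not self.conducting <= known:
            raise ModelError("conducting set references unknown state")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def with_drug(self, drug: DrugSpec | None) -> "ChannelModel":
        """Drug-extended model (or self when ``drug`` is None)."""
        if drug is None:
            return self
        if self.extender is None:
            raise ModelError(f"model {self.name!r} has no drug extension rule")
        return self.extender(self, drug)

    def undirected_edges(self) -> set[frozenset]:
        return {frozenset((t.frm, t.to)) for t in self.transitions}
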