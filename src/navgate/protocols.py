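"""Voltage-clamp protocols as data, and a runner that turns a
model/drug/protocol combination into a normalized availability curve.

Five named protocols cover the standard repertoire for separating fast
from slow inactivation:

* ``FInact_V`` — "steady-state fast inactivation": conditioning pre-pulse
  swept from -120 to -30 mV (default 0.1 s, 2 s variant), then test pulse.
* ``SInact_V`` — "steady-state slow inactivation": 10 s pre-pulse, then a
  10 ms hyperpolarizing gap at -150 mV before the test pulse so fast-
  inactivated channels recover.
* ``SInact_t`` — onset of slow inactivation: depolarizing pre-pulse of
  swept duration, same gap, then test pulse.
* ``Rec_t`` — recovery: 5 s at -20 mV, then a hyperpolarizing gap of swept
  duration (1 ms - 10 s).
* ``CR`` — concentration-response: a single test depolarization to 0 mV
  from the holding potential.

The test pulse itself is 0 mV for 10 ms (never part of the sweep); its
readout is the peak occupancy of the conducting state(s), which is
proportional to peak current since driving force and unitary conductance
cancel under normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import engine
from .model import ChannelModel, DrugSpec

__all__ = ["Segment", "Protocol", "SweepResult", "standard_protocol",
           "run_sweep", "concentration_response", "PROTOCOL_NAMES"]

PROTOCOL_NAMES = ("FInact_V", "SInact_V", "SInact_t", "Rec_t", "CR")

TEST_VOLTAGE = 0.0  # mV
TEST_DURATION = 0.010  # s
TEST_DT = 2e-5  # s, sampling step for the peak search
HOLDING_DEFAULT = -150.0  # mV


@dataclass(frozen=True)
class Segment:
    voltage: float  # mV
    duration: float  # s


@dataclass(frozen=True)
class Protocol:
    """Ordered voltage segments with exactly one swept dimension.

    ``swept`` = (segment_index, field, grid): ``field`` is ``"voltage"``
    or ``"duration"`` and the strictly monotone ``grid`` supplies the
    values.  ``test_index`` marks the test pulse, which must come after
    all conditioning segments.
    """

    name: str
    segments: tuple[Segment, ...]
    swept: tuple[int, str, tuple[float, ...]]
    test_index: int
    holding: float = HOLDING_DEFAULT

    def __post_init__(self) -> None:
        seg_i, fld, grid = self.swept
        if fld not in ("voltage", "duration"):
            raise ValueError(f"swept field must be voltage or duration, got {fld!r}")
        if not (0 <= seg_i < len(self.segments)):
            raise ValueError("swept segment index out of range")
        if seg_i >= self.test_index:
            raise ValueError("swept segment must precede the test pulse")
        if self.test_index != len(self.segments) - 1:
            raise ValueError("test pulse must be the final segment")
        diffs = np.diff(grid)
        if len(grid) < 2 or not ((diffs > 0).all() or (diffs < 0).all()):
            raise ValueError("sweep grid must be strictly monotone")

    def realize(self, value: float) -> tuple[Segment, ...]:
        """Concrete segment list for one sweep value."""
        seg_i, fld, _ = self.swept
        segs = list(self.segments)
        segs[seg_i] = replace(segs[seg_i], **{fld: float(value)})
        return tuple(segs)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "holding": self.holding,
            "segments": [[s.voltage, s.duration] for s in self.segments],
            "swept": [self.swept[0], self.swept[1], list(self.swept[2])],
            "test_index": self.test_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            name=d["name"],
            holding=d["holding"],
            segments=tuple(Segment(v, t) for v, t in d["segments"]),
            swept=(d["swept"][0], d["swept"][1], tuple(d["swept"][2])),
            test_index=d["test_index"],
        )


@dataclass(frozen=True)
class SweepResult:
    """Normalized peak-current curve over the swept dimension."""

    x: np.ndarray
    peak: np.ndarray  # raw peak conducting occupancy
    current: np.ndarray  # peak / normalization
    normalization: float
    protocol: str = ""
    condition: str = "control"

    def renormalized(self, reference: float) -> "SweepResult":
        return replace(self, current=self.peak / reference, normalization=reference)


def log_grid(lo: float, hi: float, per_decade: int = 8) -> tuple[float, ...]:
    """Log-even grid, required by the SOD statistic (area on a semilog plot)."""
    n = int(round(np.log10(hi / lo) * per_decade)) + 1
    return tuple(np.logspace(np.log10(lo), np.log10(hi), n))


def voltage_grid(lo: float = -120.0, hi: float = -30.0, step: float = 5.0):
    return tuple(np.arange(lo, hi + 0.5 * step, step))


def standard_protocol(
    name: str,
    *,
    prepulse_duration: float = 0.1,
    prepulse_voltage: float = -20.0,
    gap_duration: float = 0.010,
    gap_voltage: float = -150.0,
    holding: float = HOLDING_DEFAULT,
    per_decade: int = 8,
) -> Protocol:
    """Construct one of the named availability protocols.

    Variant hooks: ``prepulse_duration`` (0.1 vs 2 s for FInact_V),
    ``gap_duration``/``gap_voltage`` (e.g. 5 ms at -120 mV for the
    SInact_t variant, or the swept-gap analysis which rebuilds SInact_t
    at several gap durations).
    """
    if name == "FInact_V":
        return Protocol(
            name=name, holding=holding,
            segments=(Segment(-120.0, prepulse_duration),
                      Segment(TEST_VOLTAGE, TEST_DURATION)),
            swept=(0, "voltage", voltage_grid()),
            test_index=1)
    if name == "SInact_V":
        return Protocol(
            name=name, holding=holding,
            segments=(Segment(-120.0, 10.0),
                      Segment(gap_voltage, gap_duration),
                      Segment(TEST_VOLTAGE, TEST_DURATION)),
            swept=(0, "voltage", voltage_grid()),
            test_index=2)
    if name == "SInact_t":
        return Protocol(
            name=name, holding=holding,
            segments=(Segment(prepulse_voltage, 1.0),
                      Segment(gap_voltage, gap_duration),
                      Segment(TEST_VOLTAGE, TEST_DURATION)),
            swept=(0, "duration", log_grid(1e-3, 30.0, per_decade)),
            test_index=2)
    if name == "Rec_t":
        return Protocol(
            name=name, holding=holding,
            segments=(Segment(-20.0, 5.0),
                      Segment(gap_voltage, 0.1),
                      Segment(TEST_VOLTAGE, TEST_DURATION)),
            swept=(1, "duration", log_grid(1e-3, 10.0, per_decade)),
            test_index=2)
    if name == "CR":
        raise ValueError(
            "CR is a concentration sweep; use concentration_response()")
    raise ValueError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")


class _QCache:
    """Per-(model, drug) cache of rate matrices and segment propagators."""

    def __init__(self, model: ChannelModel, drug: DrugSpec | None):
        self.model = model.with_drug(drug)
        self._q: dict[float, engine.RateMatrix] = {}
        self._prop: dict[tuple[float, float], np.ndarray] = {}

    def Q(self, voltage: float) -> engine.RateMatrix:
        key = round(float(voltage), 9)
        if key not in self._q:
            self._q[key] = engine.assemble_rate_matrix(self.model, None, voltage)
        return self._q[key]

    def advance(self, p: np.ndarray, voltage: float, duration: float) -> np.ndarray:
        key = (round(float(voltage), 9), round(float(duration), 12))
        if key not in self._prop:
            from scipy.linalg import expm
            self._prop[key] = expm(self.Q(voltage).Q * duration)
        return self._prop[key] @ p


def run_sweep(
    model: ChannelModel,
    drug: DrugSpec | None,
    protocol: Protocol,
    normalization: float | None = None,
    test_dt: float = TEST_DT,
) -> SweepResult:
    """Run every sweep value of a protocol and read out peak test current.

    The initial occupancy for each sweep value is the true equilibrium at
    the holding potential with the drug present (continuous drug exposure,
    fully equilibrated holding period).  ``normalization=None`` normalizes
    to the maximum of this sweep (the convention for control curves);
    drug curves should be passed the control's normalization so that
    complete block maps to zero current everywhere.
    """
    cache = _QCache(model, drug)
    m = cache.model
    p_hold = engine.equilibrium(cache.Q(protocol.holding))
    peaks = np.empty(len(protocol.swept[2]))
    for i, value in enumerate(protocol.swept[2]):
        p = p_hold
        segs = protocol.realize(value)
        for j, seg in enumerate(segs):
            if j == protocol.test_index:
                peak, p = engine.peak_conducting(
                    cache.Q(seg.voltage), m, p, seg.duration, dt=test_dt)
                peaks[i] = peak
            elif seg.duration > 0.0:
                p = cache.advance(p, seg.voltage, seg.duration)
    norm = float(peaks.max()) if normalization is None else float(normalization)
    return SweepResult(
        x=np.asarray(protocol.swept[2], dtype=float),
        peak=peaks,
        current=peaks / norm,
        normalization=norm,
        protocol=protocol.name,
        condition="control" if drug is None or drug.concentration == 0 else drug.name,
    )


def run_control_and_drug(
    model: ChannelModel,
    drug: DrugSpec,
    protocol: Protocol,
    control: SweepResult | None = None,
    test_dt: float = TEST_DT,
) -> tuple[SweepResult, SweepResult]:
    """Control sweep plus drug sweep normalized to the control maximum."""
    if control is None:
        control = run_sweep(model, None, protocol, test_dt=test_dt)
    drugged = run_sweep(model, drug, protocol,
                        normalization=control.normalization, test_dt=test_dt)
    return control, drugged


def single_pulse_peak(
    model: ChannelModel,
    drug: DrugSpec | None,
    holding: float,
    test_voltage: float = TEST_VOLTAGE,
    test_duration: float = TEST_DURATION,
    test_dt: float = TEST_DT,
) -> float:
    """Peak conducting occupancy of one test pulse from holding equilibrium."""
    cache = _QCache(model, drug)
    p = engine.equilibrium(cache.Q(holding))
    peak, _ = engine.peak_conducting(
        cache.Q(test_voltage), cache.model, p, test_duration, dt=test_dt)
    return peak


def concentration_response(
    model: ChannelModel,
    drug_template: DrugSpec,
    holding: float,
    concentrations,
) -> np.ndarray:
    """Fractional inhibition of the peak test current vs. the drug-free
    peak at the same holding potential, per concentration."""
    control = single_pulse_peak(model, None, holding)
    inhib = np.empty(len(concentrations))
    for i, c in enumerate(concentrations):
        if c < 0:
            raise ValueError("concentrations must be >= 0")
        if c == 0:
            inhib[i] = 0.0
            continue
        peak = single_pulse_peak(model, drug_template.at(float(c)), holding)
        inhib[i] = 1.0 - peak / control
    return inhib
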