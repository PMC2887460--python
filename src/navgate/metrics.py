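"""Effectiveness statistics for state-dependent sodium-channel inhibitors.

* Boltzmann fits of voltage-availability curves (V1/2, slope);
* biexponential fits of recovery time courses (tau_fast, tau_slow);
* the normalized sum-of-differences statistic nSOD in [0, 1];
* IC50 by bisection on concentration;
* the nSOD(Rec_t) vs nSOD(SInact_t) plane with fast/slow family regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit
from shapely.geometry import Point, Polygon

from .model import ChannelModel, DrugSpec
from .protocols import (Protocol, SweepResult, run_control_and_drug,
                        run_sweep, single_pulse_peak, standard_protocol)

__all__ = [
    "BoltzmannFit", "BiexpFit", "NSODPoint",
    "fit_boltzmann", "fit_biexponential", "nsod", "ic50",
    "nsod_plane", "gap_duration_curve", "NSODPlane",
]


@dataclass(frozen=True)
class BoltzmannFit:
    """Sigmoid fit ``y = bottom + (top - bottom)/(1 + exp((V - Vhalf)/k))``.

    ``defined`` is False when the curve has no transition in range (the
    fit, and hence any V1/2 shift, cannot be determined).
    """

    Vhalf: float
    slope: float
    top: float
    bottom: float
    residual: float
    defined: bool = True


@dataclass(frozen=True)
class BiexpFit:
    """Two-exponential recovery toward a shared asymptote of 1:
    ``y = 1 - amp_fast*exp(-t/tau_fast) - amp_slow*exp(-t/tau_slow)``."""

    tau_fast: float
    tau_slow: float
    amp_fast: float
    amp_slow: float
    residual: float
    single_exponential: bool = False  # slow amplitude ~ 0


@dataclass(frozen=True)
class NSODPoint:
    """One drug located on the effectiveness plane."""

    drug: str
    nsod_onset: float  # SInact_t
    nsod_recovery: float  # Rec_t
    params: dict = field(default_factory=dict, compare=False)


def _boltzmann(v, vhalf, slope, top, bottom):
    return bottom + (top - bottom) / (1.0 + np.exp((v - vhalf) / slope))


def fit_boltzmann(curve: SweepResult | tuple[np.ndarray, np.ndarray]) -> BoltzmannFit:
    """Least-squares Boltzmann fit of an availability curve.

    Requires at least 6 points; a dynamic range below 0.2 is reported as
    fit-undefined rather than producing a meaningless midpoint.
    """
    if isinstance(curve, SweepResult):
        x, y = curve.x, curve.current
    else:
        x, y = np.asarray(curve[0], float), np.asarray(curve[1], float)
    if len(x) < 6:
        raise ValueError("need at least 6 points spanning the transition")
    rng = float(y.max() - y.min())
    if rng < 0.2:
        return BoltzmannFit(np.nan, np.nan, float(y.max()), float(y.min()),
                            np.nan, defined=False)
    # midpoint guess: crossing of the half-range level
    level = y.min() + rng / 2.0
    i = int(np.argmin(np.abs(y - level)))
    p0 = [x[i], 6.0, float(y.max()), float(y.min())]
    try:
        popt, _ = curve_fit(_boltzmann, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return BoltzmannFit(np.nan, np.nan, np.nan, np.nan, np.nan, defined=False)
    res = float(np.linalg.norm(_boltzmann(x, *popt) - y))
    vhalf, slope, top, bottom = popt
    return BoltzmannFit(float(vhalf), float(abs(slope)), float(top),
                        float(bottom), res, defined=True)


def _biexp(t, a1, tau1, a2, tau2):
    return 1.0 - a1 * np.exp(-t / tau1) - a2 * np.exp(-t / tau2)


def fit_biexponential(curve: SweepResult | tuple[np.ndarray, np.ndarray],
                      n_starts: int = 5) -> BiexpFit:
    """Biexponential recovery fit with a shared asymptote of 1.

    Multi-start least squares (deterministic log-spaced tau seed pairs)
    guards against the local minima that plague two-exponential fits.
    Components are reported fast-first; data that are effectively
    single-exponential come back flagged with ``amp_slow < 1e-3``.
    """
    if isinstance(curve, SweepResult):
        t, y = curve.x, curve.current
    else:
        t, y = np.asarray(curve[0], float), np.asarray(curve[1], float)
    span = (t.min(), t.max())
    seeds = np.geomspace(max(span[0], 1e-6), span[1], n_starts + 1)
    best = None
    deficit = max(1.0 - y[0], 0.1)
    for i in range(n_starts):
        p0 = [0.5 * deficit, seeds[i], 0.5 * deficit, seeds[i + 1]]
        try:
            popt, _ = curve_fit(
                _biexp, t, y, p0=p0, maxfev=20000,
                bounds=([0.0, 1e-9, 0.0, 1e-9], [1.5, 1e4, 1.5, 1e4]))
        except (RuntimeError, ValueError):
            continue
        res = float(np.linalg.norm(_biexp(t, *popt) - y))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        raise RuntimeError("biexponential fit failed from all starts")
    (a1, tau1, a2, tau2), res = best
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    # degenerate data: a vanishing component or two coincident taus
    single = bool(min(a1, a2) < 1e-3 or tau2 < 1.05 * tau1)
    return BiexpFit(float(tau1), float(tau2), float(a1), float(a2), res,
                    single_exponential=single)


def nsod(control: SweepResult, drug: SweepResult) -> float:
    """Normalized sum of differences between control and drug curves.

    ``sum(control - drug) / sum(control)`` on a shared, log-evenly spaced
    sweep grid, which makes the statistic proportional to the area between
    the curves on a semilog plot.  0 means no drug effect, 1 means the
    current was completely abolished; facilitation (drug above control)
    is clipped at 0.
    """
    if control.x.shape != drug.x.shape or not np.allclose(control.x, drug.x):
        raise ValueError("control and drug sweeps must share the same grid")
    total = float(control.current.sum())
    if total <= 0:
        raise ValueError("control curve has no area")
    value = float((control.current - drug.current).sum()) / total
    return float(np.clip(value, 0.0, 1.0))


def ic50(
    model: ChannelModel,
    drug_template: DrugSpec,
    holding: float,
    bracket: tuple[float, float] = (1e-3, 1e5),
    rtol: float = 0.01,
) -> float:
    """Concentration (uM) causing 50% inhibition of the peak current of a
    single test depolarization from ``holding``, by bisection on log
    concentration to 1% relative tolerance."""
    control = single_pulse_peak(model, None, holding)

    def inhibition(c: float) -> float:
        return 1.0 - single_pulse_peak(model, drug_template.at(c), holding) / control

    lo, hi = bracket
    f_lo, f_hi = inhibition(lo) - 0.5, inhibition(hi) - 0.5
    if f_lo * f_hi > 0:
        raise ValueError(
            f"50% inhibition not bracketed in [{lo}, {hi}] uM "
            f"(inhibition {f_lo + 0.5:.3f} .. {f_hi + 0.5:.3f})")
    llo, lhi = np.log(lo), np.log(hi)
    while (lhi - llo) > np.log1p(rtol):
        mid = 0.5 * (llo + lhi)
        if (inhibition(float(np.exp(mid))) - 0.5) * f_lo > 0:
            llo = mid
        else:
            lhi = mid
    return float(np.exp(0.5 * (llo + lhi)))


@dataclass(frozen=True)
class NSODPlane:
    """Drug points plus the convex-hull regions of the fast- and
    slow-inactivated-state-preferring families."""

    points: tuple[NSODPoint, ...]
    fast_region: tuple[tuple[float, float], ...]
    slow_region: tuple[tuple[float, float], ...]

    def classify(self, point: NSODPoint | tuple[float, float]) -> str:
        """fast-only / slow-only / overlap / outside."""
        if isinstance(point, NSODPoint):
            xy = (point.nsod_onset, point.nsod_recovery)
        else:
            xy = tuple(point)
        p = Point(*xy)
        in_fast = Polygon(self.fast_region).buffer(1e-9).contains(p)
        in_slow = Polygon(self.slow_region).buffer(1e-9).contains(p)
        if in_fast and in_slow:
            return "overlap"
        if in_fast:
            return "fast-only"
        if in_slow:
            return "slow-only"
        return "outside"


def _hull(points: list[tuple[float, float]]) -> tuple[tuple[float, float], ...]:
    from scipy.spatial import ConvexHull
    arr = np.asarray(points)
    if len(arr) < 3:
        raise ValueError("need at least 3 points for a region")
    hull = ConvexHull(arr)
    return tuple(map(tuple, arr[hull.vertices]))


def drug_plane_point(
    model: ChannelModel,
    drug: DrugSpec,
    onset_protocol: Protocol | None = None,
    recovery_protocol: Protocol | None = None,
    controls: tuple[SweepResult, SweepResult] | None = None,
) -> NSODPoint:
    """Locate one drug on the nSOD(Rec_t) vs nSOD(SInact_t) plane."""
    onset_protocol = onset_protocol or standard_protocol("SInact_t")
    recovery_protocol = recovery_protocol or standard_protocol("Rec_t")
    c_on = controls[0] if controls else None
    c_rec = controls[1] if controls else None
    c_on, d_on = run_control_and_drug(model, drug, onset_protocol, control=c_on)
    c_rec, d_rec = run_control_and_drug(model, drug, recovery_protocol, control=c_rec)
    return NSODPoint(
        drug=drug.name,
        nsod_onset=nsod(c_on, d_on),
        nsod_recovery=nsod(c_rec, d_rec),
        params={"ka": drug.ka, "kd": drug.kd, "CF": drug.CF, "CS": drug.CS,
                "concentration": drug.concentration},
    )


def nsod_plane(
    drugs: list[DrugSpec],
    model: ChannelModel,
    onset_protocol: Protocol | None = None,
    recovery_protocol: Protocol | None = None,
) -> NSODPlane:
    """Run every drug in both protocols and build the family regions.

    Family membership is read from the factors: CF > 1 puts a drug in the
    fast family, CS > 1 in the slow family (the neutral drug belongs to
    neither and only contributes a point).
    """
    onset_protocol = onset_protocol or standard_protocol("SInact_t")
    recovery_protocol = recovery_protocol or standard_protocol("Rec_t")
    c_on = run_sweep(model, None, onset_protocol)
    c_rec = run_sweep(model, None, recovery_protocol)
    points = [drug_plane_point(model, d, onset_protocol, recovery_protocol,
                               controls=(c_on, c_rec)) for d in drugs]
    fast = [(p.nsod_onset, p.nsod_recovery) for p, d in zip(points, drugs) if d.CF > 1]
    slow = [(p.nsod_onset, p.nsod_recovery) for p, d in zip(points, drugs) if d.CS > 1]
    return NSODPlane(points=tuple(points), fast_region=_hull(fast),
                     slow_region=_hull(slow))


def reference_plane_drugs(
    model: ChannelModel,
    fixed_concentrations: tuple[float, float] = (14.0, 81.75),
) -> list[DrugSpec]:
    """The simulated-drug set whose points define the plane regions.

    Three families are combined, mirroring how the effectiveness plane is
    explored: (i) the 100-drug kinetics-by-factor grid with each drug at
    its own IC50 at -90 mV holding (comparable potency); (ii) the factor
    series at a fixed concentration per family (14 uM for fast-state-
    preferring, 81.75 uM for slow); (iii) a concentration series (x0.1,
    x1, x10 of the fixed concentration) for the factor-10 drugs.  The
    union spans effectiveness from near the origin to saturation, so the
    convex hulls of the two families cover each mechanism's reachable
    area rather than a single iso-potency slice.
    """
    from .io import drug_grid

    out = []
    for d in drug_grid():
        out.append(d.at(ic50(model, d, holding=-90.0)))
    c_fast, c_slow = fixed_concentrations
    for d in drug_grid():
        c = c_fast if d.CF > 1 else c_slow
        out.append(d.at(c))
        if (d.CF == 10.0) or (d.CS == 10.0):
            out.append(d.at(c / 10.0))
            out.append(d.at(c * 10.0))
    return out


def gap_duration_curve(
    model: ChannelModel,
    drug: DrugSpec,
    gaps=None,
    subtract_tonic: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Drug effect on the onset (SInact_t) curve as a function of the
    hyperpolarizing gap duration (1 ms - 10 s): nSOD per gap.

    An inhibitor at finite concentration blocks a resting fraction
    ``c/(c + Kd)`` even from the holding potential; this gap-independent
    tonic component is common to every gap duration, so by default it is
    subtracted (and the result clipped at 0) to isolate the part of the
    effect that the hyperpolarizing gap can and cannot wash out.
    """
    if gaps is None:
        gaps = np.geomspace(1e-3, 10.0, 13)
    tonic = 0.0
    if subtract_tonic:
        control_peak = single_pulse_peak(model, None, -150.0)
        drug_peak = single_pulse_peak(model, drug, -150.0)
        tonic = 1.0 - drug_peak / control_peak
    effects = np.empty(len(gaps))
    for i, gap in enumerate(gaps):
        proto = standard_protocol("SInact_t", gap_duration=float(gap))
        control, drugged = run_control_and_drug(model, drug, proto)
        effects[i] = max(nsod(control, drugged) - tonic, 0.0)
    return np.asarray(gaps, float), effects


def equilibrium_vhalf(opening, closing,
                      v_lo: float = -160.0, v_hi: float = 20.0) -> float:
    """Midpoint of a two-state gate's equilibrium availability curve:
    the voltage where opening and closing rates are equal."""
    f = lambda v: np.log(opening(v)) - np.log(closing(v))
    return float(brentq(f, v_lo, v_hi))
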