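"""Effectiveness statistics: curve fits, nSOD, IC50."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navgate import metrics
from navgate.metrics import (fit_biexponential, fit_boltzmann, ic50, nsod)
from navgate.protocols import SweepResult


def sweep(x, y, **kw):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return SweepResult(x=x, peak=y, current=y, normalization=1.0, **kw)


class TestBoltzmannFit:
    def test_exact_recovery_on_noiseless_data(self):
        v = np.arange(-120.0, -29.0, 5.0)
        y = 0.02 + 0.96 / (1.0 + np.exp((v + 60.0) / 6.0))
        fit = fit_boltzmann(sweep(v, y))
        assert fit.defined
        assert fit.Vhalf == pytest.approx(-60.0, abs=1e-6)
        assert fit.slope == pytest.approx(6.0, abs=1e-6)

    def test_flat_curve_reported_undefined(self):
        v = np.arange(-120.0, -29.0, 5.0)
        fit = fit_boltzmann(sweep(v, np.ones_like(v)))
        assert not fit.defined
        assert np.isnan(fit.Vhalf)

    def test_recovery_under_noise(self):
        """1% multiplicative noise moves the recovered midpoint by less
        than half a millivolt on average."""
        v = np.arange(-120.0, -29.0, 2.5)
        clean = 1.0 / (1.0 + np.exp((v + 60.0) / 6.0))
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(100):
            y = clean * (1.0 + rng.normal(scale=0.01, size=v.shape))
            errs.append(fit_boltzmann(sweep(v, y)).Vhalf - (-60.0))
        assert np.abs(np.mean(errs)) < 0.5
        assert np.abs(errs).max() < 2.0


class TestBiexponentialFit:
    def test_exact_recovery(self):
        t = np.geomspace(1e-4, 1.0, 40)
        y = 1.0 - 0.5 * np.exp(-t / 0.002) - 0.5 * np.exp(-t / 0.060)
        fit = fit_biexponential(sweep(t, y))
        assert fit.tau_fast == pytest.approx(0.002, rel=0.01)
        assert fit.tau_slow == pytest.approx(0.060, rel=0.01)
        assert fit.amp_fast == pytest.approx(0.5, rel=0.01)

    def test_single_exponential_flagged(self):
        t = np.geomspace(1e-4, 1.0, 40)
        y = 1.0 - 0.9 * np.exp(-t / 0.005)
        fit = fit_biexponential(sweep(t, y))
        assert fit.single_exponential or min(fit.amp_fast, fit.amp_slow) < 1e-3
        recovered = fit.tau_fast if fit.amp_fast > fit.amp_slow else fit.tau_slow
        assert recovered == pytest.approx(0.005, rel=0.01)


class TestNSOD:
    def test_no_effect_gives_zero(self):
        c = sweep([1., 10., 100., 1000.], [1.0, 0.8, 0.5, 0.2])
        assert nsod(c, c) == 0.0

    def test_abolished_current_gives_one(self):
        x = [1., 10., 100., 1000.]
        c = sweep(x, [1.0, 0.8, 0.5, 0.2])
        d = sweep(x, [0.0, 0.0, 0.0, 0.0])
        assert nsod(c, d) == 1.0

    def test_hand_computed_value(self):
        x = [1., 10., 100., 1000.]
        c = sweep(x, [1.0, 1.0, 1.0, 1.0])
        d = sweep(x, [1.0, 0.5, 0.5, 1.0])
        assert nsod(c, d) == pytest.approx(0.25)

    def test_facilitation_clipped_to_zero(self):
        x = [1., 10., 100.]
        c = sweep(x, [0.5, 0.5, 0.5])
        d = sweep(x, [0.6, 0.7, 0.6])
        assert nsod(c, d) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nsod(sweep([1., 2.], [1., 1.]), sweep([1., 3.], [1., 1.]))

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_joint_rescaling(self, scale):
        x = np.array([1., 10., 100., 1000.])
        c = np.array([1.0, 0.9, 0.6, 0.3])
        d = np.array([0.8, 0.6, 0.3, 0.1])
        base = nsod(sweep(x, c), sweep(x, d))
        scaled = nsod(sweep(x, c * scale), sweep(x, d * scale))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestIC50:
    def test_resting_ic50_equals_kd(self, cube, prototypes):
        for name in ("FI_fb", "FI_sb", "SI_fb", "SI_sb"):
            c50 = ic50(cube, prototypes[name], holding=-150.0)
            assert c50 == pytest.approx(200.0, rel=0.02)

    def test_bisection_agrees_with_dense_scan(self, cube, prototypes):
        from navgate.protocols import concentration_response
        c50 = ic50(cube, prototypes["FI_fb"], holding=-90.0)
        grid = np.geomspace(c50 / 3.0, c50 * 3.0, 120)
        inhib = concentration_response(cube, prototypes["FI_fb"], -90.0, grid)
        brute = grid[np.argmin(np.abs(inhib - 0.5))]
        assert c50 == pytest.approx(brute, rel=0.02)

    def test_state_preferring_drug_gains_potency_with_depolarization(
            self, cube, prototypes):
        assert ic50(cube, prototypes["FI_fb"], -60.0) < \
            ic50(cube, prototypes["FI_fb"], -150.0)

    def test_unbracketed_raises(self, cube, prototypes):
        with pytest.raises(ValueError):
            ic50(cube, prototypes["FI_fb"], -150.0, bracket=(1e-3, 1e-2))


class TestMonotonicity:
    def test_nsod_monotone_in_concentration(self, cube, prototypes):
        """More drug, more effect: nSOD in the onset protocol never
        decreases as concentration rises."""
        from navgate.protocols import run_control_and_drug, run_sweep, standard_protocol
        proto = standard_protocol("SInact_t", per_decade=4)
        control = run_sweep(cube, None, proto)
        for name in ("FI_fb", "SI_sb"):
            prev = -1.0
            for conc in (3.0, 30.0, 300.0):
                _, d = run_control_and_drug(
                    cube, prototypes[name].at(conc), proto, control=control)
                val = nsod(control, d)
                assert val >= prev - 1e-9
                prev = val
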