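"""Structure and algebra of the gating cube and its drug extension:
topology counts, gate independence, microscopic reversibility."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navgate.engine import assemble_rate_matrix, equilibrium
from navgate.model import DrugSpec, ParameterError, RateLaw
from navgate.tetracube import (GATE_ORDER, build_free_model, extend_with_drug,
                               gate_is_open, rate_law_eval, state_name,
                               stabilization_shift)

VOLTAGES = (-150.0, -90.0, -20.0, 0.0)


class TestRateLaw:
    def test_half_maximum_at_inflection(self):
        law = RateLaw(A=1000.0, Vhalf=-50.0, r=10.0, sense="depolarized")
        assert rate_law_eval(law, -50.0) == pytest.approx(500.0)

    def test_saturating_limit_is_A(self):
        law = RateLaw(A=1000.0, Vhalf=-50.0, r=10.0, sense="depolarized")
        assert rate_law_eval(law, 200.0) == pytest.approx(1000.0, rel=1e-6)
        assert rate_law_eval(law, -400.0) == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_value(self):
        # one e-fold below the inflection of a depolarization-activated law
        law = RateLaw(A=1000.0, Vhalf=-50.0, r=10.0, sense="depolarized")
        assert rate_law_eval(law, -60.0) == pytest.approx(
            1000.0 / (1.0 + math.e), rel=1e-9)

    @given(v=st.floats(-300, 150), dv=st.floats(0.1, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, v, dv):
        law = RateLaw(A=700.0, Vhalf=-60.0, r=12.0, sense="depolarized")
        assert 0.0 < law(v) < 700.0
        assert law(v + dv) > law(v)


class TestFreeCube:
    def test_cube_topology(self, toy_gates):
        m = build_free_model(toy_gates)
        assert m.n_states == 8
        assert len(m.transitions) == 24  # 12 undirected edges
        assert len(m.undirected_edges()) == 12
        assert m.conducting == {state_name((True, True, True))}

    def test_each_edge_flips_one_gate(self, toy_gates):
        m = build_free_model(toy_gates)
        for t in m.transitions:
            flips = sum(gate_is_open(t.frm, g) != gate_is_open(t.to, g)
                        for g in GATE_ORDER)
            assert flips == 1

    @pytest.mark.parametrize("voltage", VOLTAGES)
    def test_gate_independence_equilibrium_product(self, toy_gates, voltage):
        """Full-model equilibrium occupancy factorizes into the product of
        per-gate two-state equilibria (the gates move independently)."""
        m = build_free_model(toy_gates)
        eq = equilibrium(assemble_rate_matrix(m, None, voltage))
        p_open = {g: toy_gates[g].open_probability(voltage) for g in GATE_ORDER}
        for i, s in enumerate(m.states):
            expected = 1.0
            for g in GATE_ORDER:
                expected *= p_open[g] if gate_is_open(s, g) else 1.0 - p_open[g]
            assert eq[i] == pytest.approx(expected, abs=1e-10)

    def test_full_availability_at_strong_hyperpolarization(self, calibrated_gates):
        for g in ("fast_inactivation", "slow_inactivation"):
            assert calibrated_gates[g].open_probability(-150.0) > 0.999


def cycle_product_ratio(model, cycle, voltage):
    rates = {}
    for t in model.transitions:
        rates[(t.frm, t.to)] = t.rate(voltage)
    fwd = bwd = 1.0
    for i in range(len(cycle)):
        a, b = cycle[i], cycle[(i + 1) % len(cycle)]
        fwd *= rates[(a, b)]
        bwd *= rates[(b, a)]
    return fwd / bwd


def tesseract_faces(model):
    """All square faces: pairs of parallel edges along two distinct axes
    (three gate axes plus the binding axis)."""
    edges = model.undirected_edges()
    states = list(model.states)
    faces = []
    for quad in itertools.combinations(states, 4):
        sub = [frozenset(e) for e in itertools.combinations(quad, 2)
               if frozenset(e) in edges]
        if len(sub) == 4:  # a 4-cycle among 4 vertices
            # order the quad into a cycle
            a = quad[0]
            nbrs = [s for s in quad[1:] if frozenset((a, s)) in edges]
            if len(nbrs) != 2:
                continue
            d = next(s for s in quad[1:] if s not in nbrs)
            faces.append((a, nbrs[0], d, nbrs[1]))
    return faces


class TestDrugExtension:
    def test_tesseract_topology(self, toy_gates, prototypes):
        m = extend_with_drug(build_free_model(toy_gates), prototypes["FI_fb"])
        assert m.n_states == 16
        assert len(m.transitions) == 64  # 32 undirected edges
        assert len(m.undirected_edges()) == 32
        assert len(tesseract_faces(m)) == 24

    def test_cycle_condition_on_all_faces(self, toy_gates, prototypes):
        """Microscopic reversibility: clockwise and counter-clockwise rate
        products agree on every square face at every test voltage."""
        for drug in prototypes.values():
            m = extend_with_drug(build_free_model(toy_gates), drug)
            for face in tesseract_faces(m):
                for v in VOLTAGES:
                    assert cycle_product_ratio(m, face, v) == pytest.approx(
                        1.0, rel=1e-8)

    def test_neutral_drug_bound_layer_copies_free_layer(self, toy_gates):
        neutral = DrugSpec(name="neutral", ka=0.5, kd=100.0, concentration=30.0)
        m = extend_with_drug(build_free_model(toy_gates), neutral)
        rates = {(t.frm, t.to): t.rate for t in m.transitions}
        for (frm, to), rate in list(rates.items()):
            if frm.endswith("*D") and to.endswith("*D"):
                free = rates[(frm[:-2], to[:-2])]
                for v in VOLTAGES:
                    assert rate(v) == pytest.approx(free(v))
        # binding rates identical for every configuration
        assoc = {frm: rate(0.0) for (frm, to), rate in rates.items()
                 if to == frm + "*D"}
        assert len(set(round(a, 12) for a in assoc.values())) == 1

    def test_fast_factor_scales_inactivated_affinity(self, toy_gates, prototypes):
        """CF = 10 makes the equilibrium affinity for any fast-inactivated
        configuration 10x the resting affinity."""
        m = extend_with_drug(build_free_model(toy_gates), prototypes["FI_fb"])
        rates = {(t.frm, t.to): t.rate(0.0) for t in m.transitions}
        rest = state_name((False, True, True))
        k_rest = rates[(rest, rest + "*D")] / rates[(rest + "*D", rest)]
        fi = state_name((False, False, True))
        k_fi = rates[(fi, fi + "*D")] / rates[(fi + "*D", fi)]
        assert k_fi / k_rest == pytest.approx(10.0)

    def test_neutral_marginal_dynamics_match_free_model(self, toy_gates):
        """With all factors 1 the summed bound+unbound occupancy per gate
        configuration evolves exactly like the drug-free cube."""
        from navgate.engine import propagate
        neutral = DrugSpec(name="neutral", ka=0.5, kd=100.0, concentration=30.0)
        free = build_free_model(toy_gates)
        ext = extend_with_drug(free, neutral)
        q_free = assemble_rate_matrix(free, None, -40.0)
        q_ext = assemble_rate_matrix(ext, None, -40.0)
        p0_free = equilibrium(assemble_rate_matrix(free, None, -120.0))
        p0_ext = equilibrium(assemble_rate_matrix(ext, None, -120.0))
        pf = propagate(q_free, p0_free, 0.05)
        pe = propagate(q_ext, p0_ext, 0.05)
        for i, s in enumerate(free.states):
            marginal = pe[i] + pe[ext.states.index(s + "*D")]
            assert marginal == pytest.approx(pf[i], abs=1e-9)

    def test_increasing_cf_increases_bound_fast_inactivated_occupancy(
            self, toy_gates):
        prev = -1.0
        for cf in (1.0, 3.0, 10.0, 30.0):
            d = DrugSpec(name="d", ka=0.5, kd=100.0, CF=cf, concentration=30.0)
            m = extend_with_drug(build_free_model(toy_gates), d)
            eq = equilibrium(assemble_rate_matrix(m, None, -20.0))
            occ = sum(eq[i] for i, s in enumerate(m.states)
                      if s.endswith("*D")
                      and not gate_is_open(s[:-2], "fast_inactivation"))
            assert occ > prev
            prev = occ

    def test_stabilization_shift_per_prototype(self, prototypes):
        assert stabilization_shift(prototypes["FI_fb"], "fast_inactivation") == 10.0
        assert stabilization_shift(prototypes["FI_fb"], "slow_inactivation") == 1.0
        assert stabilization_shift(prototypes["SI_fb"], "slow_inactivation") == 10.0
        neutral = DrugSpec(name="n", ka=1.0, kd=1.0)
        for g in GATE_ORDER:
            assert stabilization_shift(neutral, g) == 1.0
        with pytest.raises(ParameterError):
            stabilization_shift(neutral, "mystery_gate")

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ParameterError):
            DrugSpec(name="bad", ka=1.0, kd=1.0, CF=0.0)
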