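"""Mean-field ODE model: right-hand sides, steady state, excitability."""

import numpy as np
import pytest

from astroca import core, meanfield
from astroca.ip3r import OPEN_STATE


KIN = core.table1_kinetics()
SP = core.table1_space()


class TestRhs:
    def test_unbound_receptors_no_ligand(self):
        """With only empty receptors and no ligands, receptor and IP3
        derivatives vanish and Ca grows at the bare influx gamma."""
        V = SP.area
        y = np.zeros(9)
        y[0] = SP.N_IP3R / V
        d = meanfield.rhs(y, KIN, SP)
        np.testing.assert_allclose(d[:7], 0.0, atol=1e-15)
        assert d[7] == 0.0
        assert d[8] * V == pytest.approx(KIN.gamma)

    def test_receptor_derivatives_conserve_total(self):
        """Summed receptor derivatives vanish identically (the eighth state
        is the conservation remainder)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.uniform(0, 1e-3, size=9)
            d = meanfield.rhs(y, KIN, SP)
            # d[111]/dt = -(sum of the seven tracked derivatives)
            states = np.concatenate([y[:7],
                                     [SP.N_IP3R / SP.area - y[:7].sum()]])
            from astroca.ip3r import build_generator
            full = build_generator(y[8], y[7], KIN).T @ states
            assert full.sum() == pytest.approx(0.0, abs=1e-15)
            np.testing.assert_allclose(d[:7], full[:7], rtol=1e-12)

    def test_first_line_of_receptor_odes(self):
        """d[000]/dt = -(a1 c + a2 p + a3 c)[000] + b1[100] + b2[010]
        + b3[001], transcribed term by term."""
        rng = np.random.default_rng(4)
        y = rng.uniform(0, 1e-3, size=9)
        c, p = y[8], y[7]
        d = meanfield.rhs(y, KIN, SP)
        expected = (-(KIN.a1 * c + KIN.a2 * p + KIN.a3 * c) * y[0]
                    + KIN.b1 * y[4] + KIN.b2 * y[2] + KIN.b3 * y[1])
        assert d[0] == pytest.approx(expected, rel=1e-12)


class TestSteadyState:
    def test_table1_fixed_point_residual_and_level(self):
        ss = meanfield.steady_state(KIN, SP, tol=1e-8)
        assert ss["residual"] < 1e-8
        # the basal level of the stochastic engines is ~50 ions; the MF
        # fixed point coincides with it up to the open-channel contribution
        assert 49.0 < ss["ca_count"] < 55.0

    def test_no_source_means_empty_cytosol(self):
        kin = core.table1_kinetics(gamma=0.0, mu=0.0)
        ss = meanfield.steady_state(kin, SP)
        assert ss["ca_count"] == pytest.approx(0.0, abs=1e-6)

    def test_integration_and_root_agree(self):
        """Long-time integration lands on the root-found fixed point."""
        ss = meanfield.steady_state(KIN, SP)
        tr = meanfield.simulate_mf(KIN, SP, 5000.0, sample_dt=50.0)
        assert tr.ca[-1] == pytest.approx(ss["ca_count"], abs=1e-4)

    def test_no_limit_cycle_from_random_initial_conditions(self):
        """Trajectories from randomized positive states converge to one
        fixed point (no sustained oscillation with default parameters)."""
        rng = np.random.default_rng(11)
        ss = meanfield.steady_state(KIN, SP)
        V = SP.area
        for _ in range(4):
            y0 = meanfield.initial_state(KIN, SP)
            y0[7] = rng.uniform(0, 100) / V
            y0[8] = rng.uniform(0, 300) / V
            tr = meanfield.simulate_mf(KIN, SP, 4000.0, y0=y0, sample_dt=10.0)
            assert tr.ca[-1] == pytest.approx(ss["ca_count"], abs=0.05)
            # trajectory stays non-negative
            assert tr.ca.min() >= -1e-9 and tr.ip3.min() >= -1e-9


class TestInjection:
    def test_zero_injection_zero_amplitude(self):
        r = meanfield.ip3_injection_response(KIN, SP, 0)
        assert r["amplitude"] == pytest.approx(0.0, abs=1e-6)

    def test_negative_injection_rejected(self):
        with pytest.raises(ValueError):
            meanfield.ip3_injection_response(KIN, SP, -5)

    def test_small_a1_response_is_linear(self):
        """At low activating-site affinity, doubling the injected IP3
        doubles the Ca response."""
        kin = core.table1_kinetics(a1=0.5)
        a_n = meanfield.ip3_injection_response(kin, SP, 50)["amplitude"]
        a_2n = meanfield.ip3_injection_response(kin, SP, 100)["amplitude"]
        assert a_2n / a_n == pytest.approx(2.0, rel=0.1)

    def test_large_a1_response_is_supralinear(self):
        kin = core.table1_kinetics(a1=5.0)
        a_n = meanfield.ip3_injection_response(kin, SP, 50)["amplitude"]
        a_2n = meanfield.ip3_injection_response(kin, SP, 100)["amplitude"]
        assert a_2n / a_n > 2.5
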