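"""The 8-state receptor model: transition structure, open-state predicate,
no-cooperativity, stationary law and closure-path statistics."""

import numpy as np
import pytest

from astroca import core, ip3r


KIN = core.table1_kinetics()


class TestStates:
    def test_eight_states_round_trip(self):
        seen = set()
        for i in (0, 1):
            for j in (0, 1):
                for k in (0, 1):
                    s = ip3r.pack_state(i, j, k)
                    assert ip3r.unpack_state(s) == (i, j, k)
                    seen.add(s)
        assert seen == set(range(8))

    @pytest.mark.parametrize("triplet,expected", [
        ((1, 1, 0), True),   # the conducting state
        ((1, 1, 1), False),  # inactivating site bound
        ((0, 0, 0), False),
        ((0, 1, 0), False),
        ((1, 0, 0), False),
    ])
    def test_open_iff_110(self, triplet, expected):
        assert ip3r.is_open(ip3r.pack_state(*triplet)) is expected

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            ip3r.is_open(8)
        with pytest.raises(ValueError):
            ip3r.pack_state(2, 0, 0)


class TestTransitionRates:
    def test_empty_state_binding_rates(self):
        """From {000}: a1*c to {100}, a2*p to {010}, a3*c to {001}."""
        c, p = 2.0e-3, 5.0e-4
        rates = ip3r.transition_rates(0, c, p, KIN)
        assert rates == {
            ip3r.pack_state(1, 0, 0): pytest.approx(KIN.a1 * c),
            ip3r.pack_state(0, 1, 0): pytest.approx(KIN.a2 * p),
            ip3r.pack_state(0, 0, 1): pytest.approx(KIN.a3 * c),
        }

    def test_no_ligand_no_binding(self):
        assert ip3r.transition_rates(0, 0.0, 0.0, KIN) == {}

    def test_negative_availability_rejected(self):
        with pytest.raises(ValueError):
            ip3r.transition_rates(0, -1.0, 0.0, KIN)

    def test_no_intra_channel_cooperativity(self):
        """Each site's rate is invariant under the other two occupancies."""
        c, p = 1.3e-3, 4.2e-4
        for site, bit in enumerate((2, 1, 0)):
            for others in range(4):
                # embed the two other-site occupancies around `site`
                occ = [0, 0, 0]
                other_bits = [b for b in (2, 1, 0) if b != bit]
                occ_state = ((others & 1) << other_bits[0]) | \
                            (((others >> 1) & 1) << other_bits[1])
                s_free = occ_state  # site itself unbound
                s_bound = occ_state | (1 << bit)
                on = ip3r.transition_rates(s_free, c, p, KIN)[s_free | (1 << bit)]
                off = ip3r.transition_rates(s_bound, c, p, KIN)[s_bound & ~(1 << bit)]
                expected_on = (KIN.a2 * p if site == 1
                               else (KIN.a1 if site == 0 else KIN.a3) * c)
                expected_off = (KIN.b1, KIN.b2, KIN.b3)[site]
                assert on == pytest.approx(expected_on)
                assert off == pytest.approx(expected_off)

    def test_stationary_law_factorizes_over_sites(self):
        """The monomer CTMC stationary law equals the product of three
        independent two-state site occupancies."""
        c, p = 1.25e-3, 3.1e-4
        pi_numeric = ip3r.stationary_distribution(c, p, KIN)
        pi_product = ip3r.site_occupancy_product(c, p, KIN)
        np.testing.assert_allclose(pi_numeric, pi_product, atol=1e-12)
        assert pi_numeric.sum() == pytest.approx(1.0)


class TestClosurePaths:
    def test_single_closure(self):
        log = [(1.0, 0, ip3r.OPEN_STATE, 7)]
        st = ip3r.closure_paths(log)
        assert st.p_110_111 == 1.0 and st.n_closures == 1

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        rows = []
        t = 0.0
        for _ in range(500):
            t += rng.exponential()
            rows.append((t, 0, ip3r.OPEN_STATE,
                         rng.choice(ip3r.CLOSURE_TARGETS)))
        st = ip3r.closure_paths(np.array(rows))
        assert st.p_110_111 + st.p_110_100 + st.p_110_010 == pytest.approx(1.0)

    def test_no_closures_flagged(self):
        with pytest.raises(ip3r.NoClosuresError):
            ip3r.closure_paths([(0.5, 0, 2, ip3r.OPEN_STATE)])
        with pytest.raises(ip3r.NoClosuresError):
            ip3r.closure_paths([])

    def test_competing_exits_match_analytic_ratios(self):
        """Holding {110} with fixed ligand levels, exit probabilities are
        each exit rate over the total exit rate.  With b2 = b1 and zero Ca
        the two unbinding paths split 50/50 and {111} never occurs."""
        kin = core.table1_kinetics(b1=0.1, b2=0.1)
        rng = np.random.default_rng(42)
        rows = []
        n = 4000
        for i in range(n):
            rates = ip3r.transition_rates(ip3r.OPEN_STATE, 0.0, 0.0, kin)
            states = list(rates)
            probs = np.array([rates[s] for s in states])
            probs /= probs.sum()
            rows.append((float(i), 0, ip3r.OPEN_STATE,
                         rng.choice(states, p=probs)))
        st = ip3r.closure_paths(np.array(rows))
        assert st.p_110_111 == 0.0
        assert st.p_110_100 == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))
        assert st.p_110_010 == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_competing_exits_with_calcium(self):
        """Nonzero Ca adds the {111} exit with probability
        a3*c/(a3*c + b1 + b2)."""
        c = 2.0
        rates = ip3r.transition_rates(ip3r.OPEN_STATE, c, 0.0, KIN)
        total = sum(rates.values())
        assert rates[7] / total == pytest.approx(
            KIN.a3 * c / (KIN.a3 * c + KIN.b1 + KIN.b2))
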