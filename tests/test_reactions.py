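import numpy as np
import pytest

from casim.reactions import (BoundState, ReactionNetwork, build_specs,
                             equilibrate, reaction_rates,
                             rescale_myofibrillar, SPECIES)


def network(presets, fiber):
    return ReactionNetwork(rescale_myofibrillar(build_specs(presets[fiber]),
                                                presets[fiber]))


class TestEquilibrium:
    def test_all_rates_vanish_at_equilibrium(self, presets):
        for ft in ("I", "IIB"):
            p = presets[ft]
            specs = rescale_myofibrillar(build_specs(p), p)
            free = (p.resting.Ca_sarc_rest, p.resting.Ca_SR_rest, 0.05)
            st = equilibrate(specs, free, p.resting.Mg_free_rest)
            d, used = reaction_rates(st, free, specs)
            scale = max(abs(v) for v in (*free, p.resting.Mg_free_rest))
            for name, v in d.items():
                assert abs(v) < 1e-12 * max(scale, 1.0), name
            assert abs(used["sarcoplasm"]) < 1e-10

    def test_single_site_half_saturation(self, presets):
        net = network(presets, "IIB")
        kd_b = net.b_koff / net.b_kon
        st = net.equilibrium(0.106, 1010.0, kd_b, 780.0)
        assert st.ca_b == pytest.approx(0.5 * net.b_total, rel=1e-12)

    def test_dye_far_from_saturation_at_rest(self, presets):
        """At resting Ca2+ the 2:1 dye is far below its ~3% working bound
        fraction."""
        net = network(presets, "IIB")
        st = net.equilibrium(0.106, 1010.0, 0.05, 780.0)
        assert st.ca_dye / net.dye_total < 0.03 * 0.2

    def test_sr_store_covers_release_demand(self, presets):
        """Free plus calsequestrin-bound SR calcium exceeds the largest
        single-twitch release when referred to the sarcoplasmic volume."""
        p = presets["IIX"]
        net = network(presets, "IIX")
        st = net.equilibrium(0.106, p.resting.Ca_SR_rest, 0.05,
                             p.resting.Mg_free_rest)
        total_sr_sarc_ref = ((p.resting.Ca_SR_rest + st.ca_csq)
                             / p.volumes.ratio_sarc_to_SR)
        assert total_sr_sarc_ref > 346.0

    def test_equilibrium_is_long_time_limit(self, presets):
        """Integrating the pure reaction network from a perturbed state
        relaxes onto the algebraic equilibrium."""
        from scipy.integrate import solve_ivp
        net = network(presets, "I")
        ca, casr, cam, mg = 1.0, 1140.0, 0.1, 780.0
        eq = net.equilibrium(ca, casr, cam, mg)
        y0 = eq.as_array() * 0.9

        def rhs(t, y):
            d, *_ = net.derivs(y, ca, casr, cam, mg)
            return d

        sol = solve_ivp(rhs, (0.0, 5e4), y0, method="BDF",
                        rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[:, -1], eq.as_array(), rtol=1e-6,
                           atol=1e-9)


class TestKinetics:
    def test_competition_sign_on_calcium_step(self, presets):
        """Stepping free Ca2+ up against Mg-loaded parvalbumin drives Ca
        binding immediately and Mg unbinding as the free sites deplete."""
        from scipy.integrate import solve_ivp
        net = network(presets, "IIB")
        st = net.equilibrium(0.106, 1010.0, 0.05, 780.0)
        d2, *_ = net.derivs(st.as_array(), 16.0, 1010.0, 0.05, 780.0)
        i_ca, i_mg = SPECIES.index("ca_pv"), SPECIES.index("mg_pv")
        assert d2[i_ca] > 0.0

        def rhs(t, y):
            d, *_ = net.derivs(y, 16.0, 1010.0, 0.05, 780.0)
            return d

        sol = solve_ivp(rhs, (0.0, 1.0), st.as_array(), method="BDF",
                        rtol=1e-9, atol=1e-11)
        assert sol.y[i_ca, -1] > st.ca_pv
        assert sol.y[i_mg, -1] < st.mg_pv

    def test_forward_euler_oracle_two_species(self, presets):
        """The network's Tn + dye subsystem agrees with an independent
        tiny-step explicit integration (dt = 1e-5 ms over 1 ms)."""
        net = network(presets, "I")
        ca, casr, cam, mg = 2.0, 1140.0, 0.05, 780.0
        eq = net.equilibrium(0.106, casr, cam, mg)
        y = eq.as_array()

        # oracle: forward Euler on the same mass-action law, written
        # independently for the slow-Tn and dye steps only
        tn, dye = y[SPECIES.index("tn1")], y[SPECIES.index("ca_dye")]
        kon_t, koff_t = net.tn_kon1, net.tn_koff1
        kon_d, koff_d = net.dye_kon, net.dye_koff
        tn_tot, dye_tot = net.tn_total, net.dye_total
        dt = 1e-5
        for _ in range(100000):
            tn += dt * (kon_t * ca * (tn_tot - tn) - koff_t * tn)
            dye += dt * (kon_d * ca * (dye_tot - 2 * dye) ** 2
                         - koff_d * dye)

        from scipy.integrate import solve_ivp

        def rhs(t, yy):
            d, *_ = net.derivs(yy, ca, casr, cam, mg)
            return d

        sol = solve_ivp(rhs, (0.0, 1.0), y, method="BDF", rtol=1e-10,
                        atol=1e-13)
        got_tn = sol.y[SPECIES.index("tn1"), -1]
        got_dye = sol.y[SPECIES.index("ca_dye"), -1]
        assert got_tn == pytest.approx(tn, rel=1e-4)
        assert got_dye == pytest.approx(dye, rel=1e-4)

    def test_site_and_mg_conservation_along_trajectory(self, presets):
        """Site totals and the Mg pool are conserved to 1e-9 relative when
        the pure reaction network evolves with free ions held fixed."""
        from scipy.integrate import solve_ivp
        net = network(presets, "IIB")
        eq = net.equilibrium(0.106, 1010.0, 0.05, 780.0)
        y0 = eq.as_array()
        y0[SPECIES.index("ca_pv")] *= 0.5

        def rhs(t, y):
            d, *_ = net.derivs(y, 5.0, 900.0, 0.1, 780.0)
            return d

        sol = solve_ivp(rhs, (0.0, 50.0), y0, method="BDF", rtol=1e-10,
                        atol=1e-12)
        pv = sol.y[SPECIES.index("ca_pv")] + sol.y[SPECIES.index("mg_pv")]
        assert np.all(pv <= net.pv_total * (1 + 1e-9))

    def test_negative_state_rejected(self, presets):
        net = network(presets, "I")
        st = net.equilibrium(0.106, 1140.0, 0.05, 780.0)
        bad = st.as_array()
        bad[0] = -1.0
        with pytest.raises(ValueError):
            reaction_rates(BoundState.from_array(bad, 780.0),
                           (0.106, 1140.0, 0.05),
                           rescale_myofibrillar(build_specs(presets["I"]),
                                                presets["I"]))


class TestMyofibrillarRescale:
    def test_fast_fiber_arithmetic(self, presets):
        """240 uM of fast troponin sites rescale by 0.75/0.856."""
        p = presets["IIB"]
        specs = rescale_myofibrillar(build_specs(p), p)
        tn = next(s for s in specs if s.name == "tn")
        # two-site molecules: (240/2) * 0.75/0.856
        assert 2 * tn.total == pytest.approx(240 * 0.75 / 0.856, rel=1e-6)
        assert tn.myofibrillar_rescale

    def test_slow_fiber_arithmetic(self, presets):
        p = presets["I"]
        specs = rescale_myofibrillar(build_specs(p), p)
        tn = next(s for s in specs if s.name == "tn")
        assert tn.total == pytest.approx(120 * 0.81 / 0.815, rel=1e-6)

    def test_identity_when_ms_fills_sarcoplasm(self, presets):
        from dataclasses import replace
        p = presets["IIB"]
        v = p.volumes
        p_eq = replace(p, volumes=replace(v, v_MS=v.v_sarc))
        specs = rescale_myofibrillar(build_specs(p_eq), p_eq)
        tn = next(s for s in specs if s.name == "tn")
        assert 2 * tn.total == pytest.approx(240.0, rel=1e-12)

    def test_rescale_applies_once(self, presets):
        p = presets["IIB"]
        once = rescale_myofibrillar(build_specs(p), p)
        twice = rescale_myofibrillar(once, p)
        tn1 = next(s for s in once if s.name == "tn")
        tn2 = next(s for s in twice if s.name == "tn")
        assert tn1.total == tn2.total
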