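import math

import numpy as np
import pytest
import sympy as sp

from casim.params import ExchangerParams, HillTransport, SOCEParams
from casim.transport import (PSI_FACTOR, exchanger_flux, mcu_flux,
                             serca_flux, soce_flux)


class TestHillFluxes:
    def test_serca_half_saturation_and_limits(self):
        p = HillTransport(V=2.5, K=0.44, h=2.1)
        assert serca_flux(p.K, p) == pytest.approx(p.V / 2.0)
        assert serca_flux(0.0, p) == 0.0
        assert serca_flux(1e6, p) == pytest.approx(p.V, rel=1e-6)

    def test_serca_saturated_regime_fast_fiber(self):
        """At a fast-fiber peak (16.56 uM) the pump runs essentially at
        capacity."""
        p = HillTransport(V=2.5, K=0.44, h=2.1)
        assert serca_flux(16.56, p) == pytest.approx(2.5, rel=2e-3)

    def test_mcu_half_saturation_and_value(self):
        p = HillTransport(V=74.3e-3, K=1.97, h=3.5)
        assert mcu_flux(p.K, p) == pytest.approx(p.V / 2.0)
        # direct evaluation at 10.31 uM: nearly saturated
        expected = 74.3e-3 / (1.0 + (1.97 / 10.31) ** 3.5)
        assert mcu_flux(10.31, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(74.0e-3, rel=5e-3)

    def test_hill_monotonicity(self):
        p = HillTransport(V=1.0, K=1.0, h=2.0)
        c = np.linspace(0.0, 10.0, 101)
        f = np.array([serca_flux(x, p) for x in c])
        assert np.all(np.diff(f) > 0)

    def test_slow_uniporter_outruns_fast_at_equal_calcium(self):
        slow = HillTransport(V=74.3e-3, K=1.97, h=3.5)
        fast = HillTransport(V=18.2e-3, K=1.2, h=2.0)
        for c in (2.0, 5.0, 10.0):
            assert mcu_flux(c, slow) > mcu_flux(c, fast)


class TestSOCE:
    P = SOCEParams(V=35e-3, K=350.0, h=4.7)

    def test_half_activation(self):
        assert soce_flux(350.0, self.P) == pytest.approx(self.P.V / 2.0)

    def test_resting_store_nearly_silent(self):
        """At the fast-fiber resting SR load the open probability is below
        1%."""
        frac = soce_flux(1010.0, self.P) / self.P.V
        assert frac == pytest.approx(1.0 / (1.0 + (1010.0 / 350.0) ** 4.7),
                                     rel=1e-12)
        assert frac < 0.01

    def test_empty_store_limit_and_antitone(self):
        assert soce_flux(0.0, self.P) == pytest.approx(self.P.V)
        c = np.linspace(0.0, 2000.0, 50)
        f = [soce_flux(x, self.P) for x in c]
        assert all(a > b for a, b in zip(f, f[1:]))


NCX = ExchangerParams(V=93.2e-3, K_Ca=130.0, K_Na=11e3, dPsi=80.0)
NCE = ExchangerParams(V=9.19e-3, K_Ca=1.1e3, K_Na=8.2e3, dPsi=190.0)


class TestExchanger:
    def test_zero_potential_equilibrium(self):
        k = ExchangerParams(V=1.0, K_Ca=100.0, K_Na=1e4, dPsi=0.0)
        # Na_out^3 Ca_in = Na_in^3 Ca_out  ->  zero flux
        # here (2e4)^3 * 1 = (1e4)^3 * 8
        assert exchanger_flux(1.0, 8.0, 1e4, 2e4, k) == pytest.approx(0.0,
                                                                      abs=1e-15)

    def test_linear_in_capacity(self):
        args = (0.5, 1000.0, 1e4, 1.4e5)
        f1 = exchanger_flux(*args, NCX)
        f2 = exchanger_flux(*args, ExchangerParams(V=2 * NCX.V,
                                                   K_Ca=NCX.K_Ca,
                                                   K_Na=NCX.K_Na,
                                                   dPsi=NCX.dPsi))
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)

    def test_ncx_near_zero_at_rest_strong_at_peak(self):
        """With physiologic gradients the sarcolemmal exchanger barely
        moves Ca2+ at rest but extrudes strongly at a 16 uM peak."""
        rest = exchanger_flux(0.106, 1000.0, 10e3, 140e3, NCX)
        peak = exchanger_flux(16.0, 1000.0, 10e3, 140e3, NCX)
        assert peak > 0.0
        assert abs(rest) < 0.02 * peak

    def test_matches_sympy_rederivation(self):
        """The implementation agrees with an independent symbolic
        re-derivation of the electrogenic 3:1 exchanger at 100 random
        states to 1e-10 relative."""
        ci, co, ni, no, V, KC, KN, psi = sp.symbols(
            "ci co ni no V KC KN psi", positive=True)
        ep = sp.exp(sp.Rational(1, 2) * psi * PSI_FACTOR)
        num = (ep * (no / KN) ** 3 * (ci / KC)
               - (no * 0 + 1) / ep * (ni / KN) ** 3 * (co / KC))
        den = (1 + (no / KN) ** 3 + ci / KC + (no / KN) ** 3 * ci / KC
               + (ni / KN) ** 3 + co / KC + (ni / KN) ** 3 * co / KC)
        expr = sp.lambdify((ci, co, ni, no, V, KC, KN, psi),
                           V * num / den, "numpy")
        rng = np.random.default_rng(7)
        for _ in range(100):
            ci_, co_ = rng.uniform(1e-3, 2e3, 2)
            ni_, no_ = rng.uniform(1e3, 2e5, 2)
            k = NCE if rng.random() < 0.5 else NCX
            ours = exchanger_flux(ci_, co_, ni_, no_, k)
            ref = expr(ci_, co_, ni_, no_, k.V, k.K_Ca, k.K_Na, k.dPsi)
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_hill_fluxes_match_sympy(self):
        """Hill-type pump and SOCE gating agree with symbolic forms."""
        c, V, K, h = sp.symbols("c V K h", positive=True)
        hill = sp.lambdify((c, V, K, h), V * c**h / (c**h + K**h))
        soce = sp.lambdify((c, V, K, h), V * K**h / (c**h + K**h))
        rng = np.random.default_rng(11)
        p = HillTransport(V=2.5, K=0.44, h=2.1)
        s = SOCEParams(V=35e-3, K=350.0, h=4.7)
        for _ in range(100):
            x = rng.uniform(1e-4, 50.0)
            assert serca_flux(x, p) == pytest.approx(
                hill(x, p.V, p.K, p.h), rel=1e-10)
            xr = rng.uniform(1.0, 2000.0)
            assert soce_flux(xr, s) == pytest.approx(
                soce(xr, s.V, s.K, s.h), rel=1e-10)
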