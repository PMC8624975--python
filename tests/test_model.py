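import numpy as np
import pytest
from dataclasses import replace

from casim.model import (IDX, ModelSystem, N_STATE, conservation_audit,
                         magnesium_audit)
from casim.params import load_preset
from casim.release import ReleaseWaveform

QUIET = ReleaseWaveform(R=(1e-30,), T1=(5.0,), tau=(1.0,))


class TestRestingState:
    def test_rhs_vanishes_at_rest(self, presets, waveforms):
        """All physical state derivatives are zero at the constructed
        resting state (ledgers integrate their resting fluxes by design)."""
        for ft, p in presets.items():
            sys_ = ModelSystem(p, QUIET)
            dy = sys_.rhs(0.0, sys_.y0)
            # float floor: the CSQ step cancels two ~2e4 uM/ms gross rates,
            # so 1e-12 relative to that scale is the attainable zero
            gross = (sys_.network.csq_kon * sys_.y0[1]
                     * sys_.network.csq_total)
            assert np.max(np.abs(dy[:15])) < max(1e-12, 1e-12 * gross)

    def test_resting_values_from_presets(self, presets):
        sys_I = ModelSystem(presets["I"], QUIET)
        assert sys_I.y0[IDX["ca_sr"]] == pytest.approx(1140.0)
        for ft, p in presets.items():
            s = ModelSystem(p, QUIET)
            assert s.y0[IDX["ca_sarc"]] == pytest.approx(0.106)

    def test_mito_rest_balances_uniporter_and_exchanger(self, presets):
        from casim.transport import exchanger_flux, mcu_flux
        p = presets["I"]
        s = ModelSystem(p, QUIET)
        influx = mcu_flux(0.106, p.mcu)
        efflux = exchanger_flux(s.ca_mito_rest, 0.106, p.resting.Na_mito,
                                p.resting.Na_sarc, p.nce)
        assert efflux == pytest.approx(influx, rel=1e-9)

    def test_leak_report_fields(self, presets):
        rep = ModelSystem(presets["IIB"], QUIET).leak_report()
        assert rep["leak_SR_to_sarc_uM_per_ms"] > 0.0
        assert rep["ca_mito_rest_uM"] > 0.0


class TestRHS:
    def test_reduces_to_release_without_transport_and_buffers(self, presets,
                                                              waveforms):
        """With all transport capacities negligible and every buffer total
        (but a trace of dye) removed, the sarcoplasmic derivative equals
        the release flux."""
        p = load_preset("IIB", overrides={
            "V_SERCA": 1e-30, "V_MCU": 1e-30, "V_NCE": 1e-30,
            "V_NCX": 1e-30, "V_SOCE": 1e-30,
            "Tn_T": 1e-30, "TNS_T": 1e-30, "PV_T": 1e-30, "ATP_T": 1e-30,
            "CSQ_T": 1e-30, "B_T": 1e-30, "Dye_T": 1e-30})
        w = waveforms["IIB"]
        sys_ = ModelSystem(p, w)
        t = 3.0
        dy = sys_.rhs(t, sys_.y0)
        assert dy[IDX["ca_sarc"]] == pytest.approx(sys_.jrel(t), rel=1e-9)

    def test_total_calcium_derivative_cancels(self, presets, waveforms):
        """d(total Ca)/dt vanishes analytically; verified numerically at
        random perturbed states."""
        p = presets["IIB"]
        sys_ = ModelSystem(p, waveforms["IIB"])
        rng = np.random.default_rng(3)
        for _ in range(100):
            y = sys_.y0.copy()
            y[0] = rng.uniform(0.05, 20.0)
            y[1] *= rng.uniform(0.5, 1.0)
            y[2] = rng.uniform(0.01, 1.0)
            y[4:15] *= rng.uniform(0.5, 1.0, 11)
            t = rng.uniform(0.0, 50.0)
            dy = sys_.rhs(t, y)
            i = IDX
            d_tot = (dy[i["ca_sarc"]] + dy[i["tn1"]] + 2 * dy[i["tn2"]]
                     + dy[i["ca_tns"]] + dy[i["ca_pv"]] + dy[i["ca_atp"]]
                     + dy[i["ca_dye"]]
                     + (dy[i["ca_sr"]] + dy[i["ca_csq"]]) / sys_.r_sr
                     + (dy[i["ca_mito"]] + dy[i["ca_b"]]) / sys_.r_mito
                     + dy[i["led_ncx"]] - dy[i["led_soce"]] - sys_.leak_sl)
            assert abs(d_tot) < 1e-9

    def test_volume_ratio_consistency(self, presets, waveforms):
        """Doubling the SR volume fraction halves the SR-referenced
        concentration change produced by the same sarcoplasmic flux."""
        p = presets["IIB"]
        v = p.volumes
        p2 = replace(p, volumes=replace(v, v_SR=2 * v.v_SR))
        s1 = ModelSystem(p, waveforms["IIB"])
        s2 = ModelSystem(p2, waveforms["IIB"])
        t = 3.0
        d1 = s1.rhs(t, s1.y0)[IDX["ca_sr"]]
        d2 = s2.rhs(t, s2.y0)[IDX["ca_sr"]]
        # compare the release term dominating at t=3 ms; the CSQ reaction
        # term is zero at rest in both systems
        assert d2 / d1 == pytest.approx(s2.r_sr / s1.r_sr, rel=1e-6)


class TestConservationAudit:
    def test_zero_flux_rest_run(self, presets):
        from casim.simulate import Protocol, run
        res = run(presets["I"], QUIET,
                  Protocol(name="rest", t_end=100.0))
        assert res.conservation < 1e-9
        assert np.max(np.abs(res["ca_sarc"] - 0.106)) < 1e-9

    def test_misscaled_volume_ratio_detected(self, presets, waveforms,
                                             single_runs):
        """A deliberately mis-scaled SR volume ratio in the audit breaks
        the balance by far more than the acceptance threshold."""
        res = single_runs["IIB"]
        good = conservation_audit(res.system, res.t, res.y)
        assert good < 1e-6
        broken = ModelSystem(res.params, res.waveform)
        broken.r_sr = res.system.r_sr * 2.0
        bad = conservation_audit(broken, res.t, res.y)
        assert bad > 1.0

    def test_magnesium_conserved(self, single_runs):
        for res in single_runs.values():
            assert res.mg_conservation < 1e-9 * 3300.0
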