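"""Full multi-compartment ODE system and its conservation audit.

State vector (uM, ms):

====  ==========================================================
0     free Ca2+, sarcoplasm
1     free Ca2+, SR (SR-volume referenced)
2     free Ca2+, mitochondrial matrix (matrix referenced)
3     free Mg2+, sarcoplasm
4-14  bound species in :data:`casim.reactions.SPECIES` order
15    cumulative released Ca2+ (integral of J_Rel)
16    cumulative SERCA-pumped Ca2+
17    cumulative NCX-extruded Ca2+ (net, signed)
18    cumulative SOCE-entered Ca2+
====  ==========================================================

Fluxes that cross a compartment boundary are stated per sarcoplasmic water
volume and converted with the volume ratios v_sarc/v_SR and v_sarc/v_mito
when applied to the SR and matrix states, so that total calcium --
sarcoplasmic free plus bound, SR and matrix pools divided by their volume
ratios, plus the net amount exported across the sarcolemma -- is conserved
exactly by construction.  The MCU and NCE maximum rates refer to the matrix
volume (they were estimated from matrix Ca2+ dynamics), so the matrix
equation applies them directly and the sarcoplasm sees them divided by the
volume ratio.

At rest SERCA and NCX are not silent, so the raw equations would drift.
Two constant compensatory leaks, sized once at initialization, hold the
resting state exactly stationary: an SR-to-sarcoplasm leak equal to the
resting SERCA flux, and a sarcolemmal inward leak equal to resting NCX
minus resting SOCE.  The resting matrix Ca2+ is set where MCU influx
balances NCE efflux, so no mitochondrial leak is needed.  The leak sizes
are reported by :meth:`ModelSystem.leak_report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import FiberParams
from .reactions import (ReactionNetwork, build_specs, rescale_myofibrillar,
                        SPECIES)
from .release import ReleaseWaveform
from .transport import exchanger_flux, mcu_flux, serca_flux, soce_flux

__all__ = ["IDX", "N_STATE", "ModelSystem", "conservation_audit",
           "magnesium_audit"]

IDX = {"ca_sarc": 0, "ca_sr": 1, "ca_mito": 2, "mg_free": 3,
       **{name: 4 + i for i, name in enumerate(SPECIES)},
       "led_rel": 15, "led_serca": 16, "led_ncx": 17, "led_soce": 18}
N_STATE = 19


class FluxDiagnosticError(RuntimeError):
    """A non-finite derivative, annotated with the offending flux."""


@dataclass(frozen=True)
class FluxSet:
    """Instantaneous transport fluxes (uM/ms).

    ``j_serca``, ``j_ncx``, ``j_soce`` are sarcoplasm-referenced;
    ``j_mcu`` and ``j_nce`` are matrix-referenced.  Positive directions:
    SERCA sarcoplasm->SR, MCU sarcoplasm->matrix, NCE matrix->sarcoplasm,
    NCX sarcoplasm->extracellular, SOCE extracellular->sarcoplasm.
    """

    j_rel: float
    j_serca: float
    j_ncx: float
    j_soce: float
    j_mcu: float
    j_nce: float


class ModelSystem:
    """Assembled right-hand side for one fiber type and release waveform."""

    def __init__(self, params: FiberParams, waveform: ReleaseWaveform):
        self.params = params
        self.waveform = waveform
        specs = rescale_myofibrillar(build_specs(params), params)
        self.network = ReactionNetwork(specs)
        v = params.volumes
        self.r_sr = v.ratio_sarc_to_SR
        self.r_mito = v.ratio_sarc_to_mito
        rest = params.resting
        self.na_sarc = rest.Na_sarc
        self.na_mito = rest.Na_mito
        self.na_extra = rest.Na_extra
        self.ca_extra = rest.Ca_extra
        # release waveform unpacked for the scalar hot path
        self._gauss = [(R, T1, tau) for R, T1, tau
                       in zip(waveform.R, waveform.T1, waveform.tau)]
        self._f_rel = waveform.f_rel
        self._T2 = waveform.T2
        self._init_resting()

    # -- resting state -----------------------------------------------------
    def _resting_mito_ca(self, ca_rest: float) -> float:
        """Matrix Ca2+ at which NCE efflux equals resting MCU influx."""
        target = mcu_flux(ca_rest, self.params.mcu)

        def g(c):
            return exchanger_flux(c, ca_rest, self.na_mito, self.na_sarc,
                                  self.params.nce) - target

        lo, hi = 1e-12, 1e4
        return brentq(g, lo, hi, xtol=1e-15, rtol=1e-14)

    def _init_resting(self) -> None:
        p = self.params
        ca0 = p.resting.Ca_sarc_rest
        casr0 = p.resting.Ca_SR_rest
        mg0 = p.resting.Mg_free_rest
        cam0 = self._resting_mito_ca(ca0)
        bound0 = self.network.equilibrium(ca0, casr0, cam0, mg0)
        # compensatory leaks: stationary rest by construction
        self.leak_sr = serca_flux(ca0, p.serca)
        ncx0 = exchanger_flux(ca0, self.ca_extra, self.na_sarc,
                              self.na_extra, p.ncx)
        soce0 = soce_flux(casr0, p.soce)
        self.leak_sl = ncx0 - soce0
        self.rest_fluxes = FluxSet(j_rel=0.0, j_serca=self.leak_sr,
                                   j_ncx=ncx0, j_soce=soce0,
                                   j_mcu=mcu_flux(ca0, p.mcu),
                                   j_nce=mcu_flux(ca0, p.mcu))
        y0 = np.zeros(N_STATE)
        y0[0], y0[1], y0[2], y0[3] = ca0, casr0, cam0, mg0
        y0[4:15] = bound0.as_array()
        self.y0 = y0
        self.ca_mito_rest = cam0

    def leak_report(self) -> dict:
        """Sizes of the compensatory leaks and the resting matrix Ca2+."""
        return {"leak_SR_to_sarc_uM_per_ms": self.leak_sr,
                "leak_sarcolemmal_in_uM_per_ms": self.leak_sl,
                "ca_mito_rest_uM": self.ca_mito_rest}

    # -- fluxes ------------------------------------------------------------
    def jrel(self, t: float) -> float:
        """Scalar release flux at time t (ms)."""
        acc = 0.0
        for j, f in enumerate(self._f_rel):
            ts = t - j * self._T2
            for R, T1, tau in self._gauss:
                z = (ts - T1) / tau
                if -6.0 < z < 6.0:
                    acc += f * R * math.exp(-z * z)
        return acc

    def fluxes(self, t: float, y) -> FluxSet:
        p = self.params
        ca, casr, cam = y[0], y[1], y[2]
        return FluxSet(
            j_rel=self.jrel(t),
            j_serca=serca_flux(ca, p.serca),
            j_ncx=exchanger_flux(ca, self.ca_extra, self.na_sarc,
                                 self.na_extra, p.ncx),
            j_soce=soce_flux(casr, p.soce),
            j_mcu=mcu_flux(ca, p.mcu),
            j_nce=exchanger_flux(cam, ca, self.na_mito, self.na_sarc,
                                 p.nce),
        )

    # -- right-hand side ---------------------------------------------------
    def rhs(self, t: float, y) -> np.ndarray:
        p = self.params
        ca, casr, cam, mg = y[0], y[1], y[2], y[3]
        bound = y[4:15]
        d_bound, ca_used_sarc, f_csq, f_b, mg_used = self.network.derivs(
            bound, ca, casr, cam, mg)
        j_rel = self.jrel(t)
        j_serca = serca_flux(ca, p.serca)
        j_ncx = exchanger_flux(ca, self.ca_extra, self.na_sarc,
                               self.na_extra, p.ncx)
        j_soce = soce_flux(casr, p.soce)
        j_mcu = mcu_flux(ca, p.mcu)
        j_nce = exchanger_flux(cam, ca, self.na_mito, self.na_sarc, p.nce)

        dy = np.empty(N_STATE)
        dy[0] = (j_rel - j_serca + self.leak_sr - j_ncx + self.leak_sl
                 + j_soce - (j_mcu - j_nce) / self.r_mito - ca_used_sarc)
        dy[1] = (j_serca - j_rel - self.leak_sr) * self.r_sr - f_csq
        dy[2] = j_mcu - j_nce - f_b
        dy[3] = -mg_used
        dy[4:15] = d_bound
        dy[15] = j_rel
        dy[16] = j_serca
        dy[17] = j_ncx
        dy[18] = j_soce
        if not np.all(np.isfinite(dy)):
            self._diagnose(t, y, locals())
        return dy

    def _diagnose(self, t, y, env) -> None:
        names = {"j_rel": env.get("j_rel"), "j_serca": env.get("j_serca"),
                 "j_ncx": env.get("j_ncx"), "j_soce": env.get("j_soce"),
                 "j_mcu": env.get("j_mcu"), "j_nce": env.get("j_nce")}
        bad = [k for k, v in names.items()
               if v is not None and not math.isfinite(v)]
        raise FluxDiagnosticError(
            f"non-finite derivative at t={t:.6g} ms; offending flux(es): "
            f"{bad or 'reaction network'}; state={np.asarray(y)[:4]}")

    def initialize_resting(self) -> np.ndarray:
        """Resting state vector (free concentrations at their stated resting
        values, every bound species at equilibrium, ledgers at zero); the
        right-hand side vanishes there by construction of the leaks."""
        return self.y0.copy()

    # -- conservation ------------------------------------------------------
    def total_calcium(self, t, Y) -> np.ndarray:
        """Sarcoplasm-referenced total Ca2+ of each row of ``Y``: free plus
        bound in the sarcoplasm, the SR and matrix pools divided by their
        volume ratios, plus the net export across the sarcolemma (NCX out
        minus SOCE and leak in)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        i = IDX
        sarc = (Y[:, i["ca_sarc"]] + Y[:, i["tn1"]] + 2.0 * Y[:, i["tn2"]]
                + Y[:, i["ca_tns"]] + Y[:, i["ca_pv"]] + Y[:, i["ca_atp"]]
                + Y[:, i["ca_dye"]])
        sr = (Y[:, i["ca_sr"]] + Y[:, i["ca_csq"]]) / self.r_sr
        mito = (Y[:, i["ca_mito"]] + Y[:, i["ca_b"]]) / self.r_mito
        exported = (Y[:, i["led_ncx"]] - Y[:, i["led_soce"]]
                    - self.leak_sl * t)
        return sarc + sr + mito + exported

    def total_magnesium(self, Y) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        i = IDX
        return (Y[:, i["mg_free"]] + Y[:, i["mg_tns"]] + Y[:, i["mg_pv"]]
                + Y[:, i["mg_atp"]])


def conservation_audit(system: ModelSystem, t, Y) -> float:
    """Maximum absolute deviation of sarcoplasm-referenced total Ca2+ from
    its initial value along a trajectory (uM)."""
    tot = system.total_calcium(t, Y)
    return float(np.max(np.abs(tot - tot[0])))


def magnesium_audit(system: ModelSystem, Y) -> float:
    """Maximum absolute deviation of total Mg2+ (uM) along a trajectory."""
    tot = system.total_magnesium(Y)
    return float(np.max(np.abs(tot - tot[0])))
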