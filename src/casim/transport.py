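"""Carrier, pump and channel fluxes between compartments.

Five transport pathways shape the Ca2+ transient besides the release flux:

* SERCA  -- Hill-type pump, sarcoplasm to SR, saturating in sarcoplasmic Ca2+.
* MCU    -- Hill-type uniporter, sarcoplasm to mitochondria, independent of
            matrix Ca2+; its maximum rate refers to the matrix volume.
* NCE    -- mitochondrial 3 Na+ : 1 Ca2+ exchanger, electrogenic and
            bidirectional, normally extruding Ca2+ from the matrix.
* NCX    -- sarcolemmal exchanger of the same 3:1 form, extruding Ca2+ to
            the extracellular space.
* SOCE   -- store-operated entry, gated open by SR luminal Ca2+ depletion
            through a steeply decreasing Hill function of [Ca2+]_SR.

The two exchangers share one flux expression: a voltage-biased difference of
forward and reverse mass-action terms over a six-term saturation
denominator, positive when Ca2+ leaves the ``in`` side.  At zero membrane
potential the flux vanishes exactly when ``Na_out^3 Ca_in = Na_in^3 Ca_out``.
"""

from __future__ import annotations

import math

from .params import ExchangerParams, HillTransport, SOCEParams

__all__ = [
    "FARADAY", "GAS_CONSTANT", "TEMPERATURE_K", "PSI_FACTOR",
    "serca_flux", "mcu_flux", "exchanger_flux", "soce_flux",
]

FARADAY = 96485.0        # C mol^-1
GAS_CONSTANT = 8.314     # J mol^-1 K^-1
TEMPERATURE_K = 295.15   # 22 C
#: F / (R T) per millivolt
PSI_FACTOR = FARADAY / (GAS_CONSTANT * TEMPERATURE_K * 1e3)


def hill_flux(c: float, p: HillTransport) -> float:
    """V * c^h / (c^h + K^h); monotone in ``c`` and bounded by ``V``."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0.0:
        return 0.0
    ch = c ** p.h
    return p.V * ch / (ch + p.K ** p.h)


def serca_flux(ca_sarc: float, p: HillTransport) -> float:
    """SERCA reuptake flux (uM/ms, sarcoplasm-referenced)."""
    return hill_flux(ca_sarc, p)


def mcu_flux(ca_sarc: float, p: HillTransport) -> float:
    """Mitochondrial uniporter influx (uM/ms, matrix-referenced), a
    saturable function of sarcoplasmic Ca2+ only."""
    return hill_flux(ca_sarc, p)


def exchanger_flux(ca_in: float, ca_out: float, na_in: float, na_out: float,
                   k: ExchangerParams) -> float:
    """Electrogenic 3 Na+ : 1 Ca2+ exchange flux (uM/ms).

    Positive flux extrudes Ca2+ from the ``in`` side (mitochondrial matrix
    for the NCE, sarcoplasm for the NCX).  All concentrations in uM.
    """
    ep = math.exp(0.5 * k.dPsi * PSI_FACTOR)
    rn_out = (na_out / k.K_Na) ** 3
    rn_in = (na_in / k.K_Na) ** 3
    rc_in = ca_in / k.K_Ca
    rc_out = ca_out / k.K_Ca
    num = ep * rn_out * rc_in - (1.0 / ep) * rn_in * rc_out
    den = 1.0 + rn_out + rc_in + rn_out * rc_in + rn_in + rc_out + rn_in * rc_out
    return k.V * num / den


def soce_flux(ca_sr: float, p: SOCEParams) -> float:
    """Store-operated Ca2+ entry (uM/ms, sarcoplasm-referenced).

    The open probability is ``K^h / (ca_sr^h + K^h)``: near zero at resting
    SR load and approaching 1 as the store empties.
    """
    if ca_sr < 0:
        raise ValueError("SR calcium must be non-negative")
    kh = p.K ** p.h
    return p.V * kh / (ca_sr ** p.h + kh)
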