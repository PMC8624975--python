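"""Mass-action network of Ca2+ and Mg2+ binding sites in all compartments.

Sarcoplasm: troponin regulatory sites (two sequential sites with positive
cooperativity in fast fibers, one site in slow fibers), the non-specific
Ca/Mg troponin sites (TNS), parvalbumin (PV, Ca/Mg competition), ATP (Ca
and Mg) and the 2:1 fluorescent dye.  SR: calsequestrin (CSQ).
Mitochondrial matrix: a lumped buffer B.  Every step is a reversible
mass-action reaction; net unbinding of a site S is

    F([Ca2+], S) = k_off [SCa] - k_on [Ca2+] [S]

The dye binds as one elementary step Ca + 2 Dye <-> CaDye2 with rate
``k_on [Ca][Dye]^2 - k_off [CaDye2]``, so its equilibrium constant carries
uM^2 units and matches the in-situ calibration constant.

Troponin and TNS totals are stated per myofibrillar-space water volume and
are rescaled to sarcoplasmic averages by the volume-occupancy factor
v_MS / v_sarc before simulation.

The bound-species state is a fixed-order vector (see :data:`SPECIES`);
:func:`reaction_rates` returns its time derivative together with the net
free-ion consumption per compartment, and :func:`equilibrate` produces the
exact algebraic equilibrium used to initialize resting states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .params import FiberParams

__all__ = [
    "SPECIES", "ReactionSpec", "BoundState", "ReactionNetwork",
    "build_specs", "rescale_myofibrillar", "reaction_rates", "equilibrate",
]

#: Fixed ordering of the bound-species vector.  ``tn1``/``tn2`` are the
#: singly/doubly Ca-occupied troponin molecule concentrations in fast
#: fibers; in slow fibers ``tn1`` is Ca-bound site concentration and
#: ``tn2`` stays zero.  ``ca_dye`` is the CaDye2 complex.
SPECIES = ("tn1", "tn2", "ca_tns", "mg_tns", "ca_pv", "mg_pv",
           "ca_atp", "mg_atp", "ca_dye", "ca_csq", "ca_b")
N_SPECIES = len(SPECIES)


@dataclass(frozen=True)
class ReactionSpec:
    """One reversible binding reaction.

    ``k_on``/``k_off`` hold one pair per step: two pairs for the sequential
    two-site troponin scheme, one otherwise.  ``total`` is the site (or
    molecule) concentration in the home compartment's water volume.
    """

    name: str
    compartment: str            # sarcoplasm | SR | mito
    ligand: str                 # Ca | Mg
    scheme: str                 # single_site | two_site_sequential | two_to_one_dye
    total: float                # uM
    k_on: tuple[float, ...]
    k_off: tuple[float, ...]
    myofibrillar_rescale: bool = False

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError(f"{self.name}: total must be non-negative")
        if any(k <= 0 for k in self.k_on + self.k_off):
            raise ValueError(f"{self.name}: rate constants must be positive")
        npairs = 2 if self.scheme == "two_site_sequential" else 1
        if len(self.k_on) != npairs or len(self.k_off) != npairs:
            raise ValueError(f"{self.name}: scheme needs {npairs} rate pair(s)")


@dataclass(frozen=True)
class BoundState:
    """Bound-species concentrations (uM, home-compartment referenced) plus
    free Mg2+."""

    tn1: float
    tn2: float
    ca_tns: float
    mg_tns: float
    ca_pv: float
    mg_pv: float
    ca_atp: float
    mg_atp: float
    ca_dye: float
    ca_csq: float
    ca_b: float
    mg_free: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES])

    @classmethod
    def from_array(cls, arr: Sequence[float], mg_free: float) -> "BoundState":
        return cls(**dict(zip(SPECIES, map(float, arr))), mg_free=mg_free)


def build_specs(params: FiberParams) -> list[ReactionSpec]:
    """Assemble the reaction list for one fiber type from its parameter set
    (totals as stated, i.e. before myofibrillar rescaling)."""
    r = params.rates
    bt = params.buffer_totals
    fast = params.tn_scheme == "two_site_sequential"
    specs = [
        ReactionSpec(
            name="tn", compartment="sarcoplasm", ligand="Ca",
            scheme="two_site_sequential" if fast else "single_site",
            total=bt.Tn_T / 2.0 if fast else bt.Tn_T,  # molecules if two-site
            k_on=((r["tn_fast_site1"].k_on, r["tn_fast_site2"].k_on)
                  if fast else (r["tn_slow"].k_on,)),
            k_off=((r["tn_fast_site1"].k_off, r["tn_fast_site2"].k_off)
                   if fast else (r["tn_slow"].k_off,)),
            myofibrillar_rescale=False),
        ReactionSpec(name="tns_ca", compartment="sarcoplasm", ligand="Ca",
                     scheme="single_site", total=bt.TNS_T,
                     k_on=(r["tns_ca"].k_on,), k_off=(r["tns_ca"].k_off,)),
        ReactionSpec(name="tns_mg", compartment="sarcoplasm", ligand="Mg",
                     scheme="single_site", total=bt.TNS_T,
                     k_on=(r["tns_mg"].k_on,), k_off=(r["tns_mg"].k_off,)),
        ReactionSpec(name="pv_ca", compartment="sarcoplasm", ligand="Ca",
                     scheme="single_site", total=bt.PV_T,
                     k_on=(r["pv_ca"].k_on,), k_off=(r["pv_ca"].k_off,)),
        ReactionSpec(name="pv_mg", compartment="sarcoplasm", ligand="Mg",
                     scheme="single_site", total=bt.PV_T,
                     k_on=(r["pv_mg"].k_on,), k_off=(r["pv_mg"].k_off,)),
        ReactionSpec(name="atp_ca", compartment="sarcoplasm", ligand="Ca",
                     scheme="single_site", total=bt.ATP_T,
                     k_on=(r["atp_ca"].k_on,), k_off=(r["atp_ca"].k_off,)),
        ReactionSpec(name="atp_mg", compartment="sarcoplasm", ligand="Mg",
                     scheme="single_site", total=bt.ATP_T,
                     k_on=(r["atp_mg"].k_on,), k_off=(r["atp_mg"].k_off,)),
        ReactionSpec(name="dye", compartment="sarcoplasm", ligand="Ca",
                     scheme="two_to_one_dye", total=bt.Dye_T,
                     k_on=(r["dye_ca"].k_on,), k_off=(r["dye_ca"].k_off,)),
        ReactionSpec(name="csq", compartment="SR", ligand="Ca",
                     scheme="single_site", total=bt.CSQ_T,
                     k_on=(r["csq_ca"].k_on,), k_off=(r["csq_ca"].k_off,)),
        ReactionSpec(name="b", compartment="mito", ligand="Ca",
                     scheme="single_site", total=bt.B_T,
                     k_on=(r["b_ca"].k_on,), k_off=(r["b_ca"].k_off,)),
    ]
    return specs


def rescale_myofibrillar(specs: Sequence[ReactionSpec],
                         params: FiberParams) -> list[ReactionSpec]:
    """Rescale troponin site totals (Tn, TNS) from myofibrillar-space to
    sarcoplasm-average concentrations by v_MS / v_sarc."""
    factor = params.volumes.v_MS / params.volumes.v_sarc
    out = []
    for s in specs:
        if s.name in ("tn", "tns_ca", "tns_mg") and not s.myofibrillar_rescale:
            out.append(replace(s, total=s.total * factor,
                               myofibrillar_rescale=True))
        else:
            out.append(s)
    return out


class ReactionNetwork:
    """Unpacked, validated reaction set for fast evaluation inside the ODE
    right-hand side.  Built from a :func:`build_specs` list (normally after
    :func:`rescale_myofibrillar`)."""

    def __init__(self, specs: Sequence[ReactionSpec]):
        by_name = {s.name: s for s in specs}
        tn = by_name["tn"]
        self.tn_fast = tn.scheme == "two_site_sequential"
        self.tn_total = tn.total  # molecules (fast) or sites (slow)
        self.tn_kon1 = tn.k_on[0]
        self.tn_koff1 = tn.k_off[0]
        if self.tn_fast:
            self.tn_kon2 = tn.k_on[1]
            self.tn_koff2 = tn.k_off[1]
        if by_name["tns_ca"].total != by_name["tns_mg"].total:
            raise ValueError("TNS Ca and Mg steps must share one site total")
        if by_name["pv_ca"].total != by_name["pv_mg"].total:
            raise ValueError("PV Ca and Mg steps must share one site total")
        if by_name["atp_ca"].total != by_name["atp_mg"].total:
            raise ValueError("ATP Ca and Mg steps must share one site total")
        self.tns_total = by_name["tns_ca"].total
        self.tns_kon_ca = by_name["tns_ca"].k_on[0]
        self.tns_koff_ca = by_name["tns_ca"].k_off[0]
        self.tns_kon_mg = by_name["tns_mg"].k_on[0]
        self.tns_koff_mg = by_name["tns_mg"].k_off[0]
        self.pv_total = by_name["pv_ca"].total
        self.pv_kon_ca = by_name["pv_ca"].k_on[0]
        self.pv_koff_ca = by_name["pv_ca"].k_off[0]
        self.pv_kon_mg = by_name["pv_mg"].k_on[0]
        self.pv_koff_mg = by_name["pv_mg"].k_off[0]
        self.atp_total = by_name["atp_ca"].total
        self.atp_kon_ca = by_name["atp_ca"].k_on[0]
        self.atp_koff_ca = by_name["atp_ca"].k_off[0]
        self.atp_kon_mg = by_name["atp_mg"].k_on[0]
        self.atp_koff_mg = by_name["atp_mg"].k_off[0]
        self.dye_total = by_name["dye"].total
        self.dye_kon = by_name["dye"].k_on[0]
        self.dye_koff = by_name["dye"].k_off[0]
        self.csq_total = by_name["csq"].total
        self.csq_kon = by_name["csq"].k_on[0]
        self.csq_koff = by_name["csq"].k_off[0]
        self.b_total = by_name["b"].total
        self.b_kon = by_name["b"].k_on[0]
        self.b_koff = by_name["b"].k_off[0]

    # -- kinetics ----------------------------------------------------------
    def derivs(self, bound, ca_sarc: float, ca_sr: float, ca_mito: float,
               mg: float):
        """Time derivatives of the bound-species vector.

        Returns ``(d_bound, ca_used_sarc, ca_used_sr, ca_used_mito,
        mg_used)`` where the ``*_used`` terms are the net free-ion
        consumption rates (uM/ms) in each compartment.
        """
        (tn1, tn2, ca_tns, mg_tns, ca_pv, mg_pv, ca_atp, mg_atp,
         ca_dye, ca_csq, ca_b) = bound
        d = [0.0] * N_SPECIES
        if self.tn_fast:
            t0 = self.tn_total - tn1 - tn2
            f1 = 2.0 * self.tn_kon1 * ca_sarc * t0 - self.tn_koff1 * tn1
            f2 = self.tn_kon2 * ca_sarc * tn1 - 2.0 * self.tn_koff2 * tn2
            d[0] = f1 - f2
            d[1] = f2
            ca_tn_used = f1 + f2
        else:
            f1 = (self.tn_kon1 * ca_sarc * (self.tn_total - tn1)
                  - self.tn_koff1 * tn1)
            d[0] = f1
            ca_tn_used = f1
        tns_free = self.tns_total - ca_tns - mg_tns
        f_tns_ca = self.tns_kon_ca * ca_sarc * tns_free - self.tns_koff_ca * ca_tns
        f_tns_mg = self.tns_kon_mg * mg * tns_free - self.tns_koff_mg * mg_tns
        d[2] = f_tns_ca
        d[3] = f_tns_mg
        pv_free = self.pv_total - ca_pv - mg_pv
        f_pv_ca = self.pv_kon_ca * ca_sarc * pv_free - self.pv_koff_ca * ca_pv
        f_pv_mg = self.pv_kon_mg * mg * pv_free - self.pv_koff_mg * mg_pv
        d[4] = f_pv_ca
        d[5] = f_pv_mg
        atp_free = self.atp_total - ca_atp - mg_atp
        f_atp_ca = self.atp_kon_ca * ca_sarc * atp_free - self.atp_koff_ca * ca_atp
        f_atp_mg = self.atp_kon_mg * mg * atp_free - self.atp_koff_mg * mg_atp
        d[6] = f_atp_ca
        d[7] = f_atp_mg
        dye_free = self.dye_total - 2.0 * ca_dye
        f_dye = self.dye_kon * ca_sarc * dye_free * dye_free - self.dye_koff * ca_dye
        d[8] = f_dye
        f_csq = self.csq_kon * ca_sr * (self.csq_total - ca_csq) - self.csq_koff * ca_csq
        d[9] = f_csq
        f_b = self.b_kon * ca_mito * (self.b_total - ca_b) - self.b_koff * ca_b
        d[10] = f_b
        ca_used_sarc = ca_tn_used + f_tns_ca + f_pv_ca + f_atp_ca + f_dye
        mg_used = f_tns_mg + f_pv_mg + f_atp_mg
        return d, ca_used_sarc, f_csq, f_b, mg_used

    # -- equilibrium -------------------------------------------------------
    def equilibrium(self, ca_sarc: float, ca_sr: float, ca_mito: float,
                    mg: float) -> BoundState:
        """Exact algebraic equilibrium occupancies at the given free
        concentrations (closed forms for every scheme)."""
        if min(ca_sarc, ca_sr, ca_mito, mg) < 0:
            raise ValueError("free concentrations must be non-negative")
        if self.tn_fast:
            k1 = self.tn_koff1 / (2.0 * self.tn_kon1)
            k2 = 2.0 * self.tn_koff2 / self.tn_kon2
            r1 = ca_sarc / k1
            r2 = ca_sarc * ca_sarc / (k1 * k2)
            t0 = self.tn_total / (1.0 + r1 + r2)
            tn1, tn2 = t0 * r1, t0 * r2
        else:
            kd = self.tn_koff1 / self.tn_kon1
            tn1 = self.tn_total * ca_sarc / (ca_sarc + kd)
            tn2 = 0.0

        def compete(total, ca_ratio, mg_ratio):
            den = 1.0 + ca_ratio + mg_ratio
            return total * ca_ratio / den, total * mg_ratio / den

        ca_tns, mg_tns = compete(
            self.tns_total, ca_sarc * self.tns_kon_ca / self.tns_koff_ca,
            mg * self.tns_kon_mg / self.tns_koff_mg)
        ca_pv, mg_pv = compete(
            self.pv_total, ca_sarc * self.pv_kon_ca / self.pv_koff_ca,
            mg * self.pv_kon_mg / self.pv_koff_mg)
        ca_atp, mg_atp = compete(
            self.atp_total, ca_sarc * self.atp_kon_ca / self.atp_koff_ca,
            mg * self.atp_kon_mg / self.atp_koff_mg)
        kd_dye = self.dye_koff / self.dye_kon  # uM^2
        if ca_sarc > 0 and self.dye_total > 0:
            disc = kd_dye * kd_dye + 8.0 * ca_sarc * kd_dye * self.dye_total
            # conjugate form: stable for ca << Kd/D_T (the working regime)
            u = 2.0 * kd_dye * self.dye_total / (kd_dye + math.sqrt(disc))
            ca_dye = 0.5 * (self.dye_total - u)
        else:
            ca_dye = 0.0
        kd_csq = self.csq_koff / self.csq_kon
        ca_csq = self.csq_total * ca_sr / (ca_sr + kd_csq)
        kd_b = self.b_koff / self.b_kon
        ca_b = self.b_total * ca_mito / (ca_mito + kd_b)
        return BoundState(tn1=tn1, tn2=tn2, ca_tns=ca_tns, mg_tns=mg_tns,
                          ca_pv=ca_pv, mg_pv=mg_pv, ca_atp=ca_atp,
                          mg_atp=mg_atp, ca_dye=ca_dye, ca_csq=ca_csq,
                          ca_b=ca_b, mg_free=mg)

    def validate(self, bound) -> None:
        """Raise if a bound-species vector violates site conservation."""
        (tn1, tn2, ca_tns, mg_tns, ca_pv, mg_pv, ca_atp, mg_atp,
         ca_dye, ca_csq, ca_b) = bound
        if min(bound) < 0:
            raise ValueError("negative bound-species concentration")
        checks = [
            (tn1 + tn2, self.tn_total, "troponin"),
            (ca_tns + mg_tns, self.tns_total, "TNS"),
            (ca_pv + mg_pv, self.pv_total, "parvalbumin"),
            (ca_atp + mg_atp, self.atp_total, "ATP"),
            (2.0 * ca_dye, self.dye_total, "dye"),
            (ca_csq, self.csq_total, "calsequestrin"),
            (ca_b, self.b_total, "mito buffer"),
        ]
        for occupied, total, name in checks:
            if occupied > total * (1.0 + 1e-9):
                raise ValueError(f"{name} occupancy exceeds site total")


def _free_ca(free_ca_by_compartment) -> tuple[float, float, float]:
    if isinstance(free_ca_by_compartment, dict):
        return (free_ca_by_compartment["sarcoplasm"],
                free_ca_by_compartment["SR"],
                free_ca_by_compartment["mito"])
    ca_sarc, ca_sr, ca_mito = free_ca_by_compartment
    return ca_sarc, ca_sr, ca_mito


def reaction_rates(state: BoundState, free_ca_by_compartment,
                   specs: Sequence[ReactionSpec]):
    """Net time derivatives of every bound species plus the free-ion
    consumption per compartment.

    Returns ``(d_state, consumption)`` where ``d_state`` maps species names
    to uM/ms and ``consumption`` holds the net free Ca2+ uptake in the
    sarcoplasm, SR and mitochondria and the net free Mg2+ uptake.
    """
    net = specs if isinstance(specs, ReactionNetwork) else ReactionNetwork(specs)
    bound = state.as_array()
    net.validate(bound)
    ca_sarc, ca_sr, ca_mito = _free_ca(free_ca_by_compartment)
    if min(ca_sarc, ca_sr, ca_mito, state.mg_free) < 0:
        raise ValueError("negative free-ion concentration")
    d, ca_s, ca_r, ca_m, mg_used = net.derivs(bound, ca_sarc, ca_sr,
                                              ca_mito, state.mg_free)
    return (dict(zip(SPECIES, d)),
            {"sarcoplasm": ca_s, "SR": ca_r, "mito": ca_m, "Mg": mg_used})


def equilibrate(specs: Sequence[ReactionSpec], free_ca_by_compartment,
                free_mg: float) -> BoundState:
    """Equilibrium bound state at given free Ca2+ (per compartment) and free
    Mg2+; all reaction rates vanish there."""
    net = specs if isinstance(specs, ReactionNetwork) else ReactionNetwork(specs)
    ca_sarc, ca_sr, ca_mito = _free_ca(free_ca_by_compartment)
    if min(ca_sarc, ca_sr, ca_mito) < 0 or free_mg <= 0:
        raise ValueError("free concentrations must be positive")
    return net.equilibrium(ca_sarc, ca_sr, ca_mito, free_mg)
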