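"""Typed registry of model parameters for the four muscle fiber types.

Every number the simulator consumes lives in one of three data files shipped
with the package: a per-fiber-type preset (volumes, resting concentrations,
buffer totals, transport constants), a shared table of mass-action rate
constants with per-entry provenance, and the release-waveform kinetic
targets.  This module loads those files, converts them to a single internal
unit system (micromolar, millisecond, millivolt) and exposes them as frozen
dataclasses.

Rate constants stated at a different reference temperature are brought to
the working temperature with a Q10 factor applied equally to ``k_on`` and
``k_off`` (dissociation constants are therefore temperature-invariant);
transporter maximum rates are scaled the same way while their ``K`` and
Hill coefficients are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "FiberType",
    "RateConstant",
    "Volumes",
    "RestingState",
    "BufferTotals",
    "HillTransport",
    "ExchangerParams",
    "SOCEParams",
    "FiberParams",
    "ReleaseKinetics",
    "load_preset",
    "load_release_kinetics",
    "adjust_rates_q10",
]

# conversion factors into the internal uM / ms / mV system
_UNIT_TO_INTERNAL = {
    "uM": 1.0,
    "nM": 1e-3,
    "mM": 1e3,
    "uM/ms": 1.0,
    "uM/s": 1e-3,
    "mV": 1.0,
}


class FiberType(str, Enum):
    """The continuum of mouse fiber types, slow-oxidative to fast-glycolytic."""

    I = "I"
    IIA = "IIA"
    IIX = "IIX"
    IIB = "IIB"

    @property
    def is_fast(self) -> bool:
        return self is not FiberType.I


def _q(raw: Any) -> float:
    """Convert a ``{value, unit}`` mapping (or bare number in uM/ms/mV) to
    internal units."""
    if isinstance(raw, Mapping):
        unit = raw["unit"]
        if unit not in _UNIT_TO_INTERNAL:
            raise ValueError(f"unknown unit {unit!r}")
        return float(raw["value"]) * _UNIT_TO_INTERNAL[unit]
    return float(raw)


@dataclass(frozen=True)
class RateConstant:
    """One reversible reaction step.

    ``k_on`` is per-uM per-ms for single-ligand steps and per-uM^2 per-ms
    for the 2:1 dye step (``order == 2``); ``k_off`` is per-ms.  ``Kd`` is
    ``k_off / k_on`` (uM, or uM^2 for the dye).
    """

    name: str
    ligand: str  # "Ca" or "Mg"
    order: int
    k_on: float
    k_off: float
    ref_temp_C: float
    source: str = ""

    @property
    def Kd(self) -> float:
        return self.k_off / self.k_on

    def at_temperature(self, target_C: float, q10: float) -> "RateConstant":
        f = q10 ** ((target_C - self.ref_temp_C) / 10.0)
        return replace(self, k_on=self.k_on * f, k_off=self.k_off * f,
                       ref_temp_C=target_C)


@dataclass(frozen=True)
class Volumes:
    """Compartment volume fractions of total fiber volume.

    ``v_sarc`` is the remainder ``1 - v_SR - v_ttub - v_mito``.
    """

    v_SR: float
    v_ttub: float
    v_mito: float
    v_MS: float

    @property
    def v_sarc(self) -> float:
        return 1.0 - self.v_SR - self.v_ttub - self.v_mito

    @property
    def ratio_sarc_to_SR(self) -> float:
        return self.v_sarc / self.v_SR

    @property
    def ratio_sarc_to_mito(self) -> float:
        return self.v_sarc / self.v_mito


@dataclass(frozen=True)
class RestingState:
    """Resting free concentrations and fixed ionic milieu (uM)."""

    Ca_sarc_rest: float
    Ca_SR_rest: float
    Mg_free_rest: float
    Mg_total: float
    Na_sarc: float
    Na_mito: float
    Na_extra: float
    Ca_extra: float


@dataclass(frozen=True)
class BufferTotals:
    """Total site concentrations (uM), each referenced to the water volume
    of its home compartment (CSQ: SR; B: mitochondria; the rest:
    sarcoplasm)."""

    Tn_T: float
    TNS_T: float
    PV_T: float
    ATP_T: float
    CSQ_T: float
    B_T: float
    Dye_T: float


@dataclass(frozen=True)
class HillTransport:
    """Saturable Hill-type transporter (SERCA, MCU)."""

    V: float  # uM/ms
    K: float  # uM
    h: float


@dataclass(frozen=True)
class ExchangerParams:
    """Electrogenic 3 Na+ : 1 Ca2+ exchanger (NCE, NCX)."""

    V: float      # uM/ms
    K_Ca: float   # uM
    K_Na: float   # uM
    dPsi: float   # mV


@dataclass(frozen=True)
class SOCEParams:
    """Store-operated Ca2+ entry gated by SR luminal Ca2+."""

    V: float   # uM/ms
    K: float   # uM (SR free Ca2+ at half activation)
    h: float


@dataclass(frozen=True)
class FiberParams:
    """Complete parameter set for one fiber type, in internal units."""

    fiber_type: FiberType
    volumes: Volumes
    resting: RestingState
    buffer_totals: BufferTotals
    serca: HillTransport
    mcu: HillTransport
    nce: ExchangerParams
    ncx: ExchangerParams
    soce: SOCEParams
    rates: dict[str, RateConstant] = field(repr=False)
    tn_scheme: str = "two_site_sequential"
    temperature_C: float = 22.0

    def __post_init__(self) -> None:
        v = self.volumes
        if not (0 < v.v_SR and 0 < v.v_ttub and 0 < v.v_mito and 0 < v.v_sarc):
            raise ValueError("volume fractions must be positive and sum below 1")
        for name in ("Tn_T", "TNS_T", "PV_T", "ATP_T", "CSQ_T", "B_T", "Dye_T"):
            if getattr(self.buffer_totals, name) < 0:
                raise ValueError(f"buffer total {name} must be non-negative")
        for t in (self.serca, self.mcu):
            if t.V <= 0 or t.K <= 0 or t.h < 1:
                raise ValueError("Hill transporter requires V,K > 0 and h >= 1")
        if self.soce.V <= 0 or self.soce.K <= 0 or self.soce.h < 1:
            raise ValueError("SOCE requires V,K > 0 and h >= 1")
        for x in (self.nce, self.ncx):
            if min(x.V, x.K_Ca, x.K_Na) <= 0:
                raise ValueError("exchanger constants must be positive")
        for r in self.rates.values():
            if r.k_on <= 0 or r.k_off <= 0:
                raise ValueError(f"rate constants for {r.name} must be positive")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["fiber_type"] = self.fiber_type.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FiberParams":
        d = dict(d)
        d["fiber_type"] = FiberType(d["fiber_type"])
        d["volumes"] = Volumes(**d["volumes"])
        d["resting"] = RestingState(**d["resting"])
        d["buffer_totals"] = BufferTotals(**d["buffer_totals"])
        d["serca"] = HillTransport(**d["serca"])
        d["mcu"] = HillTransport(**d["mcu"])
        d["nce"] = ExchangerParams(**d["nce"])
        d["ncx"] = ExchangerParams(**d["ncx"])
        d["soce"] = SOCEParams(**d["soce"])
        d["rates"] = {k: RateConstant(**v) for k, v in d["rates"].items()}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "FiberParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ReleaseKinetics:
    """Scalar targets describing the release flux of one fiber type.

    ``integral`` is the single-AP released amount (uM, sarcoplasm
    referenced) used as an optional fifth fitting target; ``f_rel`` scales
    the amplitude of APs 2..M in a train (first entry 1.0); ``T2`` is the
    inter-stimulus interval of the 100 Hz train.
    """

    fiber_type: FiberType
    peak_amplitude: float  # uM/ms
    rise_10_90: float      # ms
    half_width: float      # ms
    decay_90_10: float     # ms
    f_rel: tuple[float, ...] = (1.0,)
    T2: float = 10.0
    integral: float | None = None

    def __post_init__(self) -> None:
        if self.f_rel[0] != 1.0:
            raise ValueError("first action potential is unscaled: f_rel[0] must be 1")
        if any(not (0 < f <= 1) for f in self.f_rel[1:]):
            raise ValueError("f_rel entries after the first must lie in (0, 1]")
        for name in ("peak_amplitude", "rise_10_90", "half_width",
                     "decay_90_10", "T2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("casim.data").joinpath(name).read_text()


def _load_rates() -> dict[str, RateConstant]:
    raw = yaml.safe_load(_data_text("rates.yaml"))
    return {
        name: RateConstant(
            name=name,
            ligand=e["ligand"],
            order=int(e.get("order", 1)),
            k_on=float(e["k_on"]),
            k_off=float(e["k_off"]),
            ref_temp_C=float(e["ref_temp_C"]),
            source=e.get("source", ""),
        )
        for name, e in raw.items()
    }


_OVERRIDE_GROUPS = {
    "buffer_totals": BufferTotals,
    "resting": RestingState,
    "volumes": Volumes,
}
_TRANSPORT_FIELD = {
    "V_SERCA": ("serca", "V"), "K_SERCA": ("serca", "K"), "h_SERCA": ("serca", "h"),
    "V_MCU": ("mcu", "V"), "K_MCU": ("mcu", "K"), "h_MCU": ("mcu", "h"),
    "V_NCE": ("nce", "V"), "K_NCE_Ca": ("nce", "K_Ca"), "K_NCE_Na": ("nce", "K_Na"),
    "dPsi_mito": ("nce", "dPsi"),
    "V_NCX": ("ncx", "V"), "K_NCX_Ca": ("ncx", "K_Ca"), "K_NCX_Na": ("ncx", "K_Na"),
    "dPsi_m": ("ncx", "dPsi"),
    "V_SOCE": ("soce", "V"), "K_SOCE": ("soce", "K"), "h_SOCE": ("soce", "h"),
}


def _apply_override(p: FiberParams, key: str, value: float) -> FiberParams:
    """Resolve a flat or dotted override key against the parameter tree."""
    if "." in key:
        group, key = key.split(".", 1)
        sub = getattr(p, group)
        if not hasattr(sub, key):
            raise KeyError(f"unknown override key {group}.{key}")
        return replace(p, **{group: replace(sub, **{key: float(value)})})
    for group_name in ("buffer_totals", "resting", "volumes"):
        sub = getattr(p, group_name)
        if hasattr(sub, key):
            return replace(p, **{group_name: replace(sub, **{key: float(value)})})
    if key in _TRANSPORT_FIELD:
        group_name, attr = _TRANSPORT_FIELD[key]
        sub = getattr(p, group_name)
        return replace(p, **{group_name: replace(sub, **{attr: float(value)})})
    raise KeyError(f"unknown override key {key!r}")


def load_preset(
    fiber_type: FiberType | str,
    overrides: Mapping[str, float] | None = None,
    temperature_C: float = 22.0,
    q10: float = 2.0,
) -> FiberParams:
    """Load the full parameter set for one fiber type.

    Parameters
    ----------
    fiber_type
        One of ``I``, ``IIA``, ``IIX``, ``IIB``.
    overrides
        Optional mapping of field names (flat, e.g. ``"Dye_T"``, or dotted,
        e.g. ``"mcu.V"``) to replacement values in internal units; applied
        after everything else.
    temperature_C, q10
        Working temperature of the returned set.  Rate constants stored at a
        different reference temperature are Q10-adjusted on load.
    """
    ft = FiberType(fiber_type)
    raw = yaml.safe_load(_data_text(f"fiber_{ft.value}.yaml"))
    vols = raw["volumes"]
    p = FiberParams(
        fiber_type=ft,
        volumes=Volumes(v_SR=float(vols["v_SR"]), v_ttub=float(vols["v_ttub"]),
                        v_mito=float(vols["v_mito"]), v_MS=float(vols["v_MS"])),
        resting=RestingState(**{k: _q(v) for k, v in raw["resting"].items()}),
        buffer_totals=BufferTotals(**{k: _q(v) for k, v in raw["buffer_totals"].items()}),
        serca=HillTransport(V=_q(raw["serca"]["V_SERCA"]), K=_q(raw["serca"]["K_SERCA"]),
                            h=float(raw["serca"]["h_SERCA"])),
        mcu=HillTransport(V=_q(raw["mcu"]["V_MCU"]), K=_q(raw["mcu"]["K_MCU"]),
                          h=float(raw["mcu"]["h_MCU"])),
        nce=ExchangerParams(V=_q(raw["nce"]["V_NCE"]), K_Ca=_q(raw["nce"]["K_NCE_Ca"]),
                            K_Na=_q(raw["nce"]["K_NCE_Na"]), dPsi=_q(raw["nce"]["dPsi_mito"])),
        ncx=ExchangerParams(V=_q(raw["ncx"]["V_NCX"]), K_Ca=_q(raw["ncx"]["K_NCX_Ca"]),
                            K_Na=_q(raw["ncx"]["K_NCX_Na"]), dPsi=_q(raw["ncx"]["dPsi_m"])),
        soce=SOCEParams(V=_q(raw["soce"]["V_SOCE"]), K=_q(raw["soce"]["K_SOCE"]),
                        h=float(raw["soce"]["h_SOCE"])),
        rates=_load_rates(),
        tn_scheme=raw["tn_scheme"],
        temperature_C=float(raw["temperature_C"]),
    )
    if p.temperature_C != temperature_C:
        p = adjust_rates_q10(p, temperature_C, q10)
    else:
        p = replace(p, rates={k: r.at_temperature(temperature_C, q10)
                              for k, r in p.rates.items()})
    if overrides:
        for key, value in overrides.items():
            p = _apply_override(p, key, value)
    return p


def adjust_rates_q10(params: FiberParams, target_temp_C: float,
                     q10: float = 2.0) -> FiberParams:
    """Return a copy of ``params`` with all kinetic rates Q10-adjusted.

    Every mass-action ``k_on``/``k_off`` pair is scaled by
    ``q10**((target - ref)/10)`` from its own reference temperature, and
    every transporter maximum rate from the set's working temperature.
    Dissociation constants, transporter ``K`` values and Hill coefficients
    are temperature-invariant.
    """
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    f = q10 ** ((target_temp_C - params.temperature_C) / 10.0)
    return replace(
        params,
        rates={k: r.at_temperature(target_temp_C, q10) for k, r in params.rates.items()},
        serca=replace(params.serca, V=params.serca.V * f),
        mcu=replace(params.mcu, V=params.mcu.V * f),
        nce=replace(params.nce, V=params.nce.V * f),
        ncx=replace(params.ncx, V=params.ncx.V * f),
        soce=replace(params.soce, V=params.soce.V * f),
        temperature_C=target_temp_C,
    )


def load_release_kinetics(fiber_type: FiberType | str,
                          with_integral_target: bool = True) -> ReleaseKinetics:
    """Release-flux kinetic targets (peak, rise, half-width, decay, per-AP
    scale factors) for one fiber type.

    With ``with_integral_target`` the single-AP released amount is included
    so the waveform fit also pins the time integral of the flux.
    """
    ft = FiberType(fiber_type)
    raw = yaml.safe_load(_data_text("release_kinetics.yaml"))
    row = raw["fibers"][ft.value]
    return ReleaseKinetics(
        fiber_type=ft,
        peak_amplitude=float(row["peak_amplitude"]),
        rise_10_90=float(row["rise_10_90"]),
        half_width=float(row["half_width"]),
        decay_90_10=float(row["decay_90_10"]),
        f_rel=tuple(float(f) for f in row["f_rel"]),
        T2=float(raw["T2_ms"]),
        integral=float(row["integral"]) if with_integral_target else None,
    )
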