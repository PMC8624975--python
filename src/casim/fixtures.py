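"""Synthetic fluorescence-trace generator.

Emulates single-fiber Mag-Fluo-4 recordings of twitch and 100 Hz tetanic
Ca2+ transients without any experimental data: a free-Ca2+ waveform with a
Gaussian rising limb and biexponential decay is shaped so its scalar
metrics match requested targets, mapped through the inverse 2:1 dye
calibration, and overlaid with additive white Gaussian noise (the simplest
defensible detector model; nothing photon-statistical is attempted).

Generation is deterministic given the seed; the noiseless component is
identical across seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .calibration import (DyeCalibration, Trace, ca_to_fluorescence,
                          trace_metrics)

__all__ = ["TraceSpec", "make_trace", "make_ca_waveform"]

#: resting free Ca2+ (uM) used as the baseline of synthesized waveforms
REST_CA = 0.106


@dataclass(frozen=True)
class TraceSpec:
    """Targets and acquisition settings for one synthetic recording.

    ``peak_ca`` is the peak free Ca2+ above rest (uM); rise/half-width/decay
    are the metric targets (ms) of the underlying Ca2+ transient.
    """

    peak_ca: float = 16.58
    rise_10_90: float = 1.5
    half_width: float = 4.0
    decay_90_10: float = 12.0
    n_APs: int = 1
    T2: float = 10.0
    f_rel: tuple[float, ...] | None = None  # per-AP peak scaling, first 1.0
    noise_sd: float = 0.0   # A.U. on the fluorescence
    seed: int = 0
    dt: float = 0.01        # ms
    t_end: float = 100.0    # ms
    calibration: DyeCalibration = field(default_factory=DyeCalibration)

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.dt <= 0 or self.t_end <= 0:
            raise ValueError("need noise_sd >= 0, dt > 0, t_end > 0")
        if self.peak_ca <= 0:
            raise ValueError("peak_ca must be positive")
        if self.f_rel is not None and self.f_rel[0] != 1.0:
            raise ValueError("f_rel[0] must be 1.0")


def _pulse(t: np.ndarray, t0: float, tau_a: float, tau1: float,
           tau2: float, w2: float) -> np.ndarray:
    """Unit-peak pulse starting at ``t0``: a Gaussian activation rising from
    zero multiplied by a biexponential decay, which is smooth everywhere
    (no kink at the maximum)."""
    y = np.zeros_like(t)
    td = t - t0
    up = td >= 0.0
    act = 1.0 - np.exp(-((td[up] / tau_a) ** 2))
    dec = (1.0 - w2) * np.exp(-td[up] / tau1) + w2 * np.exp(-td[up] / tau2)
    y[up] = act * dec
    m = y.max()
    return y / m if m > 0 else y


def _shape_params(spec: TraceSpec) -> tuple[float, float, float, float, float]:
    """Deterministically fit (tau_a, tau1, tau2, w2) so the noiseless pulse
    metrics hit the spec targets.  Cached on the shape-defining fields."""
    return _shape_params_cached(spec.rise_10_90, spec.half_width,
                                spec.decay_90_10, spec.dt, spec.t_end)


@lru_cache(maxsize=64)
def _shape_params_cached(rise_10_90: float, half_width: float,
                         decay_90_10: float, dt: float, t_end: float):
    spec = TraceSpec(rise_10_90=rise_10_90, half_width=half_width,
                     decay_90_10=decay_90_10, dt=dt, t_end=t_end)
    t = np.arange(0.0, spec.t_end, spec.dt)
    t0 = max(2.0, 5.0 * spec.dt)

    def resid(x):
        tau_a, tau1, tau2 = np.exp(x[:3])
        w2 = 1.0 / (1.0 + math.exp(-x[3]))  # logistic keeps w2 in (0, 1)
        y = _pulse(t, t0, tau_a, tau1, tau2, w2)
        try:
            m = trace_metrics(Trace(t=t, y=y, kind="calcium"), baseline=0.0)
        except ValueError:
            return np.full(3, 10.0)
        return np.array([m.rise_10_90 / spec.rise_10_90 - 1.0,
                         m.half_width / spec.half_width - 1.0,
                         m.decay_90_10 / spec.decay_90_10 - 1.0])

    best = None
    for tau1_scale, w2_0 in ((0.5, 0.2), (1.0, 0.1), (0.25, 0.35)):
        x0 = np.array([math.log(spec.rise_10_90),
                       math.log(spec.half_width * tau1_scale),
                       math.log(spec.decay_90_10),
                       math.log(w2_0 / (1.0 - w2_0))])
        sol = least_squares(resid, x0, xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-12:
            break
    tau_a, tau1, tau2 = np.exp(best.x[:3])
    w2 = 1.0 / (1.0 + math.exp(-best.x[3]))
    return t0, tau_a, tau1, tau2, w2


def make_ca_waveform(spec: TraceSpec) -> Trace:
    """Noiseless synthetic free-Ca2+ trace (uM) meeting the spec targets."""
    t0, tau_a, tau1, tau2, w2 = _shape_params(spec)
    t = np.arange(0.0, spec.t_end, spec.dt)
    y = np.zeros_like(t)
    f_rel = spec.f_rel or tuple([1.0] * spec.n_APs)
    for j in range(spec.n_APs):
        f = f_rel[j] if j < len(f_rel) else f_rel[-1]
        y += f * _pulse(t - j * spec.T2, t0, tau_a, tau1, tau2, w2)
    # normalize the summed envelope so the global peak equals peak_ca
    y *= spec.peak_ca / y.max()
    return Trace(t=t, y=REST_CA + y, kind="calcium")


def make_trace(spec: TraceSpec) -> Trace:
    """Synthetic fluorescence recording: the calibrated inverse of the
    synthetic Ca2+ waveform plus additive Gaussian noise (seeded)."""
    ca = make_ca_waveform(spec)
    f = ca_to_fluorescence(ca, spec.calibration)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = Trace(t=f.t, y=f.y + rng.normal(0.0, spec.noise_sd, f.y.size),
                  kind="fluorescence")
    return f
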