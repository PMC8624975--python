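"""Mag-Fluo-4 calibration and scalar kinetics of Ca2+ transients.

Mag-Fluo-4 is a low-affinity, fast Ca2+ indicator that binds with a 2:1
dye:Ca2+ stoichiometry, so its in-situ dissociation constant carries uM^2
units.  Fluorescence F maps to free Ca2+ through

    [Ca2+] = (K_d / D_T) * (F - F_min) * (F_max - F_min) / (F_max - F)^2

which is strictly increasing on [F_min, F_max) and diverges as F approaches
F_max.  The inverse map (used to synthesize fluorescence from a known Ca2+
waveform) follows from the same expression as the root of a quadratic in
(F_max - F).

The module also extracts the scalar metrics used throughout the package to
characterize transients: peak amplitude above baseline, 10-90% rise time,
half-width (time between the two 50%-of-peak crossings) and 90-10% decay
time, all with linear interpolation between bracketing samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DyeCalibration",
    "Trace",
    "TraceMetrics",
    "SaturationError",
    "fluorescence_to_ca",
    "ca_to_fluorescence",
    "trace_metrics",
    "read_trace_csv",
    "write_trace_csv",
]

#: In-situ calibration of Mag-Fluo-4 at 20-22 C (arbitrary fluorescence
#: units; K_d in uM^2 because of the 2:1 stoichiometry; total dye in uM).
DEFAULT_FMAX = 150.9
DEFAULT_FMIN = 0.14
DEFAULT_KD = 1.652e5
DEFAULT_DTOT = 229.1


class SaturationError(ValueError):
    """Fluorescence at or above F_max cannot be inverted."""


@dataclass(frozen=True)
class DyeCalibration:
    """Calibration constants of a 2:1 fluorescent Ca2+ indicator."""

    F_max: float = DEFAULT_FMAX
    F_min: float = DEFAULT_FMIN
    K_d: float = DEFAULT_KD    # uM^2
    D_T: float = DEFAULT_DTOT  # uM

    def __post_init__(self) -> None:
        if not (self.F_max > self.F_min >= 0):
            raise ValueError("need F_max > F_min >= 0")
        if self.K_d <= 0 or self.D_T <= 0:
            raise ValueError("K_d and D_T must be positive")


@dataclass(frozen=True)
class Trace:
    """A sampled time series: fluorescence (A.U.) or free Ca2+ (uM)."""

    t: np.ndarray
    y: np.ndarray
    kind: str = "fluorescence"  # or "calcium"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if self.kind not in ("fluorescence", "calcium"):
            raise ValueError("kind must be 'fluorescence' or 'calcium'")


def fluorescence_to_ca(trace: Trace, cal: DyeCalibration,
                       below_fmin: str = "error") -> Trace:
    """Convert a fluorescence trace to free [Ca2+] (uM).

    Raises :class:`SaturationError` naming the first offending sample if any
    value reaches ``F_max``.  Values below ``F_min`` (negative
    concentration) raise ``ValueError`` by default; with
    ``below_fmin="clip"`` they are clipped to ``F_min`` instead, which is
    the appropriate treatment for noisy recordings whose resting
    fluorescence sits close to ``F_min``.
    """
    if trace.kind != "fluorescence":
        raise ValueError("input trace must be of kind 'fluorescence'")
    F = trace.y
    sat = np.flatnonzero(F >= cal.F_max)
    if sat.size:
        raise SaturationError(
            f"fluorescence saturated (F >= F_max) at sample index {sat[0]}")
    neg = np.flatnonzero(F < cal.F_min)
    if neg.size:
        if below_fmin == "clip":
            F = np.maximum(F, cal.F_min)
        else:
            raise ValueError(
                f"fluorescence below F_min (negative concentration) at "
                f"sample index {neg[0]}")
    span = cal.F_max - cal.F_min
    ca = (cal.K_d / cal.D_T) * (F - cal.F_min) * span / (cal.F_max - F) ** 2
    return Trace(t=trace.t, y=ca, kind="calcium")


def ca_to_fluorescence(trace: Trace, cal: DyeCalibration) -> Trace:
    """Inverse calibration: free [Ca2+] (uM) to fluorescence (A.U.).

    Solving ``c = a (F - F_min) / (F_max - F)^2`` with
    ``a = K_d (F_max - F_min) / D_T`` for ``x = F_max - F`` gives the
    quadratic ``c x^2 + a x - a s = 0`` (``s = F_max - F_min``), whose
    positive root is taken; ``c = 0`` maps to ``F_min`` exactly.
    """
    if trace.kind != "calcium":
        raise ValueError("input trace must be of kind 'calcium'")
    c = trace.y
    if np.any(c < 0):
        raise ValueError("calcium concentrations must be non-negative")
    s = cal.F_max - cal.F_min
    a = cal.K_d * s / cal.D_T
    # conjugate form of the quadratic root: no cancellation for small c,
    # and exact (x = s, F = F_min) at c = 0
    x = 2.0 * a * s / (a + np.sqrt(a * a + 4.0 * c * a * s))
    return Trace(t=trace.t, y=cal.F_max - x, kind="fluorescence")


@dataclass(frozen=True)
class TraceMetrics:
    """Scalar kinetics of a single transient."""

    peak_amplitude: float
    rise_10_90: float
    half_width: float
    decay_90_10: float
    time_to_peak: float
    baseline: float


def _cross_time(t: np.ndarray, y: np.ndarray, level: float,
                i0: int, i1: int, step: int) -> float:
    """Linearly interpolated time at which ``y`` crosses ``level``, scanning
    from index ``i0`` toward ``i1`` in direction ``step``."""
    prev = i0
    for i in range(i0 + step, i1 + step, step):
        ya, yb = y[prev], y[i]
        if (ya - level) * (yb - level) <= 0 and ya != yb:
            frac = (level - ya) / (yb - ya)
            return t[prev] + frac * (t[i] - t[prev])
        prev = i
    raise ValueError(f"level {level:.6g} not crossed within trace")


def trace_metrics(trace: Trace, baseline: float | None = None,
                  baseline_window: float | None = None,
                  smooth_ms: float | None = None) -> TraceMetrics:
    """Extract peak amplitude, 10-90% rise, half-width and 90-10% decay.

    The baseline defaults to the mean of the samples preceding signal onset
    (the pre-stimulus window); pass ``baseline`` to fix it explicitly or
    ``baseline_window`` (ms) to average over a fixed initial interval.
    Level crossings are linearly interpolated between bracketing samples.
    ``smooth_ms`` applies a Savitzky-Golay filter of that window before
    metric extraction (for noisy recordings; leave unset for clean traces).
    """
    t, y = trace.t, trace.y
    if smooth_ms is not None and t.size >= 8:
        from scipy.signal import savgol_filter
        dt = float(np.median(np.diff(t)))
        win = max(5, int(round(smooth_ms / dt)) | 1)  # odd window
        if win < y.size:
            y = savgol_filter(y, win, polyorder=2)
    if t.size < 4:
        raise ValueError("trace too short for kinetic metrics")
    ipk = int(np.argmax(y))
    if baseline is None:
        if baseline_window is not None:
            mask = t <= t[0] + baseline_window
            if not mask.any():
                raise ValueError("empty baseline window")
            baseline = float(np.mean(y[mask]))
        else:
            # pre-onset window: samples before the signal first exceeds 5 %
            # of its range above the early median
            b0 = float(np.median(y[: max(3, t.size // 50)]))
            rng = y[ipk] - b0
            if rng <= 0:
                raise ValueError("flat trace: no peak above baseline")
            onset = np.flatnonzero(y[:ipk] > b0 + 0.05 * rng)
            n = onset[0] if onset.size else max(3, t.size // 50)
            # median: insensitive to sub-threshold rising-limb samples
            baseline = float(np.median(y[: max(n, 1)]))
    amp = float(y[ipk]) - baseline
    if amp <= 0:
        raise ValueError("flat trace: no peak above baseline")
    lv = {f: baseline + f * amp for f in (0.1, 0.5, 0.9)}
    t10r = _cross_time(t, y, lv[0.1], ipk, 0, -1)
    t90r = _cross_time(t, y, lv[0.9], ipk, 0, -1)
    t50r = _cross_time(t, y, lv[0.5], ipk, 0, -1)
    n = y.size - 1
    t90d = _cross_time(t, y, lv[0.9], ipk, n, +1)
    t50d = _cross_time(t, y, lv[0.5], ipk, n, +1)
    t10d = _cross_time(t, y, lv[0.1], ipk, n, +1)
    return TraceMetrics(
        peak_amplitude=amp,
        rise_10_90=t90r - t10r,
        half_width=t50d - t50r,
        decay_90_10=t10d - t90d,
        time_to_peak=float(t[ipk]) - float(t[0]),
        baseline=baseline,
    )


def denoise_trace(trace: Trace, smooth_ms: float = 1.5) -> Trace:
    """Savitzky-Golay smoothing of a trace.

    For noisy fluorescence recordings, smooth *before* calibrating: the
    noise is additive in the fluorescence domain, whereas the calibration
    map amplifies it enormously near the resting level of a low-affinity
    dye.
    """
    t, y = trace.t, trace.y
    if t.size < 8:
        return trace
    from scipy.signal import savgol_filter
    dt = float(np.median(np.diff(t)))
    win = max(5, int(round(smooth_ms / dt)) | 1)
    if win >= y.size:
        return trace
    return Trace(t=t, y=savgol_filter(y, win, polyorder=2), kind=trace.kind)


def read_trace_csv(path: str | Path) -> Trace:
    """Read a two-column (time_ms, value) CSV with one header line.

    A header comment of the form ``# kind: calcium`` set by
    :func:`write_trace_csv` is honored; otherwise fluorescence is assumed.
    """
    path = Path(path)
    kind = "fluorescence"
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#") and "kind:" in first:
            kind = first.split("kind:")[1].strip()
            fh.readline()  # column header
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return Trace(t=data[:, 0], y=data[:, 1], kind=kind)


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    label = "ca_uM" if trace.kind == "calcium" else "fluorescence_au"
    with Path(path).open("w") as fh:
        fh.write(f"# kind: {trace.kind}\n")
        fh.write(f"time_ms,{label}\n")
        for ti, yi in zip(trace.t, trace.y):
            fh.write(f"{ti:.10g},{yi:.10g}\n")
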