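"""Pressure-waveform metrics and foot-to-foot pulse wave velocity.

The wave foot is located by the maximum of the second derivative of the
pressure signal on the systolic upstroke (computed on a smoothed copy of
the waveform and restricted to the window between the end-diastolic
minimum and the systolic peak).  Transit time between a proximal and a
distal site is the difference of the two foot times, wrapped into one
cardiac period, and PWV is path distance divided by transit time.

Waveforms are analysed at 900 Hz, well above the ~100 Hz temporal
resolution needed to resolve the short radial-to-digital delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .topology import PathMeasurement

__all__ = [
    "PressureWaveform",
    "PWVMeasurement",
    "WaveMetrics",
    "resample",
    "foot_time",
    "transit_time",
    "compute_pwv",
    "wave_metrics",
]

ANALYSIS_FS = 900.0      # Hz
SMOOTH_CUTOFF = 25.0     # Hz, zero-phase low-pass before differentiating


class WaveformError(ValueError):
    """Waveform unsuitable for the requested analysis."""


@dataclass
class PressureWaveform:
    """One (or more) uniformly sampled cardiac cycles at a named site."""

    site: str
    times: np.ndarray          # s
    pressures: np.ndarray      # mmHg
    fs: float                  # Hz
    period: float              # s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.times.shape != self.pressures.shape or self.times.ndim != 1:
            raise WaveformError("times and pressures must be matching 1-D arrays")
        if self.times.size < 8:
            raise WaveformError("waveform too short")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise WaveformError("waveform must be uniformly sampled")
        # one period sampled periodically omits the endpoint sample
        covered = self.times[-1] - self.times[0] + 1.0 / self.fs
        if covered < self.period * (1 - 1e-6):
            raise WaveformError("waveform must cover at least one full period")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class WaveMetrics:
    """Cycle pressure metrics (mmHg).

    SBP is the systolic peak; end_DBP the end-diastolic minimum (the
    wave foot); early_DBP the first post-systolic local minimum (the
    incisura region); PP = SBP - end_DBP; mean is the cycle average.
    """

    SBP: float
    early_DBP: float | None
    end_DBP: float
    PP: float
    mean: float


@dataclass
class PWVMeasurement:
    """A foot-to-foot PWV estimate over a measured arterial path."""

    path: PathMeasurement
    ptt: float                  # s
    pwv: float                  # m/s
    foot_times: tuple[float, float] = field(default=(np.nan, np.nan))


# ---------------------------------------------------------------------- #


def resample(wave: PressureWaveform, fs: float = ANALYSIS_FS) -> PressureWaveform:
    """Band-limited resampling of a periodic cycle onto a uniform grid.

    Fourier resampling is exact for band-limited periodic signals; the
    input must contain an integer number of periods (a single converged
    cycle in practice).
    """
    n_in = wave.times.size
    duration = n_in / wave.fs          # full periodic extent
    n_out = int(round(duration * fs))
    if n_out < 8:
        raise WaveformError("resampling target leaves too few samples")
    p = signal.resample(wave.pressures, n_out)
    t = wave.times[0] + np.arange(n_out) / fs
    return PressureWaveform(wave.site, t, p, fs, wave.period)


def _smooth(p: np.ndarray, fs: float, cutoff: float = SMOOTH_CUTOFF) -> np.ndarray:
    """Zero-phase low-pass on a periodic signal (wrap-around padding)."""
    if cutoff >= 0.45 * fs:
        return p.copy()
    sos = signal.butter(4, cutoff, fs=fs, output="sos")
    ext = np.concatenate([p, p, p])
    sm = signal.sosfiltfilt(sos, ext)
    n = p.size
    return sm[n:2 * n]


def _cycle_indices(p: np.ndarray) -> tuple[int, int]:
    """Indices (foot_min, sys_peak) of one upstroke in a periodic cycle."""
    i_max = int(np.argmax(p))
    # end-diastolic minimum immediately preceding the systolic peak
    rolled = np.roll(p, -i_max)       # peak at index 0
    i_min_rel = int(np.argmin(rolled))
    i_min = (i_min_rel + i_max) % p.size
    return i_min, i_max


def foot_time(wave: PressureWaveform, cutoff: float = SMOOTH_CUTOFF) -> float:
    """Time of the wave foot: maximum second derivative on the upstroke.

    The search window runs from the end-diastolic minimum to the
    systolic peak; the peak of the (smoothed) second derivative is
    refined to sub-sample precision by parabolic interpolation.
    """
    p = wave.pressures
    if np.ptp(p) < 1e-9 * max(1.0, abs(p).max()):
        raise WaveformError(f"waveform at {wave.site!r} is flat; no foot")
    fs = wave.fs
    n = p.size
    sm = _smooth(p, fs, cutoff)
    # derivatives on the periodic extension
    d1 = np.gradient(np.concatenate([sm, sm, sm])) * fs
    d2 = (np.gradient(d1) * fs)[n:2 * n]
    d1 = d1[n:2 * n]
    # anchor on the steepest systolic upstroke, then walk backwards to
    # where the rise begins (slope below 15% of its peak); searching the
    # whole diastolic tail instead would let noise-induced curvature
    # peaks on the flat baseline masquerade as the foot
    i_up = int(np.argmax(d1))
    back = max(3, int(round(0.30 * wave.period * fs)))
    lim = 0.15 * d1[i_up]
    steps = 1
    while steps < back and d1[(i_up - steps) % n] > lim:
        steps += 1
    i_min = (i_up - min(steps + 2, back)) % n
    span = (i_up - i_min) % n
    if span == 0:
        raise WaveformError(f"no systolic upstroke found at {wave.site!r}")
    window = (i_min + np.arange(span + 1)) % n
    seg = d2[window]
    # the foot is the earliest prominent curvature peak on the rising
    # limb: two-stage upstrokes (a moderate takeoff followed by a
    # steeper, reflection-augmented rise) otherwise pull the global
    # maximum halfway up the wave; requiring a positive slope rejects
    # noise-induced curvature peaks on the diastolic tail
    k = int(np.argmax(seg))
    thresh = 0.5 * seg[k]
    for j in range(1, seg.size - 1):
        if (seg[j] >= thresh and seg[j] >= seg[j - 1]
                and seg[j] >= seg[j + 1] and d1[window[j]] > 0.0):
            k = j
            break
    i_foot = window[k]
    # parabolic sub-sample refinement
    ip, im = (i_foot + 1) % n, (i_foot - 1) % n
    y0, y1, y2 = d2[im], d2[i_foot], d2[ip]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.0 if abs(denom) < 1e-30 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    return float(wave.times[0] + ((i_foot + shift) % n) / fs)


def transit_time(proximal: PressureWaveform, distal: PressureWaveform) -> float:
    """Foot-to-foot pulse transit time (s), wrapped into (0, T]."""
    if abs(proximal.period - distal.period) > 1e-9 * proximal.period:
        raise WaveformError("waveforms have mismatched cardiac periods")
    t_p = foot_time(proximal)
    t_d = foot_time(distal)
    T = proximal.period
    ptt = (t_d - t_p) % T
    if ptt == 0.0:
        raise WaveformError("degenerate transit time of 0 s (identical feet)")
    return float(ptt)


def compute_pwv(path: PathMeasurement, ptt: float,
                foot_times: tuple[float, float] = (np.nan, np.nan)
                ) -> PWVMeasurement:
    """PWV = path distance / transit time, in m/s."""
    if ptt <= 0:
        raise WaveformError(
            f"non-positive transit time {ptt} s (foot mis-detection?)"
        )
    return PWVMeasurement(path, float(ptt), path.distance_m / ptt, foot_times)


def measure_pwv(proximal: PressureWaveform, distal: PressureWaveform,
                path: PathMeasurement) -> PWVMeasurement:
    """Convenience: foot-to-foot PWV straight from two site waveforms."""
    t_p = foot_time(proximal)
    t_d = foot_time(distal)
    ptt = (t_d - t_p) % proximal.period
    meas = compute_pwv(path, ptt, (t_p, t_d))
    return meas


def wave_metrics(wave: PressureWaveform) -> WaveMetrics:
    """SBP, early-/end-diastolic pressures, pulse pressure and mean."""
    p = wave.pressures
    sbp = float(p.max())
    i_min, i_max = _cycle_indices(p)
    end_dbp = float(p[i_min])
    n = p.size
    # first local minimum after the systolic peak (incisura region),
    # searched on a lightly smoothed copy of the downstroke
    sm = _smooth(p, wave.fs, cutoff=min(SMOOTH_CUTOFF * 2, 0.4 * wave.fs))
    early = None
    span = (i_min - i_max) % n
    for j in range(2, max(span - 1, 3)):
        i = (i_max + j) % n
        if sm[i] < sm[(i - 1) % n] and sm[i] <= sm[(i + 1) % n]:
            if (i - 1) % n != i_min and i != i_min:
                early = float(p[i])
            break
    if np.ptp(p) < 1e-12:
        sbp = end_dbp = float(p[0])
        early = None
    return WaveMetrics(
        SBP=sbp,
        early_DBP=early,
        end_DBP=end_dbp,
        PP=sbp - end_dbp,
        mean=float(p.mean()),
    )
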