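"""Proximal boundary models: time-varying elastance ventricle, or a
prescribed aortic inflow.

The ventricle follows the classic time-varying elastance description
P_lv = E(t) (V_lv - V0), with E(t) cycling between E_min and E_max along
a smooth double-Hill activation curve.  An ideal valve with a small
series resistance couples the chamber to the aortic root: it opens when
chamber pressure exceeds root pressure and closes on flow reversal (no
regurgitation is modelled).  Diastolic filling is drawn from a constant
preload pressure through a filling resistance; no atrium is modelled.

Default parameter values are a documented re-calibration that targets a
healthy resting state on the packaged reference tree: heart rate 75 bpm,
cardiac output ~5 L/min, aortic pressure ~118/73 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import MMHG_TO_PA, ML_TO_M3

__all__ = [
    "ElastanceHeartParams",
    "HeartState",
    "normalized_elastance",
    "ElastanceHeart",
    "PrescribedInflow",
    "prescribed_inflow",
]

# double-Hill shape constants (rise exponent, decay exponent, and the
# ratio of the decay to the rise time constant); the activation curve is
# h1/(1+h1) * 1/(1+h2) with h1=(t/tau1)^n1, h2=(t/tau2)^n2
_N1, _N2 = 1.9, 21.9
_TAU2_OVER_TAU1 = 1.58


def _raw_shape(t_frac: np.ndarray, tau1: float) -> np.ndarray:
    tau2 = _TAU2_OVER_TAU1 * tau1
    h1 = (t_frac / tau1) ** _N1
    h2 = (t_frac / tau2) ** _N2
    return (h1 / (1.0 + h1)) / (1.0 + h2)


def _calibrate_tau1(t_peak_frac: float) -> tuple[float, float]:
    """Find tau1 so the activation peaks at t_peak_frac; return (tau1, peak)."""
    grid = np.linspace(1e-4, 1.0, 4001)
    tau1 = t_peak_frac  # starting guess
    for _ in range(40):
        y = _raw_shape(grid, tau1)
        m = grid[np.argmax(y)]
        tau1 *= t_peak_frac / m
    y = _raw_shape(grid, tau1)
    return tau1, float(y.max())


@dataclass
class ElastanceHeartParams:
    """Ventricle, valve and preload parameters (clinical units)."""

    E_max: float = 1.2           # mmHg/mL, peak elastance
    E_min: float = 0.08          # mmHg/mL, diastolic elastance
    V0: float = 15.0             # mL, unstressed (dead) volume
    T: float = 0.8               # s, cardiac period (75 bpm)
    t_peak_frac: float = 0.38    # fraction of T at peak elastance
    preload_pressure: float = 14.5    # mmHg, constant filling pressure
    valve_resistance: float = 0.05    # mmHg.s/mL, aortic valve + outflow tract
    filling_resistance: float = 0.015  # mmHg.s/mL, mitral inflow
    edv: float = 125.0           # mL, initial (end-diastolic) volume

    def __post_init__(self) -> None:
        if not self.E_max > self.E_min > 0:
            raise ValueError("need E_max > E_min > 0")
        if not 0.0 < self.t_peak_frac < 1.0:
            raise ValueError("t_peak_frac must lie in (0, 1)")
        if self.T <= 0:
            raise ValueError("cardiac period must be positive")
        if self.valve_resistance <= 0 or self.filling_resistance <= 0:
            raise ValueError("valve and filling resistances must be positive")

    @property
    def heart_rate(self) -> float:
        return 60.0 / self.T


@dataclass
class HeartState:
    """Instantaneous chamber state."""

    V_lv: float          # mL
    valve_open: bool
    Q_out: float         # mL/s


def normalized_elastance(t_frac, t_peak_frac: float = 0.38):
    """Normalized double-Hill elastance in [0, 1], peaking at t_peak_frac.

    ``t_frac`` is the fraction of the cardiac cycle; values outside
    [0, 1) are wrapped modulo 1.
    """
    tau1, peak = _calibrate_tau1(t_peak_frac)
    t = np.mod(np.asarray(t_frac, dtype=float), 1.0)
    out = _raw_shape(t, tau1) / peak
    return float(out) if out.ndim == 0 else out


class ElastanceHeart:
    """Stateful elastance ventricle working in SI units internally."""

    def __init__(self, params: ElastanceHeartParams | None = None):
        self.params = params or ElastanceHeartParams()
        p = self.params
        self._tau1, self._peak = _calibrate_tau1(p.t_peak_frac)
        _e_unit = MMHG_TO_PA / ML_TO_M3        # mmHg/mL -> Pa/m^3
        self.E_max = p.E_max * _e_unit
        self.E_min = p.E_min * _e_unit
        self.V0 = p.V0 * ML_TO_M3
        self.T = p.T
        self.R_valve = p.valve_resistance * MMHG_TO_PA / ML_TO_M3
        self.R_fill = p.filling_resistance * MMHG_TO_PA / ML_TO_M3
        self.P_preload = p.preload_pressure * MMHG_TO_PA
        self.reset()

    def reset(self) -> None:
        self.V = self.params.edv * ML_TO_M3
        self.valve_open = False
        self.Q_out = 0.0

    def elastance(self, t: float) -> float:
        """E(t) in Pa/m^3."""
        tf = (t / self.T) % 1.0
        e = _raw_shape(np.float64(tf), self._tau1) / self._peak
        return self.E_min + (self.E_max - self.E_min) * float(e)

    def plv(self, t: float) -> float:
        """Chamber pressure in Pa at time t for the current volume."""
        return self.elastance(t) * (self.V - self.V0)

    def commit(self, t: float, Q_out: float, dt: float) -> None:
        """Advance the chamber volume after the root flow is known."""
        plv = self.plv(t)
        q_fill = max(0.0, (self.P_preload - plv) / self.R_fill)
        self.V += (q_fill - Q_out) * dt
        self.Q_out = Q_out

    @property
    def state(self) -> HeartState:
        return HeartState(
            V_lv=self.V / ML_TO_M3,
            valve_open=self.valve_open,
            Q_out=self.Q_out / ML_TO_M3,
        )


class PrescribedInflow:
    """Periodic root inflow boundary given as a sampled waveform.

    ``times`` (s) and ``flows`` (mL/s) describe one period; the waveform
    must be periodic (first and last samples consistent).
    """

    def __init__(self, times, flows, rtol: float = 0.05):
        t = np.asarray(times, dtype=float)
        q = np.asarray(flows, dtype=float)
        if t.ndim != 1 or t.shape != q.shape or t.size < 3:
            raise ValueError("need matching 1-D time/flow arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        self.T = float(t[-1] - t[0])
        scale = max(abs(q).max(), 1e-12)
        if abs(q[-1] - q[0]) > rtol * scale:
            raise ValueError(
                "inflow waveform is not periodic: endpoint flows differ by "
                f"{abs(q[-1] - q[0]):.3g} mL/s"
            )
        self._t = t - t[0]
        self._q = q * ML_TO_M3

    @classmethod
    def from_table(cls, path) -> "PrescribedInflow":
        """Read a two-column (time s, flow mL/s) whitespace/comma table."""
        data = np.loadtxt(path, delimiter=None if str(path).endswith(".txt")
                          else ",")
        return cls(data[:, 0], data[:, 1])

    def flow(self, t: float) -> float:
        """Flow in m^3/s at time t (periodic extension)."""
        return float(np.interp(t % self.T, self._t, self._q))


def prescribed_inflow(waveform) -> PrescribedInflow:
    """Coerce a (times, flows) pair or PrescribedInflow into a root boundary."""
    if isinstance(waveform, PrescribedInflow):
        return waveform
    times, flows = waveform
    return PrescribedInflow(times, flows)
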