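"""Tube laws, distensibility algebra and perturbation schemes.

The link between wall distensibility D = (1/A) dA/dP and pulse wave
velocity is the Bramwell-Hill relation c = 1/sqrt(rho * D).  Segment
distensibility is declared at a reference pressure; the tube law extends
it to a full pressure-area relation.  Three constitutive options are
provided:

``linear``
    P = P_ref + (A - A0) / (D_ref * A0).  Compliance independent of
    pressure; local wave speed still grows weakly with area.
``power``
    P = P_ref + ((A/A0)**m - 1) / (D_ref * m).  The exponent m >= 1 sets
    how strongly the wall stiffens with distension; m = 1 recovers the
    linear law.  Near the reference point d(ln c)/dP ~ (m/2) * D_ref.
``exponential``
    Wave speed prescribed as c(P)^2 = c_ref^2 * exp(2 sigma (P - P_ref)),
    i.e. a constant relative wave-speed pressure sensitivity
    d(ln c)/dP = sigma at every pressure, integrating to
    A(P) = A0 * exp[(D_ref/(2 sigma)) (1 - exp(-2 sigma (P - P_ref)))].
    sigma grows for smaller lumen diameters (peripheral, muscular
    arteries respond to pressure more strongly than the aorta), which is
    what makes medium-artery PWV react more to a blood-pressure rise
    than aortic PWV.
``arctan``
    A(P) = A_m * (1/2 + arctan((P - P0)/P1) / pi), the classic
    sigmoidal pressure-area curve of large arteries; (A_m, P1) are
    solved per node so that area and distensibility match their
    reference values at P_ref.

All three perturbation schemes of the staged-kidney studies operate on
the declared reference distensibility: a uniform scaling, a non-uniform
diameter-stratified reduction, and replacement by literature in-vivo
values for end-stage renal disease with a default 30% reduction for
segments without a published value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .topology import ArterialTree
from .units import DIST_UNIT_TO_PA, MMHG_TO_PA

__all__ = [
    "WallModelParams",
    "DistensibilityScenario",
    "bramwell_hill_pwv",
    "distensibility_from_pwv",
    "pwv_from_diameter",
    "compliance_per_length",
    "scale_distensibility_uniform",
    "scale_distensibility_nonuniform",
    "apply_invivo_table",
    "apply_scenario",
    "make_tube_law",
    "DEFAULT_CLASS_RULE",
    "INSILICO_DISTENSIBILITY",
    "INVIVO_DISTENSIBILITY",
]

RHO_BLOOD = 1050.0   # kg/m^3; consistent with every printed (D, PWV) pair

#: Default in-silico distensibility by arterial territory
#: (kPa^-1 x 10^-3, at the reference pressure).
INSILICO_DISTENSIBILITY = {
    "aorta": 27.0,
    "carotid": 23.0,
    "femoral": 10.6,
    "tibial": 9.0,
    "brachial": 7.3,
    "radial": 6.4,
    "coronary": 6.1,
    "cerebral": 8.1,
    "digital": 5.3,
    "dorsal": 5.7,
}

#: Literature in-vivo distensibility in end-stage renal disease, same units.
#: aorta/carotid/brachial/radial are measured; the remaining territories
#: are interpolated values.
INVIVO_DISTENSIBILITY = {
    "aorta": 21.0,
    "carotid": 18.0,
    "femoral": 6.6,
    "tibial": 5.0,
    "brachial": 3.5,
    "radial": 2.6,
    "coronary": 4.5,
    "cerebral": 4.1,
    "digital": 3.4,
    "dorsal": 3.2,
}


def _default_diameter_coeffs() -> tuple[float, float]:
    # inverse power law c = a * d**(-b) through two anchor points of the
    # default wall table: aorta (25 mm, 5.9 m/s) and radial (3 mm, 12.2 m/s)
    b = math.log(12.2 / 5.9) / math.log(25.0 / 3.0)
    a = 5.9 * 25.0 ** b
    return a, b


DEFAULT_PWV_DIAMETER_COEFFS = _default_diameter_coeffs()

#: Diameter-stratified distensibility reductions (lo mm < d <= hi mm, cut):
#: -40% above 14 mm, -25% for 11-14 mm, -15% for 8-11 mm, -10% for 3-8 mm,
#: -5% at or below 3 mm.
DEFAULT_CLASS_RULE = [
    (14.0, math.inf, 0.40),
    (11.0, 14.0, 0.25),
    (8.0, 11.0, 0.15),
    (3.0, 8.0, 0.10),
    (0.0, 3.0, 0.05),
]


@dataclass
class WallModelParams:
    """Blood and wall constitutive parameters shared by a simulation."""

    rho_blood: float = RHO_BLOOD               # kg/m^3
    mu_blood: float = 0.004                    # Pa.s
    P_ref: float = 100.0                       # mmHg, reference pressure
    pwv_diameter_coeffs: tuple[float, float] = DEFAULT_PWV_DIAMETER_COEFFS
    tube_law_kind: str = "arctan"   # linear | power | exponential | arctan
    power_exponent: float = 3.0                # m of the power law
    #: relative wave-speed pressure sensitivity d(ln c)/dP (Pa^-1) of a
    #: 10 mm vessel; for the power law the exponent is m = 2*sigma/D_ref
    pressure_sensitivity: float | None = 7e-5
    #: sigma scales with (10 mm / d)**gamma: smaller arteries stiffer
    #: with pressure
    sensitivity_diameter_exp: float = 0.5
    #: arctan inflection pressure: p0 for vessels >= 8 mm, rising
    #: linearly to p0_small at <= 3 mm (muscular arteries keep their
    #: compliance peak closer to working pressures, which makes their
    #: wave speed respond more strongly to a blood-pressure rise)
    arctan_p0: float = 45.0                    # mmHg
    arctan_p0_small: float = 55.0              # mmHg, for d <= 3 mm
    arctan_branch: str = "stiff"               # gentle | stiff

    def __post_init__(self) -> None:
        if self.rho_blood <= 0:
            raise ValueError("rho_blood must be positive")
        a, b = self.pwv_diameter_coeffs
        if a <= 0 or b < 0:
            raise ValueError("pwv_diameter_coeffs require a > 0, b >= 0")
        kinds = ("linear", "power", "exponential", "arctan")
        if self.tube_law_kind not in kinds:
            raise ValueError(f"unknown tube law {self.tube_law_kind!r}")
        if self.power_exponent < 1.0:
            raise ValueError("power_exponent must be >= 1")

    @property
    def P_ref_pa(self) -> float:
        return self.P_ref * MMHG_TO_PA


@dataclass
class DistensibilityScenario:
    """Declarative description of a wall-stiffness perturbation.

    kind = "default" (no change), "uniform_scale" (every segment scaled
    by 1 + factor), "nonuniform_by_diameter" (diameter-class reductions),
    or "invivo_overrides" (published per-territory values plus a default
    fractional reduction for everything else).
    """

    kind: str = "default"
    factor: float = 0.0
    class_rule: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_CLASS_RULE)
    )
    overrides: dict[str, float] = field(default_factory=dict)
    default_reduction: float = 0.30

    def __post_init__(self) -> None:
        kinds = ("default", "uniform_scale", "nonuniform_by_diameter",
                 "invivo_overrides")
        if self.kind not in kinds:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.factor <= -1.0:
            raise ValueError("scale factor must exceed -1")


# ---------------------------------------------------------------------- #
# Bramwell-Hill algebra


def bramwell_hill_pwv(D: float, rho: float = RHO_BLOOD) -> float:
    """Pulse wave velocity (m/s) from distensibility (kPa^-1 x 10^-3)."""
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("distensibility must be positive")
    out = 1.0 / np.sqrt(rho * D * DIST_UNIT_TO_PA)
    return float(out) if out.ndim == 0 else out


def distensibility_from_pwv(c: float, rho: float = RHO_BLOOD) -> float:
    """Exact inverse of :func:`bramwell_hill_pwv` (kPa^-1 x 10^-3)."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("wave speed must be positive")
    out = 1.0 / (rho * c ** 2) / DIST_UNIT_TO_PA
    return float(out) if out.ndim == 0 else out


def pwv_from_diameter(
    d_mm: float, coeffs: tuple[float, float] = DEFAULT_PWV_DIAMETER_COEFFS
) -> float:
    """Wave speed (m/s) from lumen diameter (mm) via c = a * d**(-b).

    Used only to fill in wall stiffness for segments whose territory has
    no tabulated distensibility.
    """
    d = np.asarray(d_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    a, b = coeffs
    out = a * d ** (-b)
    return float(out) if out.ndim == 0 else out


def compliance_per_length(A: float, c: float, rho: float = RHO_BLOOD) -> float:
    """Area compliance per unit length C_A = A / (rho c^2)  [m^2/Pa].

    Equivalently D = C_A / A; this identity ties the solver's tube law to
    the declared distensibility.
    """
    A = np.asarray(A, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(A <= 0) or np.any(c <= 0):
        raise ValueError("area and wave speed must be positive")
    out = A / (rho * c ** 2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------- #
# perturbation schemes (operate on trees in file units)


def scale_distensibility_uniform(tree: ArterialTree, factor: float) -> ArterialTree:
    """Multiply every segment's distensibility by (1 + factor)."""
    if factor <= -1.0:
        raise ValueError("factor must exceed -1")
    new = tree.copy()
    for seg in new.segments.values():
        seg.distensibility_ref *= 1.0 + factor
    return new


def _classify(d_mm: float, rule) -> float:
    for lo, hi, cut in rule:
        if lo < d_mm <= hi:
            return cut
    raise ValueError(f"diameter {d_mm} mm not covered by the class rule")


def scale_distensibility_nonuniform(
    tree: ArterialTree, class_rule=None
) -> ArterialTree:
    """Reduce each segment's distensibility by its diameter class's cut.

    Classification uses the mean lumen diameter; larger vessels receive
    larger reductions (aortic stiffening dominates peripheral stiffening).
    """
    rule = list(class_rule) if class_rule is not None else DEFAULT_CLASS_RULE
    cuts = [c for _, _, c in rule]
    if any(c2 > c1 for c1, c2 in zip(cuts, cuts[1:])):
        # rule rows must be ordered large->small diameter with
        # non-increasing reductions
        raise ValueError("class rule must not give larger cuts to smaller vessels")
    new = tree.copy()
    for seg in new.segments.values():
        seg.distensibility_ref *= 1.0 - _classify(seg.mean_diameter, rule)
    return new


def apply_invivo_table(
    tree: ArterialTree,
    overrides: dict[str, float] | None = None,
    default_reduction: float = 0.30,
) -> ArterialTree:
    """Set per-territory distensibility from published in-vivo values.

    Segments whose ``group`` appears in ``overrides`` take the published
    value verbatim; every other segment is reduced by
    ``default_reduction`` of its default value.
    """
    if overrides is None:
        overrides = dict(INVIVO_DISTENSIBILITY)
    new = tree.copy()
    groups_present = {seg.group for seg in new.segments.values()}
    for grp in overrides:
        if grp not in groups_present:
            warnings.warn(
                f"in-vivo override group {grp!r} matches no segment",
                stacklevel=2,
            )
    for seg in new.segments.values():
        if seg.group in overrides:
            seg.distensibility_ref = float(overrides[seg.group])
        else:
            seg.distensibility_ref *= 1.0 - default_reduction
    return new


def apply_scenario(
    tree: ArterialTree, scenario: DistensibilityScenario
) -> ArterialTree:
    """Dispatch a :class:`DistensibilityScenario` onto a tree."""
    if scenario.kind == "default":
        return tree.copy()
    if scenario.kind == "uniform_scale":
        return scale_distensibility_uniform(tree, scenario.factor)
    if scenario.kind == "nonuniform_by_diameter":
        return scale_distensibility_nonuniform(tree, scenario.class_rule)
    return apply_invivo_table(
        tree, scenario.overrides or None, scenario.default_reduction
    )


# ---------------------------------------------------------------------- #
# tube laws (SI units throughout)


class LinearTubeLaw:
    """P = P_ref + (A - A0)/(D_ref A0); node-wise A0, D_ref."""

    def __init__(self, A0: np.ndarray, D_ref: np.ndarray, P_ref: float):
        self.A0 = np.asarray(A0, dtype=float)
        self.D_ref = np.broadcast_to(
            np.asarray(D_ref, dtype=float), self.A0.shape
        ).copy()
        self.P_ref = float(P_ref)
        self._k = 1.0 / (self.D_ref * self.A0)    # dP/dA, constant

    def pressure(self, A: np.ndarray) -> np.ndarray:
        return self.P_ref + (A - self.A0) * self._k

    def area(self, P: np.ndarray) -> np.ndarray:
        return self.A0 * (1.0 + self.D_ref * (P - self.P_ref))

    def dPdA(self, A: np.ndarray) -> np.ndarray:
        return np.broadcast_to(self._k, np.shape(A))

    def wave_speed(self, A: np.ndarray, rho: float) -> np.ndarray:
        return np.sqrt(A * self._k / rho)


class PowerTubeLaw:
    """P = P_ref + ((A/A0)**m - 1)/(D_ref m); stiffens with distension.

    ``m`` may be a scalar or a per-node array; near the reference point
    the relative wave-speed sensitivity is d(ln c)/dP ~ (m/2) D_ref.
    """

    def __init__(self, A0, D_ref, P_ref: float, m):
        self.A0 = np.asarray(A0, dtype=float)
        self.D_ref = np.broadcast_to(
            np.asarray(D_ref, dtype=float), self.A0.shape
        ).copy()
        self.P_ref = float(P_ref)
        self.m = np.broadcast_to(np.asarray(m, dtype=float),
                                 self.A0.shape).copy()

    def pressure(self, A):
        r = np.maximum(A / self.A0, 1e-6)
        return self.P_ref + (r ** self.m - 1.0) / (self.D_ref * self.m)

    def area(self, P):
        base = 1.0 + self.m * self.D_ref * (P - self.P_ref)
        base = np.maximum(base, 1e-6)
        return self.A0 * base ** (1.0 / self.m)

    def dPdA(self, A):
        r = np.maximum(A / self.A0, 1e-6)
        return r ** (self.m - 1.0) / (self.D_ref * self.A0)

    def wave_speed(self, A, rho: float):
        return np.sqrt(A * self.dPdA(A) / rho)


class ExponentialTubeLaw:
    """Constant-sensitivity stiffening law.

    Wave speed is prescribed directly as a function of pressure:

        c(P)^2 = (1/(rho D_ref)) * exp(2 sigma (P - P_ref))   for P <= P_ref
        c(P)^2 = (1/(rho D_ref)) * (1 + 2 sigma (P - P_ref))  for P >  P_ref

    (C^1-matched at the reference point, d(ln c)/dP = sigma there and at
    every sub-reference pressure).  Integrating dA/A = dP/(rho c^2)
    gives closed forms both ways; with the auxiliary variable
    z = (2 sigma / D_ref) ln(A/A0):

        c^2 = e^z/(rho D_ref)        for z >= 0
        c^2 = 1/(rho D_ref (1 - z))  for z <  0

    The lumen closes smoothly (A -> 0, c -> 0) at very low pressure and
    never saturates at high pressure.
    """

    _ZMAX = 3.0    # sanity clip; c is capped at e^1.5 * c_ref

    def __init__(self, A0, D_ref, P_ref: float, sigma):
        self.A0 = np.asarray(A0, dtype=float)
        self.D_ref = np.broadcast_to(
            np.asarray(D_ref, dtype=float), self.A0.shape
        ).copy()
        self.P_ref = float(P_ref)
        self.sigma = np.broadcast_to(np.asarray(sigma, dtype=float),
                                     self.A0.shape).copy()

    def _z(self, A):
        return np.clip(
            (2.0 * self.sigma / self.D_ref)
            * np.log(np.maximum(A, 1e-14) / self.A0),
            -1e6, self._ZMAX,
        )

    def area(self, P):
        dP = P - self.P_ref
        s2 = 2.0 * self.sigma
        z = np.where(
            dP >= 0.0,
            np.log1p(s2 * np.maximum(dP, 0.0)),
            -np.expm1(np.clip(-s2 * dP, None, 30.0)),
        )
        return self.A0 * np.exp(self.D_ref / s2 * z)

    def pressure(self, A):
        z = self._z(A)
        s2 = 2.0 * self.sigma
        return self.P_ref + np.where(
            z >= 0.0,
            np.expm1(z) / s2,
            -np.log1p(-np.minimum(z, 0.0)) / s2,
        )

    def _c2rho(self, A):
        # rho c^2 as a function of area
        z = self._z(A)
        return np.where(z >= 0.0, np.exp(z), 1.0 / (1.0 - np.minimum(z, 0.0))
                        ) / self.D_ref

    def dPdA(self, A):
        return self._c2rho(A) / np.maximum(A, 1e-14)

    def wave_speed(self, A, rho: float):
        return np.sqrt(self._c2rho(A) / rho)


def sigma_for_diameter(A0, params: "WallModelParams"):
    """Per-node wave-speed pressure sensitivity from the lumen diameter."""
    d_mm = np.sqrt(4.0 * np.asarray(A0, dtype=float) / math.pi) / 1e-3
    s0 = params.pressure_sensitivity or 0.0
    gamma = params.sensitivity_diameter_exp
    return np.clip(s0 * (10.0 / d_mm) ** gamma, 0.0, 3e-4)


def _arctan_kappa() -> float:
    # max over r of r / (pi (1+r^2) (1/2 + atan(1/r)/pi)); scale-invariant
    f = lambda r: -r / (math.pi * (1 + r * r) * (0.5 + math.atan(1 / r) / math.pi))
    res = minimize_scalar(f, bounds=(0.1, 10.0), method="bounded")
    return -res.fun, res.x


_KAPPA, _R_PEAK = _arctan_kappa()


class ArctanTubeLaw:
    """Sigmoidal A(P) = A_m (1/2 + arctan((P-P0)/P1)/pi).

    (A_m, P1) are solved per node so that A(P_ref) = A0 and the
    distensibility at P_ref equals D_ref.  P0 is pushed towards P_ref
    only as far as the constraint remains solvable; the ``gentle``
    branch picks the wider of the two admissible P1 roots (flatter,
    more linear curve), ``stiff`` the narrower one.
    """

    def __init__(self, A0, D_ref, P_ref: float, P0_target,
                 branch: str = "gentle"):
        A0 = np.atleast_1d(np.asarray(A0, dtype=float))
        D = np.broadcast_to(np.atleast_1d(np.asarray(D_ref, float)), A0.shape)
        P0t = np.broadcast_to(np.atleast_1d(np.asarray(P0_target, float)),
                              A0.shape)
        self.A0 = A0
        self.D_ref = D.copy()
        self.P_ref = float(P_ref)
        self.P0 = np.empty(A0.shape)
        self.P1 = np.empty(A0.shape)
        self.A_m = np.empty(A0.shape)
        for i in range(A0.size):
            p0, p1, am = self._solve_node(A0.flat[i], D.flat[i],
                                          P_ref, P0t.flat[i], branch)
            self.P0.flat[i], self.P1.flat[i], self.A_m.flat[i] = p0, p1, am

    @staticmethod
    def _solve_node(A0: float, D: float, P_ref: float, P0_target: float,
                    branch: str) -> tuple[float, float, float]:
        # admissibility: max_P1 g(P1; dP) = kappa/dP must exceed D
        dP_max = 0.95 * _KAPPA / D
        dP = min(P_ref - P0_target, dP_max)
        P0 = P_ref - dP

        def g(r):  # distensibility at P_ref for P1 = r*dP
            return r / (math.pi * (1 + r * r)
                        * (0.5 + math.atan(1.0 / r) / math.pi)) / dP

        target = D
        if branch == "gentle":
            lo, hi = _R_PEAK, 1e6
        else:
            lo, hi = 1e-12, _R_PEAK
        r = brentq(lambda r: g(r) - target, lo, hi, xtol=1e-10)
        P1 = r * dP
        frac = 0.5 + math.atan(dP / P1) / math.pi
        A_m = A0 / frac
        return P0, P1, A_m

    def area(self, P):
        return self.A_m * (0.5 + np.arctan((P - self.P0) / self.P1) / np.pi)

    def pressure(self, A):
        s = np.clip(A / self.A_m, 1e-9, 1.0 - 1e-9)
        return self.P0 + self.P1 * np.tan(np.pi * (s - 0.5))

    def dPdA(self, A):
        s = np.clip(A / self.A_m, 1e-9, 1.0 - 1e-9)
        t = np.tan(np.pi * (s - 0.5))
        return np.pi * self.P1 / self.A_m * (1.0 + t * t)

    def wave_speed(self, A, rho: float):
        return np.sqrt(A * self.dPdA(A) / rho)


def make_tube_law(A0, D_ref_pa, params: WallModelParams):
    """Build the configured tube law for one segment's nodes (SI units)."""
    kind = params.tube_law_kind
    if kind == "linear":
        return LinearTubeLaw(A0, D_ref_pa, params.P_ref_pa)
    if kind == "power":
        if params.pressure_sensitivity is not None:
            m = np.clip(2.0 * params.pressure_sensitivity
                        / np.asarray(D_ref_pa, dtype=float), 1.0, 60.0)
        else:
            m = params.power_exponent
        return PowerTubeLaw(A0, D_ref_pa, params.P_ref_pa, m)
    if kind == "exponential":
        if not params.pressure_sensitivity:
            raise ValueError("exponential law needs pressure_sensitivity")
        sigma = sigma_for_diameter(A0, params)
        return ExponentialTubeLaw(A0, D_ref_pa, params.P_ref_pa, sigma)
    d_mm = np.sqrt(4.0 * np.asarray(A0, dtype=float) / math.pi) / 1e-3
    frac = np.clip((8.0 - d_mm) / 5.0, 0.0, 1.0)
    p0 = params.arctan_p0 + (params.arctan_p0_small - params.arctan_p0) * frac
    return ArctanTubeLaw(A0, D_ref_pa, params.P_ref_pa,
                         p0 * MMHG_TO_PA, params.arctan_branch)
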