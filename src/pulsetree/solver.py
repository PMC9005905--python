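"""Space-time integration of the 1-D flow equations over an arterial tree.

Per segment the cross-section-averaged continuity and momentum equations

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx = -k_f (mu/rho) (Q/A)

are advanced with an explicit two-step (Richtmyer) Lax-Wendroff scheme
in finite-volume form: the state lives at cell centres, the half-step
produces fluxes at the cell faces (grid nodes), and segment-end fluxes
come from characteristic boundary solves.  Because junction solves
enforce flow balance and every face flux is single-valued, the discrete
scheme conserves volume globally to round-off.  P follows from the
configured tube law; k_f = 2 pi (zeta + 2) is the friction constant of
an assumed power-law velocity profile (zeta = 9, near-plug, default).

Junctions enforce mass conservation and continuity of total pressure
P + rho u^2 / 2, solved together with the outgoing characteristic
compatibility relation of each adjoining vessel end.  Terminal segments
couple to three-element Windkessel loads integrated with the same time
step; the root couples to the elastance ventricle (or to a prescribed
inflow waveform).

Cycles are repeated until the maximum cycle-to-cycle change of any site
pressure drops below a tolerance, and the final converged cycle is
extracted at the configured sites and resampled to 900 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .heart import ElastanceHeart, ElastanceHeartParams, PrescribedInflow
from .pwv_analysis import PressureWaveform, resample
from .topology import ArterialTree, WindkesselOutlet
from .units import (CM_TO_M, C_UNIT_TO_SI, MM_TO_M, MMHG_TO_PA, PA_TO_MMHG,
                    M3_TO_ML, R_UNIT_TO_SI)
from .wall_mechanics import (DistensibilityScenario, WallModelParams,
                             apply_scenario, make_tube_law)

__all__ = [
    "Grid",
    "SolverError",
    "SimulationResult",
    "simulate",
    "windkessel_update",
    "WindkesselOutlet",
]

ANALYSIS_FS = 900.0


def windkessel_update(
    P_internal: float, Q_in: float, outlet: WindkesselOutlet, dt: float
) -> tuple[float, float]:
    """One backward-Euler step of the three-element Windkessel (RCR).

    ``P_internal`` is the pressure on the capacitor node (mmHg), ``Q_in``
    the inflow (mL/s).  Returns ``(P_terminal, P_internal_new)``: the
    pressure seen at the vessel end (across R1) and the updated capacitor
    pressure.  For steady inflow the fixed point is exactly
    P_terminal = Q (R1 + R2) + P_out, and with zero inflow the internal
    pressure relaxes to P_out with time constant R2 C.
    """
    denom = 1.0 + dt / (outlet.R2 * outlet.C)
    P_new = (P_internal
             + dt / outlet.C * (Q_in + outlet.P_out / outlet.R2)) / denom
    return P_new + Q_in * outlet.R1, P_new


class SolverError(RuntimeError):
    """Numerical failure (instability, non-convergence) during a run."""


@dataclass
class Grid:
    """Per-segment spatial discretisation (SI units)."""

    seg_ids: list[int]
    n_cells: np.ndarray          # cells per segment
    dx: np.ndarray               # m, per segment
    lengths: np.ndarray          # m

    @property
    def n_max(self) -> int:
        return int(self.n_cells.max())


@dataclass
class ConvergenceDiagnostics:
    converged: bool
    cycles_run: int
    cycle_residuals_mmhg: list[float]
    inflow_volume_ml: float
    outflow_volumes_ml: dict[str, float]
    stroke_volume_ml: float
    cardiac_output_lmin: float


@dataclass
class SimulationResult:
    """Converged-cycle fields extracted at the configured sites.

    ``site_pressure``/``site_flow`` hold the final cycle at solver
    resolution (mmHg, mL/s); ``waveforms`` the same pressures resampled
    to 900 Hz as :class:`PressureWaveform` objects.
    """

    time: np.ndarray
    period: float
    dt: float
    site_pressure: dict[str, np.ndarray]
    site_flow: dict[str, np.ndarray]
    waveforms: dict[str, PressureWaveform]
    diagnostics: ConvergenceDiagnostics
    meta: dict = field(default_factory=dict)

    def waveform(self, site: str) -> PressureWaveform:
        return self.waveforms[site]

    def to_hdf(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["period"] = self.period
            fh.attrs["dt"] = self.dt
            fh.create_dataset("time", data=self.time)
            for name in self.site_pressure:
                g = fh.create_group(f"sites/{name}")
                g.create_dataset("pressure_mmhg", data=self.site_pressure[name])
                g.create_dataset("flow_ml_s", data=self.site_flow[name])

    def to_csv(self, directory) -> None:
        import pandas as pd
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in self.site_pressure:
            pd.DataFrame(
                {
                    "time_s": self.time,
                    "pressure_mmhg": self.site_pressure[name],
                    "flow_ml_s": self.site_flow[name],
                }
            ).to_csv(d / f"{name}.csv", index=False)


# ---------------------------------------------------------------------- #
# scalar tube-law access for boundary nodes


class _NodeLaw:
    """Scalar tube-law evaluation at one segment end."""

    __slots__ = ("kind", "A0", "D", "P_ref", "m", "A_m", "P0", "P1", "sigma")

    def __init__(self, law, kind: str, idx: tuple[int, int]):
        self.kind = kind
        self.A_m = self.P0 = self.P1 = self.sigma = 0.0
        self.A0 = self.D = self.P_ref = self.m = 0.0
        if kind == "arctan":
            self.A_m = float(law.A_m[idx])
            self.P0 = float(law.P0[idx])
            self.P1 = float(law.P1[idx])
        else:
            self.A0 = float(law.A0[idx])
            self.D = float(law.D_ref[idx])
            self.P_ref = float(law.P_ref)
            m = getattr(law, "m", 1.0)
            self.m = float(m[idx]) if np.ndim(m) else float(m)
            if kind == "exponential":
                self.sigma = float(law.sigma[idx])

    def area(self, P: float) -> float:
        if self.kind == "arctan":
            return self.A_m * (0.5 + math.atan((P - self.P0) / self.P1) / math.pi)
        if self.kind == "linear":
            return self.A0 * max(1.0 + self.D * (P - self.P_ref), 1e-3)
        if self.kind == "exponential":
            dP = P - self.P_ref
            s2 = 2.0 * self.sigma
            if dP >= 0.0:
                z = math.log1p(s2 * dP)
            else:
                z = -math.expm1(min(-s2 * dP, 30.0))
            return self.A0 * math.exp(self.D / s2 * z)
        base = max(1.0 + self.m * self.D * (P - self.P_ref), 1e-6)
        return self.A0 * base ** (1.0 / self.m)

    def dAdP(self, P: float) -> float:
        if self.kind == "arctan":
            dp = P - self.P0
            return (self.A_m / math.pi) * self.P1 / (dp * dp + self.P1 * self.P1)
        if self.kind == "linear":
            return self.A0 * self.D
        if self.kind == "exponential":
            # dA/dP = A / (rho c^2) with the prescribed c(P)
            dP = P - self.P_ref
            s2 = 2.0 * self.sigma
            if dP >= 0.0:
                c2rho = (1.0 + s2 * dP) / self.D
            else:
                c2rho = math.exp(max(s2 * dP, -30.0)) / self.D
            return self.area(P) / c2rho
        base = max(1.0 + self.m * self.D * (P - self.P_ref), 1e-6)
        return self.A0 * self.D * base ** (1.0 / self.m - 1.0)


class _BoundaryValue:
    __slots__ = ("A", "Q", "P")

    def __init__(self, A: float, Q: float, P: float):
        self.A, self.Q, self.P = A, Q, P


# ---------------------------------------------------------------------- #


class _TreeSolver:
    """Assembled numerical model for one tree + boundary conditions."""

    def __init__(
        self,
        tree: ArterialTree,
        wall_params: WallModelParams,
        dx_target: float,
        dt: float,
        zeta: float,
        init_pressure_mmhg: float,
        visc: float = 0.6,
    ):
        self.tree = tree
        self.params = wall_params
        self.rho = wall_params.rho_blood
        self.nu = wall_params.mu_blood / self.rho
        self.k_f = 2.0 * math.pi * (zeta + 2.0)
        self.visc = visc

        ids = sorted(tree.segments)
        self.ids = ids
        self.index = {sid: k for k, sid in enumerate(ids)}
        S = len(ids)
        lengths = np.array([tree[sid].length * CM_TO_M for sid in ids])
        n_cells = np.maximum(2, np.round(lengths / dx_target).astype(int))
        dx = lengths / n_cells
        self.grid = Grid(ids, n_cells, dx, lengths)
        M = self.grid.n_max

        def _area_matrix(positions) -> np.ndarray:
            """Reference area at fractional positions per segment."""
            out = np.ones((S, positions(2).size))
            for k, sid in enumerate(ids):
                seg = tree[sid]
                x = positions(n_cells[k])
                d_m = (seg.diameter_prox
                       + (seg.diameter_dist - seg.diameter_prox) * x) * MM_TO_M
                out[k, : x.size] = math.pi / 4.0 * d_m ** 2
            return out

        # cell centres (S, M) and interior faces (S, M-1)
        A0_cell = np.ones((S, M))
        A0_face = np.ones((S, M - 1))
        D_cell = np.full((S, M), 1e-9)
        D_face = np.full((S, M - 1), 1e-9)
        for k, sid in enumerate(ids):
            seg = tree[sid]
            m = n_cells[k]
            xc = (np.arange(m) + 0.5) / m
            xf = np.arange(1, m) / m
            dp, dd = seg.diameter_prox, seg.diameter_dist
            dc = (dp + (dd - dp) * xc) * MM_TO_M
            df = (dp + (dd - dp) * xf) * MM_TO_M
            A0_cell[k, :m] = math.pi / 4.0 * dc ** 2
            A0_face[k, : m - 1] = math.pi / 4.0 * df ** 2
            D_cell[k, :m] = seg.distensibility_ref * 1e-6
            D_face[k, : m - 1] = seg.distensibility_ref * 1e-6
        # segment-end reference areas for the boundary laws
        A0_end = np.ones((S, 2))
        D_end = np.full((S, 2), 1e-9)
        for k, sid in enumerate(ids):
            seg = tree[sid]
            A0_end[k, 0] = math.pi / 4.0 * (seg.diameter_prox * MM_TO_M) ** 2
            A0_end[k, 1] = math.pi / 4.0 * (seg.diameter_dist * MM_TO_M) ** 2
            D_end[k, :] = seg.distensibility_ref * 1e-6

        self.A0_cell = A0_cell
        self.law = make_tube_law(A0_cell, D_cell, wall_params)
        self.law_face = make_tube_law(A0_face, D_face, wall_params)
        law_end = make_tube_law(A0_end, D_end, wall_params)
        self.kind = wall_params.tube_law_kind

        self.S, self.M = S, M
        self.m_cells = n_cells
        self.dxc = dx[:, None]

        self.active = np.zeros((S, M), bool)
        for k in range(S):
            self.active[k, : n_cells[k]] = True

        # boundary bookkeeping
        self.root_k = self.index[tree.root_id]
        self.junctions = []       # (parent_k, [child_k...])
        for sid in ids:
            seg = tree[sid]
            if seg.child_ids:
                self.junctions.append(
                    (self.index[sid], [self.index[c] for c in seg.child_ids])
                )
        self.terminals = []       # (k, R1, R2, C, P_out) in SI
        for sid in ids:
            seg = tree[sid]
            if seg.terminal:
                wk = seg.windkessel
                self.terminals.append(
                    (
                        self.index[sid],
                        wk.R1 * R_UNIT_TO_SI,
                        wk.R2 * R_UNIT_TO_SI,
                        wk.C * C_UNIT_TO_SI,
                        wk.P_out * MMHG_TO_PA,
                    )
                )

        self._nlaw_in = {k: _NodeLaw(law_end, self.kind, (k, 0))
                         for k in range(S)}
        self._nlaw_out = {k: _NodeLaw(law_end, self.kind, (k, 1))
                          for k in range(S)}

        # state at cell centres
        P_init = init_pressure_mmhg * MMHG_TO_PA
        self.A = np.asarray(self.law.area(np.full((S, M), P_init)), float).copy()
        self.Q = np.zeros((S, M))
        self.P_wk = {k: P_init for k, *_ in self.terminals}
        # boundary values (per segment end) carried between steps
        self.bv_in = {
            k: _BoundaryValue(float(self.A[k, 0]), 0.0, P_init)
            for k in range(S)
        }
        self.bv_out = {
            k: _BoundaryValue(float(self.A[k, n_cells[k] - 1]), 0.0, P_init)
            for k in range(S)
        }
        self.t = 0.0
        self.dt = dt

    # ------------------------------------------------------------------ #

    def pressures(self) -> np.ndarray:
        return np.asarray(self.law.pressure(self.A), dtype=float)

    def wave_speeds(self) -> np.ndarray:
        return np.asarray(self.law.wave_speed(self.A, self.rho), dtype=float)

    def check_cfl(self) -> float:
        c = self.wave_speeds()
        u = np.abs(self.Q / self.A)
        lam = (u + c)[self.active]
        dx = np.broadcast_to(self.dxc, self.A.shape)[self.active]
        return float(np.min(dx / lam))

    def check_health(self) -> None:
        bad = ~np.isfinite(self.A) | (self.A <= 0)
        bad |= ~np.isfinite(self.Q)
        bad &= self.active
        if bad.any():
            k, j = np.argwhere(bad)[0]
            sid = self.ids[k]
            raise SolverError(
                f"solver instability in segment {sid} "
                f"({self.tree[sid].name!r}) cell {j} at t = {self.t:.4f} s"
            )

    # ------------------------------------------------------------------ #
    # characteristic foot states from cell-centre data

    def _char_outlet(self, P, c, k):
        e = self.m_cells[k] - 1
        A_e, Q_e = self.A[k, e], self.Q[k, e]
        u_e = Q_e / A_e
        lam = u_e + c[k, e]
        xi = min(max(lam, 0.0) * self.dt / self.grid.dx[k], 1.0)
        u_m = self.Q[k, e - 1] / self.A[k, e - 1]
        u_s = (1 - xi) * u_e + xi * u_m
        P_s = (1 - xi) * P[k, e] + xi * P[k, e - 1]
        c_s = (1 - xi) * c[k, e] + xi * c[k, e - 1]
        A_s = (1 - xi) * A_e + xi * self.A[k, e - 1]
        return u_s, P_s, c_s, A_s

    def _char_inlet(self, P, c, k):
        A_0, Q_0 = self.A[k, 0], self.Q[k, 0]
        u_0 = Q_0 / A_0
        lam = u_0 - c[k, 0]
        xi = min(max(-lam, 0.0) * self.dt / self.grid.dx[k], 1.0)
        u_s = (1 - xi) * u_0 + xi * self.Q[k, 1] / self.A[k, 1]
        P_s = (1 - xi) * P[k, 0] + xi * P[k, 1]
        c_s = (1 - xi) * c[k, 0] + xi * c[k, 1]
        A_s = (1 - xi) * A_0 + xi * self.A[k, 1]
        return u_s, P_s, c_s, A_s

    # ------------------------------------------------------------------ #
    # boundary solves (set self.bv_in / self.bv_out at the new time)

    def _solve_junction(self, P, c, pk, children) -> None:
        rho = self.rho
        up, Pp, cp, Ap_s = self._char_outlet(P, c, pk)
        ch = [self._char_inlet(P, c, ck) for ck in children]
        law_p = self._nlaw_out[pk]
        laws_c = [self._nlaw_in[ck] for ck in children]

        hp = 0.5 * rho * up * up
        hc = [0.5 * rho * u * u for (u, _, _, _) in ch]
        pi_tot = Pp + hp
        bp = 1.0 / (rho * cp)
        bc = [1.0 / (rho * cs) for (_, _, cs, _) in ch]

        Qp = up * Ap_s
        Qc = [u * As for (u, _, _, As) in ch]
        P_p = Pp
        for _ in range(40):
            P_p = pi_tot - hp
            u_p = up - bp * (P_p - Pp)
            A_p = law_p.area(P_p)
            Qp = A_p * u_p
            resid = Qp
            dres = law_p.dAdP(P_p) * u_p - A_p * bp
            for i, (u_s, P_s, c_s, _) in enumerate(ch):
                P_i = pi_tot - hc[i]
                u_i = u_s + bc[i] * (P_i - P_s)
                A_i = laws_c[i].area(P_i)
                Qc[i] = A_i * u_i
                resid -= Qc[i]
                dres -= laws_c[i].dAdP(P_i) * u_i + A_i * bc[i]
            hp = 0.5 * rho * u_p * u_p
            for i in range(len(ch)):
                A_i = laws_c[i].area(pi_tot - hc[i])
                hc[i] = 0.5 * rho * (Qc[i] / A_i) ** 2
            if abs(resid) < 1e-13:
                break
            pi_tot -= resid / dres
        # enforce exact flow balance for conservation: distribute the
        # (tiny) residual onto the parent flux
        Qp = sum(Qc)
        bv = self.bv_out[pk]
        bv.A, bv.Q, bv.P = law_p.area(pi_tot - hp), Qp, pi_tot - hp
        for i, ck in enumerate(children):
            P_i = pi_tot - hc[i]
            bv = self.bv_in[ck]
            bv.A, bv.Q, bv.P = laws_c[i].area(P_i), Qc[i], P_i

    def _solve_terminal(self, P, c, term) -> float:
        k, R1, R2, C, P_out = term
        u_s, P_s, c_s, A_s = self._char_outlet(P, c, k)
        law = self._nlaw_out[k]
        Pc = self.P_wk[k]
        dt = self.dt
        denom_c = 1.0 + dt / (R2 * C)
        gamma = (Pc + dt / C * P_out / R2) / denom_c
        delta = (dt / C) / denom_c
        bv = self.bv_out[k]
        A_b, P_b, Q_b = bv.A, bv.P, bv.Q
        for _ in range(3):
            beta = A_b / (self.rho * c_s)
            alpha = A_b * u_s + beta * P_s
            Q_b = (alpha - beta * gamma) / (1.0 + beta * (R1 + delta))
            P_b = gamma + (R1 + delta) * Q_b
            A_b = law.area(P_b)
        self.P_wk[k] = gamma + delta * Q_b
        bv.A, bv.Q, bv.P = A_b, Q_b, P_b
        return Q_b

    def _solve_root(self, P, c, heart, inflow, t_new) -> float:
        k = self.root_k
        u_s, P_s, c_s, A_s = self._char_inlet(P, c, k)
        law = self._nlaw_in[k]
        bv = self.bv_in[k]
        A_b = bv.A
        if inflow is not None:
            Q_b = inflow.flow(t_new)
            P_b = bv.P
            for _ in range(3):
                beta = A_b / (self.rho * c_s)
                alpha = A_b * u_s - beta * P_s
                P_b = (Q_b - alpha) / beta
                A_b = law.area(P_b)
            bv.A, bv.Q, bv.P = A_b, Q_b, P_b
            return Q_b

        P_lv = heart.plv(t_new)
        R_v = heart.R_valve
        Q_b, P_b = 0.0, bv.P
        for _ in range(3):
            beta = A_b / (self.rho * c_s)
            alpha = A_b * u_s - beta * P_s
            P_closed = -alpha / beta
            if not heart.valve_open and P_lv > P_closed:
                heart.valve_open = True
            if heart.valve_open:
                P_b = (P_lv - alpha * R_v) / (1.0 + beta * R_v)
                Q_b = alpha + beta * P_b
                if Q_b <= 0.0:
                    heart.valve_open = False
                    Q_b, P_b = 0.0, P_closed
            else:
                Q_b, P_b = 0.0, P_closed
            A_b = law.area(P_b)
        heart.commit(t_new, Q_b, self.dt)
        bv.A, bv.Q, bv.P = A_b, Q_b, P_b
        return Q_b

    # ------------------------------------------------------------------ #

    def step(self, heart, inflow) -> tuple[float, dict[int, float]]:
        """Advance one time step; returns (root inflow, terminal outflows)."""
        A, Q, dt = self.A, self.Q, self.dt
        dxc = self.dxc
        P = self.pressures()
        c = self.wave_speeds()

        # boundary solves give segment-end values at the new time level
        t_new = self.t + dt
        q_root = self._solve_root(P, c, heart, inflow, t_new)
        for pk, children in self.junctions:
            self._solve_junction(P, c, pk, children)
        q_out = {}
        for term in self.terminals:
            q_out[term[0]] = self._solve_terminal(P, c, term)

        # interior faces at the half time level (Richtmyer predictor)
        F2 = Q * Q / A
        A_avg = 0.5 * (A[:, :-1] + A[:, 1:])
        Q_avg = 0.5 * (Q[:, :-1] + Q[:, 1:])
        dPdx = (P[:, 1:] - P[:, :-1]) / dxc
        src = -(A_avg / self.rho) * dPdx - self.k_f * self.nu * Q_avg / A_avg
        Af = A_avg - 0.5 * dt / dxc * (Q[:, 1:] - Q[:, :-1])
        Qf = Q_avg - 0.5 * dt / dxc * (F2[:, 1:] - F2[:, :-1]) + 0.5 * dt * src
        Pf = np.asarray(self.law_face.pressure(Af), dtype=float)
        F2f = Qf * Qf / Af
        if self.visc > 0.0:
            # Rusanov-type conservative dissipation on the interior faces
            # keeps steep nonlinear fronts monotone; acts on the deviation
            # from the reference taper so a tapered rest state is exact
            u = Q / A
            lam = np.abs(u) + c
            lam_f = 0.5 * (lam[:, :-1] + lam[:, 1:]) * self.visc
            dAdev = (A - self.A0_cell)
            Qf = Qf - lam_f * (dAdev[:, 1:] - dAdev[:, :-1])
            F2f = F2f - lam_f * (Q[:, 1:] - Q[:, :-1])

        # assemble full face arrays (S, M+1) including segment ends
        S, M = self.S, self.M
        Q_face = np.zeros((S, M + 1))
        F2_face = np.zeros((S, M + 1))
        P_face = np.zeros((S, M + 1))
        A_face = np.ones((S, M + 1))
        Q_face[:, 1:M] = Qf
        F2_face[:, 1:M] = F2f
        P_face[:, 1:M] = Pf
        A_face[:, 1:M] = Af
        for k in range(S):
            m = self.m_cells[k]
            bi, bo = self.bv_in[k], self.bv_out[k]
            Q_face[k, 0] = bi.Q
            F2_face[k, 0] = bi.Q * bi.Q / bi.A
            P_face[k, 0] = bi.P
            A_face[k, 0] = bi.A
            Q_face[k, m] = bo.Q
            F2_face[k, m] = bo.Q * bo.Q / bo.A
            P_face[k, m] = bo.P
            A_face[k, m] = bo.A
            if m < M:       # close padding so padded cells stay inert
                Q_face[k, m + 1:] = 0.0
                F2_face[k, m + 1:] = 0.0
                P_face[k, m + 1:] = bo.P
                A_face[k, m + 1:] = bo.A

        # corrector: conservative cell update
        dQ = Q_face[:, 1:] - Q_face[:, :-1]
        A_bar = 0.5 * (A_face[:, 1:] + A_face[:, :-1])
        Q_bar = 0.5 * (Q_face[:, 1:] + Q_face[:, :-1])
        dPf = P_face[:, 1:] - P_face[:, :-1]
        src2 = -(A_bar / self.rho) * dPf / dxc \
            - self.k_f * self.nu * Q_bar / np.maximum(A_bar, 1e-12)
        self.A = A - dt / dxc * dQ
        self.Q = Q - dt / dxc * (F2_face[:, 1:] - F2_face[:, :-1]) + dt * src2
        # keep padded cells at their reference state
        self.A[~self.active] = A[~self.active]
        self.Q[~self.active] = 0.0
        self.t = t_new
        return q_root, q_out


# ---------------------------------------------------------------------- #


def _site_cells(tree: ArterialTree, solver: _TreeSolver,
                sites: list[str] | None) -> dict[str, tuple[int, int]]:
    names = sites if sites is not None else sorted(tree.named_sites)
    out: dict[str, tuple[int, int]] = {}
    for name in names:
        sid, pos = tree.site_location(name)
        k = solver.index[sid]
        frac = pos / tree[sid].length
        j = int(np.clip(round(frac * solver.m_cells[k] - 0.5), 0,
                        solver.m_cells[k] - 1))
        out[name] = (k, j)
    out.setdefault("aortic_root", (solver.root_k, 0))
    return out


def simulate(
    tree: ArterialTree,
    heart: ElastanceHeartParams | ElastanceHeart | PrescribedInflow | None = None,
    scenario: DistensibilityScenario | None = None,
    wall_params: WallModelParams | None = None,
    n_cycles: int = 10,
    tol: float = 0.5,
    dt: float = 1e-4,
    dx: float = 0.01,
    sites: list[str] | None = None,
    zeta: float = 9.0,
    init_pressure: float = 90.0,
    min_cycles: int = 3,
    visc: float = 0.6,
) -> SimulationResult:
    """Run an arterial tree to periodic steady state and extract waveforms.

    Parameters are in user units (tol in mmHg, init_pressure in mmHg,
    dx/dt in m and s).  Cycles repeat until the maximum cycle-to-cycle
    site-pressure change is below ``tol`` or ``n_cycles`` is exhausted
    (the result is then flagged as non-converged).
    """
    if n_cycles < 2:
        raise ValueError("need n_cycles >= 2")
    wall_params = wall_params or WallModelParams()
    if scenario is not None:
        tree = apply_scenario(tree, scenario)
    tree.validate()

    inflow = None
    if heart is None:
        heart = ElastanceHeart()
    elif isinstance(heart, ElastanceHeartParams):
        heart = ElastanceHeart(heart)
    elif isinstance(heart, PrescribedInflow):
        inflow = heart
        heart = None
    if inflow is not None:
        T = inflow.T
    else:
        heart.reset()
        T = heart.T

    steps = int(round(T / dt))
    dt = T / steps
    sol = _TreeSolver(tree, wall_params, dx, dt, zeta, init_pressure,
                      visc=visc)
    cfl_dt = sol.check_cfl()
    if dt > cfl_dt:
        raise SolverError(
            f"time step {dt:.2e} s violates the CFL bound {cfl_dt:.2e} s; "
            f"reduce dt or coarsen the grid"
        )

    site_cells = _site_cells(tree, sol, sites)
    names = list(site_cells)
    ks = np.array([site_cells[nm][0] for nm in names])
    js = np.array([site_cells[nm][1] for nm in names])

    buf_P = np.empty((steps, len(names)))
    buf_Q = np.empty((steps, len(names)))
    buf_qroot = np.empty(steps)
    prev_P = None
    residuals: list[float] = []
    converged = False
    inflow_vol = 0.0
    out_vol: dict[int, float] = {}
    cycles_run = 0

    for cycle in range(n_cycles):
        inflow_vol = 0.0
        out_vol = {term[0]: 0.0 for term in sol.terminals}
        for m in range(steps):
            P_now = sol.pressures()
            buf_P[m] = P_now[ks, js]
            buf_Q[m] = sol.Q[ks, js]
            q_root, q_out = sol.step(heart, inflow)
            buf_qroot[m] = q_root
            inflow_vol += q_root * dt
            for kk, qv in q_out.items():
                out_vol[kk] += qv * dt
            if m % 200 == 0:
                sol.check_health()
        sol.check_health()
        cycles_run = cycle + 1
        if prev_P is not None:
            resid = float(np.max(np.abs(buf_P - prev_P))) * PA_TO_MMHG
            residuals.append(resid)
            if resid < tol and cycles_run >= min_cycles:
                converged = True
                break
        prev_P = buf_P.copy()

    if not converged:
        import warnings

        warnings.warn(
            f"simulation did not converge below {tol} mmHg in "
            f"{n_cycles} cycles (last residual "
            f"{residuals[-1] if residuals else float('nan'):.3f} mmHg)",
            stacklevel=2,
        )

    time = np.arange(steps) * dt
    site_pressure = {
        nm: buf_P[:, i] * PA_TO_MMHG for i, nm in enumerate(names)
    }
    site_flow = {nm: buf_Q[:, i] * M3_TO_ML for i, nm in enumerate(names)}
    site_flow["aortic_root"] = buf_qroot * M3_TO_ML
    waveforms = {}
    for nm in names:
        raw = PressureWaveform(nm, time, site_pressure[nm], 1.0 / dt, T)
        waveforms[nm] = resample(raw, ANALYSIS_FS)

    outflow_named = {
        tree[sol.ids[k]].name: v * M3_TO_ML for k, v in out_vol.items()
    }
    sv_ml = inflow_vol * M3_TO_ML
    diag = ConvergenceDiagnostics(
        converged=converged,
        cycles_run=cycles_run,
        cycle_residuals_mmhg=residuals,
        inflow_volume_ml=sv_ml,
        outflow_volumes_ml=outflow_named,
        stroke_volume_ml=sv_ml,
        cardiac_output_lmin=sv_ml / T * 60.0 / 1000.0,
    )
    return SimulationResult(
        time=time,
        period=T,
        dt=dt,
        site_pressure=site_pressure,
        site_flow=site_flow,
        waveforms=waveforms,
        diagnostics=diag,
        meta={"tube_law": wall_params.tube_law_kind, "dx": dx, "zeta": zeta},
    )
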