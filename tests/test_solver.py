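"""Numerical scheme: equilibria, boundary conditions, conservation."""

import numpy as np
import pytest

from pulsetree.experiments import make_single_tube_fixture
from pulsetree.heart import PrescribedInflow
from pulsetree.solver import (SolverError, simulate, windkessel_update,
                              _TreeSolver)
from pulsetree.topology import ArterialTree, Segment, WindkesselOutlet
from pulsetree.wall_mechanics import WallModelParams


def _zero_inflow(T=0.8):
    t = np.linspace(0.0, T, 50)
    return PrescribedInflow(t, np.zeros(50))


def test_uniform_tube_equilibrium_is_preserved():
    """Zero inflow + uniform pressure + matched outflow pressure stays put."""
    tube = make_single_tube_fixture(1.0, 20.0, 27.0)
    tube[1].windkessel = WindkesselOutlet(R1=0.1, R2=1.0, C=0.4, P_out=90.0)
    res = simulate(tube, heart=_zero_inflow(),
                   wall_params=WallModelParams(tube_law_kind="linear"),
                   n_cycles=2, tol=1.0, dt=2e-4, init_pressure=90.0,
                   min_cycles=2)
    for wave in res.site_pressure.values():
        assert np.allclose(wave, 90.0, atol=1e-6)


def test_relaxation_to_outflow_pressure():
    """With no inflow, pressures decay towards the Windkessel outflow
    pressure."""
    tube = make_single_tube_fixture(0.5, 20.0, 27.0)
    res = simulate(tube, heart=_zero_inflow(),
                   wall_params=WallModelParams(tube_law_kind="linear"),
                   n_cycles=10, tol=0.05, dt=2e-4, init_pressure=60.0)
    final = res.site_pressure["prox"][-1]
    assert final < 12.0          # P_out = 5 mmHg


def test_windkessel_dc_limit_is_exact():
    wk = WindkesselOutlet(R1=0.1, R2=1.0, C=0.8, P_out=5.0)
    Q = 70.0
    P_c = Q * wk.R2 + wk.P_out            # analytic fixed point
    P_term, P_new = windkessel_update(P_c, Q, wk, dt=1e-4)
    assert P_new == pytest.approx(P_c, rel=1e-14)
    assert P_term == pytest.approx(Q * (wk.R1 + wk.R2) + wk.P_out, rel=1e-14)
    # C -> 0 gives a purely resistive load in one step
    wk0 = WindkesselOutlet(R1=0.1, R2=1.0, C=1e-9, P_out=5.0)
    P_term0, _ = windkessel_update(40.0, Q, wk0, dt=1e-4)
    assert P_term0 == pytest.approx(Q * 1.1 + 5.0, rel=1e-4)


def test_windkessel_decay_constant():
    """Zero-inflow relaxation of the capacitor follows exp(-t/(R2 C))."""
    wk = WindkesselOutlet(R1=0.1, R2=1.2, C=0.9, P_out=5.0)
    dt = 1e-4
    n = int(round(wk.R2 * wk.C / dt))     # integrate for one time constant
    P = 100.0
    for _ in range(n):
        _, P = windkessel_update(P, 0.0, wk, dt)
    expected = wk.P_out + (100.0 - wk.P_out) * np.exp(-1.0)
    assert P == pytest.approx(expected, rel=0.05)


def test_single_tube_speed_matches_tube_law(single_tube_runs):
    """Foot-to-foot speed across two sites 0.4 m apart agrees with the
    Bramwell-Hill speed of the declared distensibility within 5%."""
    from pulsetree.pwv_analysis import transit_time

    for D, (tube, res) in single_tube_runs.items():
        ptt = transit_time(res.waveforms["prox"], res.waveforms["dist"])
        speed = tube.meta["site_distance_m"] / ptt
        assert speed == pytest.approx(tube.meta["bh_pwv"], rel=0.05), D


def test_junction_impedance_match_transmits_without_reflection():
    """A junction whose child duplicates the parent behaves like an
    unbroken tube: the waveforms either side of the junction match the
    single-tube reference, so the junction itself neither reflects nor
    attenuates."""
    wk = make_single_tube_fixture(1.0, 20.0, 27.0)[1].windkessel

    def split_tree():
        a = Segment(id=1, name="a", length=50.0, diameter_prox=20.0,
                    diameter_dist=20.0, distensibility_ref=27.0,
                    child_ids=[2], group="tube")
        b = Segment(id=2, name="b", length=50.0, diameter_prox=20.0,
                    diameter_dist=20.0, distensibility_ref=27.0,
                    parent_id=1, windkessel=wk, group="tube")
        return ArterialTree([a, b], root_id=1,
                            named_sites={"up": (1, 25.0), "down": (2, 25.0)})

    def whole_tree():
        s = Segment(id=1, name="a", length=100.0, diameter_prox=20.0,
                    diameter_dist=20.0, distensibility_ref=27.0,
                    windkessel=wk, group="tube")
        return ArterialTree([s], root_id=1,
                            named_sites={"up": (1, 25.0), "down": (1, 75.0)})

    T = 0.8
    t = np.linspace(0.0, T, 201)
    q = 80 + 40 * np.exp(-0.5 * ((t - 0.2) / 0.04) ** 2)
    q[-1] = q[0]
    wall = WallModelParams(tube_law_kind="linear")
    res_split, res_whole = (
        simulate(tree, heart=PrescribedInflow(t, q), wall_params=wall,
                 n_cycles=8, tol=0.3, dt=2e-4)
        for tree in (split_tree(), whole_tree())
    )
    for site in ("up", "down"):
        a = res_split.site_pressure[site]
        b = res_whole.site_pressure[site]
        assert np.ptp(a) == pytest.approx(np.ptp(b), rel=0.02)
        assert np.max(np.abs(a - b)) < 0.02 * np.ptp(b)


def test_junction_flow_balance(config_results):
    """Terminal outflow volumes sum to the inflow volume, so junction
    flow residuals cannot accumulate anywhere in the tree."""
    # small residual capacitor storage remains at the convergence
    # tolerance; the discrete scheme itself conserves volume to round-off
    d = config_results["2KDN"].diagnostics
    assert sum(d.outflow_volumes_ml.values()) == pytest.approx(
        d.inflow_volume_ml, rel=2e-3
    )


def test_cfl_violation_is_reported():
    tube = make_single_tube_fixture(1.0, 20.0, 27.0)
    with pytest.raises(SolverError, match="CFL"):
        simulate(tube, heart=_zero_inflow(),
                 wall_params=WallModelParams(tube_law_kind="linear"),
                 n_cycles=2, dt=5e-3, dx=0.01)


def test_temporal_convergence_single_tube():
    """Halving the time step changes systolic pressure by < 0.5 mmHg."""

    def sbp(dt):
        tube = make_single_tube_fixture(1.0, 20.0, 27.0, mean_flow_mls=70.0)
        T = 0.8
        t = np.linspace(0.0, T, 201)
        q = 80 + 40 * np.exp(-0.5 * ((t - 0.2) / 0.04) ** 2)
        q[-1] = q[0]
        res = simulate(tube, heart=PrescribedInflow(t, q),
                       wall_params=WallModelParams(tube_law_kind="linear"),
                       n_cycles=8, tol=0.2, dt=dt, init_pressure=95.0)
        return res.site_pressure["prox"].max()

    assert abs(sbp(2e-4) - sbp(1e-4)) < 0.5


def test_instability_diagnostic_names_segment():
    tube = make_single_tube_fixture(1.0, 20.0, 27.0)
    wall = WallModelParams(tube_law_kind="linear")
    sol = _TreeSolver(tube, wall, 0.01, 2e-4, 9.0, 90.0)
    sol.A[0, 3] = np.nan
    with pytest.raises(SolverError, match="tube"):
        sol.check_health()


def test_results_are_deterministic():
    """Identical settings give bit-identical waveforms."""
    def run():
        tube = make_single_tube_fixture(0.5, 20.0, 27.0)
        return simulate(tube, heart=_zero_inflow(),
                        wall_params=WallModelParams(tube_law_kind="linear"),
                        n_cycles=3, tol=5.0, dt=2e-4, init_pressure=80.0)

    a, b = run(), run()
    assert np.array_equal(a.site_pressure["prox"], b.site_pressure["prox"])


def test_simulation_result_export(tmp_path, single_tube_runs):
    import pandas as pd

    _, res = single_tube_runs[27.0]
    res.to_csv(tmp_path)
    df = pd.read_csv(tmp_path / "prox.csv")
    assert {"time_s", "pressure_mmhg", "flow_ml_s"} <= set(df.columns)
    assert len(df) == len(res.time)
    res.to_hdf(tmp_path / "f.h5")
    import h5py

    with h5py.File(tmp_path / "f.h5") as fh:
        assert "sites/prox/pressure_mmhg" in fh
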