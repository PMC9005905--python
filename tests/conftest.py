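"""Shared fixtures.

The expensive periodic-steady-state runs (four kidney configurations,
the stiffened comparison and the single-tube wave-speed fixtures) are
session-scoped so the study, solver and acceptance tests share them.
"""

import numpy as np
import pytest

from pulsetree.experiments import (StudySpec, make_reference_tree,
                                   make_single_tube_fixture)
from pulsetree.heart import PrescribedInflow
from pulsetree.solver import simulate
from pulsetree.wall_mechanics import (DistensibilityScenario, WallModelParams,
                                      apply_scenario)

SOLVER_OPTS = dict(n_cycles=14, tol=0.3, dt=1e-4, dx=0.01)


@pytest.fixture(scope="session")
def ref_tree():
    return make_reference_tree()


def _run_config(config, scenario=None):
    tree = make_reference_tree().apply_kidney_configuration(config)
    if scenario is not None:
        tree = apply_scenario(tree, scenario)
    return simulate(tree, **SOLVER_OPTS)


@pytest.fixture(scope="session")
def config_results():
    """Converged runs of all four kidney configurations (default wall)."""
    return {cfg: _run_config(cfg) for cfg in ("2KDN", "1KDN", "0KDN", "TX")}


@pytest.fixture(scope="session")
def nonuni_result():
    """0KDN with the diameter-stratified distensibility reduction."""
    return _run_config(
        "0KDN", DistensibilityScenario(kind="nonuniform_by_diameter")
    )


def run_single_tube(distensibility, diameter_mm=20.0, mean_flow=17.0,
                    pulse=40.0, n_cycles=8):
    """Drive a matched single tube near the reference pressure with a
    small base flow (advection would otherwise bias the foot speed by
    u/c ~ 4%); the linear tube law keeps the local wave speed at the
    Bramwell-Hill value of the declared distensibility."""
    tube = make_single_tube_fixture(1.0, diameter_mm, distensibility,
                                    mean_flow_mls=15.0)
    T = 0.8
    t = np.linspace(0.0, T, 201)
    q = mean_flow + pulse * np.exp(-0.5 * ((t - 0.2) / 0.04) ** 2)
    q -= (q.mean() - mean_flow)          # keep the stated mean flow
    q[-1] = q[0]
    inflow = PrescribedInflow(t, q)
    wall = WallModelParams(tube_law_kind="linear")
    res = simulate(tube, heart=inflow, wall_params=wall, n_cycles=n_cycles,
                   tol=0.5, dt=2e-4, dx=0.01, init_pressure=95.0)
    return tube, res


@pytest.fixture(scope="session")
def single_tube_runs():
    return {D: run_single_tube(D) for D in (27.0, 10.6, 2.6)}
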