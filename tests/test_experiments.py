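"""Study runners, synthetic fixtures and the staged-kidney findings."""

import numpy as np
import pytest

from pulsetree.experiments import (DEFAULT_PATHS, StudySpec,
                                   make_delayed_pair, make_reference_tree,
                                   make_single_tube_fixture,
                                   run_distensibility_sweep)
from pulsetree.heart import PrescribedInflow
from pulsetree.pwv_analysis import measure_pwv, wave_metrics
from pulsetree.wall_mechanics import WallModelParams

CONFIG_ORDER = ["2KDN", "1KDN", "0KDN"]
TABLE_SITES = ["aortic_root", "carotid", "radial", "digital"]


def _pwv(result, tree, a, b):
    path = tree.arterial_path(a, b)
    return measure_pwv(result.waveforms[a], result.waveforms[b], path).pwv


# ---------------------------------------------------------------------- #
# synthetic fixtures


def test_single_tube_fixture_ground_truth():
    tube = make_single_tube_fixture(1.0, 20.0, 27.0)
    assert tube.meta["bh_pwv"] == pytest.approx(5.9, abs=0.05)
    assert tube.meta["site_distance_m"] == pytest.approx(0.4)
    small = make_single_tube_fixture(1.0, 4.0, 2.6)
    assert small.meta["bh_pwv"] == pytest.approx(19.1, abs=0.05)
    with pytest.raises(ValueError):
        make_single_tube_fixture(-1.0, 20.0, 27.0)


def test_delayed_pair_determinism_and_bounds():
    a1 = make_delayed_pair(delay=0.08, noise_rms=1.0, seed=7)
    a2 = make_delayed_pair(delay=0.08, noise_rms=1.0, seed=7)
    assert np.array_equal(a1[0].pressures, a2[0].pressures)
    assert np.array_equal(a1[1].pressures, a2[1].pressures)
    b = make_delayed_pair(delay=0.08, noise_rms=1.0, seed=8)
    assert not np.array_equal(a1[0].pressures, b[0].pressures)
    with pytest.raises(ValueError):
        make_delayed_pair(delay=0.9)


def test_reference_tree_is_valid_and_complete(ref_tree):
    ref_tree.validate()
    assert {"carotid", "brachial", "radial", "digital", "iliac", "femoral",
            "renal_left", "renal_right"} <= set(ref_tree.named_sites)
    assert ref_tree[36].terminal and ref_tree[38].terminal
    # resting flow fractions are a partition of the cardiac output
    from pulsetree.experiments import DEFAULT_FLOW_FRACTIONS

    assert sum(DEFAULT_FLOW_FRACTIONS.values()) == pytest.approx(1.0)
    assert set(DEFAULT_FLOW_FRACTIONS) == set(ref_tree.terminal_ids)


def test_study_spec_validation():
    with pytest.raises(ValueError, match="unknown kidney"):
        StudySpec(configs=["5KDN"])


# ---------------------------------------------------------------------- #
# staged-kidney-removal findings (on the shared converged runs)


def test_all_configurations_converge(config_results):
    for cfg, res in config_results.items():
        assert res.diagnostics.converged, cfg


def test_sbp_rises_with_staged_kidney_removal(config_results):
    """SBP strictly increases 2KDN -> 1KDN -> 0KDN at every site."""
    for site in TABLE_SITES:
        sbp = [wave_metrics(config_results[c].waveforms[site]).SBP
               for c in CONFIG_ORDER]
        assert sbp[0] < sbp[1] < sbp[2], site


def test_pulse_pressure_rises_with_staged_kidney_removal(config_results):
    for site in TABLE_SITES:
        pp = [wave_metrics(config_results[c].waveforms[site]).PP
              for c in CONFIG_ORDER]
        assert pp[0] < pp[1] < pp[2], site


def test_pwv_rises_with_staged_kidney_removal(config_results, ref_tree):
    for a, b in DEFAULT_PATHS:
        v = [_pwv(config_results[c], ref_tree, a, b) for c in CONFIG_ORDER]
        assert v[0] < v[1] < v[2], (a, b)


def test_transplant_restores_towards_single_kidney(config_results, ref_tree):
    """TX pressures and PWVs sit between 1KDN and 0KDN, near 1KDN."""
    for site in TABLE_SITES:
        vals = {c: wave_metrics(config_results[c].waveforms[site]).SBP
                for c in config_results}
        assert vals["2KDN"] < vals["TX"] < vals["0KDN"]
        assert abs(vals["TX"] - vals["1KDN"]) < abs(vals["TX"] - vals["0KDN"])
    for a, b in DEFAULT_PATHS:
        vals = {c: _pwv(config_results[c], ref_tree, a, b)
                for c in config_results}
        assert abs(vals["TX"] - vals["1KDN"]) < abs(vals["TX"] - vals["0KDN"])


def test_peak_peripheral_flow_falls_with_kidney_removal(config_results):
    """Stepwise kidney removal lowers peak carotid and radial flow."""
    for site in ["carotid", "radial"]:
        peaks = [config_results[c].site_flow[site].max() for c in CONFIG_ORDER]
        assert peaks[0] > peaks[2], site


def test_aortic_flow_decreases_downstream(config_results):
    res = config_results["2KDN"]
    assert res.site_flow["aortic_root"].max() > \
        res.site_flow["abdominal_aorta"].max() > \
        res.site_flow["carotid"].max() > res.site_flow["digital"].max()


# ---------------------------------------------------------------------- #
# distensibility sweep (linear wall, small factor set)


def test_sweep_pwv_monotone_and_scaling():
    """Foot-to-foot PWV decreases with rising distensibility; with the
    linear law an 80% distensibility cut speeds the wave by ~sqrt(5)."""
    spec = StudySpec(configs=["2KDN"],
                     wall=WallModelParams(tube_law_kind="linear"),
                     n_cycles=10, tol=0.5, dt=1e-4)
    report = run_distensibility_sweep(spec, factors=(-0.8, 0.0))
    pwv = report.pwv
    assert report.convergence["2KDN@-0.8"] and report.convergence["2KDN@+0.0"]
    for row in ("cfPWV", "crPWV", "rdPWV"):
        assert pwv.loc[row, "2KDN@-0.8"] > pwv.loc[row, "2KDN@+0.0"]
    ratio = pwv.loc["cfPWV", "2KDN@-0.8"] / pwv.loc["cfPWV", "2KDN@+0.0"]
    assert ratio == pytest.approx(np.sqrt(5.0), rel=0.15)


def test_sweep_rejects_bad_factor():
    with pytest.raises(ValueError):
        run_distensibility_sweep(StudySpec(configs=["2KDN"]), factors=(-1.0,))
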