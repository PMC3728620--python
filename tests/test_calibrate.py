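import numpy as np
import pytest

from phendo import measured_tau, model_tau, recover_cell_params
from phendo.calibrate import (
    MOUSE_37C_CONSTRAINTS,
    RAT_30C_CONSTRAINTS,
    RAT_37C_CONSTRAINTS,
    _measured_line,
    calibrate_defaults,
    cell_from_config,
)


def test_rat_37c_hits_measured_constraints(defaults):
    p = defaults["37C"]["cell"]
    t = {
        n: measured_tau(p["tau1"], p["slope_m"], p["alpha_max"], p["delta_a"], p["tau_pers"], n)
        for n in (5, 25, 100, 300)
    }
    c = RAT_37C_CONSTRAINTS
    assert (t[5] - t[25]) / t[5] == pytest.approx(c["accel_5_25"], abs=1e-4)
    assert (t[100] - t[25]) / t[25] == pytest.approx(c["slow_25_100"], abs=1e-4)
    assert (t[300] - t[100]) / t[100] == pytest.approx(c["slow_100_300"], abs=1e-4)
    assert t[5] == pytest.approx(c["tau_5ap"], rel=1e-4)


def test_rat_30c_hits_measured_line_and_ca_ratio(defaults):
    p = defaults["30C"]["cell"]
    sl, ic = _measured_line(
        p["tau1"], p["slope_m"], p["alpha_max"], p["delta_a"], p["tau_pers"]
    )
    c = RAT_30C_CONSTRAINTS
    assert sl == pytest.approx(c["slope"], abs=1e-4)
    assert ic == pytest.approx(c["intercept"], rel=1e-3)
    f = defaults["30C"]["condition_factors"]["ca_slope_factor"]
    sl4, _ = _measured_line(
        p["tau1"], f * p["slope_m"], p["alpha_max"], p["delta_a"], p["tau_pers"]
    )
    assert sl4 / sl == pytest.approx(c["ca_slope_ratio"], rel=1e-3)


def test_mouse_37c_hits_measured_constraints(defaults):
    p = defaults["37C_mouse"]["cell"]
    t = {
        n: measured_tau(p["tau1"], p["slope_m"], p["alpha_max"], p["delta_a"], p["tau_pers"], n)
        for n in (10, 100)
    }
    c = MOUSE_37C_CONSTRAINTS
    assert (t[10] - t[100]) / t[10] == pytest.approx(c["accel_10_100"], abs=1e-4)
    assert t[100] == pytest.approx(c["tau_100ap"], rel=1e-4)


def test_measured_tau_exceeds_model_tau_for_long_trains(defaults):
    # the finite-tail fit reads a long slow decay as slower still at small
    # n but compresses large taus; both stay positive and ordered in n
    p = defaults["37C"]["cell"]
    args = (p["tau1"], p["slope_m"], p["alpha_max"], p["delta_a"], p["tau_pers"])
    for n in (5, 100):
        assert measured_tau(*args, n) > 0
        assert model_tau(*args, n) > 0
    assert measured_tau(*args, 300) > measured_tau(*args, 100)


def test_tuning_curve_minimum_at_25ap(defaults):
    p = defaults["37C"]["cell"]
    stimuli = (5, 10, 15, 25, 50, 100)
    args = (p["tau1"], p["slope_m"], p["alpha_max"], p["delta_a"], p["tau_pers"])
    measured = [measured_tau(*args, n) for n in stimuli]
    true = [model_tau(*args, n) for n in stimuli]
    assert stimuli[int(np.argmin(measured))] == 25
    assert stimuli[int(np.argmin(true))] == 25


def test_recover_cell_params_round_trip():
    truth = dict(tau1=12.0, slope_m=0.03)
    alpha, delta, tp = 0.7, 0.2, 20.0
    measured = {
        n: measured_tau(truth["tau1"], truth["slope_m"], alpha, delta, tp, n)
        for n in (5, 25, 100)
    }
    rec = recover_cell_params(measured, alpha_max=alpha, delta_a=delta)
    assert rec["tau1"] == pytest.approx(truth["tau1"], rel=1e-6)
    assert rec["slope_m"] == pytest.approx(truth["slope_m"], rel=1e-5)
    with pytest.raises(ValueError):
        recover_cell_params({5: 8.0}, alpha_max=alpha, delta_a=delta)


def test_defaults_structure_and_cache(defaults):
    assert set(defaults) == {"37C", "30C", "37C_mouse"}
    for section in defaults.values():
        assert {"cell", "population", "fit", "condition_factors"} <= set(section)
    # memoized: the no-constraint call returns the same object
    assert calibrate_defaults() is calibrate_defaults()


def test_cell_from_config_matches_section(defaults, cell37):
    sec = defaults["37C"]
    assert cell37 == cell_from_config(sec)
    assert cell37.tau1 == sec["cell"]["tau1"]
    assert cell37.n_vesicles == 2000


def test_shipped_yaml_matches_calibration(defaults):
    from phendo import load_default_config

    for name in ("37C", "30C", "37C_mouse"):
        shipped = load_default_config(name)
        calc = defaults[name]
        for key, val in calc["cell"].items():
            assert shipped["cell"][key] == pytest.approx(val, rel=1e-9), (name, key)
        assert shipped["population"] == pytest.approx(calc["population"], rel=1e-9)
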