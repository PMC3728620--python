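import math

import pytest

from phendo import (
    AccelState,
    CellKinetics,
    accel_after_train,
    apply_condition,
    apply_genotype,
    effective_tau,
    update_accel_state,
)
from phendo.kinetics import decay_accel, increment_accel


def make_cell(**kw):
    base = dict(tau1=10.0, slope_m=0.058, alpha_max=0.5, delta_a=0.2, tau_pers=20.0)
    base.update(kw)
    return CellKinetics(**base)


def test_saturating_increment_closed_form():
    # a_n = 1 - (1 - delta)^n for instantaneous APs
    cell = make_cell()
    a = accel_after_train(cell.replace(tau_pers=1e12), 5, 1e9)
    assert a == pytest.approx(1.0 - 0.8**5, rel=1e-9)


def test_exponential_state_decay():
    s = AccelState(a=0.5, t_last=0.0)
    s2 = decay_accel(s, 20.0, tau_pers=20.0)
    assert s2.a == pytest.approx(0.5 * math.exp(-1.0), rel=1e-12)
    with pytest.raises(ValueError):
        decay_accel(s2, 0.0, tau_pers=20.0)  # time must not run backwards


def test_increment_saturates_below_one():
    s = AccelState(a=0.999, t_last=0.0)
    for _ in range(100):
        s = increment_accel(s, 0.5)
    assert s.a <= 1.0


def test_effective_tau_formula():
    cell = make_cell()
    # tau1*(1 - alpha*a) + m*(n-1)
    assert effective_tau(cell, 100, 0.5) == pytest.approx(10.0 * 0.75 + 0.058 * 99)
    assert effective_tau(cell, 1, 0.0) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        effective_tau(cell, 100, 1.5)
    with pytest.raises(ValueError):
        effective_tau(cell, 0, 0.0)


def test_update_accel_state_requires_exactly_one_event():
    cell = make_cell()
    s = AccelState()
    with pytest.raises(ValueError):
        update_accel_state(s, cell)
    with pytest.raises(ValueError):
        update_accel_state(s, cell, ap_time=1.0, t=1.0)


def test_accel_train_between_limits():
    cell = make_cell()
    a_fast = accel_after_train(cell, 10, 1e9)  # no decay between APs
    a_slow = accel_after_train(cell, 10, 0.01)  # long gaps, heavy decay
    a_mid = accel_after_train(cell, 10, 10.0)
    assert a_slow < a_mid < a_fast
    assert 0.0 <= a_slow and a_fast <= 1.0


def test_genotype_presets():
    cell = make_cell()
    a = apply_genotype(cell, "S774_8A")
    assert a.tau1 == pytest.approx(cell.tau1 * (1 - cell.alpha_max))
    assert a.alpha_max == 0.0 and a.delta_a == 0.0
    assert a.slope_m == cell.slope_m  # slowing retained

    d = apply_genotype(cell, "S774_8D")
    assert d.tau1 == cell.tau1
    assert d.alpha_max == 0.0 and d.delta_a == 0.0

    dko = apply_genotype(cell, "dyn13_DKO")
    assert dko.tau1 == pytest.approx(10 * cell.tau1)
    assert dko.slope_m == 0.0

    assert apply_genotype(cell, "control") == cell
    assert apply_genotype(cell, "dyn1_rescue") == cell
    with pytest.raises(ValueError):
        apply_genotype(cell, "unknown")


def test_condition_presets():
    cell = make_cell()
    ca4 = apply_condition(cell, "control", 4.0, ca_slope_factor=8.0)
    assert ca4.slope_m == pytest.approx(8 * cell.slope_m)
    assert ca4.tau1 == cell.tau1

    egta = apply_condition(cell, "EGTA", 2.0, egta_slow_factor=1.5, egta_residual_alpha=0.1)
    assert egta.slope_m == 0.0
    assert egta.tau1 == pytest.approx(1.5 * cell.tau1)
    assert egta.alpha_max <= 0.1

    baf = apply_condition(cell, "bafilomycin", 2.0)
    assert baf.tau1 == cell.tau1  # pharmacology of the reporter, not kinetics


@pytest.mark.parametrize(
    "kw",
    [dict(tau1=-1.0), dict(alpha_max=1.0), dict(delta_a=1.5), dict(p_release=0.0),
     dict(slope_m=-0.1), dict(n_vesicles=0), dict(noise_sd=-1.0)],
)
def test_cell_validation(kw):
    with pytest.raises(ValueError):
        make_cell(**kw)
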