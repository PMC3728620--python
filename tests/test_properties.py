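"""Property-based invariants (hypothesis)."""

import numpy as np
import pytest

hypothesis = pytest.importorskip("hypothesis")
from hypothesis import given, settings, strategies as st  # noqa: E402

from phendo import (  # noqa: E402
    BiexpParams,
    CellKinetics,
    accel_after_train,
    biexp_fluorescence,
    effective_tau,
    read_trace,
    simulate_trace,
    single_burst,
    write_trace,
)
from phendo.simulate import lognormal_from_mean_cv  # noqa: E402

COMMON = settings(max_examples=25, deadline=None, derandomize=True)

cell_st = st.builds(
    CellKinetics,
    tau1=st.floats(1.0, 50.0),
    slope_m=st.floats(0.0, 0.2),
    alpha_max=st.floats(0.0, 0.95),
    delta_a=st.floats(0.0, 1.0),
    tau_pers=st.floats(1.0, 100.0),
)


@COMMON
@given(cell=cell_st, n_ap=st.integers(1, 300), freq=st.floats(0.1, 100.0))
def test_accel_state_bounded(cell, n_ap, freq):
    a = accel_after_train(cell, n_ap, freq)
    assert 0.0 <= a <= 1.0


@COMMON
@given(cell=cell_st, n_ap=st.integers(1, 300), a1=st.floats(0.0, 1.0), a2=st.floats(0.0, 1.0))
def test_effective_tau_positive_and_monotone_in_acceleration(cell, n_ap, a1, a2):
    lo, hi = sorted((a1, a2))
    t_lo, t_hi = effective_tau(cell, n_ap, lo), effective_tau(cell, n_ap, hi)
    assert t_lo > 0 and t_hi > 0
    assert t_hi <= t_lo  # more acceleration never slows endocytosis


@COMMON
@given(
    tau_e=st.floats(0.5, 60.0),
    tau_r=st.floats(0.0, 20.0),
    t=st.floats(0.0, 200.0),
)
def test_biexp_bounded_unit_interval(tau_e, tau_r, t):
    f = biexp_fluorescence(BiexpParams(tau_e, tau_r), t)
    assert 0.0 <= f <= 1.0 + 1e-12


@COMMON
@given(mean=st.floats(0.5, 50.0), cv=st.floats(0.0, 1.5), seed=st.integers(0, 2**31))
def test_lognormal_draws_positive(mean, cv, seed):
    x = lognormal_from_mean_cv(np.random.default_rng(seed), mean, cv, 50)
    assert np.all(x > 0)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(n_ap=st.integers(1, 120), seed=st.integers(0, 2**31))
def test_simulated_counts_conserved(n_ap, seed):
    cell = CellKinetics(tau1=8.0, slope_m=0.02, alpha_max=0.5, delta_a=0.2,
                        tau_pers=20.0, n_vesicles=500, p_release=0.01, noise_sd=0.0)
    _, states = simulate_trace(cell, single_burst(n_ap, 10.0), seed, return_states=True)
    assert np.all(states.total() == cell.n_vesicles)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31))
def test_trace_io_round_trip(seed, tmp_path_factory):
    cell = CellKinetics(tau1=8.0, slope_m=0.02, alpha_max=0.5, delta_a=0.2,
                        tau_pers=20.0, n_vesicles=500, p_release=0.01, noise_sd=3.0)
    tr = simulate_trace(cell, single_burst(10, 10.0), seed)
    path = tmp_path_factory.mktemp("io") / "t.tsv"
    write_trace(tr, path)
    back = read_trace(path)
    assert np.array_equal(back.t, tr.t)
    assert np.array_equal(back.dF, tr.dF)
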