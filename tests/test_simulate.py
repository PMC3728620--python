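import numpy as np
import pytest

from phendo import (
    CellKinetics,
    PopulationSpec,
    draw_population,
    expected_trace,
    simulate_population,
    simulate_trace,
    single_burst,
)
from phendo.simulate import burst_effective_taus, lognormal_from_mean_cv


def make_cell(**kw):
    base = dict(tau1=8.0, slope_m=0.02, alpha_max=0.5, delta_a=0.2, tau_pers=20.0,
                tau_reacid=2.5, n_vesicles=2000, p_release=0.01, noise_sd=0.0)
    base.update(kw)
    return CellKinetics(**base)


def test_seed_is_mandatory():
    with pytest.raises(ValueError):
        simulate_trace(make_cell(), single_burst(5, 10.0), None)


def test_determinism_and_seed_sensitivity():
    cell = make_cell(noise_sd=5.0)
    prot = single_burst(25, 10.0)
    a = simulate_trace(cell, prot, 42)
    b = simulate_trace(cell, prot, 42)
    c = simulate_trace(cell, prot, 43)
    assert np.array_equal(a.dF, b.dF)
    assert not np.array_equal(a.dF, c.dF)


def test_vesicle_conservation():
    cell = make_cell()
    for n_ap in (5, 100):
        _, states = simulate_trace(cell, single_burst(n_ap, 10.0), 7, return_states=True)
        assert np.all(states.total() == cell.n_vesicles)
        for arr in (states.available, states.surface, states.internalized, states.reacidified):
            assert np.all(arr >= 0)


def test_bafilomycin_trace_monotone_and_cumulative():
    cell = make_cell()
    prot = single_burst(200, 10.0, condition="bafilomycin", post_window=30.0)
    tr, states = simulate_trace(cell, prot, 3, return_states=True)
    assert np.all(np.diff(tr.dF) >= 0)
    assert np.all(states.reacidified == 0)


def test_noiseless_trace_is_integer_counts():
    tr = simulate_trace(make_cell(), single_burst(25, 10.0), 5)
    assert np.allclose(tr.dF, np.round(tr.dF))


def test_pool_exhaustion_warns_once():
    cell = make_cell(n_vesicles=5, p_release=0.9)
    with pytest.warns(RuntimeWarning, match="pool exhausted"):
        simulate_trace(cell, single_burst(100, 10.0), 1)


def test_expected_trace_matches_ensemble_mean():
    cell = make_cell()
    prot = single_burst(25, 10.0)
    exp = expected_trace(cell, prot)
    sims = np.mean([simulate_trace(cell, prot, s).dF for s in range(300)], axis=0)
    peak = exp.dF.max()
    assert np.max(np.abs(sims - exp.dF)) < 0.05 * peak


def test_expected_trace_bafilomycin_is_cumulative_release():
    cell = make_cell()
    prot = single_burst(50, 10.0, condition="bafilomycin", post_window=30.0)
    exp = expected_trace(cell, prot)
    released = cell.n_vesicles * (1 - (1 - cell.p_release) ** 50)
    assert exp.dF[-1] == pytest.approx(released, rel=1e-12)
    assert np.all(np.diff(exp.dF) >= 0)


def test_burst_effective_taus_second_burst_accelerated():
    from phendo import burst_train

    cell = make_cell()
    prot = burst_train(n_bursts=2, n_ap=5, freq=10.0, spacing=20.0)
    taus = burst_effective_taus(cell, prot)
    assert taus[1] < taus[0]  # residual acceleration persists into burst 2


def test_lognormal_mean_cv(rng):
    x = lognormal_from_mean_cv(rng, mean=10.0, cv=0.5, size=200_000)
    assert x.mean() == pytest.approx(10.0, rel=0.02)
    assert x.std() / x.mean() == pytest.approx(0.5, rel=0.03)
    y = lognormal_from_mean_cv(rng, mean=3.0, cv=0.0, size=10)
    assert np.all(y == 3.0)


def test_draw_population_deterministic():
    spec = PopulationSpec(n_cells=5, tau1_mean=10.0, tau1_cv=0.3,
                          slope_mean=0.05, slope_cv=0.5, base=make_cell())
    a = draw_population(spec, np.random.SeedSequence(1))
    b = draw_population(spec, np.random.SeedSequence(1))
    assert [c.tau1 for c in a] == [c.tau1 for c in b]
    assert all(c.tau1 > 0 and c.slope_m >= 0 for c in a)


def test_simulate_population_shape_and_metadata():
    spec = PopulationSpec(n_cells=2, tau1_mean=10.0, tau1_cv=0.2,
                          slope_mean=0.05, slope_cv=0.3, base=make_cell())
    prots = [single_burst(5, 10.0), single_burst(25, 10.0)]
    pop = simulate_population(spec, prots, seed=9, n_repeats=2)
    assert len(pop) == 2
    for ci, per_cell in enumerate(pop):
        assert set(per_cell) == set(prots)
        for runs in per_cell.values():
            assert len(runs) == 2
            assert all(tr.meta.cell_id == f"cell{ci}" for tr in runs)
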