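import numpy as np
import pytest

from phendo import (
    FluorescenceTrace,
    adjusted_r2,
    fit_config_for,
    fit_exp_offset,
    fit_linear_rate,
    fit_rising_exp,
    remaining_fraction,
    single_burst,
)
from phendo.fitting import FitConfig, WindowError


def trace_from(fn, duration=100.0, dt=0.5, protocol=None):
    protocol = protocol or single_burst(1, 10.0, onset=0.0, post_window=duration)
    t = np.arange(0.0, duration + dt / 2, dt)
    return FluorescenceTrace(t=t, dF=fn(t), protocol=protocol)


def grid_oracle_sse(tt, yy, t0):
    """Dense grid least squares over (A, tau) for A*exp(-(t-t0)/tau)."""
    best = np.inf
    for tau in np.linspace(0.5, 60.0, 4000):
        shape = np.exp(-(tt - t0) / tau)
        a = float(np.dot(yy, shape) / np.dot(shape, shape))  # optimal A given tau
        sse = float(np.sum((a * shape - yy) ** 2))
        best = min(best, sse)
    return best


def test_exact_recovery_noiseless_exponential():
    cfg = FitConfig(offset_t0=2.5, window_len=60.0, window_mode="tail")
    tr = trace_from(lambda t: 7.0 * np.exp(-(t - 2.5) / 10.0))
    fit = fit_exp_offset(tr, 0, cfg)
    assert fit.converged
    assert fit.tau == pytest.approx(10.0, rel=1e-6)
    assert fit.amplitude == pytest.approx(7.0, rel=1e-6)
    assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)


def test_window_robustness_noiseless():
    tr = trace_from(lambda t: 5.0 * np.exp(-(t - 2.5) / 8.0), duration=150.0)
    tau1 = fit_exp_offset(tr, 0, FitConfig(offset_t0=2.5, window_len=40.0)).tau
    tau2 = fit_exp_offset(tr, 0, FitConfig(offset_t0=2.5, window_len=80.0)).tau
    assert abs(tau2 - tau1) / tau1 < 1e-6


def test_fit_sse_beats_grid_oracle():
    rng = np.random.default_rng(0)
    cfg = FitConfig(offset_t0=2.5, window_len=60.0, window_mode="tail")
    tr = trace_from(lambda t: 50.0 * np.exp(-(t - 2.5) / 6.0))
    tr.dF = tr.dF + rng.normal(0, 2.0, tr.dF.shape)
    fit = fit_exp_offset(tr, 0, cfg)
    m = (tr.t >= 2.5 - 1e-9) & (tr.t <= 62.5 + 1e-9)
    tt, yy = tr.t[m], tr.dF[m]
    sse_fit = float(np.sum((fit.amplitude * np.exp(-(tt - 2.5) / fit.tau) - yy) ** 2))
    assert sse_fit <= grid_oracle_sse(tt, yy, 2.5) + 1e-8


def test_plateau_mode_recovers_plateau_decay():
    cfg = FitConfig(offset_t0=3.0, window_len=60.0, window_mode="plateau")
    tr = trace_from(lambda t: 4.0 * np.exp(-np.maximum(t - 3.0, 0.0) / 12.0))
    fit = fit_exp_offset(tr, 0, cfg)
    assert fit.converged
    assert fit.tau == pytest.approx(12.0, rel=1e-6)


def test_free_baseline_mode():
    cfg = FitConfig(offset_t0=2.5, window_len=60.0, baseline_mode="free")
    tr = trace_from(lambda t: 6.0 * np.exp(-(t - 2.5) / 9.0) + 1.5)
    fit = fit_exp_offset(tr, 0, cfg)
    assert fit.tau == pytest.approx(9.0, rel=1e-5)
    assert fit.baseline == pytest.approx(1.5, rel=1e-4)


def test_nondecaying_input_reports_nonconvergence():
    tr = trace_from(lambda t: 1.0 + 0.01 * t)
    fit = fit_exp_offset(tr, 0, FitConfig(offset_t0=2.5))
    assert not fit.converged


def test_window_error_on_too_few_points():
    prot = single_burst(1, 10.0, onset=0.0, post_window=60.0, sample_interval=0.5)
    t = np.array([0.0, 1.0, 3.0])
    tr = FluorescenceTrace(t=t, dF=np.ones(3), protocol=prot)
    with pytest.raises(WindowError):
        fit_exp_offset(tr, 0, FitConfig(offset_t0=0.0, window_len=5.0))


def test_window_clipped_at_next_burst():
    from phendo import burst_train

    prot = burst_train(n_bursts=2, n_ap=5, freq=10.0, spacing=20.0)
    t = np.arange(0.0, prot.trace_duration, 0.5)
    tr = FluorescenceTrace(t=t, dF=np.exp(-t / 10.0), protocol=prot)
    fit = fit_exp_offset(tr, 0, FitConfig(offset_t0=2.5, window_len=60.0))
    assert fit.window[1] <= prot.bursts[1].onset + 1e-9


def test_linear_rate_exact_line():
    cfg = FitConfig(offset_t0=0.0, window_len=5.0, window_mode="tail")
    tr = trace_from(lambda t: 10.0 - 1.0 * t, duration=8.0, dt=0.25)
    fit = fit_linear_rate(tr, 0, cfg)
    assert fit.converged
    assert fit.amplitude == pytest.approx(10.0, rel=1e-9)
    assert fit.tau == pytest.approx(10.0, rel=1e-9)  # 1/Rate, amplitude-normalized


def test_linear_rate_matches_ols_oracle():
    cfg = FitConfig(offset_t0=0.0, window_len=3.0, window_mode="tail")
    tr = trace_from(lambda t: np.exp(-t / 10.0), duration=10.0, dt=0.25)
    fit = fit_linear_rate(tr, 0, cfg)
    m = (tr.t >= -1e-9) & (tr.t <= 3.0 + 1e-9)
    slope, intercept = np.polyfit(tr.t[m], tr.dF[m], 1)
    assert fit.tau == pytest.approx(intercept / abs(slope), rel=1e-9)


def test_linear_rate_rejects_rising_data():
    cfg = FitConfig(offset_t0=0.0, window_len=5.0, window_mode="tail")
    tr = trace_from(lambda t: 1.0 + t, duration=8.0, dt=0.25)
    assert not fit_linear_rate(tr, 0, cfg).converged


def test_remaining_fraction_interpolated():
    tr = trace_from(lambda t: np.exp(-t / 15.0), duration=40.0)
    # burst ends at t=0; value at 15 s over value at 0
    assert remaining_fraction(tr, 0, at_s=15.0) == pytest.approx(np.exp(-1.0), rel=1e-6)
    with pytest.raises(ValueError):
        remaining_fraction(tr, 0, at_s=100.0)


def test_rising_exp_recovery():
    prot = single_burst(300, 10.0, onset=0.0, post_window=30.0, condition="bafilomycin")
    t = np.arange(0.0, prot.trace_duration, 0.5)
    dF = 2000.0 * (1.0 - np.exp(-t / 9.95))
    dF[t > prot.bursts[0].t_end] = dF[t <= prot.bursts[0].t_end][-1]
    tr = FluorescenceTrace(t=t, dF=dF, protocol=prot)
    fit = fit_rising_exp(tr)
    assert fit.converged
    assert fit.tau == pytest.approx(9.95, rel=1e-3)
    assert fit.amplitude == pytest.approx(2000.0, rel=1e-3)


def test_rising_exp_nonsaturating_flagged():
    prot = single_burst(50, 10.0, onset=0.0, post_window=30.0, condition="bafilomycin")
    t = np.arange(0.0, prot.trace_duration, 0.5)
    tr = FluorescenceTrace(t=t, dF=3.0 * t, protocol=prot)  # no saturation in window
    assert not fit_rising_exp(tr).converged


def test_adjusted_r2_hand_computed():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    resid = np.array([0.1, -0.1, 0.1, -0.1])
    # R2 = 1 - 0.04/5 = 0.992; adj = 1 - (1-0.992)*3/2 = 0.988
    assert adjusted_r2(resid, y, 1) == pytest.approx(0.988, abs=1e-12)
    with pytest.raises(ValueError):
        adjusted_r2(resid[:2], y[:2], 1)  # n <= k+1
    with pytest.raises(ValueError):
        adjusted_r2(np.zeros(4), np.full(4, 2.0), 1)  # zero variance


def test_fit_config_for_offsets():
    assert fit_config_for("37C").offset_t0 == pytest.approx(2.5)
    assert fit_config_for("30C").offset_t0 == pytest.approx(5.0)
    assert fit_config_for("37C", "plateau").offset_t0 == pytest.approx(1.3 * 2.5)
    with pytest.raises(KeyError):
        fit_config_for("25C")


def test_fit_config_validation():
    with pytest.raises(ValueError):
        FitConfig(offset_t0=-1.0)
    with pytest.raises(ValueError):
        FitConfig(window_mode="sliding")
    with pytest.raises(ValueError):
        FitConfig(min_points=2)
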