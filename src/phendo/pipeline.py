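"""Protocol orchestration: tuning curves, persistence analysis and
population statistics.

The per-cell unit of analysis is the stimulus tuning curve: repeated
runs of each stimulus are averaged sample-by-sample before fitting (the
acquisition-style averaging used for small stimuli), each averaged decay
is fitted, and the per-cell curve is summarized by its linear
tau-vs-AP regression (slope in s/AP, intercept = predicted 1 AP time
constant) and, optionally, the tau-vs-endocytic-load regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import EndoFit, FitConfig, fit_exp_offset, fit_linear_rate
from .kinetics import CellKinetics
from .protocols import StimulusProtocol, burst_train, single_burst
from .simulate import FluorescenceTrace, PopulationSpec, draw_population, simulate_trace

Stimulus = tuple[int, float]  # (n_ap, freq)


@dataclass
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    n: int


@dataclass
class TuningCurveResult:
    """Per-cell stimulus tuning curve and its derived regressions."""

    fits: dict[Stimulus, EndoFit]
    peaks: dict[Stimulus, float] = field(default_factory=dict)
    regression: RegressionResult | None = None
    load_regression: RegressionResult | None = None

    def tau(self, stim: Stimulus) -> float:
        return self.fits[stim].tau

    def normalized(self, reference: Stimulus) -> dict[Stimulus, float]:
        return normalize_curve({s: f.tau for s, f in self.fits.items()}, reference)


def average_traces(traces: Sequence[FluorescenceTrace]) -> FluorescenceTrace:
    """Sample-by-sample mean of repeat runs of the same protocol."""
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0):
            raise ValueError("repeat traces must share the sampling grid")
    dF = np.mean([tr.dF for tr in traces], axis=0)
    return FluorescenceTrace(t=t0.copy(), dF=dF, protocol=traces[0].protocol, meta=traces[0].meta)


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if x.size < 3:
        raise ValueError("regression requires >= 3 stimulus levels")
    if np.allclose(x, x[0]):
        raise ValueError("singular design: all x identical")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        r2=float(res.rvalue**2),
        n=int(x.size),
    )


def run_protocol_suite(
    trace_sets: Mapping[Stimulus, Sequence[FluorescenceTrace]],
    cfg: FitConfig | None = None,
    *,
    regress: bool = True,
) -> TuningCurveResult:
    """Fit a cell's tuning curve from repeat traces per stimulus.

    Repeats are averaged before fitting.  With >= 3 stimulus levels the
    tau-vs-AP OLS regression (slope s/AP, predicted 1 AP intercept) and
    the tau-vs-peak-dF (endocytic load) regression are attached.
    """
    cfg = cfg or FitConfig()
    fits: dict[Stimulus, EndoFit] = {}
    peaks: dict[Stimulus, float] = {}
    for stim, traces in trace_sets.items():
        avg = average_traces(traces)
        fits[stim] = fit_exp_offset(avg, -1, cfg)
        t_end = avg.protocol.bursts[-1].t_end
        peaks[stim] = float(np.interp(t_end, avg.t, avg.dF))
    result = TuningCurveResult(fits=fits, peaks=peaks)
    good = [s for s, f in fits.items() if f.converged]
    if regress and len(good) >= 3:
        x = np.array([s[0] for s in good], float)
        y = np.array([fits[s].tau for s in good], float)
        result.regression = _ols(x, y)
        xl = np.array([peaks[s] for s in good], float)
        result.load_regression = _ols(xl, y)
    return result


def normalize_curve(
    taus: Mapping[Stimulus, float], reference: Stimulus
) -> dict[Stimulus, float]:
    """tau values divided by the reference stimulus tau (reference -> 1)."""
    if reference not in taus:
        raise KeyError(f"reference stimulus {reference} missing from curve")
    ref = taus[reference]
    if ref == 0:
        raise ZeroDivisionError("zero reference tau")
    return {s: v / ref for s, v in taus.items()}


def percent_change(tau_a: float, tau_b: float, mode: str) -> float:
    """Percent acceleration or slowing between two time constants.

    ``accel``: 100 * (tau_a - tau_b) / tau_a, with ``tau_a`` the
    smaller-stimulus (slower) value.  ``slow``: 100 * (tau_b - tau_a) /
    tau_a with ``tau_a`` the reference stimulus value.
    """
    if tau_a <= 0 or tau_b <= 0:
        raise ValueError("time constants must be positive")
    if mode == "accel":
        return 100.0 * (tau_a - tau_b) / tau_a
    if mode == "slow":
        return 100.0 * (tau_b - tau_a) / tau_a
    raise ValueError("mode must be 'accel' or 'slow'")


def tau_vs_load(curve: TuningCurveResult) -> RegressionResult:
    """OLS of tau against the end-of-stimulus dF (endocytic load)."""
    good = [s for s, f in curve.fits.items() if f.converged]
    if len(good) < 3:
        raise ValueError("need >= 3 stimulus levels with recorded peaks")
    x = np.array([curve.peaks[s] for s in good], float)
    y = np.array([curve.fits[s].tau for s in good], float)
    return _ols(x, y)


# ---------------------------------------------------------------------------
# Simulation-driven studies
# ---------------------------------------------------------------------------


def default_repeats(n_ap: int) -> int:
    """Repeat-averaging rule: more rounds for small stimuli (up to 10)."""
    return int(np.clip(round(100 / n_ap), 1, 10))


def simulate_cell_suite(
    cell: CellKinetics,
    stimuli: Sequence[Stimulus],
    seed: int | np.random.SeedSequence,
    *,
    repeats: Callable[[int], int] | None = None,
    temperature: str = "37C",
    ca_mM: float = 2.0,
    condition: str = "control",
    post_window: float = 60.0,
) -> dict[Stimulus, list[FluorescenceTrace]]:
    """Simulate repeat runs of each stimulus for one cell."""
    repeats = repeats or default_repeats
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(repeats(n) for n, _ in stimuli)))
    out: dict[Stimulus, list[FluorescenceTrace]] = {}
    for n_ap, freq in stimuli:
        prot = single_burst(
            n_ap, freq, temperature=temperature, ca_mM=ca_mM,
            condition=condition, post_window=post_window,
        )
        out[(n_ap, freq)] = [
            simulate_trace(cell, prot, next(children)) for _ in range(repeats(n_ap))
        ]
    return out


def population_tuning_study(
    spec: PopulationSpec,
    stimuli: Sequence[Stimulus],
    seed: int,
    cfg: FitConfig | None = None,
    *,
    temperature: str = "37C",
    ca_mM: float = 2.0,
    condition: str = "control",
) -> list[TuningCurveResult]:
    """Simulate a population and fit each cell's tuning curve."""
    ss = np.random.SeedSequence(seed)
    cell_seed, *cell_trace_seeds = ss.spawn(1 + spec.n_cells)
    cells = draw_population(spec, cell_seed)
    curves = []
    for cell, tseed in zip(cells, cell_trace_seeds):
        sets = simulate_cell_suite(
            cell, stimuli, tseed, temperature=temperature, ca_mM=ca_mM, condition=condition
        )
        curves.append(run_protocol_suite(sets, cfg, regress=len(stimuli) >= 3))
    return curves


@dataclass
class CaSlopeResult:
    """Paired 2 mM vs 4 mM Ca2+ slope comparison across cells."""

    slopes_2mM: np.ndarray
    slopes_4mM: np.ndarray
    intercepts_2mM: np.ndarray
    intercepts_4mM: np.ndarray
    group_increase_pct: float
    slope_test: "TestResult"
    intercept_test: "TestResult"


def ca_slope_study(
    spec: PopulationSpec,
    seed: int,
    cfg: FitConfig | None = None,
    *,
    stimuli: Sequence[Stimulus] = ((25, 10.0), (50, 10.0), (100, 10.0)),
    ca_slope_factor: float = 8.0,
    temperature: str = "30C",
) -> CaSlopeResult:
    """Within-cell paired comparison of the slowing slope at 2 vs 4 mM Ca2+.

    Each cell is run through the same stimulus suite under both Ca2+
    presets (same per-cell trace seeds, a paired design); per-condition
    slopes come from the tau-vs-AP OLS.  The headline number is the
    percent increase of the population-mean slope — with strongly
    heterogeneous slopes (CV near 100%) the mean of per-cell ratios is
    dominated by cells whose 2 mM slope is near zero and is not a
    meaningful summary.
    """
    from .kinetics import apply_condition

    ss = np.random.SeedSequence(seed)
    cell_seed, *trace_seeds = ss.spawn(1 + spec.n_cells)
    cells = draw_population(spec, cell_seed)
    s2, s4, i2, i4 = [], [], [], []
    for cell, tseed in zip(cells, trace_seeds):
        per_ca = {}
        for ca in (2.0, 4.0):
            ccell = apply_condition(cell, "control", ca, ca_slope_factor=ca_slope_factor)
            sets = simulate_cell_suite(
                ccell, list(stimuli), tseed, temperature=temperature, ca_mM=ca
            )
            per_ca[ca] = run_protocol_suite(sets, cfg)
        s2.append(per_ca[2.0].regression.slope)
        s4.append(per_ca[4.0].regression.slope)
        i2.append(per_ca[2.0].regression.intercept)
        i4.append(per_ca[4.0].regression.intercept)
    s2, s4 = np.asarray(s2), np.asarray(s4)
    i2, i4 = np.asarray(i2), np.asarray(i4)
    increase = 100.0 * (s4.mean() - s2.mean()) / s2.mean()
    return CaSlopeResult(
        slopes_2mM=s2,
        slopes_4mM=s4,
        intercepts_2mM=i2,
        intercepts_4mM=i4,
        group_increase_pct=float(increase),
        slope_test=paired_test(s2, s4),
        intercept_test=paired_test(i2, i4),
    )


# ---------------------------------------------------------------------------
# Burst-train persistence
# ---------------------------------------------------------------------------


@dataclass
class PersistenceResult:
    """Normalized per-burst endocytic measures for a 5-burst train."""

    normalized: np.ndarray  # (n_cells, n_bursts), burst 1 == 1
    method: str
    pvalues: np.ndarray  # one-sample t vs 1 per burst >= 2


def persistence_analysis(
    cell_traces: Sequence[Sequence[FluorescenceTrace]],
    spacing: float,
    cfg: FitConfig | None = None,
    *,
    n_bursts: int = 5,
) -> PersistenceResult:
    """Per-burst tau (or 1/Rate) normalized to burst 1, across cells.

    Exponential fits are used for spacings >= 20 s (and the contiguous
    0 s protocol); at 15 s spacing the decay window is too short for a
    robust exponential fit and the amplitude-normalized 1/Rate measure
    is used instead.  For spacing > 0, each cell's entry holds repeat
    runs of the spaced-burst protocol, averaged before fitting each
    burst's decay.  For the contiguous protocol (spacing == 0) the
    bursts fuse, so each cell's entry instead holds one (pre-averaged)
    trace per cumulative burst count (5, 10, ... AP) and the final decay
    of each is fitted.  Returns the normalized matrix and two-sided
    one-sample t-test p-values against 1 for bursts 2..n.
    """
    cfg = cfg or FitConfig(window_len=12.0)
    use_rate = 0 < spacing < 20.0
    fitter = fit_linear_rate if use_rate else fit_exp_offset
    rows = []
    for runs in cell_traces:
        if spacing == 0:
            if len(runs) < n_bursts:
                raise ValueError(f"need >= {n_bursts} cumulative-burst traces")
            taus = []
            for tr in runs[:n_bursts]:
                fit = fitter(tr, -1, cfg)
                taus.append(fit.tau if fit.converged else np.nan)
        else:
            avg = average_traces(list(runs))
            if len(avg.protocol.bursts) < n_bursts:
                raise ValueError(f"protocol must contain >= {n_bursts} bursts")
            taus = []
            for bi in range(n_bursts):
                fit = fitter(avg, bi, cfg)
                taus.append(fit.tau if fit.converged else np.nan)
        taus = np.asarray(taus)
        rows.append(taus / taus[0])
    norm = np.vstack(rows)
    pvals = np.array(
        [sps.ttest_1samp(norm[:, j][~np.isnan(norm[:, j])], 1.0).pvalue for j in range(1, n_bursts)]
    )
    return PersistenceResult(
        normalized=norm, method="linear_rate" if use_rate else "exp_offset", pvalues=pvals
    )


def simulate_persistence_study(
    spec: PopulationSpec,
    spacing: float,
    seed: int,
    *,
    n_runs: int = 4,
    n_bursts: int = 5,
    n_ap: int = 5,
    freq: float = 10.0,
    cfg: FitConfig | None = None,
) -> PersistenceResult:
    """Simulate the 5x5AP burst-train protocol for a population and analyze it.

    For spacing == 0 the contiguous equivalent is used: one cumulative
    single burst of k*n_ap APs per stage (k = 1..n_bursts), repeat runs
    averaged per stage.
    """
    ss = np.random.SeedSequence(seed)
    cell_seed, *trace_seeds = ss.spawn(1 + spec.n_cells * n_runs * (n_bursts if spacing == 0 else 1))
    cells = draw_population(spec, cell_seed)
    per_cell = []
    k = 0
    if spacing == 0:
        prots = [single_burst(j * n_ap, freq) for j in range(1, n_bursts + 1)]
        for cell in cells:
            stages = []
            for prot in prots:
                runs = []
                for _ in range(n_runs):
                    runs.append(simulate_trace(cell, prot, trace_seeds[k]))
                    k += 1
                stages.append(average_traces(runs))
            per_cell.append(stages)
    else:
        prot = burst_train(n_bursts=n_bursts, n_ap=n_ap, freq=freq, spacing=spacing)
        for cell in cells:
            runs = []
            for _ in range(n_runs):
                runs.append(simulate_trace(cell, prot, trace_seeds[k]))
                k += 1
            per_cell.append(runs)
    if cfg is None:
        cfg = FitConfig(window_len=12.0)
    return persistence_analysis(per_cell, spacing, cfg, n_bursts=n_bursts)


# ---------------------------------------------------------------------------
# Population statistics
# ---------------------------------------------------------------------------


@dataclass
class MetricSummary:
    mean: float
    sem: float
    cv_pct: float
    n: int
    outliers_removed: int


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    n: int


@dataclass
class PopulationStats:
    summaries: dict[str, MetricSummary]
    tests: list[TestResult] = field(default_factory=list)


def exclude_outliers(values: np.ndarray, n_sd: float = 3.0) -> tuple[np.ndarray, int]:
    """One-pass exclusion of samples > n_sd standard deviations from the mean."""
    values = np.asarray(values, float)
    sd = values.std(ddof=1)
    if sd == 0:
        return values, 0
    keep = np.abs(values - values.mean()) <= n_sd * sd
    return values[keep], int((~keep).sum())


def summarize_metric(values, *, outlier_sd: float | None = 3.0) -> MetricSummary:
    values = np.asarray(values, float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need n >= 2")
    removed = 0
    if outlier_sd is not None:
        values, removed = exclude_outliers(values, outlier_sd)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return MetricSummary(
        mean=mean,
        sem=sd / math.sqrt(values.size),
        cv_pct=100.0 * sd / mean if mean != 0 else float("inf"),
        n=int(values.size),
        outliers_removed=removed,
    )


def one_sample_test(values, popmean: float = 1.0, *, log: bool = False) -> TestResult:
    """Two-sided one-sample t-test, optionally on log-transformed ratios.

    With ``log=True`` the test is t of ln(values) against ln(popmean),
    the log-corrected test appropriate for ratio metrics.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need n >= 2")
    if log:
        res = sps.ttest_1samp(np.log(values), math.log(popmean))
        name = "one-sample t (log-corrected)"
    else:
        res = sps.ttest_1samp(values, popmean)
        name = "one-sample t"
    return TestResult(name, float(res.statistic), float(res.pvalue), int(values.size))


def paired_test(a, b) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired test needs equal-length samples with n >= 2")
    res = sps.ttest_rel(a, b)
    return TestResult("paired t", float(res.statistic), float(res.pvalue), int(a.size))


def ks_test(a, b) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("KS test needs n >= 2 per group")
    res = sps.ks_2samp(a, b)
    return TestResult("two-sample KS", float(res.statistic), float(res.pvalue), int(a.size + b.size))


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in reports)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def population_summary(
    metrics: Mapping[str, Sequence[float]],
    tests: Sequence[tuple] = (),
    *,
    outlier_sd: float | None = 3.0,
) -> PopulationStats:
    """Mean/SEM/CV per metric with one-pass >3 SD outlier exclusion.

    ``tests`` is a sequence of tuples: ``("one_sample", metric, popmean)``
    (append ``"log"`` for the log-corrected variant), ``("paired",
    metric_a, metric_b)`` or ``("ks", metric_a, metric_b)``.
    """
    summaries = {
        name: summarize_metric(vals, outlier_sd=outlier_sd) for name, vals in metrics.items()
    }
    results = []
    for spec in tests:
        kind = spec[0]
        if kind == "one_sample":
            log = len(spec) > 3 and spec[3] == "log"
            results.append(one_sample_test(metrics[spec[1]], spec[2], log=log))
        elif kind == "paired":
            results.append(paired_test(metrics[spec[1]], metrics[spec[2]]))
        elif kind == "ks":
            results.append(ks_test(metrics[spec[1]], metrics[spec[2]]))
        else:
            raise ValueError(f"unknown test kind {kind!r}")
    return PopulationStats(summaries=summaries, tests=results)


def curves_to_frame(curves: Sequence[TuningCurveResult]) -> pd.DataFrame:
    """Tidy per-cell, per-stimulus table of fitted time constants."""
    rows = []
    for ci, c in enumerate(curves):
        for (n_ap, freq), fit in c.fits.items():
            rows.append(
                {
                    "cell": ci,
                    "n_ap": n_ap,
                    "freq_hz": freq,
                    "tau_s": fit.tau,
                    "tau_se_s": fit.tau_se,
                    "adj_r2": fit.adj_r2,
                    "converged": fit.converged,
                    "peak_dF": c.peaks.get((n_ap, freq), np.nan),
                }
            )
    return pd.DataFrame(rows)
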