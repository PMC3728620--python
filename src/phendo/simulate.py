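"""Stochastic per-vesicle simulation of vGlut-pHluorin fluorescence traces.

Each AP releases a binomial draw from the available recycling pool; every
surface vesicle contributes one fluorescence unit until it is requenched,
which happens after an exponential endocytosis waiting time (rate set by
the burst's effective time constant, frozen at burst end) followed by an
exponential reacidification delay.  Under bafilomycin requenching is
disabled, so fluorescence reports cumulative exocytosis.  Gaussian read
noise is added per sample.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import (
    AccelState,
    CellKinetics,
    effective_tau,
    update_accel_state,
)
from .protocols import StimulusProtocol


@dataclass(frozen=True)
class TraceMeta:
    cell_id: str = "cell0"
    genotype: str = "control"
    rng_seed: int | None = None


@dataclass
class FluorescenceTrace:
    """Uniformly sampled, baseline-subtracted dF time series."""

    t: np.ndarray
    dF: np.ndarray
    protocol: StimulusProtocol
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dF = np.asarray(self.dF, dtype=float)
        if self.t.shape != self.dF.shape:
            raise ValueError("t and dF must have the same length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class VesicleStates:
    """Per-sample vesicle state counts (conservation diagnostic)."""

    available: np.ndarray
    surface: np.ndarray
    internalized: np.ndarray
    reacidified: np.ndarray

    def total(self) -> np.ndarray:
        return self.available + self.surface + self.internalized + self.reacidified


def burst_effective_taus(cell: CellKinetics, protocol: StimulusProtocol) -> list[float]:
    """Effective endocytic time constant of each burst, frozen at burst end.

    The acceleration state is propagated through the full AP sequence of
    the protocol (saturating increment per AP, exponential relaxation in
    the gaps), so closely spaced bursts inherit residual acceleration.
    """
    ap = protocol.ap_times()
    state = AccelState(a=0.0, t_last=ap[0][0] if ap else 0.0)
    a_end = [0.0] * len(protocol.bursts)
    for t, bi in ap:
        state = update_accel_state(state, cell, ap_time=t)
        a_end[bi] = state.a
    return [
        effective_tau(cell, b.n_ap, a_end[i]) for i, b in enumerate(protocol.bursts)
    ]


def simulate_trace(
    cell: CellKinetics,
    protocol: StimulusProtocol,
    seed: int | np.random.SeedSequence,
    *,
    return_states: bool = False,
) -> FluorescenceTrace | tuple[FluorescenceTrace, VesicleStates]:
    """Simulate one fluorescence trace.

    ``seed`` is mandatory: every simulation is reproducible bit-for-bit
    from (cell, protocol, seed).
    """
    if seed is None:
        raise ValueError("seed is required; simulations must be reproducible")
    rng = np.random.default_rng(seed)

    taus = burst_effective_taus(cell, protocol)
    baf = protocol.condition == "bafilomycin"

    exo_times: list[np.ndarray] = []
    endo_times: list[np.ndarray] = []
    quench_times: list[np.ndarray] = []
    available = cell.n_vesicles
    exhausted_warned = False
    for t, bi in protocol.ap_times():
        if available <= 0:
            if not exhausted_warned:
                warnings.warn(
                    "recycling pool exhausted; continuing with zero release",
                    RuntimeWarning,
                    stacklevel=2,
                )
                exhausted_warned = True
            continue
        k = int(rng.binomial(available, cell.p_release))
        available -= k
        if k == 0:
            continue
        exo = np.full(k, t)
        endo = exo + rng.exponential(taus[bi], size=k)
        if baf:
            quench = np.full(k, np.inf)
        elif cell.tau_reacid > 0:
            quench = endo + rng.exponential(cell.tau_reacid, size=k)
        else:
            quench = endo.copy()
        exo_times.append(exo)
        endo_times.append(endo)
        quench_times.append(quench)

    exo_all = np.sort(np.concatenate(exo_times)) if exo_times else np.empty(0)
    endo_all = np.sort(np.concatenate(endo_times)) if endo_times else np.empty(0)
    quench_all = np.sort(np.concatenate(quench_times)) if quench_times else np.empty(0)

    n = int(np.floor(protocol.trace_duration / protocol.sample_interval)) + 1
    t_grid = np.arange(n) * protocol.sample_interval
    n_exo = np.searchsorted(exo_all, t_grid, side="right")
    n_endo = np.searchsorted(endo_all, t_grid, side="right")
    n_quench = np.searchsorted(quench_all, t_grid, side="right")

    dF = (n_exo - n_quench).astype(float)
    if cell.noise_sd > 0:
        dF = dF + rng.normal(0.0, cell.noise_sd, size=dF.shape)

    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    trace = FluorescenceTrace(
        t=t_grid,
        dF=dF,
        protocol=protocol,
        meta=TraceMeta(rng_seed=int(seed_int) if seed_int is not None else None),
    )
    if not return_states:
        return trace
    states = VesicleStates(
        available=cell.n_vesicles - n_exo,
        surface=n_exo - n_endo,
        internalized=n_endo - n_quench,
        reacidified=n_quench.copy(),
    )
    return trace, states


def expected_trace(cell: CellKinetics, protocol: StimulusProtocol) -> FluorescenceTrace:
    """Noise-free expected fluorescence trace (ensemble mean).

    Each AP contributes its expected release (deterministic binomial
    mean, with pool depletion) convolved with the two-compartment
    surface + internalized-unacidified decay kernel of its burst's
    effective time constant.  Under bafilomycin the kernel is a step
    (no requenching).  This is the n_vesicles -> infinity limit of
    :func:`simulate_trace` per unit release, used for calibration.
    """
    taus = burst_effective_taus(cell, protocol)
    baf = protocol.condition == "bafilomycin"
    n = int(np.floor(protocol.trace_duration / protocol.sample_interval)) + 1
    t_grid = np.arange(n) * protocol.sample_interval
    dF = np.zeros(n)
    avail = float(cell.n_vesicles)
    for t_ap, bi in protocol.ap_times():
        w = avail * cell.p_release
        avail -= w
        dt = t_grid - t_ap
        m = dt >= 0
        if baf:
            dF[m] += w
            continue
        te, tr = taus[bi], cell.tau_reacid
        if tr == 0:
            dF[m] += w * np.exp(-dt[m] / te)
        elif abs(te - tr) <= 1e-9 * te:
            dF[m] += w * (1.0 + dt[m] / te) * np.exp(-dt[m] / te)
        else:
            dF[m] += w * (te * np.exp(-dt[m] / te) - tr * np.exp(-dt[m] / tr)) / (te - tr)
    return FluorescenceTrace(t=t_grid, dF=dF, protocol=protocol)


@dataclass(frozen=True)
class PopulationSpec:
    """Lognormal population of cells sharing a genotype and base kinetics.

    Per-cell ``tau1`` and ``slope_m`` are drawn from lognormal
    distributions with the given arithmetic means and coefficients of
    variation; all other kinetic parameters are shared via ``base``.
    """

    n_cells: int
    tau1_mean: float
    tau1_cv: float
    slope_mean: float
    slope_cv: float
    genotype: str = "control"
    base: CellKinetics = field(default_factory=CellKinetics)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("tau1_cv", "slope_cv"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (np.isfinite(self.tau1_mean) and self.tau1_mean > 0):
            raise ValueError("tau1_mean must be finite and > 0")
        if not (np.isfinite(self.slope_mean) and self.slope_mean >= 0):
            raise ValueError("slope_mean must be finite and >= 0")


def lognormal_from_mean_cv(
    rng: np.random.Generator, mean: float, cv: float, size: int
) -> np.ndarray:
    """Lognormal samples parameterized by arithmetic mean and CV.

    sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2 / 2, so the sample
    arithmetic mean converges to ``mean`` and the sample CV to ``cv``.
    """
    if cv == 0:
        return np.full(size, mean)
    s2 = np.log1p(cv**2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size)


def draw_population(spec: PopulationSpec, seed: int | np.random.SeedSequence) -> list[CellKinetics]:
    """Draw per-cell kinetics (genotype preset applied after sampling)."""
    from .kinetics import apply_genotype

    rng = np.random.default_rng(seed)
    tau1 = lognormal_from_mean_cv(rng, spec.tau1_mean, spec.tau1_cv, spec.n_cells)
    if spec.slope_mean == 0:
        slope = np.zeros(spec.n_cells)
    else:
        slope = lognormal_from_mean_cv(rng, spec.slope_mean, spec.slope_cv, spec.n_cells)
    cells = []
    for i in range(spec.n_cells):
        c = spec.base.replace(tau1=float(tau1[i]), slope_m=float(slope[i]))
        cells.append(apply_genotype(c, spec.genotype))
    return cells


def simulate_population(
    spec: PopulationSpec,
    protocols: list[StimulusProtocol],
    seed: int,
    *,
    n_repeats: int = 1,
) -> list[dict[StimulusProtocol, list[FluorescenceTrace]]]:
    """Simulate every protocol (with repeats) for every cell in the population.

    Returns one dict per cell mapping protocol -> list of repeat traces.
    Deterministic given ``seed``: cell parameters and every trace get
    independent child seeds spawned from it.
    """
    ss = np.random.SeedSequence(seed)
    cell_seed, *trace_seeds = ss.spawn(1 + spec.n_cells * len(protocols) * n_repeats)
    cells = draw_population(spec, cell_seed)
    out = []
    k = 0
    for ci, cell in enumerate(cells):
        per_cell: dict[StimulusProtocol, list[FluorescenceTrace]] = {}
        for prot in protocols:
            runs = []
            for _ in range(n_repeats):
                tr = simulate_trace(cell, prot, trace_seeds[k])
                tr.meta = TraceMeta(cell_id=f"cell{ci}", genotype=spec.genotype)
                runs.append(tr)
                k += 1
            per_cell[prot] = runs
        out.append(per_cell)
    return out
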