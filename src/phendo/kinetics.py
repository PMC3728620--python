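"""Per-cell endocytic kinetics and their activity-dependent modulation.

The endocytic time constant of a cell is modelled as

    tau_eff(n_ap, a) = tau1 * (1 - alpha_max * a) + slope_m * (n_ap - 1)

where ``tau1`` is the time constant extrapolated to a single AP (the
"intercept"), ``slope_m`` the linear activity-dependent slowing (s/AP),
and ``a`` in [0, 1] an acceleration state driven by AP firing: each AP
increments it by ``delta_a * (1 - a)`` and it relaxes exponentially with
time constant ``tau_pers`` between events.  The acceleration state stands
for the dephosphorylation level of dynamin 1 at S774/778: its saturating
build-up during bursts and slow (~20 s) relaxation produce both the
acceleration phase of the stimulus tuning curve and the persistence of
acceleration between closely spaced bursts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

GENOTYPES = (
    "control",
    "dyn1_rescue",
    "dyn13_DKO",
    "S774_8A",
    "S774_8D",
    "dyn2_rescue",
)


@dataclass(frozen=True)
class CellKinetics:
    """Ground-truth kinetic parameters of one simulated cell.

    Times in seconds; ``alpha_max`` is the maximal fractional reduction of
    the base time constant when the acceleration state is saturated.
    ``quench_ratio`` (the ~20-fold surface/vesicle fluorescence ratio) is
    kept for the optional pH mode; the default reporter model is binary
    fluorescent/quenched.
    """

    tau1: float = 8.31
    slope_m: float = 0.058
    alpha_max: float = 0.0
    delta_a: float = 0.0
    tau_pers: float = 20.0
    tau_reacid: float = 5.0
    n_vesicles: int = 2000
    p_release: float = 0.01
    surface_frac: float = 0.0
    noise_sd: float = 0.0
    quench_ratio: float = 20.0

    def __post_init__(self) -> None:
        for name in ("tau1", "tau_pers", "quench_ratio"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not (math.isfinite(self.tau_reacid) and self.tau_reacid >= 0):
            raise ValueError(f"tau_reacid must be >= 0, got {self.tau_reacid}")
        if not (0.0 <= self.alpha_max < 1.0):
            raise ValueError(f"alpha_max must be in [0, 1), got {self.alpha_max}")
        if not (0.0 <= self.delta_a <= 1.0):
            raise ValueError(f"delta_a must be in [0, 1], got {self.delta_a}")
        if not (0.0 < self.p_release <= 1.0):
            raise ValueError(f"p_release must be in (0, 1], got {self.p_release}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.slope_m < 0 or not math.isfinite(self.slope_m):
            raise ValueError(f"slope_m must be finite and >= 0, got {self.slope_m}")
        if self.n_vesicles < 1:
            raise ValueError("n_vesicles must be >= 1")
        if self.quench_ratio <= 1:
            raise ValueError("quench_ratio must be > 1")

    def replace(self, **kw) -> "CellKinetics":
        return replace(self, **kw)


@dataclass
class AccelState:
    """Acceleration state ``a`` in [0, 1] and the time of its last update."""

    a: float = 0.0
    t_last: float = 0.0


def effective_tau(cell: CellKinetics, n_ap: int, a_end: float, freq: float | None = None) -> float:
    """Endocytic time constant for a burst, frozen at burst end.

    ``a_end`` is the acceleration state after the last AP of the burst.
    The value is the one the post-burst fluorescence decay exhibits; the
    within-decay evolution of the state is not modelled because a single
    time constant is fitted per decay.
    """
    if not (0.0 <= a_end <= 1.0):
        raise ValueError(f"a_end must be in [0, 1], got {a_end}")
    if n_ap < 1:
        raise ValueError("n_ap must be >= 1")
    tau = cell.tau1 * (1.0 - cell.alpha_max * a_end) + cell.slope_m * (n_ap - 1)
    if not (math.isfinite(tau) and tau > 0):
        raise ValueError(f"effective tau must be finite and positive, got {tau}")
    return tau


def decay_accel(state: AccelState, t: float, tau_pers: float) -> AccelState:
    """Relax the acceleration state exponentially up to time ``t``."""
    dt = t - state.t_last
    if dt < 0:
        raise ValueError(f"events must be time-ordered (dt={dt})")
    return AccelState(a=state.a * math.exp(-dt / tau_pers), t_last=t)


def increment_accel(state: AccelState, delta_a: float) -> AccelState:
    """Apply the per-AP saturating increment ``a <- a + delta_a * (1 - a)``."""
    a = state.a + delta_a * (1.0 - state.a)
    return AccelState(a=min(a, 1.0), t_last=state.t_last)


def update_accel_state(
    state: AccelState, cell: CellKinetics, *, ap_time: float | None = None, t: float | None = None
) -> AccelState:
    """Advance the acceleration state to an AP (``ap_time``) or to time ``t``.

    An AP event first relaxes the state to the AP time, then applies the
    saturating increment.  A plain time event only relaxes.
    """
    if (ap_time is None) == (t is None):
        raise ValueError("pass exactly one of ap_time or t")
    if ap_time is not None:
        return increment_accel(decay_accel(state, ap_time, cell.tau_pers), cell.delta_a)
    return decay_accel(state, t, cell.tau_pers)


def accel_after_train(
    cell: CellKinetics, n_ap: int, freq: float, a0: float = 0.0, t0: float = 0.0
) -> float:
    """Acceleration state after an ``n_ap``-AP burst at ``freq`` Hz.

    The first AP fires at ``t0`` with starting state ``a0`` (already
    relaxed to ``t0``).
    """
    state = AccelState(a=a0, t_last=t0)
    for k in range(n_ap):
        state = update_accel_state(state, cell, ap_time=t0 + k / freq)
    return state.a


def apply_genotype(cell: CellKinetics, genotype: str) -> CellKinetics:
    """Dynamin genotype presets.

    - ``control`` / ``dyn1_rescue``: wild-type modulation, unchanged.
    - ``S774_8A`` (phospho-deficient): acceleration locked on; the base
      time constant is permanently scaled by ``(1 - alpha_max)``.
    - ``S774_8D`` (phosphomimetic): acceleration locked off.
      Both mutants retain the activity-dependent slowing slope.
    - ``dyn13_DKO``: >10-fold slowed base time constant, modulation off.
    - ``dyn2_rescue``: partial rescue, approximated as a 3x slowed base.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    if genotype in ("control", "dyn1_rescue"):
        return cell
    if genotype == "S774_8A":
        return cell.replace(tau1=cell.tau1 * (1.0 - cell.alpha_max), alpha_max=0.0, delta_a=0.0)
    if genotype == "S774_8D":
        return cell.replace(alpha_max=0.0, delta_a=0.0)
    if genotype == "dyn13_DKO":
        return cell.replace(tau1=cell.tau1 * 10.0, alpha_max=0.0, delta_a=0.0, slope_m=0.0)
    # dyn2_rescue: partial rescue multiplier, flagged approximate
    return cell.replace(tau1=cell.tau1 * 3.0)


def apply_condition(
    cell: CellKinetics,
    condition: str = "control",
    ca_mM: float = 2.0,
    *,
    ca_slope_factor: float = 8.0,
    egta_slow_factor: float = 1.5,
    egta_residual_alpha: float = 0.1,
) -> CellKinetics:
    """External Ca2+ and pharmacology presets.

    4 mM Ca2+ multiplies the slowing slope by ``ca_slope_factor`` (default
    8, the ~700% increase) leaving the intercept unchanged.  EGTA loading
    abolishes activity-dependent slowing, slows all time constants by
    ``egta_slow_factor`` and caps the acceleration amplitude at a small
    residual.  Bafilomycin has no kinetic effect here; it disables
    requenching in the trace simulator.
    """
    if condition not in ("control", "EGTA", "bafilomycin"):
        raise ValueError(f"unknown condition {condition!r}")
    if ca_mM not in (2.0, 4.0, 2, 4):
        raise ValueError(f"no preset for ca_mM={ca_mM}; supported: 2, 4")
    out = cell
    if float(ca_mM) == 4.0:
        out = out.replace(slope_m=out.slope_m * ca_slope_factor)
    if condition == "EGTA":
        out = out.replace(
            slope_m=0.0,
            tau1=out.tau1 * egta_slow_factor,
            alpha_max=min(out.alpha_max, egta_residual_alpha),
        )
    return out
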