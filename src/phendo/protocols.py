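"""Stimulus protocols: action-potential burst trains driving exo/endocytosis.

A protocol is an ordered sequence of AP bursts (count, frequency, onset)
plus the recording conditions (temperature, external Ca2+, pharmacology)
and the sampling grid of the fluorescence trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

TEMPERATURES = ("30C", "37C")
CONDITIONS = ("control", "EGTA", "bafilomycin")


@dataclass(frozen=True)
class Burst:
    """One burst of ``n_ap`` action potentials at ``freq`` Hz starting at ``onset`` s."""

    n_ap: int
    freq: float
    onset: float

    def __post_init__(self) -> None:
        if self.n_ap < 1:
            raise ValueError(f"n_ap must be >= 1, got {self.n_ap}")
        if not self.freq > 0:
            raise ValueError(f"freq must be > 0, got {self.freq}")
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")

    @property
    def t_end(self) -> float:
        """Time of the last AP in the burst (s)."""
        return self.onset + (self.n_ap - 1) / self.freq

    def ap_times(self) -> list[float]:
        return [self.onset + k / self.freq for k in range(self.n_ap)]


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping AP bursts with recording conditions.

    Parameters
    ----------
    bursts:
        Time-ordered bursts; consecutive bursts must not overlap.
    temperature:
        ``"30C"`` or ``"37C"``.
    ca_mM:
        External Ca2+ concentration (mM); presets exist for 2 and 4.
    condition:
        ``"control"``, ``"EGTA"`` (slow Ca2+ chelator loaded) or
        ``"bafilomycin"`` (vesicular proton pump blocked, no requenching).
    trace_duration:
        Total recorded time (s); must cover the last burst plus a post
        window for the decay fit.
    sample_interval:
        Frame interval of the sampled trace (s).
    """

    bursts: tuple[Burst, ...]
    temperature: str = "37C"
    ca_mM: float = 2.0
    condition: str = "control"
    trace_duration: float = 90.0
    sample_interval: float = 0.5
    post_window: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bursts", tuple(self.bursts))
        if not self.bursts:
            raise ValueError("protocol requires at least one burst")
        if self.temperature not in TEMPERATURES:
            raise ValueError(f"temperature must be one of {TEMPERATURES}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be > 0")
        prev_end = -float("inf")
        for b in self.bursts:
            if b.onset <= prev_end:
                raise ValueError("bursts must be time-ordered and non-overlapping")
            prev_end = b.t_end
        if self.trace_duration < self.bursts[-1].t_end + self.post_window:
            raise ValueError(
                "trace_duration must cover the last burst end plus the post window"
            )

    def ap_times(self) -> list[tuple[float, int]]:
        """All AP times as (time, burst_index), in time order."""
        out: list[tuple[float, int]] = []
        for i, b in enumerate(self.bursts):
            out.extend((t, i) for t in b.ap_times())
        return out

    def with_condition(self, condition: str) -> "StimulusProtocol":
        return replace(self, condition=condition)


def single_burst(
    n_ap: int,
    freq: float = 10.0,
    *,
    onset: float = 10.0,
    post_window: float = 60.0,
    temperature: str = "37C",
    ca_mM: float = 2.0,
    condition: str = "control",
    sample_interval: float = 0.5,
) -> StimulusProtocol:
    """Protocol with one burst and a post-stimulus decay window."""
    b = Burst(n_ap=n_ap, freq=freq, onset=onset)
    return StimulusProtocol(
        bursts=(b,),
        temperature=temperature,
        ca_mM=ca_mM,
        condition=condition,
        trace_duration=b.t_end + post_window + onset,
        sample_interval=sample_interval,
        post_window=post_window,
    )


def burst_train(
    n_bursts: int = 5,
    n_ap: int = 5,
    freq: float = 10.0,
    spacing: float = 30.0,
    *,
    onset: float = 10.0,
    post_window: float = 60.0,
    temperature: str = "37C",
    ca_mM: float = 2.0,
    condition: str = "control",
    sample_interval: float = 0.5,
) -> StimulusProtocol:
    """Train of identical bursts separated end-to-start by ``spacing`` s.

    ``spacing=0`` makes the train equivalent to one continuous burst of
    ``n_bursts * n_ap`` APs at ``freq`` (next burst starts one inter-AP
    interval after the last AP of the previous burst).
    """
    bursts = []
    t = onset
    for _ in range(n_bursts):
        b = Burst(n_ap=n_ap, freq=freq, onset=t)
        bursts.append(b)
        t = b.t_end + 1.0 / freq + spacing
    return StimulusProtocol(
        bursts=tuple(bursts),
        temperature=temperature,
        ca_mM=ca_mM,
        condition=condition,
        trace_duration=bursts[-1].t_end + post_window + onset,
        sample_interval=sample_interval,
        post_window=post_window,
    )
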