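"""Spike-train statistics and stimulus-response experiments.

Covers the evaluation toolbox used to characterize the neuron classes:
upward-threshold spike detection with sub-grid interpolation, interspike
interval (ISI) statistics — the coefficient of variation

    CV = sqrt( (1/(m-1)) sum_i (T_i - Tbar)^2 ) / Tbar

and Shinomoto's local variation

    LV = (1/(m-1)) sum_{i=1}^{m-1} 3 (T_i - T_{i+1})^2 / (T_i + T_{i+1})^2

(m = number of intervals; both are 0 for perfectly regular trains and LV
has expectation 1 for a Poisson train), burst segmentation by an ISI gap
threshold, phase-resetting curves Delta(theta) = (T - T_i)/T, graded
response curves, and ISI-transition experiments under step stimuli.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import (
    StimulusProgram,
    Trace,
    find_equilibrium,
    simulate,
)
from .params import PQNParams

__all__ = [
    "SpikeTrain",
    "ISISequence",
    "PhaseResponseCurve",
    "BurstSummary",
    "StatisticError",
    "detect_spikes",
    "isi_sequence",
    "cv_stat",
    "lv_stat",
    "poisson_spike_train",
    "compute_prc",
    "graded_response_curve",
    "isi_transition_experiment",
    "mse_points",
    "segment_bursts",
]


class StatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. too few ISIs)."""


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times in seconds."""

    times: tuple[float, ...]
    source: str = ""

    def __post_init__(self) -> None:
        ts = self.times
        if any(t < 0 for t in ts):
            raise ValueError("spike times must be non-negative")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def isis(self) -> "ISISequence":
        return isi_sequence(self)


@dataclass(frozen=True)
class ISISequence:
    """Inter-spike intervals T_i with their arithmetic mean."""

    intervals: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.intervals):
            raise ValueError("ISIs must be positive")

    @property
    def m(self) -> int:
        return len(self.intervals)

    @property
    def mean(self) -> float:
        if not self.intervals:
            raise StatisticError("mean ISI undefined for an empty sequence")
        return float(np.mean(self.intervals))


def isi_sequence(train: SpikeTrain) -> ISISequence:
    return ISISequence(tuple(np.diff(train.times)))


@dataclass(frozen=True)
class PhaseResponseCurve:
    """First-order phase shifts Delta(theta) of a spiking limit cycle.

    theta in [0, 1) is the fraction of the unperturbed period T at which
    the probe pulse lands; Delta > 0 means the perturbed cycle ended early
    (phase advance).
    """

    period: float
    phases: tuple[float, ...]
    shifts: tuple[float, ...]
    pulse_amp: float
    pulse_dur: float


@dataclass(frozen=True)
class BurstSummary:
    """Burst sizes and the gaps between consecutive bursts."""

    spikes_per_burst: tuple[int, ...]
    interburst_intervals: tuple[float, ...]
    gap_threshold: float
    leading_complete: bool = True
    trailing_complete: bool = True


# ---------------------------------------------------------------------------
# spike detection and ISI statistics

def detect_spikes(
    trace: Trace,
    threshold: float = 0.0,
    min_separation: float | None = None,
) -> SpikeTrain:
    """Upward threshold crossings of v, with linear sub-grid interpolation.

    A spike is registered at the first grid interval where
    v[j-1] < threshold <= v[j]; crossings within ``min_separation``
    (default 2*dt) of the previous spike are debounced.  The spike time is
    refined by linear interpolation between the bracketing samples.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    dt = trace.dt
    if min_separation is None:
        min_separation = 2.0 * dt
    v = trace.v
    t = trace.times
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    times: list[float] = []
    last = -math.inf
    for j in up:
        dv = v[j + 1] - v[j]
        frac = 0.0 if dv == 0 else (threshold - v[j]) / dv
        ts = float(t[j] + frac * dt)
        if ts - last >= min_separation:
            times.append(ts)
            last = ts
    return SpikeTrain(tuple(times), source=f"threshold={threshold} on {trace.meta.get('mode', '?')}")


def _require_intervals(isis: ISISequence, least: int) -> None:
    if isis.m < least:
        raise StatisticError(f"statistic needs >= {least} intervals, got {isis.m}")


def cv_stat(isis: ISISequence) -> float:
    """Coefficient of variation of the ISIs (sample std / mean)."""
    _require_intervals(isis, 2)
    t = np.asarray(isis.intervals)
    return float(np.std(t, ddof=1) / np.mean(t))


def lv_stat(isis: ISISequence) -> float:
    """Local variation of adjacent ISIs (Poisson expectation 1)."""
    _require_intervals(isis, 2)
    t = np.asarray(isis.intervals)
    a, b = t[:-1], t[1:]
    return float(np.sum(3.0 * (a - b) ** 2 / (a + b) ** 2) / (isis.m - 1))


def poisson_spike_train(rate: float, n_intervals: int, seed: int) -> SpikeTrain:
    """Homogeneous Poisson train: cumulative i.i.d. exponential intervals."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n_intervals < 1:
        raise ValueError("need at least one interval")
    rng = np.random.default_rng(seed)
    gaps = rng.exponential(1.0 / rate, size=n_intervals)
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    return SpikeTrain(tuple(times), source=f"poisson(rate={rate}, seed={seed})")


def mse_points(a, b) -> float:
    """Mean squared componentwise difference over matched data points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty point lists")
    return float(np.mean((a - b) ** 2))


def segment_bursts(train: SpikeTrain, gap_threshold: float | None = None) -> BurstSummary:
    """Split a train into bursts wherever an ISI exceeds the gap threshold.

    Default threshold is 5x the median ISI, which is scale-free across the
    bursting classes.  Leading/trailing bursts may be clipped by the
    recording window; they are flagged, not dropped.
    """
    if len(train) == 0:
        raise ValueError("need at least one spike")
    isis = np.diff(train.times)
    if gap_threshold is None:
        if len(isis) == 0:
            raise ValueError("cannot infer a gap threshold from a single spike")
        gap_threshold = 5.0 * float(np.median(isis))
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be positive")
    sizes: list[int] = []
    gaps: list[float] = []
    count = 1
    for gap in isis:
        if gap > gap_threshold:
            sizes.append(count)
            gaps.append(float(gap))
            count = 1
        else:
            count += 1
    sizes.append(count)
    return BurstSummary(
        spikes_per_burst=tuple(sizes),
        interburst_intervals=tuple(gaps),
        gap_threshold=float(gap_threshold),
        leading_complete=False,  # window start may clip the first burst
        trailing_complete=False,
    )


# ---------------------------------------------------------------------------
# stimulus-response experiments

#: fraction of simulated time discarded before steady-state statistics
TRANSIENT_FRACTION = 0.2


def _steady_spikes(trace: Trace, transient_fraction: float = TRANSIENT_FRACTION) -> SpikeTrain:
    train = detect_spikes(trace)
    cutoff = transient_fraction * trace.times[-1]
    return SpikeTrain(tuple(t for t in train.times if t >= cutoff), source=train.source)


def compute_prc(
    p: PQNParams,
    I_base: float,
    pulse_amp: float,
    pulse_dur: float,
    n_phases: int = 20,
    t_settle: float | None = None,
    dt: float | None = None,
) -> PhaseResponseCurve:
    """Phase-resetting curve of the limit cycle under constant drive I_base.

    The unperturbed period T is the mean post-transient ISI (the run must
    settle to >= 10 consecutive ISIs within 2 dt of their mean).  For each
    phase theta_j = j/n_phases a fresh simulation applies the probe pulse
    at t_i = t_s + theta_j * T inside a late cycle starting at spike time
    t_s, and the shift is Delta = (T - T_i)/T where T_i is that cycle's
    perturbed length.
    """
    dt = p.dt if dt is None else dt
    base_stim = StimulusProgram.constant(I_base)
    if t_settle is None:
        t_settle = 3.0  # seconds; long enough for every bundled mode
    trace = simulate(p, base_stim, t_max=t_settle, dt=dt)
    train = _steady_spikes(trace)
    isis = np.diff(train.times)
    if len(isis) < 10:
        raise StatisticError(
            f"no sustained oscillation: only {len(isis)} post-transient ISIs"
        )
    tail = isis[-10:]
    T = float(np.mean(tail))
    if np.max(np.abs(tail - T)) > 2.0 * dt:
        raise StatisticError("oscillation not periodic: tail ISIs vary by more than 2 dt")

    # probe a cycle that starts well after the transient but leaves room
    # for the perturbed cycle plus one more spike before t_max
    t_s = train.times[-3]
    t_max = trace.times[-1] + 3.0 * T
    phases: list[float] = []
    shifts: list[float] = []
    for j in range(n_phases):
        theta = j / n_phases
        t_i = t_s + theta * T
        stim = base_stim.overlay(StimulusProgram.pulse(t_i, pulse_dur, pulse_amp))
        pert = simulate(p, stim, t_max=t_max, dt=dt)
        ptrain = detect_spikes(pert)
        after = [t for t in ptrain.times if t > t_s + dt]
        if not after:
            raise StatisticError(f"perturbed run lost the oscillation at theta={theta}")
        T_i = after[0] - t_s
        phases.append(theta)
        shifts.append((T - T_i) / T)
    return PhaseResponseCurve(
        period=T,
        phases=tuple(phases),
        shifts=tuple(shifts),
        pulse_amp=pulse_amp,
        pulse_dur=pulse_dur,
    )


def graded_response_curve(
    p: PQNParams,
    amplitudes,
    pulse_t0: float = 0.1,
    pulse_dur: float = 0.002,
    t_max: float | None = None,
    dt: float | None = None,
) -> list[float]:
    """Peak v after a brief pulse, per amplitude, starting from rest."""
    dt = p.dt if dt is None else dt
    if t_max is None:
        t_max = pulse_t0 + pulse_dur + 0.2
    peaks: list[float] = []
    eq = find_equilibrium(p)
    for amp in amplitudes:
        stim = StimulusProgram.pulse(pulse_t0, pulse_dur, amp)
        trace = simulate(p, stim, t_max=t_max, init=eq, dt=dt)
        onset = int(round(pulse_t0 / dt))
        peaks.append(float(np.max(trace.v[onset:])))
    return peaks


def isi_transition_experiment(
    p: PQNParams,
    step_amps,
    t_on: float = 0.1,
    t_max: float = 2.0,
    dt: float | None = None,
) -> dict[float, list[float]]:
    """Ordered ISI lists (index -> length) under step inputs of varying size."""
    if len(step_amps) == 0:
        raise ValueError("need at least one step amplitude")
    dt = p.dt if dt is None else dt
    eq = find_equilibrium(p)
    out: dict[float, list[float]] = {}
    for amp in step_amps:
        stim = StimulusProgram.step(t_on, amp)
        trace = simulate(p, stim, t_max=t_max, init=eq, dt=dt)
        train = detect_spikes(trace)
        after = [t for t in train.times if t >= t_on]
        out[float(amp)] = list(np.diff(after))
    return out
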