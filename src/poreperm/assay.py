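"""Quantification of the study's functional assays.

Covers the four measurement pipelines around connexin hemichannel activity:

* dual voltage-clamp junctional conductance, g_j = -I_b / (V_a - V_b),
  where I_b is the current recorded in the non-stepped cell (pA), V_a the
  stepped potential and V_b the holding potential (mV); pA/mV gives nS;
* single-channel event idealization of current traces by half-amplitude
  threshold crossing, and from the idealized events the unitary-conductance
  histogram (amplitude / driving voltage, pA/mV -> pS x1000), the modal
  conductance and the open probability P_o (open time / total time);
* dye-uptake kinetics: ordinary least-squares fluorescence slope per
  annotated experiment phase (AU/min), with fold-change and percent-block
  summaries between phases;
* ratiometric Fura-2 calcium signal, F340/F380.

The idealizer is deterministic: closed and open current levels are
estimated by an iterative two-means (Ridler-Calvard) split of the samples,
states are assigned by threshold at a configurable fraction (default 0.5,
i.e. half-amplitude) of the level separation, and dwells shorter than a
minimum duration are merged into their surroundings.  Transition durations
are 10-90% crossing times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "JunctionalRecord",
    "ChannelTrace",
    "Event",
    "EventList",
    "ChannelEstimate",
    "UptakeTrace",
    "UptakeRates",
    "DetectConfig",
    "junctional_conductance",
    "detect_events",
    "conductance_estimate",
    "uptake_rate",
    "ca_ratio",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Junctional conductance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionalRecord:
    """One dual voltage-clamp measurement.

    I_b : current in the non-stepped cell b, pA.
    V_a : potential of the stepped cell a, mV.
    V_b : holding potential of cell b, mV (-60 mV in the standard protocol).
    """

    I_b: float
    V_a: float
    V_b: float = -60.0


def junctional_conductance(rec: JunctionalRecord) -> float:
    """Junctional conductance g_j = -I_b / (V_a - V_b), in nS.

    Raises
    ------
    ValueError
        If V_a equals V_b (no transjunctional driving force).
    """
    dv = rec.V_a - rec.V_b
    if dv == 0:
        raise ValueError("V_a must differ from V_b: conductance undefined")
    return -rec.I_b / dv


# ---------------------------------------------------------------------------
# Single-channel traces and idealization
# ---------------------------------------------------------------------------

@dataclass
class ChannelTrace:
    """Sampled membrane current (pA) under voltage clamp."""

    samples: np.ndarray
    sampling_rate: float      # Hz
    holding_voltage: float    # mV
    protocol: str = "step +60 mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class Event:
    """One idealized dwell (open or closed)."""

    start: float        # s
    end: float          # s
    state: str          # "open" | "closed"
    amplitude: float    # pA relative to baseline (0 for closed events)
    transition_ms: float  # 10-90% entry-transition duration, ms

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class EventList:
    """Time-ordered, non-overlapping idealized dwells plus trace metadata."""

    events: tuple[Event, ...]
    baseline: float          # closed-current level, pA
    total_time: float        # s

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError("events overlap or are out of order")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def open_events(self) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.state == "open")

    @property
    def open_time(self) -> float:
        return sum(e.duration for e in self.open_events)


@dataclass(frozen=True)
class DetectConfig:
    """Idealization settings.

    baseline_window_s : initial stretch used to seed the closed-level
        estimate (the final levels come from the two-means split).
    threshold_fraction : state threshold as a fraction of the closed-open
        separation (0.5 = half-amplitude).
    min_dwell_ms : dwells shorter than this are merged away.
    min_snr : minimum level separation, in units of the closed-state noise
        SD, below which the trace is treated as eventless.
    """

    baseline_window_s: float = 0.5
    threshold_fraction: float = 0.5
    min_dwell_ms: float = 2.0
    min_snr: float = 4.0


def _two_means_threshold(dev: np.ndarray) -> float:
    """Ridler-Calvard iterative midpoint threshold on 1-D samples."""
    t = 0.5 * (dev.min() + dev.max())
    for _ in range(200):
        low = dev[dev < t]
        high = dev[dev >= t]
        if len(low) == 0 or len(high) == 0:
            break
        t_new = 0.5 * (low.mean() + high.mean())
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return t


def _merge_short_runs(states: np.ndarray, min_len: int) -> np.ndarray:
    """Flip runs shorter than ``min_len`` samples into their surroundings,
    shortest first, until every run is long enough (or one run remains)."""
    states = states.copy()
    while True:
        # run-length encode
        change = np.flatnonzero(np.diff(states.astype(np.int8))) + 1
        bounds = np.concatenate([[0], change, [len(states)]])
        lengths = np.diff(bounds)
        if len(lengths) <= 1:
            break
        short = np.flatnonzero(lengths < min_len)
        if len(short) == 0:
            break
        j = short[np.argmin(lengths[short])]
        states[bounds[j]:bounds[j + 1]] = ~states[bounds[j]]
    return states


def _transition_ms(
    dev: np.ndarray, edge: int, amplitude: float, rate: float
) -> float:
    """10-90% crossing time (ms) around an opening edge at sample ``edge``."""
    if amplitude <= 0:
        return 0.0
    lo, hi = 0.1 * amplitude, 0.9 * amplitude
    i10 = edge
    while i10 > 0 and dev[i10 - 1] > lo:
        i10 -= 1
    i90 = edge
    while i90 < len(dev) - 1 and dev[i90] < hi:
        i90 += 1
    return max(i90 - i10, 0) / rate * 1000.0


def detect_events(
    trace: ChannelTrace, config: DetectConfig | None = None
) -> EventList:
    """Idealize a two-state single-channel trace into open/closed dwells.

    A flat trace (or one whose level separation is below ``min_snr`` times
    the closed-state noise) yields an empty event list, not an error.
    """
    config = config or DetectConfig()
    x = trace.samples
    rate = trace.sampling_rate
    n_base = max(int(config.baseline_window_s * rate), 1)
    if len(x) <= n_base:
        raise ValueError("trace shorter than the baseline window")
    polarity = -1.0 if trace.holding_voltage < 0 else 1.0
    dev = polarity * (x - np.median(x[:n_base]))
    if np.ptp(dev) == 0.0:
        return EventList(events=(), baseline=float(x[0]), total_time=trace.duration)
    t = _two_means_threshold(dev)
    closed = dev[dev < t]
    opened = dev[dev >= t]
    if len(closed) == 0 or len(opened) == 0:
        return EventList(events=(), baseline=float(np.median(x)), total_time=trace.duration)
    closed_level = float(np.median(closed))
    open_level = float(np.median(opened))
    separation = open_level - closed_level
    noise_sd = 1.4826 * float(np.median(np.abs(closed - closed_level)))
    if separation <= config.min_snr * noise_sd:
        return EventList(events=(), baseline=float(np.median(x)), total_time=trace.duration)
    threshold = closed_level + config.threshold_fraction * separation
    states = dev >= threshold  # True = open
    min_len = max(int(round(config.min_dwell_ms / 1000.0 * rate)), 1)
    states = _merge_short_runs(states, min_len)
    baseline_dev = float(np.median(dev[~states])) if (~states).any() else closed_level
    baseline = float(np.median(x[:n_base])) + polarity * baseline_dev
    change = np.flatnonzero(np.diff(states.astype(np.int8))) + 1
    bounds = np.concatenate([[0], change, [len(states)]])
    events: list[Event] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        is_open = bool(states[s])
        if is_open:
            seg = dev[s:e]
            # brief sub-dwell closures merged into the event would dilute a
            # plain mean; average only the above-threshold samples
            above = seg[seg >= threshold]
            amp_dev = float(above.mean() if len(above) else seg.mean()) - baseline_dev
            amplitude = polarity * amp_dev
            trans = _transition_ms(dev - baseline_dev, s, amp_dev, rate)
        else:
            amplitude = 0.0
            trans = 0.0
        events.append(
            Event(
                start=s / rate,
                end=e / rate,
                state="open" if is_open else "closed",
                amplitude=amplitude,
                transition_ms=trans,
            )
        )
    return EventList(events=tuple(events), baseline=baseline, total_time=trace.duration)


@dataclass(frozen=True)
class ChannelEstimate:
    """Unitary-conductance and open-probability summary of an event list."""

    modal_conductance: float               # pS, center of the tallest bin
    histogram: tuple[np.ndarray, np.ndarray]  # (bin edges pS, counts)
    open_probability: float
    mean_transition_ms: float
    conductances: np.ndarray               # per open event, pS


def conductance_estimate(
    events: EventList,
    V: float,
    V_rev: float = 0.0,
    bin_width: float = 5.0,
) -> ChannelEstimate:
    """Per-event conductances, modal conductance and open probability.

    Conductance per open event is amplitude / (V - V_rev) x 1000 (pA/mV to
    pS); the reversal potential defaults to 0 mV (the current reverses at
    0 mV for a non-selective channel).  The modal conductance is the center
    of the tallest histogram bin (default width 5 pS).  P_o is total open
    time over total trace time.
    """
    if V == V_rev:
        raise ValueError("V must differ from V_rev")
    open_events = events.open_events
    if not open_events:
        raise ValueError("no open events to estimate conductance from")
    g = np.array([e.amplitude / (V - V_rev) * 1000.0 for e in open_events])
    # bins centered on multiples of bin_width, so an exact 75 pS event
    # reports a 75 pS mode at the default 5 pS granularity
    lo = (np.round(g.min() / bin_width) - 0.5) * bin_width
    hi = (np.round(g.max() / bin_width) + 0.5) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(g, bins=edges)
    i_mode = int(np.argmax(counts))
    modal = float(0.5 * (edges[i_mode] + edges[i_mode + 1]))
    p_open = events.open_time / events.total_time if events.total_time > 0 else 0.0
    transitions = [e.transition_ms for e in open_events]
    return ChannelEstimate(
        modal_conductance=modal,
        histogram=(edges, counts),
        open_probability=float(min(max(p_open, 0.0), 1.0)),
        mean_transition_ms=float(np.mean(transitions)),
        conductances=g,
    )


# ---------------------------------------------------------------------------
# Dye uptake kinetics
# ---------------------------------------------------------------------------

@dataclass
class UptakeTrace:
    """Fluorescence-vs-time recording with labelled experiment phases.

    time : minutes, strictly increasing.
    fluorescence : arbitrary units.
    phases : (label, t_start, t_end) intervals; a sample belongs to the
        first phase whose half-open interval [t_start, t_end) contains it
        (the final phase is closed on the right).
    """

    time: np.ndarray
    fluorescence: np.ndarray
    phases: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.time) != len(self.fluorescence):
            raise ValueError("time and fluorescence lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        self.phases = tuple(self.phases)

    def phase_mask(self, label: str) -> np.ndarray:
        for i, (name, t0, t1) in enumerate(self.phases):
            if name == label:
                last = i == len(self.phases) - 1
                if last:
                    return (self.time >= t0) & (self.time <= t1)
                return (self.time >= t0) & (self.time < t1)
        raise KeyError(label)


@dataclass(frozen=True)
class UptakeRates:
    """Per-phase OLS slopes (AU/min) with comparison helpers."""

    slopes: dict[str, float]
    intercepts: dict[str, float]
    skipped: tuple[str, ...]

    def fold_change(self, reference: str, phase: str) -> float:
        """slope(phase) / slope(reference)."""
        ref = self.slopes[reference]
        if ref == 0:
            raise ZeroDivisionError(f"reference phase {reference!r} has zero slope")
        return self.slopes[phase] / ref

    def percent_block(self, trigger: str, blocker: str) -> float:
        """Percent reduction of the trigger-phase slope in the blocker phase."""
        trig = self.slopes[trigger]
        if trig == 0:
            raise ZeroDivisionError(f"trigger phase {trigger!r} has zero slope")
        return 100.0 * (1.0 - self.slopes[blocker] / trig)


def uptake_rate(trace: UptakeTrace) -> UptakeRates:
    """Ordinary least-squares fluorescence slope per annotated phase.

    Phases with fewer than three samples are skipped with a warning; all
    in-phase samples are used, with no outlier rejection.
    """
    slopes: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    skipped: list[str] = []
    for label, _, _ in trace.phases:
        mask = trace.phase_mask(label)
        if mask.sum() < 3:
            logger.warning("phase %r has fewer than 3 samples; skipped", label)
            skipped.append(label)
            continue
        fit = stats.linregress(trace.time[mask], trace.fluorescence[mask])
        slopes[label] = float(fit.slope)
        intercepts[label] = float(fit.intercept)
    return UptakeRates(slopes=slopes, intercepts=intercepts, skipped=tuple(skipped))


# ---------------------------------------------------------------------------
# Calcium signal
# ---------------------------------------------------------------------------

def ca_ratio(F340: Sequence[float], F380: Sequence[float]) -> np.ndarray:
    """Ratiometric calcium signal F340/F380, elementwise.

    Raises
    ------
    ValueError
        On length mismatch or any non-positive F380 sample.
    """
    a = np.asarray(F340, dtype=float)
    b = np.asarray(F380, dtype=float)
    if a.shape != b.shape:
        raise ValueError("F340 and F380 must have equal length")
    if np.any(b <= 0):
        raise ValueError("F380 must be positive everywhere")
    return a / b
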