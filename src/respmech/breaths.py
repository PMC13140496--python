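"""Breath segmentation and per-breath timing / slope features.

Respiratory efforts are detected on an "analysis trace": either an EMG
envelope, or the magnitude of the inspiratory pressure deflection below
the zero-flow baseline (inspiratory oesophageal pressure is negative, so
the trace is ``baseline - pressure``).  The detection threshold is
data-adaptive: baseline statistics come from the quietest decile of
200 ms windows within the interval, the onset threshold sits
``threshold_k`` baseline SDs above the baseline median (floored by an
amplitude-aware term, see ``ONSET_RANGE_FRAC``), and offsets use a
lower hysteresis threshold plus a fraction-of-peak termination term.
Bursts closer than ``min_separation`` are merged, then bursts shorter
than ``min_ti`` or failing the ``min_peak_k`` prominence gate are
discarded — in that order, deterministically.

Timing follows standard respirometry conventions: Ti is onset-to-offset,
Ttot is onset-to-next-onset (undefined for the last breath of a
segment), and duty cycle is Ti/Ttot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from respmech.io import SampledSignal, StateInterval

BASELINE_WINDOW_S = 0.2
MIN_INTERVAL_S = 0.5

#: For strictly positive traces (EMG envelopes) the quietest-decile SD can
#: be a tiny fraction of the baseline level itself, putting the detection
#: threshold inside the noise floor; the SD is floored at this fraction of
#: the baseline median (no effect on zero-median deflection traces).
SD_FLOOR_FRAC = 0.1

#: A burst also terminates when the trace falls below this fraction of its
#: own peak elevation.  Filter ringing from large bursts lifts the
#: inter-burst floor above a purely baseline-derived offset threshold;
#: keying the offset on the burst peak keeps termination amplitude-adaptive.
#: Tail chatter this creates is reassembled by the merge rule.
OFFSET_PEAK_FRAC = 0.1

#: The onset threshold is floored at this fraction of the trace's
#: 99th-percentile elevation above baseline.  A narrow notch (Q = 35)
#: rings for hundreds of milliseconds, and zero-phase filtering smears
#: each burst's line-frequency content symmetrically in time; those
#: tails scale with burst amplitude (roughly 2% of the peak) and can top
#: a purely baseline-derived threshold when the burst SNR is high.
#: A zero-burst trace has a 99th percentile near baseline, so the floor
#: is inert on quiet signals, and it is scale-invariant by construction.
ONSET_RANGE_FRAC = 0.05


@dataclass(frozen=True)
class SegmentationSpec:
    """Burst-detection parameters.

    threshold_k
        Onset threshold in multiples of the baseline SD above the
        baseline median.
    hysteresis_frac
        Offset threshold as a fraction of the onset threshold's
        elevation above the baseline median.
    min_ti : s
        Bursts shorter than this are discarded.
    min_separation : s
        Bursts separated by less than this are merged.
    min_peak_k
        Amplitude-prominence gate: a burst is kept only if its peak
        reaches this many baseline SDs above the baseline median.
        Genuine respiratory bursts sit far above the noise floor; this
        gate rejects slow noise excursions that clear the (lower) onset
        threshold long enough to pass the duration gate.
    """

    threshold_k: float = 3.0
    hysteresis_frac: float = 0.5
    min_ti: float = 0.03
    min_separation: float = 0.05
    min_peak_k: float = 8.0

    def __post_init__(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if not (0 < self.hysteresis_frac < 1):
            raise ValueError("hysteresis_frac must be in (0, 1)")


@dataclass
class Breath:
    """One segmented respiratory effort.

    ``peak_envelope`` / ``peak_pressure`` hold the analysis-trace peak
    depending on the source channel; the other is NaN until filled from
    the complementary channel.  ``ttot``/``duty_cycle`` are NaN until
    assigned by :func:`breath_timing` (the last breath of a segment has
    no defined Ttot).
    """

    onset_time: float
    peak_time: float
    offset_time: float
    peak_value: float
    source_channel: str
    ti: float = float("nan")
    ttot: float = float("nan")
    duty_cycle: float = float("nan")
    peak_envelope: float = float("nan")
    peak_pressure: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.onset_time <= self.peak_time <= self.offset_time):
            raise ValueError("require onset_time <= peak_time <= offset_time")
        if np.isnan(self.ti):
            self.ti = self.offset_time - self.onset_time
        if self.ti <= 0:
            raise ValueError("ti must be positive")
        if self.source_channel == "pressure":
            self.peak_pressure = self.peak_value
        else:
            self.peak_envelope = self.peak_value


def baseline_stats(
    x: np.ndarray, rate: float, window_s: float = BASELINE_WINDOW_S
) -> tuple[float, float]:
    """Baseline (median, SD) from the quietest decile of short windows.

    The signal is cut into ``window_s`` windows, ranked by RMS, and the
    samples of the quietest 10% of windows (at least one) are pooled.
    """
    w = max(1, int(round(window_s * rate)))
    nwin = max(1, x.size // w)
    trimmed = x[: nwin * w].reshape(nwin, -1)
    rms = np.sqrt(np.mean(trimmed**2, axis=1))
    k = max(1, int(np.ceil(0.1 * nwin)))
    quiet = trimmed[np.argsort(rms, kind="stable")[:k]].ravel()
    return float(np.median(quiet)), float(np.std(quiet))


def analysis_trace(
    signal: SampledSignal,
    interval: StateInterval,
    kind: Literal["envelope", "pressure"],
) -> SampledSignal:
    """Return the detection trace for an interval.

    For ``envelope`` the segment is used as-is; for ``pressure`` the
    trace is the deflection magnitude ``baseline_median - pressure``
    (inspiratory deflections are sub-atmospheric).
    """
    seg = signal.segment(interval.start_time, interval.end_time)
    if kind == "pressure":
        med, _ = baseline_stats(seg.samples, seg.rate)
        return SampledSignal(med - seg.samples, seg.rate, seg.label, seg.units, seg.t0)
    return seg


def _burst_bounds(
    y: np.ndarray, thr_on: float, thr_off: float, med: float
) -> list[tuple[int, int]]:
    """Hysteresis state machine: [on, off) index pairs, off exclusive.

    A burst ends when the trace falls below the hysteresis threshold or
    below ``OFFSET_PEAK_FRAC`` of the burst's running peak elevation,
    whichever is higher.
    """
    bursts: list[tuple[int, int]] = []
    active = False
    start = 0
    peak = 0.0
    for i, v in enumerate(y):
        if not active:
            if v > thr_on:
                active = True
                start = i
                peak = v
        else:
            if v > peak:
                peak = v
            off = max(thr_off, med + OFFSET_PEAK_FRAC * (peak - med))
            if v <= off:
                bursts.append((start, i))
                active = False
    if active:
        bursts.append((start, y.size))
    return bursts


def detect_breaths(
    signal: SampledSignal,
    interval: StateInterval,
    spec: SegmentationSpec = SegmentationSpec(),
    kind: Literal["envelope", "pressure"] = "pressure",
) -> list[Breath]:
    """Segment respiratory efforts within one state interval.

    Returns breaths ordered by onset, with Ti set and Ttot/duty cycle
    left for :func:`breath_timing`.  The detected count is invariant to
    uniform amplitude scaling of the signal because the threshold is
    data-adaptive.
    """
    if interval.duration < MIN_INTERVAL_S:
        raise ValueError("interval too short")
    trace = analysis_trace(signal, interval, kind)
    y = trace.samples
    med, sd = baseline_stats(y, trace.rate)
    sd = max(sd, SD_FLOOR_FRAC * abs(med))
    p99 = float(np.percentile(y, 99))
    thr_on = max(med + spec.threshold_k * sd, med + ONSET_RANGE_FRAC * (p99 - med))
    thr_off = med + spec.hysteresis_frac * (thr_on - med)
    bursts = _burst_bounds(y, thr_on, thr_off, med)

    # merge bursts separated by less than min_separation, then drop short ones
    merged: list[tuple[int, int]] = []
    gap = int(round(spec.min_separation * trace.rate))
    for on, off in bursts:
        if merged and on - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    min_len = int(round(spec.min_ti * trace.rate))
    peak_gate = med + spec.min_peak_k * sd
    kept = [
        (on, off)
        for on, off in merged
        if off - on >= min_len and np.max(y[on:off]) >= peak_gate
    ]

    breaths = []
    for on, off in kept:
        pk = on + int(np.argmax(y[on:off]))  # argmax takes the earliest tie
        breaths.append(
            Breath(
                onset_time=trace.t0 + on / trace.rate,
                peak_time=trace.t0 + pk / trace.rate,
                offset_time=trace.t0 + off / trace.rate,
                peak_value=float(y[pk]),
                source_channel=signal.label or kind,
            )
        )
    return breaths


def breath_timing(breaths: list[Breath]) -> list[Breath]:
    """Assign Ttot (onset-to-next-onset) and duty cycle in place.

    The last breath keeps Ttot = NaN and is excluded from duty-cycle
    statistics.  A single breath yields no timing and a warning.
    """
    if len(breaths) < 2:
        if len(breaths) == 1:
            warnings.warn("single breath: Ttot undefined, no timing computed")
        return breaths
    for cur, nxt in zip(breaths, breaths[1:]):
        cur.ttot = nxt.onset_time - cur.onset_time
        cur.duty_cycle = cur.ti / cur.ttot
    return breaths


def onset_to_peak_slope(trace: SampledSignal, breath: Breath) -> float:
    """Endpoint slope of the analysis trace from breath onset to peak.

    ``trace`` must be in analysis orientation (envelope, or pressure
    deflection magnitude), so the slope of a genuine effort is >= 0.
    Units are trace-units per second (cmH2O/s for the inspiratory drive
    rate, uV/s for the EMG rise slope).
    """
    if breath.peak_time <= breath.onset_time:
        raise ValueError("degenerate breath: peak_time == onset_time")
    i_on = int(round((breath.onset_time - trace.t0) * trace.rate))
    i_pk = int(round((breath.peak_time - trace.t0) * trace.rate))
    if not (0 <= i_on < trace.samples.size and 0 <= i_pk < trace.samples.size):
        raise ValueError("breath lies outside trace")
    dv = trace.samples[i_pk] - trace.samples[i_on]
    return float(dv / (breath.peak_time - breath.onset_time))
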