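"""Sustained tracheal-occlusion analysis: per-effort pressures, task
failure, and the composite pressure-time AUC.

Each inspiratory effort against the occluded airway contributes one
(time, peak deflection magnitude) point to a pressure-time plot.  The
"sustained peak nadir" is the maximum-magnitude effort (the pressure
nadir, since inspiratory pressure is negative).  Task failure is the
first effort after the nadir at which ``k_consecutive`` successive
efforts all fall below ``decline_frac`` of the nadir magnitude; if no
such run exists, the last effort is used and flagged.  The AUC of the
effort-point envelope is the trapezoid of (times, peaks) from the first
effort through the failure effort, in cmH2O*s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from respmech.breaths import Breath, SegmentationSpec, detect_breaths
from respmech.io import SampledSignal, StateInterval

DECLINE_FRAC = 0.9
K_CONSECUTIVE = 2
MIN_EFFORTS = 3


@dataclass
class EffortSeries:
    """Per-effort peak pressures during a sustained occlusion.

    ``effort_times`` are peak times in seconds from occlusion onset;
    ``effort_peaks`` are deflection magnitudes (cmH2O).
    """

    effort_times: np.ndarray
    effort_peaks: np.ndarray
    breaths: list[Breath] = field(default_factory=list)
    failure_index: int | None = None
    no_failure: bool = False
    auc: float = float("nan")

    def __post_init__(self) -> None:
        self.effort_times = np.asarray(self.effort_times, dtype=float)
        self.effort_peaks = np.asarray(self.effort_peaks, dtype=float)
        if self.effort_times.size != self.effort_peaks.size:
            raise ValueError("times and peaks must have equal length")
        if np.any(np.diff(self.effort_times) <= 0):
            raise ValueError("effort_times must be strictly increasing")

    @property
    def n_efforts(self) -> int:
        return int(self.effort_times.size)

    @property
    def nadir_index(self) -> int:
        """Index of the maximum-magnitude effort (earliest on ties)."""
        return int(np.argmax(self.effort_peaks))


def extract_efforts(
    pressure: SampledSignal,
    occlusion: StateInterval,
    spec: SegmentationSpec = SegmentationSpec(),
) -> EffortSeries:
    """Detect occlusion efforts on the pressure channel.

    Reuses breath segmentation on the inspiratory deflection trace; one
    point per effort, with times relative to occlusion onset.  Fewer
    than 3 efforts (e.g. a flat trace) is an error.
    """
    breaths = detect_breaths(pressure, occlusion, spec, kind="pressure")
    if len(breaths) < MIN_EFFORTS:
        raise ValueError("too few efforts for occlusion analysis")
    times = np.array([b.peak_time - occlusion.start_time for b in breaths])
    peaks = np.array([b.peak_pressure for b in breaths])
    return EffortSeries(times, peaks, breaths=breaths)


def detect_task_failure(
    series: EffortSeries,
    decline_frac: float = DECLINE_FRAC,
    k_consecutive: int = K_CONSECUTIVE,
) -> EffortSeries:
    """Locate task failure and store it on the series.

    failure_index = first index after the nadir at which
    ``k_consecutive`` successive efforts are all below
    ``decline_frac x nadir magnitude``.  Without such a run the last
    effort is used and ``no_failure`` set.
    """
    if series.n_efforts < MIN_EFFORTS:
        raise ValueError("too few efforts for failure detection")
    peaks = series.effort_peaks
    threshold = decline_frac * peaks[series.nadir_index]
    below = peaks < threshold
    for i in range(series.nadir_index + 1, series.n_efforts - k_consecutive + 1):
        if below[i : i + k_consecutive].all():
            series.failure_index = i
            series.no_failure = False
            return series
    series.failure_index = series.n_efforts - 1
    series.no_failure = True
    return series


def pressure_time_auc(series: EffortSeries) -> float:
    """Trapezoidal AUC of the effort points through the failure effort.

    Requires a failure index (run :func:`detect_task_failure` first).
    A single effort yields 0 with a warning.
    """
    if series.failure_index is None:
        raise ValueError("failure_index not set; run detect_task_failure first")
    stop = series.failure_index + 1
    t = series.effort_times[:stop]
    p = series.effort_peaks[:stop]
    if t.size < 2:
        warnings.warn("single effort: pressure-time AUC is 0")
        series.auc = 0.0
        return 0.0
    series.auc = float(np.trapezoid(p, t))
    return series.auc


def analyse_occlusion(
    pressure: SampledSignal,
    occlusion: StateInterval,
    spec: SegmentationSpec = SegmentationSpec(),
    decline_frac: float = DECLINE_FRAC,
    k_consecutive: int = K_CONSECUTIVE,
) -> EffortSeries:
    """Full occlusion analysis: efforts, task failure, AUC."""
    series = extract_efforts(pressure, occlusion, spec)
    detect_task_failure(series, decline_frac, k_consecutive)
    pressure_time_auc(series)
    return series
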