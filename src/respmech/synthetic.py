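"""Seeded generator of synthetic respiratory recordings with ground truth.

The generator emulates the signal structure the analysis assumes, for an
anaesthetised-mouse-like preparation:

* **EMG** (20 kHz, per muscle): a half-sine burst envelope (duration Ti,
  period Ttot) multiplied by band-limited Gaussian noise spectrally
  shaped to the 30-1000 Hz myoelectric band.  The noise is normalised to
  unit mean absolute value, so the rectified EMG tracks the configured
  envelope amplitude and the noise-free burst integral
  ``(2/pi) * amp * Ti`` is an exact ground truth for the per-breath
  integrated EMG.  A 50 Hz line-noise sinusoid and a periodic biphasic
  low-frequency ECG-like pulse train are superimposed; a tonic baseline
  noise floor keeps detection thresholds realistic.  A genotype scaling
  factor multiplies the whole EMG (dystrophic-like preparations have
  reduced raw EMG amplitude; the NRD normalisation must cancel it).
* **Pressure** (1 kHz): per breath, a negative (sub-atmospheric)
  half-sine deflection whose magnitude is ``nme_gain`` times the
  noise-free diaphragm EMG integral of that breath, so the configured
  neuromechanical gain is recoverable exactly, plus white sensor noise.
* **States** laid out sequentially: baseline, post-vagotomy (identical
  statistics), hypercapnic hypoxia (burst amplitude scaled up, Ttot
  shortened), then a sustained occlusion of escalating discrete efforts
  that decline to task failure after a configured effort index.

Fixing the seed makes the output bit-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import signal as sps

from respmech.io import Recording, SampledSignal, State, StateInterval

EMG_LABELS = ("dia", "eic", "ps")


@dataclass(frozen=True)
class OcclusionSchedule:
    """Piecewise-linear per-effort amplitude schedule for the occlusion.

    Effort fractions rise linearly from ``escalation_frac`` to 1 at
    effort ``failure_onset_effort - 1`` (the nadir) and then decline
    linearly to ``failure_decline_frac`` at the last effort.
    ``amp_factor`` scales the tidal burst amplitude up to maximal-effort
    level.
    """

    n_efforts: int = 15
    escalation_frac: float = 0.5
    failure_onset_effort: int = 11
    failure_decline_frac: float = 0.5
    amp_factor: float = 3.0
    ti: float = 0.15
    ttot: float = 0.5

    def fractions(self) -> np.ndarray:
        n, fo = self.n_efforts, self.failure_onset_effort
        if not (1 <= fo < n):
            raise ValueError("failure_onset_effort must lie inside the effort series")
        up = np.linspace(self.escalation_frac, 1.0, fo)
        down = np.linspace(1.0, self.failure_decline_frac, n - fo + 1)[1:]
        return np.concatenate([up, down])


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    rate_emg: float = 20000.0
    rate_pressure: float = 1000.0
    n_breaths: int = 20
    ti: float = 0.15
    ttot: float = 0.5
    burst_amp: dict = field(
        default_factory=lambda: {"dia": 8.0, "eic": 5.0, "ps": 4.0}
    )
    emg_band: tuple[float, float] = (30.0, 1000.0)
    nme_gain: float = 4.0
    genotype_scale: float = 1.0
    line_noise_amp: float = 2.0
    ecg_amp: float = 5.0
    ecg_rate: float = 10.0
    ecg_width: float = 0.04
    baseline_noise_amp: float = 0.2
    hchx_amp_factor: float = 2.0
    hchx_ttot_factor: float = 0.8
    occlusion: OcclusionSchedule = field(default_factory=OcclusionSchedule)
    pressure_noise: float = 0.05
    pad: float = 1.0
    pad_end: float = 0.5
    subject: str = "sim01"
    genotype: str = "wt"
    age_months: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.ti < self.ttot):
            raise ValueError("require 0 < ti < ttot")
        if any(v < 0 for v in self.burst_amp.values()):
            raise ValueError("amplitudes must be non-negative")
        if not (0 < self.emg_band[0] < self.emg_band[1] < self.rate_emg / 2):
            raise ValueError("emg_band outside (0, rate/2)")


@dataclass
class StateTruth:
    """Configured per-breath ground truth for one state."""

    interval: StateInterval
    onsets: np.ndarray
    peak_times: np.ndarray
    offsets: np.ndarray
    burst_amps: dict  # muscle -> per-breath envelope amplitude (uV)
    dia_integrals: np.ndarray  # noise-free rectified integral (uV*s)
    pressure_amps: np.ndarray  # deflection magnitudes (cmH2O)
    ti: float
    ttot: float


@dataclass
class GroundTruth:
    config: GeneratorConfig
    states: dict
    effort_times: np.ndarray  # occlusion effort peak times from occlusion onset
    effort_peaks: np.ndarray  # configured deflection magnitudes
    failure_onset_effort: int
    mip: float

    def to_jsonable(self) -> dict:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (StateInterval,)):
                return {"state": o.state.value, "start": o.start_time, "end": o.end_time}
            if isinstance(o, StateTruth):
                return {k: conv(v) for k, v in vars(o).items()}
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            return o

        return {
            "config": conv(asdict(self.config)),
            "states": conv(self.states),
            "effort_times": self.effort_times.tolist(),
            "effort_peaks": self.effort_peaks.tolist(),
            "failure_onset_effort": self.failure_onset_effort,
            "mip": self.mip,
        }


def _band_noise(rng: np.random.Generator, n: int, rate: float, band) -> np.ndarray:
    """Band-limited Gaussian noise normalised to unit mean absolute value."""
    w = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", output="sos", fs=rate)
    x = sps.sosfiltfilt(sos, w)
    return x / np.mean(np.abs(x))


def _pressure_noise(
    rng: np.random.Generator, n: int, rate: float, sigma: float, cutoff: float = 30.0
) -> np.ndarray:
    """Low-pass sensor noise (oesophageal pressure is a slow signal; the
    transducer chain does not produce sample-independent white noise)."""
    if sigma == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    sos = sps.butter(2, cutoff, btype="lowpass", output="sos", fs=rate)
    x = sps.sosfiltfilt(sos, w)
    return sigma * x / np.std(x)


def _ecg_train(t: np.ndarray, amp: float, rate_hz: float, width: float) -> np.ndarray:
    """Periodic biphasic pulse: one sine cycle of duration ``width`` per beat.

    Energy is concentrated below the 30 Hz analysis floor (fundamental
    1/width = 25 Hz for the default width), so the bandpass and the
    spectral band limit both exclude it.
    """
    phase = np.mod(t, 1.0 / rate_hz)
    pulse = np.where(phase < width, np.sin(2 * np.pi * phase / width), 0.0)
    return amp * pulse


def _burst_envelope(t: np.ndarray, onsets: np.ndarray, amps: np.ndarray, ti: float) -> np.ndarray:
    env = np.zeros_like(t)
    for t0, a in zip(onsets, amps):
        i0 = np.searchsorted(t, t0)
        i1 = np.searchsorted(t, t0 + ti)
        env[i0:i1] = a * np.sin(np.pi * (t[i0:i1] - t0) / ti)
    return env


def generate_recording(config: GeneratorConfig) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic recording plus its configured ground truth."""
    rng = np.random.default_rng(config.seed)
    occ = config.occlusion

    # ---- lay out states sequentially -------------------------------------
    plan = []  # (state, n_breaths, ti, ttot, amp_scale)
    plan.append((State.BASELINE, config.n_breaths, config.ti, config.ttot, 1.0))
    plan.append((State.POST_VAGOTOMY, config.n_breaths, config.ti, config.ttot, 1.0))
    plan.append(
        (
            State.HCHX,
            config.n_breaths,
            config.ti,
            config.ttot * config.hchx_ttot_factor,
            config.hchx_amp_factor,
        )
    )
    plan.append((State.OCCLUSION, occ.n_efforts, occ.ti, occ.ttot, occ.amp_factor))

    t_cursor = 0.0
    states: dict[str, StateTruth] = {}
    occ_fracs = occ.fractions()
    for state, n, ti, ttot, amp_scale in plan:
        duration = config.pad + n * ttot + config.pad_end
        interval = StateInterval(state, t_cursor, t_cursor + duration)
        onsets = t_cursor + config.pad + np.arange(n) * ttot
        fracs = occ_fracs if state is State.OCCLUSION else np.ones(n)
        burst_amps = {
            m: config.burst_amp[m] * config.genotype_scale * amp_scale * fracs
            for m in EMG_LABELS
        }
        dia_int = (2 / np.pi) * burst_amps["dia"] * ti
        p_amps = config.nme_gain * dia_int
        states[state.value] = StateTruth(
            interval=interval,
            onsets=onsets,
            peak_times=onsets + ti / 2,
            offsets=onsets + ti,
            burst_amps=burst_amps,
            dia_integrals=dia_int,
            pressure_amps=p_amps,
            ti=ti,
            ttot=ttot,
        )
        t_cursor += duration
    total_duration = t_cursor

    # ---- EMG channels ----------------------------------------------------
    n_emg = int(round(total_duration * config.rate_emg))
    t_emg = np.arange(n_emg) / config.rate_emg
    channels: dict[str, SampledSignal] = {}
    for muscle in EMG_LABELS:
        env = np.zeros(n_emg)
        for st in states.values():
            env += _burst_envelope(t_emg, st.onsets, st.burst_amps[muscle], st.ti)
        noise = _band_noise(rng, n_emg, config.rate_emg, config.emg_band)
        emg = (env + config.baseline_noise_amp * config.genotype_scale) * noise
        emg = emg + config.line_noise_amp * np.sin(2 * np.pi * 50.0 * t_emg)
        emg = emg + _ecg_train(t_emg, config.ecg_amp, config.ecg_rate, config.ecg_width)
        channels[muscle] = SampledSignal(emg, config.rate_emg, muscle, "uV")

    # ---- pressure channel ------------------------------------------------
    n_p = int(round(total_duration * config.rate_pressure))
    t_p = np.arange(n_p) / config.rate_pressure
    pressure = _pressure_noise(rng, n_p, config.rate_pressure, config.pressure_noise)
    for st in states.values():
        pressure -= _burst_envelope(t_p, st.onsets, st.pressure_amps, st.ti)
    channels["pressure"] = SampledSignal(pressure, config.rate_pressure, "pressure", "cmH2O")

    recording = Recording(
        channels,
        [st.interval for st in states.values()],
        {
            "id": config.subject,
            "genotype": config.genotype,
            "age_months": config.age_months,
        },
    )
    occ_truth = states[State.OCCLUSION.value]
    truth = GroundTruth(
        config=config,
        states=states,
        effort_times=occ_truth.peak_times - occ_truth.interval.start_time,
        effort_peaks=occ_truth.pressure_amps.copy(),
        failure_onset_effort=occ.failure_onset_effort,
        mip=float(np.max(occ_truth.pressure_amps)),
    )
    return recording, truth
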