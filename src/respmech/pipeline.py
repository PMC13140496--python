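"""Batch analysis driver: read every recording in a directory, run all
stages per muscle per state, and emit tidy result tables.

Outputs (CSV, deterministic row order, schema-stable even when measures
are invalid):

* ``breaths.csv``    — per-breath rows with timing, amplitudes and indices
* ``indices.csv``    — per-state median NRD / NME / TTI / IDR / EMG rise
* ``spectra.csv``    — per-muscle, per-state Welch spectrum parameters
* ``entropy.csv``    — per-muscle, per-state Shannon / ApEn / SampEn
* ``occlusion.csv``  — per-effort pressure-time points, failure index, AUC
* ``manifest.json``  — run configuration, software version, per-recording
  status (processing continues past per-recording failures)

Group-level statistics are deliberately not computed here: the tables
are long-format and ready for any external statistics package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import respmech
from respmech.breaths import (
    SegmentationSpec,
    analysis_trace,
    breath_timing,
    detect_breaths,
    onset_to_peak_slope,
)
from respmech.entropy import EntropyParams, entropy_summary
from respmech.indices import MaxReference, compute_emg_max, per_state_indices
from respmech.io import (
    EMG_LABELS,
    PRESSURE_LABEL,
    Recording,
    State,
    read_recording,
)
from respmech.occlusion import DECLINE_FRAC, K_CONSECUTIVE, analyse_occlusion
from respmech.preprocess import (
    EnvelopeSpec,
    FilterSpec,
    apply_filters,
    breath_emg_integral,
    design_filters,
    envelope,
)
from respmech.spectral import SpectralParams, spectrum_summary

log = logging.getLogger("respmech")

TIDAL_STATES = (State.BASELINE, State.POST_VAGOTOMY, State.HCHX)


@dataclass
class RunConfig:
    """All module parameter blocks plus the segmentation driver channel."""

    filters: FilterSpec = field(default_factory=FilterSpec)
    envelope: EnvelopeSpec = field(default_factory=EnvelopeSpec)
    segment: SegmentationSpec = field(default_factory=SegmentationSpec)
    segment_channel: str = "pressure"  # "pressure" or an EMG label (envelope mode)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    occlusion_decline_frac: float = DECLINE_FRAC
    occlusion_k_consecutive: int = K_CONSECUTIVE

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        filt = raw.get("filters", {})
        band = filt.pop("band", None)
        if band is not None:
            filt["band_low"], filt["band_high"] = band
        spect = raw.get("spectral", {})
        if "band" in spect:
            spect["band"] = tuple(spect["band"])
        if "overlap" in spect:
            spect["overlap_frac"] = spect.pop("overlap")
        ent = raw.get("entropy", {})
        if "precision" in ent:
            ent["shannon_precision"] = ent.pop("precision")
        if "min_len_apen" in ent:
            ent["min_len_apen_sampen"] = ent.pop("min_len_apen")
        seg = dict(raw.get("segment", {}))
        channel = seg.pop("channel", "pressure")
        occ = raw.get("occlusion", {})
        return cls(
            filters=FilterSpec(**filt),
            envelope=EnvelopeSpec(**raw.get("envelope", {})),
            segment=SegmentationSpec(**seg),
            segment_channel=channel,
            spectral=SpectralParams(**spect),
            entropy=EntropyParams(**ent),
            occlusion_decline_frac=occ.get("decline_frac", DECLINE_FRAC),
            occlusion_k_consecutive=occ.get("k_consecutive", K_CONSECUTIVE),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def analyse_recording(recording: Recording, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every analysis stage on one recording; returns the five tables."""
    meta = {
        "subject": recording.subject,
        "genotype": recording.subject_meta.get("genotype", ""),
        "age_months": recording.subject_meta.get("age_months", float("nan")),
    }
    pressure = recording.channels.get(PRESSURE_LABEL)
    muscles = [m for m in EMG_LABELS if m in recording.channels]
    if not muscles:
        raise ValueError("recording has no EMG channels")

    # --- filtering + envelopes -------------------------------------------
    filtered: dict[str, object] = {}
    envelopes: dict[str, object] = {}
    for m in muscles:
        bank = design_filters(config.filters, recording.channels[m].rate)
        filtered[m] = apply_filters(recording.channels[m], bank)
        envelopes[m] = envelope(filtered[m], config.envelope)

    # --- segmentation driver ---------------------------------------------
    if config.segment_channel == "pressure":
        if pressure is None:
            raise ValueError("pressure channel required for pressure-driven segmentation")
        driver, kind = pressure, "pressure"
    else:
        driver, kind = envelopes[config.segment_channel], "envelope"

    breaths_by_state: dict[State, list] = {}
    for iv in recording.states:
        breaths = breath_timing(detect_breaths(driver, iv, config.segment, kind=kind))
        if not breaths:
            warnings.warn(f"no breaths detected in state {iv.state.value}; state omitted")
            continue
        breaths_by_state[iv.state] = breaths
        log.info("%s/%s: %d breaths", recording.subject, iv.state.value, len(breaths))

    # --- occlusion + reference maxima ------------------------------------
    occ_rows = []
    references: dict[str, MaxReference] = {}
    occ_iv = next((iv for iv in recording.states if iv.state is State.OCCLUSION), None)
    if occ_iv is None or pressure is None:
        raise ValueError("occlusion interval and pressure channel are required")
    series = analyse_occlusion(
        pressure,
        occ_iv,
        config.segment,
        config.occlusion_decline_frac,
        config.occlusion_k_consecutive,
    )
    mip = float(np.max(series.effort_peaks))
    for m in muscles:
        peaks = [
            float(np.max(envelopes[m].segment(b.onset_time, b.offset_time).samples))
            for b in series.breaths
        ]
        emg_max, few = compute_emg_max(peaks)
        references[m] = MaxReference(emg_max=emg_max, mip=mip, few_efforts=few)
    for i in range(series.n_efforts):
        occ_rows.append(
            {
                **meta,
                "effort": i,
                "effort_time": series.effort_times[i],
                "effort_peak": series.effort_peaks[i],
                "nadir_index": series.nadir_index,
                "failure_index": series.failure_index,
                "no_failure": series.no_failure,
                "auc": series.auc,
            }
        )

    # --- per-breath metrics ----------------------------------------------
    breath_rows = []
    for state, breaths in breaths_by_state.items():
        iv = recording.interval(state)
        p_trace = (
            analysis_trace(pressure, iv, "pressure") if pressure is not None else None
        )
        env_traces = {m: analysis_trace(envelopes[m], iv, "envelope") for m in muscles}
        for j, b in enumerate(breaths):
            p_amp = float("nan")
            idr = float("nan")
            if p_trace is not None:
                seg = p_trace.segment(b.onset_time, b.offset_time)
                p_amp = float(np.max(seg.samples))
                try:
                    idr = onset_to_peak_slope(p_trace, b)
                except ValueError:
                    pass
            for m in muscles:
                env_seg = env_traces[m].segment(b.onset_time, b.offset_time)
                pk_i = int(np.argmax(env_seg.samples))
                peak_env = float(env_seg.samples[pk_i])
                peak_t = env_seg.t0 + pk_i / env_seg.rate
                rise = (
                    (peak_env - float(env_seg.samples[0])) / (peak_t - b.onset_time)
                    if peak_t > b.onset_time
                    else float("nan")
                )
                integral = breath_emg_integral(filtered[m], b)
                breath_rows.append(
                    {
                        **meta,
                        "muscle": m,
                        "state": state.value,
                        "breath": j,
                        "onset_time": b.onset_time,
                        "ti": b.ti,
                        "ttot": b.ttot,
                        "duty_cycle": b.duty_cycle,
                        "peak_envelope": peak_env,
                        "peak_pressure": p_amp,
                        "emg_integral": integral,
                        "idr": idr,
                        "emg_rise": rise,
                    }
                )
    breath_df = pd.DataFrame(breath_rows)
    breath_df, state_df = per_state_indices(breath_df, references)

    # --- spectra + entropy per muscle per state ---------------------------
    spec_rows, ent_rows = [], []
    for iv in recording.states:
        for m in muscles:
            seg = filtered[m].segment(iv.start_time, iv.end_time)
            s = spectrum_summary(seg, config.spectral)
            spec_rows.append(
                {
                    **meta,
                    "muscle": m,
                    "state": iv.state.value,
                    "mean_freq": s.mean_freq,
                    "power_at_mean": s.power_at_mean,
                    "median_freq": s.median_freq,
                    "power_at_median": s.power_at_median,
                    "max_freq": s.max_freq,
                    "power_at_max": s.power_at_max,
                    "total_power": s.total_power,
                    "n_segments": s.n_segments,
                    "valid": s.valid,
                }
            )
            e = entropy_summary(seg, config.entropy)
            ent_rows.append(
                {
                    **meta,
                    "muscle": m,
                    "state": iv.state.value,
                    "shannon": e.shannon,
                    "apen": e.apen,
                    "sampen": e.sampen,
                    "n": e.n,
                    "shannon_valid": e.valid_flags.get("shannon", False),
                    "apen_valid": e.valid_flags.get("apen", False),
                    "sampen_valid": e.valid_flags.get("sampen", False),
                    "degenerate": e.degenerate,
                }
            )
            log.info("%s/%s/%s: spectra+entropy done", recording.subject, iv.state.value, m)

    return {
        "breaths": breath_df,
        "indices": state_df,
        "spectra": pd.DataFrame(spec_rows),
        "entropy": pd.DataFrame(ent_rows),
        "occlusion": pd.DataFrame(occ_rows),
    }


SORT_KEYS = {
    "breaths": ["subject", "muscle", "state", "breath"],
    "indices": ["subject", "muscle", "state"],
    "spectra": ["subject", "muscle", "state"],
    "entropy": ["subject", "muscle", "state"],
    "occlusion": ["subject", "effort"],
}


def run_batch(input_dir: Path | str, output_dir: Path | str, config: RunConfig) -> dict:
    """Process every recording in ``input_dir``; write tables to ``output_dir``.

    Per-recording failures are logged and recorded in the manifest;
    processing continues.  Returns the manifest dict (``n_failed`` > 0
    signals partial failure).
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    subjects = sorted(f.name[: -len("_states.txt")] for f in input_dir.glob("*_states.txt"))
    if not subjects:
        raise ValueError(f"no recordings found in {input_dir}")
    output_dir.mkdir(parents=True, exist_ok=True)

    tables: dict[str, list[pd.DataFrame]] = {k: [] for k in SORT_KEYS}
    status = []
    for subject in subjects:
        try:
            rec = read_recording(input_dir, subject=subject)
            result = analyse_recording(rec, config)
            for k, df in result.items():
                tables[k].append(df)
            status.append({"subject": subject, "ok": True, "error": ""})
        except Exception as exc:  # noqa: BLE001 - batch must continue
            log.warning("recording %s failed: %s", subject, exc)
            status.append({"subject": subject, "ok": False, "error": str(exc)})

    for name, parts in tables.items():
        df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
        if len(df):
            df = df.sort_values(SORT_KEYS[name], kind="stable").reset_index(drop=True)
        df.to_csv(output_dir / f"{name}.csv", index=False, na_rep="NA")

    cfg = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "version": respmech.__version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(cfg.encode()).hexdigest(),
        "recordings": status,
        "n_failed": sum(not s["ok"] for s in status),
        "n_warnings": sum(not s["ok"] for s in status),
    }
    (output_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest
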