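"""Reading and writing recordings, state annotations, and result tables.

A recording on disk is a directory of plain-text files:

* ``<subject>_<channel>.txt`` — two whitespace- or comma-delimited columns
  (time in seconds, amplitude), one file per channel, with an optional
  single header line.  EMG channels are in microvolts, pressure in cmH2O.
  Channels may be sampled at different rates (e.g. EMG at 20 kHz,
  oesophageal pressure at 1 kHz).
* ``<subject>_states.txt`` — one behavioural-state interval per line:
  ``state,start_s,end_s``.
* ``<subject>_meta.json`` (optional) — subject metadata (id, genotype,
  age_months).

Sampling rates are inferred from the median inter-sample interval;
irregular sampling (any interval deviating from the median by more than
1%) is rejected.  Non-finite samples are kept but flagged at read time —
removing them is an explicit cleaning step downstream, not an I/O side
effect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EMG_LABELS = ("dia", "eic", "ps")
PRESSURE_LABEL = "pressure"
KNOWN_UNITS = {"dia": "uV", "eic": "uV", "ps": "uV", "pressure": "cmH2O"}

#: Relative tolerance on inter-sample spacing before a file is declared
#: irregularly sampled.
MAX_INTERVAL_DEVIATION = 0.01


class State(str, Enum):
    """Behavioural / experimental states of a recording."""

    BASELINE = "baseline"
    POST_VAGOTOMY = "post_vagotomy"
    HCHX = "hchx"
    OCCLUSION = "occlusion"


@dataclass
class SampledSignal:
    """One uniformly sampled channel of physiological data.

    Parameters
    ----------
    samples
        Amplitude values (microvolts for EMG, cmH2O for pressure).
    rate
        Sampling frequency in Hz; must be positive.
    label
        Channel name (``dia``, ``eic``, ``ps`` or ``pressure``).
    units
        Amplitude units string.
    t0
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    rate: float
    label: str = ""
    units: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n_nonfinite(self) -> int:
        """Number of NaN/inf samples (flagged, never silently dropped)."""
        return int(np.sum(~np.isfinite(self.samples)))

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    def segment(self, start: float, end: float) -> "SampledSignal":
        """Return the sub-signal covering ``[start, end)`` seconds."""
        i0 = max(0, int(np.ceil((start - self.t0) * self.rate - 1e-9)))
        i1 = min(self.samples.size, int(np.floor((end - self.t0) * self.rate + 1e-9)))
        if i1 <= i0:
            raise ValueError("empty segment")
        return SampledSignal(
            self.samples[i0:i1], self.rate, self.label, self.units, self.t0 + i0 / self.rate
        )


@dataclass(frozen=True)
class StateInterval:
    """A labelled behavioural-state interval ``[start_time, end_time]``."""

    state: State
    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_time < self.end_time):
            raise ValueError("require 0 <= start_time < end_time")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class Recording:
    """A set of channels plus labelled state intervals and subject metadata."""

    channels: dict[str, SampledSignal]
    states: list[StateInterval] = field(default_factory=list)
    subject_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ivs = sorted(self.states, key=lambda s: s.start_time)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_time < a.end_time - 1e-12:
                raise ValueError(
                    f"state intervals overlap: {a.state.value} and {b.state.value}"
                )
        for iv in self.states:
            for sig in self.channels.values():
                if iv.end_time > sig.t0 + sig.duration + 1e-9:
                    raise ValueError(
                        f"interval {iv.state.value} extends past channel {sig.label!r}"
                    )

    def interval(self, state: State) -> StateInterval:
        for iv in self.states:
            if iv.state == state:
                return iv
        raise KeyError(f"no interval for state {state.value}")

    @property
    def subject(self) -> str:
        return str(self.subject_meta.get("id", ""))


def _load_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a delimited (time, amplitude) file, skipping a non-numeric header."""
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    try:
        float(first.replace(",", " ").split()[0])
        skip = 0
    except (ValueError, IndexError):
        skip = 1
    data = np.loadtxt(path, delimiter=delimiter, skiprows=skip, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path.name}: expected two columns, got {data.shape[1]}")
    return data[:, 0], data[:, 1]


def read_signal(path: Path | str, label: str = "", units: str = "") -> SampledSignal:
    """Read one channel from a two-column (time, amplitude) text file.

    The sampling rate is inferred from the median inter-sample interval;
    integer rates are snapped exactly.  Raises on a non-monotone time
    column or irregular sampling.
    """
    path = Path(path)
    t, x = _load_two_column(path)
    if t.size < 2:
        raise ValueError(f"{path.name}: need at least 2 samples to infer rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"{path.name}: non-monotone time column at row {row}")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > MAX_INTERVAL_DEVIATION * med:
        raise ValueError(f"{path.name}: irregular sampling (interval deviation > 1%)")
    rate = 1.0 / med
    if abs(rate - round(rate)) < 1e-6 * rate:
        rate = float(round(rate))
    return SampledSignal(x, rate, label=label, units=units, t0=float(t[0]))


def _read_states(path: Path) -> list[StateInterval]:
    intervals = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("state"):
            continue
        name, start, end = [f.strip() for f in line.replace("\t", ",").split(",")]
        intervals.append(StateInterval(State(name), float(start), float(end)))
    return intervals


def read_recording(
    path: Path | str,
    subject: str | None = None,
    channels: Sequence[str] = EMG_LABELS + (PRESSURE_LABEL,),
) -> Recording:
    """Read a recording from a directory of per-channel text files.

    Missing channels produce a warning and a partial :class:`Recording`;
    a missing state annotation file is an error only if no channel file
    exists either.
    """
    path = Path(path)
    if subject is None:
        hits = sorted(path.glob("*_states.txt"))
        if not hits:
            raise FileNotFoundError(f"no *_states.txt annotation in {path}")
        subject = hits[0].name[: -len("_states.txt")]
    loaded: dict[str, SampledSignal] = {}
    for label in channels:
        f = path / f"{subject}_{label}.txt"
        if not f.exists():
            warnings.warn(f"channel file missing: {f.name}; returning partial recording")
            continue
        loaded[label] = read_signal(f, label=label, units=KNOWN_UNITS.get(label, ""))
    if not loaded:
        raise FileNotFoundError(f"no channel files for subject {subject!r} in {path}")
    states_file = path / f"{subject}_states.txt"
    states = _read_states(states_file) if states_file.exists() else []
    meta_file = path / f"{subject}_meta.json"
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    meta.setdefault("id", subject)
    return Recording(loaded, states, meta)


def write_recording(recording: Recording, path: Path | str) -> None:
    """Write a recording in the same per-channel text layout `read_recording` reads.

    Amplitudes and times are written with 17 significant digits so the
    read/write round trip is exact for float64 data.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    subject = recording.subject or "subject"
    for label, sig in recording.channels.items():
        out = np.column_stack([sig.times(), sig.samples])
        np.savetxt(path / f"{subject}_{label}.txt", out, fmt="%.17g", delimiter=",")
    lines = [
        f"{iv.state.value},{iv.start_time:.17g},{iv.end_time:.17g}"
        for iv in recording.states
    ]
    (path / f"{subject}_states.txt").write_text("\n".join(lines) + "\n")
    (path / f"{subject}_meta.json").write_text(
        json.dumps(recording.subject_meta, indent=2, sort_keys=True) + "\n"
    )


SUMMARY_KEY = ["subject", "muscle", "state", "metric"]
SUMMARY_COLUMNS = ["subject", "genotype", "age_months", "muscle", "state", "metric", "value"]


def write_summary_table(records: Sequence[Mapping], path: Path | str) -> pd.DataFrame:
    """Write result rows as a long-format CSV with a deterministic row order.

    Rows are sorted by (subject, muscle, state, metric); NaN values are
    serialised as ``NA`` and the row is retained.  Writing the same rows
    twice yields byte-identical files.
    """
    df = pd.DataFrame(list(records), columns=SUMMARY_COLUMNS)
    if len(df):
        df = df.sort_values(SUMMARY_KEY, kind="stable").reset_index(drop=True)
    df.to_csv(path, index=False, na_rep="NA")
    return df
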