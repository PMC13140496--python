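"""Neuromuscular and neuromechanical indices: NRD, NME, TTI, drive rates.

* **NRD** (neural respiratory drive, %): per-breath peak of the
  rectified-integrated EMG envelope as a percentage of the reference
  maximum EMG — the mean envelope peak over the five consecutive peak
  efforts of the sustained tracheal occlusion with the largest mean.
  Because numerator and reference share any amplitude scaling, NRD is
  invariant to uniform gain changes of the EMG channel.
* **NME** (neuromechanical efficiency, cmH2O per uV*s): the breath's
  inspiratory pressure deflection magnitude divided by its EMG
  time-integral.
* **TTI** (tension-time index, dimensionless):
  (P / MIP) x (Ti / Ttot), where MIP is the single largest inspiratory
  deflection magnitude during occlusion.
* **IDR / EMG rise slope**: onset-to-peak endpoint slopes of the
  pressure deflection and EMG envelope respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from respmech.breaths import Breath

N_PEAK_EFFORTS = 5


@dataclass
class MaxReference:
    """Reference maxima from the sustained occlusion.

    ``emg_max`` is the five-consecutive-effort mean envelope peak (per
    muscle); ``mip`` is the single largest inspiratory deflection
    magnitude.  ``few_efforts`` flags the fallback used when fewer than
    five efforts were available.
    """

    emg_max: float
    mip: float
    source: str = "occlusion"
    few_efforts: bool = False

    def __post_init__(self) -> None:
        if not self.emg_max > 0:
            raise ValueError("emg_max must be positive")
        if not self.mip > 0:
            raise ValueError("mip must be positive")


def compute_emg_max(peak_envelopes: "list[float] | list[Breath]") -> tuple[float, bool]:
    """Reference maximum EMG from occlusion efforts.

    Mean envelope peak over the 5-consecutive-effort window with the
    largest mean (earliest window on ties).  With fewer than 5 efforts,
    falls back to the mean of all efforts and sets the warning flag.
    Accepts either raw peak values or :class:`Breath` objects.
    """
    peaks = np.asarray(
        [b.peak_envelope if isinstance(b, Breath) else b for b in peak_envelopes],
        dtype=float,
    )
    if peaks.size == 0:
        raise ValueError("no occlusion efforts")
    if peaks.size < N_PEAK_EFFORTS:
        warnings.warn(
            f"only {peaks.size} occlusion efforts (< {N_PEAK_EFFORTS}); "
            "using mean of all efforts as EMG reference"
        )
        return float(np.mean(peaks)), True
    window_means = np.convolve(peaks, np.ones(N_PEAK_EFFORTS) / N_PEAK_EFFORTS, "valid")
    best = int(np.argmax(window_means))  # argmax -> earliest tie
    return float(window_means[best]), False


def nrd(peak_envelope: float, emg_max: float) -> float:
    """Neural respiratory drive: 100 x peak envelope / reference maximum (%)."""
    if emg_max <= 0:
        raise ValueError("emg_max must be positive")
    return 100.0 * peak_envelope / emg_max


def nme(pressure_amp: float, emg_integral: float) -> float:
    """Neuromechanical efficiency: pressure per unit integrated EMG.

    Returns NaN (silent muscle) when the EMG integral is zero.
    """
    if emg_integral < 0:
        raise ValueError("emg_integral must be non-negative")
    if emg_integral == 0:
        return float("nan")
    return pressure_amp / emg_integral


def tti(p: float, mip: float, ti: float, ttot: float) -> float:
    """Tension-time index: (p/mip) x (ti/ttot)."""
    if mip <= 0:
        raise ValueError("mip must be positive")
    if ttot <= 0:
        raise ValueError("ttot must be positive")
    if ti > ttot:
        raise ValueError("ti exceeds ttot")
    return (p / mip) * (ti / ttot)


#: Columns of the per-breath index table.
BREATH_INDEX_COLUMNS = [
    "subject",
    "genotype",
    "age_months",
    "muscle",
    "state",
    "breath",
    "nrd",
    "nme",
    "tti",
    "idr",
    "emg_rise",
    "ti",
    "ttot",
    "duty_cycle",
    "peak_envelope",
    "peak_pressure",
    "emg_integral",
]

#: Aggregated (median) per-state columns.
STATE_INDEX_COLUMNS = [
    "subject",
    "genotype",
    "age_months",
    "muscle",
    "state",
    "nrd",
    "nme",
    "tti",
    "idr",
    "emg_rise",
    "n_breaths",
]

NRD_FLAG_LIMIT = 120.0


def per_state_indices(
    breath_rows: pd.DataFrame, reference: MaxReference | dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-breath indices plus per-state median aggregates.

    ``breath_rows`` needs one row per (muscle, state, breath) with
    columns ``peak_envelope``, ``peak_pressure``, ``emg_integral``,
    ``ti``, ``ttot``, ``idr``, ``emg_rise`` plus identifiers.
    ``reference`` is one :class:`MaxReference` (single-muscle input) or
    a muscle -> MaxReference mapping.  NRD values above 120% are
    flagged.  States with no breaths are simply absent; the last breath
    of each state (NaN Ttot) contributes no TTI.
    """
    refs = reference if isinstance(reference, dict) else None
    rows = breath_rows.copy()
    out_nrd, out_nme, out_tti = [], [], []
    for _, row in rows.iterrows():
        ref = refs[row["muscle"]] if refs is not None else reference
        out_nrd.append(nrd(row["peak_envelope"], ref.emg_max))
        out_nme.append(nme(row["peak_pressure"], row["emg_integral"]))
        if np.isfinite(row["ttot"]) and row["ti"] <= row["ttot"]:
            out_tti.append(tti(row["peak_pressure"], ref.mip, row["ti"], row["ttot"]))
        else:
            out_tti.append(float("nan"))
    rows["nrd"] = out_nrd
    rows["nme"] = out_nme
    rows["tti"] = out_tti
    rows["nrd_flag"] = rows["nrd"] > NRD_FLAG_LIMIT
    n_flagged = int(rows["nrd_flag"].sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} breaths with NRD > {NRD_FLAG_LIMIT}%")

    group_cols = [c for c in ("subject", "genotype", "age_months", "muscle", "state") if c in rows]
    agg = (
        rows.groupby(group_cols, sort=True, dropna=False)
        .agg(
            nrd=("nrd", "median"),
            nme=("nme", "median"),
            tti=("tti", "median"),
            idr=("idr", "median"),
            emg_rise=("emg_rise", "median"),
            n_breaths=("nrd", "size"),
        )
        .reset_index()
    )
    return rows, agg
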