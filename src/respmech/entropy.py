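"""Shannon, approximate, and sample entropy of EMG signals.

Three complementary complexity measures are computed on the filtered
(not enveloped) myoelectric signal of each state interval:

* **Shannon entropy** quantifies amplitude-distribution complexity.
  Amplitudes are discretised to 3 decimal places and
  ``H = -sum p_i log2 p_i`` is taken over the empirical frequencies of
  the distinct discretised values, in bits.  Requires >= 50 samples.
* **Approximate entropy** (ApEn) with embedding dimension m = 2 and
  tolerance r = 0.25 x SD of the signal: ``Phi^m - Phi^{m+1}`` with
  Chebyshev template distance, self-matches included, counts normalised
  per template.  Requires >= 200 samples.
* **Sample entropy** (SampEn): ``-ln(A/B)`` where B and A count ordered
  pairs (i != j) of length-m and length-(m+1) templates within
  tolerance r; self-matches are excluded.  Both counts run over the
  first N - m template positions (Richman-Moorman convention) so every
  length-m template has a length-(m+1) extension, guaranteeing A <= B
  and hence SampEn >= 0.  Requires >= 200 samples and at least one
  (m+1)-match for a finite value.

Because r scales with the SD, ApEn and SampEn are invariant to affine
transforms of the signal; Shannon entropy is not (its discretisation
grid is absolute).

Cleaning (:func:`clean_for_entropy`) removes non-finite samples and the
least-squares linear trend.  A constant (zero-SD) signal is a degenerate
case: both regularity measures are defined as 0 with a flag rather than
an error, so batch result tables stay rectangular.

The implementations are vectorised but chunked, keeping memory bounded
at roughly ``CHUNK_ELEMS`` floats; they match a naive O(N^2) double loop
to within 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from respmech.io import SampledSignal

#: Cap on elements per broadcasted distance block (memory control).
CHUNK_ELEMS = 16_000_000


@dataclass(frozen=True)
class EntropyParams:
    """Entropy parameters: m, r as a fraction of SD, and validity gates."""

    m: int = 2
    r_frac: float = 0.25
    shannon_precision: int = 3
    min_len_shannon: int = 50
    min_len_apen_sampen: int = 200
    decimate_to_hz: float | None = 2000.0
    max_samples: int | None = 5000

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be positive")
        if self.shannon_precision < 0:
            raise ValueError("precision must be >= 0")


@dataclass
class EntropySummary:
    """Per-signal entropy results with validity flags and match counts."""

    shannon: float
    apen: float
    sampen: float
    n: int
    valid_flags: dict = field(default_factory=dict)
    A: int = 0
    B: int = 0
    degenerate: bool = False


def clean_for_entropy(signal: SampledSignal) -> SampledSignal:
    """Drop non-finite samples and remove the least-squares linear trend."""
    x = signal.samples[np.isfinite(signal.samples)]
    if x.size == 0:
        raise ValueError("all samples non-finite")
    if x.size >= 2:
        x = sps.detrend(x, type="linear")
    return SampledSignal(x, signal.rate, signal.label, signal.units, signal.t0)


def decimate_signal(signal: SampledSignal, target_hz: float) -> SampledSignal:
    """Anti-aliased decimation to approximately ``target_hz`` (no-op if lower)."""
    factor = int(round(signal.rate / target_hz))
    if factor <= 1:
        return signal
    y = sps.decimate(signal.samples, factor, zero_phase=True)
    return SampledSignal(y, signal.rate / factor, signal.label, signal.units, signal.t0)


def shannon_entropy(x: np.ndarray, precision: int = 3) -> float:
    """Shannon entropy (bits) of the amplitude distribution.

    Amplitudes are rounded to ``precision`` decimals; p_i is the
    empirical frequency of each distinct rounded value.
    """
    x = np.asarray(x, dtype=float)
    rounded = np.round(x, precision)
    # round() may emit -0.0; collapse it onto 0.0 so they count as one symbol
    rounded = rounded + 0.0
    _, counts = np.unique(rounded, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _templates(x: np.ndarray, m: int) -> np.ndarray:
    return sliding_window_view(np.asarray(x, dtype=float), m)


def _chebyshev_counts(T: np.ndarray, r: float) -> np.ndarray:
    """For each template, the number of templates (including itself)
    within Chebyshev distance r.  Chunked over rows to bound memory."""
    M, m = T.shape
    counts = np.empty(M, dtype=np.int64)
    chunk = max(1, int(CHUNK_ELEMS // (M * m)))
    for s in range(0, M, chunk):
        d = np.abs(T[s : s + chunk, None, :] - T[None, :, :]).max(axis=2)
        counts[s : s + chunk] = (d <= r).sum(axis=1)
    return counts


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Standard ApEn: Phi^m - Phi^{m+1}, self-matches included.

    ``r`` defaults to 0.25 x sample SD (ddof=1) of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.25 * float(np.std(x, ddof=1))
    if r <= 0:
        raise ValueError("tolerance r must be positive (constant signal?)")

    def phi(mm: int) -> float:
        T = _templates(x, mm)
        c = _chebyshev_counts(T, r) / T.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy_counts(
    x: np.ndarray, m: int = 2, r: float | None = None
) -> tuple[int, int]:
    """Ordered-pair match counts (A, B) for SampEn, self-matches excluded.

    Both counts run over template positions 1..N-m so A <= B by
    construction.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.25 * float(np.std(x, ddof=1))
    if r <= 0:
        raise ValueError("tolerance r must be positive (constant signal?)")
    n = x.size
    if n <= m + 1:
        raise ValueError("signal too short for the requested embedding")
    Tm1 = _templates(x, m + 1)  # (n-m, m+1); first m columns are the m-templates
    M = Tm1.shape[0]
    A = 0
    B = 0
    chunk = max(1, int(CHUNK_ELEMS // (M * (m + 1))))
    for s in range(0, M, chunk):
        diff = np.abs(Tm1[s : s + chunk, None, :] - Tm1[None, :, :])
        d_m = diff[:, :, :m].max(axis=2)
        d_m1 = np.maximum(d_m, diff[:, :, m])
        nrows = d_m.shape[0]
        # subtract the self-match on the diagonal of this block
        B += int((d_m <= r).sum()) - nrows
        A += int((d_m1 <= r).sum()) - nrows
    return A, B


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn = -ln(A/B); raises if no template matches exist (A or B = 0)."""
    A, B = sample_entropy_counts(x, m, r)
    if A == 0 or B == 0:
        raise ValueError("no template matches")
    return float(-np.log(A / B))


def entropy_summary(
    signal: SampledSignal, params: EntropyParams = EntropyParams()
) -> EntropySummary:
    """Clean a signal and compute all three entropies with validity gating.

    Signals shorter than the per-measure minimum lengths are flagged
    invalid (NaN value, no exception); a constant signal yields ApEn =
    SampEn = 0 with the ``degenerate`` flag.  When ``decimate_to_hz`` is
    set and the signal is faster, it is decimated first (the regularity
    measures are otherwise prohibitively quadratic at 20 kHz).
    """
    cleaned = clean_for_entropy(signal)
    if params.decimate_to_hz is not None and cleaned.rate > params.decimate_to_hz:
        cleaned = decimate_signal(cleaned, params.decimate_to_hz)
    x = cleaned.samples
    if params.max_samples is not None and x.size > params.max_samples:
        # analyse the central window: representative and quadratic-cost bounded
        start = (x.size - params.max_samples) // 2
        x = x[start : start + params.max_samples]
    n = x.size
    flags = {"shannon": n >= params.min_len_shannon, "apen": False, "sampen": False}
    shannon = (
        shannon_entropy(x, params.shannon_precision) if flags["shannon"] else float("nan")
    )
    apen = sampen = float("nan")
    A = B = 0
    degenerate = False
    if n >= params.min_len_apen_sampen:
        sd = float(np.std(x, ddof=1))
        # detrending a constant signal leaves ~1e-16-scale numerical noise;
        # treat anything at machine-noise level of the raw amplitude as constant
        finite = signal.samples[np.isfinite(signal.samples)]
        noise_floor = 1e-12 * max(1.0, float(np.max(np.abs(finite))))
        if sd <= noise_floor:
            apen = sampen = 0.0
            degenerate = True
            flags["apen"] = flags["sampen"] = True
        else:
            r = params.r_frac * sd
            apen = approximate_entropy(x, params.m, r)
            flags["apen"] = True
            A, B = sample_entropy_counts(x, params.m, r)
            if A > 0 and B > 0:
                sampen = float(-np.log(A / B))
                flags["sampen"] = True
            else:
                flags["sampen"] = False
                flags["sampen_reason"] = "no template matches"
    return EntropySummary(
        shannon=shannon,
        apen=apen,
        sampen=sampen,
        n=n,
        valid_flags=flags,
        A=A,
        B=B,
        degenerate=degenerate,
    )
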