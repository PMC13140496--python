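# Methods

`respmech` analyses multi-channel respiratory neuromuscular recordings:
EMG from obligatory inspiratory pump muscles (diaphragm `dia`, external
intercostal `eic`, parasternal intercostal `ps`, in µV at 20 kHz) and
oesophageal pressure (`pressure`, in cmH2O at 1 kHz, negative during
inspiration), annotated with behavioural-state intervals (baseline,
post-vagotomy, hypercapnic hypoxia, sustained tracheal occlusion).
This note documents the model assumptions, the parameters that matter,
and the numerical choices made where the design was genuinely open.

## Signal conditioning

Raw EMG passes through a 50 Hz notch (quality factor Q = 35, i.e.
1.4 Hz bandwidth) and a fourth-order Butterworth bandpass (30–1000 Hz;
the order names the low-pass prototype, so the discrete bandpass has
eight poles). Filters are designed in transfer-function form; stability
is verified by a pole-magnitude test (all poles strictly inside the
unit circle, tolerance 1 − 1e−9), and an unstable polynomial form falls
back to a second-order-section factorisation, flagged on the designed
filter. At 20 kHz the default design is stable in polynomial form;
an eighth-order prototype is not, and exercises the fallback.

Both filters are applied zero-phase (forward-backward). This preserves
burst onset timing — needed for rise-time and drive-rate slopes — at the
cost of doubling attenuation in dB, which the tests account for. The 30 Hz
high-pass edge exists to exclude ECG contamination; accordingly no ECG
template subtraction is attempted.

The "integrated EMG" trace is a full-wave rectified, centred
moving-average envelope. The window (default 50 ms) must resolve mouse
inspiratory bursts (~100–300 ms) while smoothing individual spikes; it
is configurable (`envelope.window`). Per-breath EMG activity is the
trapezoidal time-integral of the rectified filtered EMG over the breath
(µV·s), which scales linearly with signal gain.

## Breath segmentation

Efforts are detected on an analysis trace: the EMG envelope, or the
inspiratory pressure deflection magnitude (baseline median − pressure).
Baseline statistics come from the quietest decile of 200 ms windows,
ranked by RMS. The onset threshold is the baseline median plus
`threshold_k` (default 3) baseline SDs; offsets fire at a hysteresis
fraction (default 0.5) of the onset elevation. Bursts separated by less
than `min_separation` (50 ms) are merged, then bursts shorter than
`min_ti` (30 ms) discarded, in that order.

Three refinements, all scale-invariant, harden this rule against
failure modes observed on realistic signals:

* **SD floor** (`SD_FLOOR_FRAC` = 0.1 of the baseline median): for
  strictly positive envelope traces the quietest-decile SD can be a few
  percent of the baseline level itself, placing thresholds inside the
  noise floor. Inert for zero-median deflection traces.
* **Amplitude-aware onset floor** (`ONSET_RANGE_FRAC` = 0.05 of the
  99th-percentile elevation): a Q = 35 notch rings for hundreds of
  milliseconds and zero-phase filtering spreads each burst's 50 Hz
  content symmetrically in time, producing tails of roughly 2% of burst
  amplitude. At high burst SNR these tails top any purely
  baseline-derived threshold; a floor keyed to the trace's own
  amplitude scale rejects them while staying inert on burst-free
  traces.
* **Prominence gate** (`min_peak_k` = 8 baseline SDs) and a
  fraction-of-peak offset term (`OFFSET_PEAK_FRAC` = 0.1): reject slow
  noise excursions that outlast `min_ti` via the merge rule, and
  terminate bursts whose tails hover above the fixed hysteresis level.

Peak time is the trace argmax within the burst (earliest sample on
ties). Ti is onset-to-offset; Ttot is onset-to-next-onset (standard
respirometry; undefined for the last breath of a segment, which is
excluded from duty-cycle statistics); duty cycle is Ti/Ttot. Slopes
(inspiratory drive rate from pressure, EMG rise slope from the
envelope) are two-point endpoint slopes from onset to peak — because
onsets sit at the detection threshold a few percent up the burst, the
endpoint slope of an ideal half-sine burst reads ~2–3% below the
zero-crossing ideal.

Segmentation defaults to the pressure channel (present and informative
in every state, including occlusion); EMG-envelope mode is available
(`segment.channel`).

## Spectral parameters

One Welch PSD per muscle per state interval, on the filtered EMG:
Hamming windows of 2048 samples, 50% overlap, mean detrending per
segment, or a single window of the maximum available length for shorter
signals. Microvolts are converted to millivolts beforehand so powers
are in mV². Over the 30–1000 Hz band: mean frequency is the
power-weighted average Σf·P/ΣP; median frequency is the first bin where
the cumulative trapezoid reaches half the band total (bin-resolution,
no interpolation); maximum frequency is the PSD argmax (earliest bin on
ties); total power is the trapezoidal area under the PSD. An all-zero
band yields an invalid-flagged summary with zero total power.

## Entropy measures

Computed per muscle per state on the filtered (not enveloped) EMG,
after removing non-finite samples and the least-squares linear trend:

* **Shannon entropy** (bits): amplitudes rounded to 3 decimals,
  H = −Σ pᵢ log₂ pᵢ over the empirical frequencies of distinct rounded
  values; needs ≥ 50 samples. The discretisation grid is absolute, so
  H is *not* gain-invariant — by design, it measures amplitude
  distribution complexity.
* **Approximate entropy** (m = 2, r = 0.25 × SD, Chebyshev distance,
  self-matches included): Φᵐ − Φᵐ⁺¹; needs ≥ 200 samples.
* **Sample entropy**: −ln(A/B) with self-matches excluded; A and B
  count ordered template pairs of lengths m+1 and m over the first
  N − m positions (Richman–Moorman convention), so A ≤ B and
  SampEn ≥ 0 by construction. Zero matches yields an invalid flag, not
  an infinity.

SD is the sample standard deviation (ddof = 1) of the cleaned signal.
Because r scales with SD, ApEn and SampEn are invariant to affine
transforms of the signal. A constant signal (SD at the machine-noise
level left by detrending) returns 0 with a degenerate flag so batch
tables stay rectangular. Both implementations are vectorised but
chunked (bounded memory) and match naive O(N²) double-loop references
to 1e−9.

Cost control: the regularity measures are quadratic, so signals are
decimated (anti-aliased) to 2 kHz by default and the central 5000
samples analysed (`entropy.decimate_to_hz`, `entropy.max_samples`).
At 2 kHz the 30–1000 Hz myoelectric band is fully preserved.

## Neuromuscular indices

All reference maxima come from the sustained occlusion. The EMG
reference `emg_max` (per muscle) is the mean envelope peak over the
five-consecutive-effort window with the largest mean (earliest window
on ties; fewer than five efforts falls back to the mean of all efforts,
flagged). MIP is the single largest inspiratory deflection magnitude —
conventionally a single best effort, deliberately distinct from the
five-effort EMG mean.

* **NRD** (%) = 100 × per-breath envelope peak / `emg_max`. Numerator
  and reference share any channel gain, so NRD is invariant to uniform
  EMG amplitude scaling — the property that makes drive comparable
  across preparations with different raw EMG amplitudes. Values above
  120% are flagged. Occlusion-state NRD uses the same reference and is
  therefore near 100% by construction (a near-tautology, noted).
* **NME** (cmH2O/µV·s) = breath pressure deflection magnitude /
  breath EMG integral, per muscle. A zero integral (silent muscle)
  yields NaN, flagged.
* **TTI** (dimensionless) = (P/MIP) × (Ti/Ttot). The last breath of a
  segment (no Ttot) contributes no TTI. No fatigue-threshold
  classification is applied.

Per-state aggregation is the median (robust to occasional
mis-segmented breaths); per-breath rows are always emitted so any other
aggregate can be recomputed.

## Occlusion pressure–time analysis

Each occlusion effort contributes one (peak time, deflection magnitude)
point. The nadir is the maximum-magnitude effort. Task failure is the
first effort after the nadir where `k_consecutive` (default 2)
successive efforts all fall below `decline_frac` (default 0.9) of the
nadir magnitude — both are declared conventions, exposed as config,
since "decline" admits no unique quantification. If no such run exists
the last effort is used and flagged. The AUC is the trapezoid of the
effort points from the first effort through the failure effort
(cmH2O·s) — an envelope-of-points area, not the integral of the
continuous pressure trace.

## Synthetic recordings

The generator provides seeded, bit-reproducible recordings with exact
ground truth for every pipeline stage. Default conditions model an
anaesthetised mouse preparation: Ti 0.15 s, Ttot 0.5 s (120
breaths/min, duty cycle 0.3), 20 breaths per tidal state, burst
amplitudes 8/5/4 µV (dia/eic/ps), 2 µV of 50 Hz line noise, a 5 µV
biphasic ECG-like pulse train at 10 Hz (~600 bpm), and a 0.2 µV tonic
EMG floor.

EMG = half-sine burst envelope × band-limited (30–1000 Hz) Gaussian
noise normalised to unit mean absolute value. That normalisation makes
the rectified EMG track the envelope amplitude, so the noise-free burst
integral (2/π)·amp·Ti is an exact per-breath ground truth for the
integrated EMG. Hypercapnic hypoxia doubles burst amplitude and
shortens Ttot by 20% (a pure amplitude/timing change; no gas-exchange
model). A genotype scale factor multiplies the whole EMG, emulating the
reduced raw amplitude of dystrophic muscle that the NRD normalisation
must cancel.

Pressure deflections are half-sines of magnitude
`nme_gain` × (noise-free diaphragm integral), so the configured
neuromechanical gain (default 4 cmH2O/µV·s) is exactly recoverable;
sensor noise is low-pass Gaussian (30 Hz, σ = 0.05 cmH2O) — a
transducer chain does not produce sample-independent white noise. The
occlusion is a piecewise-linear effort schedule: escalation from 50% to
a peak at the configured failure-onset effort, then decline to 50%,
with EMG bursts scaled ×3 (maximal efforts) in proportion.

The ECG pulse is one sine cycle of 40 ms (25 Hz fundamental), i.e.
energy concentrated below the 30 Hz analysis floor, so the spectral
band limit demonstrably excludes it.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: motor-unit structure and recruitment
nonstationarity, cardiorespiratory coupling, breath-to-breath timing
variability, electrode movement artifacts, and genuine gas-exchange
dynamics during chemostimulation. Parameter-recovery results bound
algorithmic error, not biological variability.

## Batch pipeline

`run_batch` processes every recording in a directory and writes five
long-format CSVs (per-breath, per-state indices, spectra, entropy,
occlusion) plus a JSON manifest (config, config hash, version,
per-recording status). Row order is deterministic and column sets are
schema-stable regardless of which measures were invalid (invalid values
are `NA` with flags). Per-recording failures are logged and recorded;
processing continues. Group-level statistics (ANOVA etc.) are
deliberately out of scope — the tables are ready for any statistics
package.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the generator at the
default study conditions (20 breaths per state, 15 occlusion efforts)
for parameter recovery, and shorter recordings (4–10 breaths) for
structural and determinism checks; entropy oracle equivalence uses 20
random signals of n = 300 against pure-Python O(N²) references. These
sizes were chosen so every check completes in minutes on one CPU while
keeping ≥ 20 breaths per median where a tolerance is asserted.

## Known limitations

* The hysteresis/prominence segmentation assumes bursts well above the
  baseline floor; heavily fatigued or silent muscles may need
  `segment.threshold_k` or `min_peak_k` lowered.
* Shannon entropy at a fixed 3-decimal grid saturates for signals whose
  dynamic range is large relative to 0.001 of a unit; the precision is
  configurable.
* Median frequency is reported at bin resolution (~9.77 Hz at 20 kHz /
  2048); no interpolation between bins.
* Entropy decimation to 2 kHz is transparent for the 30–1000 Hz band
  but would alias content above 1 kHz if the bandpass is reconfigured
  wider.
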