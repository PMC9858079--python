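# Methods

This note records the models, parameter choices and numerical decisions
behind `ecgwave`, and what the synthetic-data experiments do and do not
demonstrate about real recordings.

## Synthetic ECG model

Each heartbeat is a sum of five Gaussian deflections (P, Q, R, S, T), in the
spirit of Gaussian-kernel ECG simulators, but without the dynamical system:
closed-form deflections give closed-form fiducials, which is the point — the
generator exists to provide exact ground truth for the delineator.

Default template (lead-II textbook scale, fs = 360 Hz):

| wave | amplitude (mV) | center rel. R (s) | σ (s) |
|------|----------------|-------------------|-------|
| P    | 0.25           | −0.22             | 0.020 |
| Q    | −0.15          | −0.040            | 0.008 |
| R    | 1.60           | 0                 | 0.012 |
| S    | −0.15          | 0.040             | 0.008 |
| T    | 0.30           | 0.28              | 0.040 |

The amplitudes sit at the midpoints of the standard clinical ranges
(P ≈ 0.25 mV, R the largest at 1.6 mV, T within 0.1–0.5 mV); Q/S are small
negative flanks, a common simulator convention. The T timing (center
0.28 s, σ 0.040 s) keeps the T offset inside half an RR interval at 72 bpm,
so the half-peak-to-peak trim rule provably retains the last T wave.

**Ground-truth onsets/offsets.** A deflection's onset (offset) is the
first (last) sample where its absolute value reaches 1% of its peak, and
each deflection is generated as exactly zero outside that support. This
makes the inter-wave baseline identically zero, so the zero-crossing
delineator's target coincides with the stored truth to within one sample.
With untruncated Gaussian tails this would not hold: the analytic zero
crossing between the P tail and the Q rise sits tens of milliseconds away
from any fixed-threshold definition, making "ground truth" ill-posed. The
QRS onset/offset truth is the Q deflection's support start and the S
deflection's support end.

**Rate scaling.** Beat timing intervals (centers and widths) are multiplied
by RR/RR_ref (RR_ref = 60/72 s), clipped to [0.35, 1.25]. This emulates the
physiological shortening of intra-beat intervals at high rates and is
*necessary*: with fixed timing, a T offset at +0.40 s cannot fit inside the
0.43 s RR interval of a 140 bpm rhythm. Amplitudes are not scaled.

**Record assembly.** Beats are placed at RR = 60/bpm s; the number of beats
is ⌊duration/RR⌋ and the first R is positioned so all beats fit completely
with equal zero-baseline margins. Optional Gaussian RR jitter (default
σ = 0) emulates sinus variability. Rates whose beats would overlap are
rejected rather than silently distorted. Noise is additive: a baseline
sinusoid (default 0.3 Hz), a power-line sinusoid (50 or 60 Hz) and seeded
white noise; `NoiseSpec.broadband_for_snr` sets the white-noise power for a
target SNR in dB relative to the record's RMS.

**Rhythm labels** follow the clinical rate rule: <60 bpm bradycardia,
60–100 bpm (inclusive) normal sinus rhythm, >100 bpm tachycardia.

## Preprocessing

* **Bandpass:** 4th-order Butterworth, 0.5–40 Hz, applied
  forward-backward. Zero-phase application preserves fiducial timing; its
  cost is that the composite magnitude is |H|², so the measured −3 dB point
  of the *applied* filter sits near 35.8 Hz while the designed corner is at
  40 Hz, and 50 Hz mains is attenuated by ≈18.6 dB (|H(50)|² with the
  4th-order design). The filter order is configurable.
* **Wavelet denoising:** nine-level db8 decomposition (symmetric padding
  for signals shorter than 2⁹). Soft thresholding of detail levels 1–2 with
  the universal threshold σ√(2 ln N), σ = MAD(d₁)/0.6745 — the standard
  VisuShrink recipe; the two finest levels carry ~75% of white-noise power
  at typical ECG sampling rates. The level-9 approximation (≲0.35 Hz at
  360 Hz) is zeroed for baseline-wander removal. Both behaviours can be
  switched off, in which case the transform round-trips to numerical
  tolerance. Note the baseline-zeroing step assumes the bandpass ran first;
  applied to a raw record it also removes genuine near-DC signal content.
* **Normalization** divides by max |x| (not min–max), deliberately: the
  zero baseline and the location of every zero crossing — which the
  delineator depends on — are invariant under positive scaling.
* **Trimming** keeps [r₀ − (r₁−r₀)//2, r_last + (r_last−r_prev)//2),
  integer floor division, clamped to the record.

The pipeline order is filter → denoise → normalize → trim; each stage is
exposed separately so other orders can be composed.

## Delineation

* **R peaks:** 5–15 Hz Butterworth (zero-phase) → five-point derivative
  (kernel [1, 2, 0, −2, −1]·fs/8) → squaring → 150 ms moving-window
  integral → adaptive dual threshold (running signal/noise peak estimates
  with 0.125/0.875 updates) → 200 ms refractory period. Detections are
  refined to the raw-signal argmax within ±100 ms, so indices land on the R
  apex. The chain is amplitude-scale invariant because all thresholds are
  data-driven.
* **P/T windows:** P = [R − 0.35·RR, R − 60 ms), T = (R + 80 ms,
  R + 0.6·RR], with RR the median R-R interval (1 s fallback for single
  beats). These spans cover the template timings across 40–180 bpm after
  rate scaling; both are configurable. Beats whose windows collapse at
  record edges are dropped and logged.
* **Zero crossings:** a crossing is an exact zero sample or a sign change
  between consecutive samples; the reported index is the far-side sample
  from the peak. The QRS onset takes the *last* crossing in [P_off, Q)
  regardless of scan direction (a forward scan for a "last" crossing is
  direction-independent); windows without crossings fall back to the inner
  boundary (Q−1 / S+1) with a warning.
* **Q/S:** local minima within 80 ms left/right of R. Beats violating the
  ordering P_on < P_peak < P_off ≤ QRS_on < Q < R < S < QRS_off ≤ T_on <
  T_peak < T_off are dropped, never repaired.

## Time-frequency representations

* **Spectrogram:** Hann window, length min(64, ⌈n/4⌉) rounded to even
  (floor 4), 75% overlap default, zero-padded to a 256-point DFT so short
  wave segments still get fine frequency sampling. One-sided density
  convention (non-DC/non-Nyquist bins doubled): Σ PSD·Δf·Δt reproduces
  Σx²/fs (verified to ≲1% for Hann at 50% overlap).
* **dB conversion:** 10·log₁₀(psd + 10⁻¹²), clipped exactly to ±120 dB.
  The 10⁻¹² power floor maps silence to −120 dB instead of −∞.
* **Irisgram:** θ = linspace(−π, π, T) with T the number of time columns;
  ρ = max(f)/3 + f, so the annulus inner radius ("pupil") is max(f)/3 and
  the outer radius 4·max(f)/3; X = ρ cos θ, Y = ρ sin θ as outer-product
  grids. One full revolution corresponds to the segment duration.
* **Scalogram:** Morlet mother wavelet (center frequency f_c = 0.8125 Hz·s),
  64 logarithmically spaced scales with pseudo-frequencies f = f_c·fs/a
  spanning the wave's band — P: 5–30 Hz, QRS: 8–50 Hz, T: 0.5–10 Hz (the
  nominal T band starts at 0 Hz, clamped away from DC since the scale
  diverges there). Bands are further clamped per segment: the upper edge to
  Nyquist, the lower edge so at least one wavelet period fits the segment
  (2·f_c·fs/n). Short T segments (~250 ms) therefore image ≈6–10 Hz in
  practice; the clamp is logged. The surface is |W| (coefficient
  magnitude).

## Imaging and evaluation

Images are 224 × 224 × 3 (the ImageNet-family input size) with a fixed
perceptually uniform colormap (viridis). dB surfaces are mapped over the
fixed [−120, 120] range so equal values always render to equal colors;
scalograms over their own [0, max] range. The irisgram is rasterized
top-down onto its annulus with nearest-neighbour sampling (background =
floor color); rectangular surfaces are color-mapped and bilinearly resized.
Everything is deterministic — byte-identical PNGs on re-runs.

Splits stratify by rhythm class only; beats from one record can land on
both sides, mirroring beat-level dataset accounting. This inflates
apparent accuracy when beats within a record are highly correlated — group
the split by record id externally if subject-level generalization matters.

The classifier is pluggable behind `model_spec`. The default is
standardized 24 × 24 grayscale pixel features into multinomial logistic
regression — deterministic, CPU-cheap, and sufficient to separate the rate
classes, whose wave segments differ systematically in duration and hence in
image structure; an MLP option is included and any fit/predict estimator
over flattened features can be substituted. Reported metrics: per-class
sensitivity and precision, overall accuracy (all exact rational arithmetic
on confusion counts, rounded to 1 decimal only for presentation), and
k-fold summaries as mean ± sample (n−1) standard deviation of macro
sensitivity, macro precision and accuracy. A class never predicted gets
precision 0 with an `undefined_precision` flag rather than NaN.

## Problem sizes

Tests and examples use 10-s records at 360 Hz (6–23 beats depending on
rate), ~70 beats per class for classification runs, and 1–2 s tones for
spectral checks; these sizes keep the full suite under a minute while every
rate regime (40/72/140 bpm) is exercised.

## What the synthetic experiments show — and don't

Passing the delineation suite means the windowed-search and zero-crossing
rules are implemented exactly: on a zero-baseline signal with isolated
waves they recover every fiducial to one sample. Real ECGs violate those
assumptions — waves overlap (P on T at high rates), baselines are not zero
after imperfect detrending, morphologies vary beat to beat, and noise is
not white — so the ±20 ms synthetic accuracy is an upper bound, not a
clinical claim. Likewise the 100% synthetic classification accuracy shows
the imaging/evaluation plumbing is sound and the rate classes are separable
by construction; it says nothing about discriminating rhythms on real
records, which differ in far subtler ways. No pathological morphologies
(atrial fibrillation, ectopy) and no multi-lead signals are modelled.

## Known limitations

* WFDB binary record I/O is not included; records enter as CSV or are
  generated synthetically.
* The decimated wavelet transform only (no stationary/undecimated variant).
* The adaptive R-peak thresholding is the classic recipe without search-back;
  at very low SNR (<5 dB) recall degrades before precision.
* The irisgram renderer is a top-down orthographic projection; no 3-D
  surface view or interactive inspection.
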