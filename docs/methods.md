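# Methods

## Alignment model

Two devices record the same cardiac electrical activity through different
leads. Let the reference `x` be an `m`-second sample at working rate `fs`
and the search `y` a sample spanning `m + 2·margin` seconds of the other
lead (default `margin = 30 s`). For every integer lag
`k ∈ [0, len(y) − len(x)]` — full-overlap positions only — we compute the
Pearson coefficient between `x` and `y[k : k+len(x)]` and estimate the lag
as the argmax, ties broken toward the smallest `k`. Restricting to full
overlap avoids the spurious edge maxima that zero-padded correlation
produces, and is exactly the range in which the construction guarantees
the true lag lies. The sync delay `|τ̂ − τ_true|` is the evaluation
metric.

Per-lag normalization (Pearson) is the default because plain inner
products favour high-energy windows regardless of shape; the unnormalized
`raw` mode is kept for parity with classic cross-correlation routines. The
fast path computes all lags with one FFT convolution plus sliding-window
sums (extended-precision cumulative sums keep the agreement with a naive
per-lag loop below 1e-10) and is pinned against that loop in the tests.

Preprocessing, in fixed order: (1) polyphase resampling to 250 Hz with a
Kaiser-windowed anti-aliasing low-pass — the 257→250 ratio is expressed
exactly as up 250 / down 257; (2) second-order Butterworth band-pass
2–10 Hz applied forward–backward, odd-reflection padding of 3× the
effective impulse-response length (≈ one period of the 2 Hz edge) at each
end, so the filter has exactly zero phase and cannot bias the lag;
(3) min–max normalization over the whole sample, which is invariant to
each lead's gain and offset.

An irreducible bias remains: when the two leads weight the P/QRS/T waves
differently, the correlation peak can sit a couple of samples off the true
alignment (≈ 8 ms at 250 Hz on the synthetic morphologies). This floor is
visible in every clean benchmark number.

## Dynamic signal-quality index

Beats are found by an energy detector (band-pass 5–15 Hz, derivative,
squaring, 150 ms moving integration, adaptive threshold at 30% of the
99th percentile, 200 ms refractory, peak refinement to the filtered-signal
maximum). Each beat window (R − 0.25 s to R + 0.45 s, covering P–QRS–T at
normal rates) is mapped to a discrete smoothed pseudo Wigner–Ville
distribution: analytic signal via Hilbert transform, instantaneous
autocorrelation `K[n, m] = z[n+m]·conj(z[n−m])` tapered in lag by a
Hamming window of length `2⌊0.03·fs⌋+1`, smoothed in time by a Hamming
window of length `2⌊0.01·fs⌋+1`, Fourier-transformed over lag (zero-padded
to 128 bins) and truncated to 0–40 Hz, keeping magnitudes. The windows
trade cross-term suppression against time–frequency resolution; the 40 Hz
cap covers where ECG energy lives.

Scoring is sliding: beat `k` is compared (zero-lag 2-D Pearson) against
the mean map of beats `k−3, k−2, k−1`; the first three beats have no
template and are unscored. Because the distribution is bilinear, a gain
change scales all maps by the squared gain and leaves Pearson scores
untouched. A beat is "good" at score ≥ 0.9 (configurable;
`sqi.good_beat_threshold`); the sample dSQI is the good fraction among
scored beats. The 0.9 cut-off is calibrated on this package's synthetic
records — clean regular records score exactly 1.0, −6 dB electrode-motion
records score well under 0.5 — and should be recalibrated for other
devices or settings, as template-matching SQIs generally must be.

## Synthetic data: what it emulates, what it does not

The generator emulates the study's input geometry: 257 Hz two-lead records
up to 30 minutes, beats shared sample-exactly between leads, per-lead
Gaussian-bump morphology (lead I with dominant R; V2 with deep S and tall
T — amplitudes differ, wave timings do not), AR(1) beat-to-beat RR jitter
(coefficient 0.8, SD 40 ms), optional premature beats with compensatory
pauses (default rate 0.05/beat, echoing an arrhythmia-rich population) and
an atrial-fibrillation mode (i.i.d. RR on [0.4, 1.2] s). Sample pairs cut
an `m`-second lead-I reference and a `(m+60)`-second lead-V2 window
starting 30 s earlier, 100 pairs per record, uniform starts, overlaps
allowed: the true lag is 30 s by construction.

Noise is synthesized rather than downloaded: baseline wander as three
random sinusoids in 0.05–0.5 Hz plus a low-passed random walk (≥ 95% of
power below 1 Hz); muscle artifact as 20–50 Hz noise with 0.5–2 s
burst-like amplitude modulation (≥ 90% of power above 15 Hz); electrode
motion as Poisson step transients (rate 0.2/s, exponential decay) plus
1–60 Hz bursts shaped to a 1/f amplitude spectrum, mirroring the steep
low-frequency roll-off of recorded electrode-motion noise. All noise is
unit-RMS and added at exact SNR, with power defined as the full-segment
variance of each signal (round-trip accurate to ≪ 0.01 dB). Note this
convention differs from QRS-amplitude-based signal-power conventions used
by some noise-stress tools; the same nominal SNR is "cleaner" here, so SNR
axes are comparable within this package but not across conventions.

What the generator does **not** reproduce — and hence what passing
benchmarks do and do not show: real beat-to-beat morphology variability,
respiration modulation, conduction abnormalities and nonstationary real
noise are absent, so absolute synthetic delays (milliseconds on clean
pairs) are far below those on clinical recordings. The benchmark asserts
*directions* — shorter samples worse, quality gating better, low SNR
worse with a pivot near 6 dB, sampling rate immaterial, cross-correlation
ahead of the DTW baseline — not clinical magnitudes. Because baseline
wander and muscle artifact lie almost entirely outside the 2–10 Hz
analysis band, they barely perturb alignment at any tested SNR; electrode
motion is the class that stresses the method, which is why the named noise
presets (mild = EM 6 dB, moderate = EM 0 dB, stress = EM −6 dB,
mixed = half 24 dB/half −6 dB) all use it.

## DTW baseline

The comparator replaces correlation with dynamic time warping on RR
series: beats are detected per lead, successive differences form the RR
sequence, both sequences are z-normalized (degenerate constant sequences
fall back to unnormalized cost with a warning), and an open-begin/open-end
subsequence DTW (Euclidean local cost; diagonal/vertical/horizontal steps;
endpoints free on the search side only) aligns the reference series inside
the search series. The warping path is collapsed to a scalar delay as the
median over path pairs of the matched-beat time offsets — robust to path
wander at the ends. Its resolution is bounded below by beat timing, and
stretches of unremarkable rhythm make the subsequence match ambiguous;
both effects show up as the large DTW delays in the method comparison.

## Experiments and statistics

The five experiments follow one template: build seeded sample pairs,
inject the preset's noise into both leads independently at the stated SNR,
preprocess, align, record sync delays in a tidy table keyed by the
factors. Grids default to durations 10–50 s step 10, dSQI thresholds 0–1
step 0.1, SNR {−6, 0, 6, 12, 18, 24} dB × {BW, EM, MA}, and rates
{150, 200, 250} Hz (identical pairs re-preprocessed per rate). The dSQI
used for filtering is computed on the resampled noisy search signal
*before* the 2–10 Hz alignment band-pass, which would otherwise erase the
0–40 Hz morphology the SPWVD template match needs. Statistics mirror the
evaluation design: one-way ANOVA with Tukey HSD for duration and rate,
Pearson correlation for threshold vs. mean delay, two-way ANOVA with
simple main effects and Tukey follow-up for noise, a two-sample t-test for
the method comparison; α = 0.05 throughout, and ANOVA assumptions are
applied as-is, not checked.

Benchmark problem sizes in the shipped tests and acceptance script —
100–200 pairs per cell from 600 s records (the sampling-design check uses
the full 75 × 30 min × 100-sample layout, 7500 pairs) — were chosen so a
full run completes in about a minute on one CPU while leaving every
directional test decisively powered.

## Numerical and degenerate-input choices

Timestamps are 64-bit seconds, sample indices 0-based, windows half-open.
Zero-variance search windows get `r = −inf` so they can never win the
argmax; a zero-variance reference is an error. Constant signals raise a
degenerate-signal error in normalization; empty or too-short inputs raise
explicit length errors before any filtering. Ties in the correlation curve
break to the smallest lag for determinism. Every generator and experiment
is a pure function of its seed (child seeds derive via `SeedSequence`), so
any table cell regenerates bit-identically.

## Known limitations

- No sub-sample lag interpolation; resolution is one sample at the
  working rate, plus the ~2-sample cross-lead morphology bias.
- No clock-drift estimation: a single constant offset is assumed over the
  sample, appropriate for 30–90 s windows only.
- The dSQI good-beat threshold and the SPWVD windows are calibration
  points, not universal constants.
- WFDB support covers format 16 single-segment records (the subset this
  package writes); annotations beyond an R-time CSV sidecar are out of
  scope.
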