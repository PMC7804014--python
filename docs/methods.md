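# Methods

This note documents the models implemented in `bluefin`, the parameter
choices that matter, what the synthetic scenes do and do not emulate, and
the numerical decisions taken where the underlying methodology is open.

## Annotation model and features

An annotation is a half-open time interval `[begin, end)` (seconds from file
start) with a frequency box `(f_low, f_high)` in Hz and one of eight
classification labels: `Bm-Ant-A`, `Bm-Ant-B`, `Bm-Ant-Z`, `Bm-D`,
`Bp-20Hz`, `Bp-20Plus`, `Bp-Downsweep`, `Unidentified`. Selection tables are
tab-separated with columns located by header name (`Begin Time (s)`,
`End Time (s)`, `Low Freq (Hz)`, `High Freq (Hz)`, plus a label column), so
column order never matters; numeric fields are written with a fixed `%.6f`
format to make write→read→write round trips byte-identical.

Features per annotation are energy percentiles of the spectrogram restricted
to the box: `t90` is the span between the 5th and 95th percentiles of
cumulative in-box energy over time, and `f5`/`f95` the corresponding
frequency percentiles, all found by linear interpolation on cumulative
marginals. With the detection frontend's 1.024 s frames, `t90` of a call
shorter than ~2 frames collapses towards zero — a resolution limit, not a
bug; use finer spectrogram parameters when features of sub-second calls
matter.

## The SNR statistic

For an annotation of duration `d`, the signal+noise level `Z_s+n` is the RMS
of the band-passed series over the annotation; noise is measured over two
windows of `d/2` s placed 1 s before and after the annotation (the buffer
absorbs loosely drawn boxes), concatenated. With `Z_n` the noise RMS and
`var_n` the variance of instantaneous power over those samples,

    SNR_dB = 20 * log10( (Z_s+n - Z_n)^2 / sqrt(var_n) ).

This statistic mixes amplitude and power conventions and is offset from a
conventional power-ratio SNR; it is implemented verbatim because it is the
form used for detector characterisation in this field, and all detectability
results are expressed on its scale. A conventional
`10*log10((P_s+n - P_n)/P_n)` is available as `conventional_snr` for
comparison but is never used on the characterisation path. Numerical
choices: the band-pass is a 4th-order zero-phase Butterworth (the
methodology band-limits but names no filter); noise statistics are computed
over the concatenated samples of both windows rather than per-window;
default bands are 17–29 Hz for blue song labels and 20–30 Hz for fin pulse
labels. Noise windows that would cross a file edge shrink symmetrically
with a warning; if no noise samples fit, the measurement is an error rather
than a guess. `var_n = 0` or `Z_s+n <= Z_n` yields an explicit undefined
flag, never a clamped value.

## Spectrogram frontend

Magnitude-squared STFT with a Hann window, 1.024 s window and 1.024 s hop
(no overlap) — at 250 Hz this is a 256-sample window with 0.977 Hz bins
(printed in configuration tables as 0.98 Hz). Detection uses no overlap;
high-overlap settings are display conventions only. Noise normalisation is
a per-bin decaying average: the running average is subtracted from each
slice *before* being updated towards it (`A_t = (1-α)A_{t-1} + α S_t`,
initialised to the first slice), so a transient call cannot instantly cancel
itself. The update/initialisation order of the original implementation is
undocumented; this recursion is normative here. Negative post-subtraction
values are kept for the correlation detector (signed contrast helps) and
clipped at zero inside the energy detector's squared sum (scores must be
non-negative).

## Detectors

**Frequency drift.** Antarctic blue whale song declines in frequency by
0.135 Hz per 365 days from 27.6659 Hz at 12 March 2002; per site-year the
unit-A frequency `f_a` is evaluated at 1 June of the nominal year.

**Z-call kernel.** Contour: 8 s at `f_a` (unit A), 2 s linear descent to
19.5 Hz (unit B), 2 s at 18.75 Hz (unit C, midpoint of its 18.5–19.0 Hz
band), 12 s total. The per-slice cross-section is a Ricker
(second-derivative-of-Gaussian) ridge of width σ = 1 Hz with the slice mean
removed, so every slice sums to zero and flat spectrogram regions score ~0.
The kernel profile is not specified by the methodology; the Ricker family is
the canonical spectrogram-correlation choice and satisfies the zero-mean
requirement by construction.

**Scores.** Correlation score at lag τ is the full pixel-wise sum of
kernel × spectrogram with the kernel starting at slice τ. Energy score per
slice is the sum of squared (clipped) normalised values over 15–30 Hz.
Correlation operates on linear normalised power, not dB (undocumented in the
original; linear chosen).

**Score units.** Recognition-score units are arbitrary, so the threshold
sweeps (20…10240 for correlation, 0.5…64 for energy) are meaningful only
relative to a score scale. The pipelines therefore normalise by a robust
noise scale: the MAD-based σ of the normalised spectrogram over the
detection band. The energy pipeline additionally divides by
`2*sqrt(n_band_bins)`, putting the quiescent score near 0.125. These
constants were fixed once, at design time, so that the configured sweeps
span the operating range on synthetic scenes — from noise-floor triggering
at the lowest thresholds to only the strongest calls at the highest.

**Trigger logic.** A maximal run of consecutive supra-threshold samples
whose duration lies within `[min_over, max_over]` (no upper bound for the
correlation detector) raises one detection; its boundaries span the mean
annotation duration d̄ (defaults: 13 s for pooled blue song, 2.5 s for
pooled fin pulses; both overridable from data via `mean_duration`), centred
on the run. Whether the original implementation centred boundaries on the
trigger or started at it is unstated; centring is used. After each
detection, no new detection may begin until `max(min_gap, d̄)` after its
start — the refractory period that absorbs multipath — which also
guarantees detections never overlap. Fin detector gap is 1 s per its
configuration table. Note one subtlety: raising the threshold cannot
increase the detection count for short isolated peaks, but a long run can be
*split* by a higher threshold (or shortened past `max_over` by a lower one),
so strict count monotonicity is a property of call-like score series, not of
arbitrary ones; it holds on all scenes the generator produces.

## Evaluation

Matching is greedy in ascending trigger order with the any-overlap
criterion; the first detection to overlap an unclaimed annotation claims it
(earliest-beginning annotation first), later detections overlapping only
claimed annotations are duplicates, counted in neither TP nor FP. Because
detections cannot overlap, a recording of duration T holds `floor(T/Δ)`
detection slots (Δ = effective detection period, default d̄); negatives are
those slots minus `ceil(total annotated time / Δ)`, FPR = FP/negatives,
TPR = recall = TP/annotations, TN = negatives − FP. The exact composition of
the negative denominator is not fully specified by the methodology; this
formula is documented and Δ is one configurable scalar per detector. At
Δ = 2.5 s a 1% FPR is ~14.4 false alarms per hour; at 13 s, ~2.8. Pooling:
the blue detector is evaluated against Bm-Ant-A/B/Z together, the fin
detector against Bp-20Hz/Bp-20Plus together (callers filter annotations to
the pooled set before matching).

## Synthetic scenes

The generator emulates the *statistical content* of the annotated library:
tonal song units as linear-FM chirps with 0.2 s raised-cosine edge tapers
(avoiding spectral splatter), a fin pulse as a 1 s 23→17 Hz sweep, optional
~95 Hz secondary components at −10 dB, Gaussian background noise with a
−1 dB/octave spectral slope (capped below 0.5 Hz), and a 20–30 Hz chorus
band at −3 dB relative to the broadband RMS — chorus level and echo delays
are not quantified by the source methodology, so these defaults are
configuration, not claims about real data. Per-event amplitudes are
calibrated closed-loop against the local background (analytic
power-additivity initial guess, then render–measure–rescale on the SNR
statistic, tolerance 0.25 dB), because the statistic's squared-difference
form makes one-shot analytic inversion unreliable. Echoes are delayed,
attenuated copies added to the audio but never to the truth. Duty cycles
keep the first `recorded` seconds of each cycle, concatenate the recorded
windows into a compressed timeline, clip straddling truth records at window
edges and drop records wholly inside gaps (with a warning). Scenes are
bit-reproducible from their seed.

What the scenes do **not** emulate: propagation and multipath physics
beyond fixed echoes, instrument self-noise and frequency response, ice
noise, call-to-call variability within a classification, analyst
variability in box placement, and diel/seasonal call-rate structure.
Passing tests on these scenes demonstrate the pipeline's correctness and
internal consistency, not field performance; site-specific ROC/PR/SNR
results on real recordings are outside what desk-scale synthesis can
reproduce.

## Subsampling design

Chunks (default 1 h; 5/10/25-minute duty variants model the exceptional
site-years) are sampled systematically: every `t_s`-th chunk from a random
start in `[1, t_s]`. The spacing rule — the exact formula is not printed in
the source methodology, so this rule is normative for this artifact — takes
the largest `t_s` fitting about the target number of chunks (floor 150,
target ~200), then, for hourly chunks, decreases it until coprime with 24:
any shared factor with 24 confines visits to a strict subset of clock
hours, while a coprime spacing cycles through all 24, giving the 5–10
visits per clock hour that a ~200-chunk year-long sample implies.

## Detectability vs SNR

Outcomes (per annotation: measured SNR, detected 0/1 at a chosen threshold)
are fitted per site with a binomial GAM: logit link, penalized cubic
B-spline smooth of SNR with basis dimension 10. The penalty weight is
chosen on a deterministic log-spaced grid (10⁻¹…10⁶) by AIC
(deviance + 2·edf — the UBRE/GCV-family criterion for a binomial family
with known scale). Confidence bands use the Bayesian posterior covariance
of the penalized fit, `(XᵀWX + λS)⁻¹`, the standard construction for
penalized regression splines with good across-the-function coverage;
intervals are formed on the link scale and mapped through the inverse
logit, then clipped into the open unit interval so saturated fits stay in
(0, 1). Spline knots extend 5 dB beyond the observed SNR range, and curve
evaluation is refused further out. Sites where every annotation was
detected (or none) leave a logistic smooth unidentifiable; by default such
sites get a flagged constant-probability model with a Jeffreys binomial
interval, or can be made a hard error (`on_degenerate="raise"`).

## Problem sizes in the test suite

The suite exercises the pipeline at desk scale: scenes of 10–20 minutes at
250 Hz with 8–30 calls, 2000-outcome GAM recovery simulations, and an
8760-chunk synthetic year for the subsampling properties. The full suite
runs in a few seconds on one CPU.

## Known limitations

- Score units (and hence which printed thresholds are "interesting") depend
  on the robust-scale normalisation; detectors run through other frontends
  will need their own sweep calibration.
- The SNR statistic is undefined when the annotation level does not exceed
  the flanking noise level; weak calls in strong chorus can therefore have
  no SNR and are excluded from detectability fits.
- Greedy any-overlap matching is order-stable but not globally optimal;
  with d̄-wide detections and dense calls, assignment differences against
  an optimal matcher are possible in principle.
- `t90` is not robust to analysts' (or templates') generous time bounds at
  the frontend's 1 s resolution.
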