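# Methods

## The model

`remcycle` models the ultradian timing of REM sleep in mice through the
relationship between the duration of a REM episode, `REM_pre`, and the total
amount of NREM sleep, `|N|`, in the following inter-REM interval.  A *sleep
cycle* is one REM episode plus the inter-REM interval that follows it; the
interval decomposes into `|N|` (NREM time, microarousals included) and `|W|`
(wake time).  All durations live on a fixed 2.5 s epoch grid.

Within each 30 s bin of `REM_pre` below 240 s, `ln|N|` is fit as a
two-component Gaussian mixture

    P(ln|N|) = k_short N(mu_short, sigma_short^2) + k_long N(mu_long, sigma_long^2)

by maximum likelihood (EM).  The component with the larger mean is "long";
bins with `REM_pre >= 150 s` are treated as unimodal (`k_long = 1`, single
Gaussian fit).  Each of the five parameters is then modelled as a function
of `REM_pre = x` by whichever of

    linear       y = a x + b
    logarithmic  y = a ln(x + b) + c,  b >= 0

achieves the lower residual sum of squares (bounded trust-region least
squares for the logarithmic kind, multi-started from b in {0, 1, 10, 100});
the weight curve is clamped, `k_long(x) = min(a ln(x+b) + c, 1)`, and is fit
on the first six bin values only, because it is identically 1 beyond the
unimodality threshold.  The assembled conditional model exposes the mixture
pdf, the cdf

    F(N | x) = k_long(x) Phi((ln N - mu_long(x)) / sigma_long(x))
             + k_short(x) Phi((ln N - mu_short(x)) / sigma_short(x))

(the *REM propensity* accumulated after `N` seconds of NREM), sampling, and
its domain minimum: the smallest grid `REM_pre` at which the two weighted
component densities intersect strictly between their means.  Below that
value the sequential/single taxonomy is undefined.

Derived quantities:

- **Sequential vs single cycles.**  A cycle is sequential when `ln|N|` falls
  below the between-means intersection of the weighted component densities
  at its `REM_pre` — equivalently, when the weighted short density exceeds
  the weighted long one.  If the closed-form quadratic has no root between
  the means (possible under extrapolated curves), the density-comparison
  rule is applied directly.
- **Refractory period.**  For single cycles, NREM time up to the 1st
  percentile of the long component, `exp(mu_long + sigma_long z_0.01)`,
  is refractory; the remainder of the interval is permissive.  Wake epochs
  accumulate into neither period but do not reset the accumulator.
- **Goodness of fit.**  Because the mixture parameters are estimated from
  the tested sample, the per-bin KS test is Monte-Carlo corrected
  (Lilliefors): replicate samples are drawn from the fitted mixture, the
  mixture is re-estimated on each replicate, and the observed statistic is
  referred to the simulated distribution (reject when it exceeds the 95th
  percentile).  A `refit=False` switch skips the re-estimation and yields
  the conservative parameters-known null instead.

## EEG analyses

Spectral densities use Welch's method: 3 s Hann windows with 50% overlap
(1/3 Hz resolution at 1 kHz), constant-detrended, pooled across all windows
of all segments.  Band powers are midpoint Riemann sums over cells whose
midpoints fall in the half-open band `[lo, hi)`; the analysis bands are
delta 0.5–4.5 Hz, theta 5–9.5 Hz, sigma 10–15 Hz.  These are deliberately
distinct from the staging bands (below) and from the spindle detection band
(10–16.67 Hz); each set is a named constant.

**Spindle detection** runs on a 600 ms / 100 ms-step spectrogram of the
prefrontal EEG.  A bin is a candidate when (1) its largest local spectral
maximum in 10–16.67 Hz exceeds the recording-wide 96th percentile of such
peaks and (2) that peak exceeds half the 0–10 Hz maximum.  Candidate runs
are merged, runs separated by gaps under 300 ms are fused, events lasting
at most 200 ms are discarded, and an event is kept only if its per-bin peak
frequency lies in the sigma range for at least half of its bins.  The
per-bin peak frequency is the dominant peak *within the detector's 0–16.67
Hz range*: under a whole-spectrum reading the majority rule would reject
every event whenever delta power tops the spectrum — which is nearly always
true in NREM — so that reading would make the rule self-defeating.
Detection is restricted to NREM (incl. MA) epochs by default, since spindle
rates are reported per minute of NREM; a flag enables whole-recording
detection.  Because the analysis window is six times the hop, a strong
burst briefer than the window still flags several consecutive bins; the
duration rule therefore discriminates short events sharply only at
moderate SNR.

**Automatic staging** computes spectrogram band powers in 5 s
half-overlapping windows (delta 0.5–4, theta 5–12, sigma 12–20, high gamma
100–150, EMG 50–500 Hz) and classifies each 2.5 s bin by threshold rules:
each band is split at its temporal mean (mean + 1 sd for EMG and the
theta/delta ratio).  REM requires high theta/delta, low EMG and low delta;
NREM requires high delta with low theta/delta and low EMG, or low EMG and
low delta with high sigma; wake covers low delta with high EMG plus a
high-gamma override applied after the REM check.  Rule order is REM, gamma
override, NREM, wake; unmatched bins inherit the previous label (the first
defaults to wake).  Thresholds are data-relative, so classification is
invariant to rescaling all channels by a positive constant; a tiny relative
epsilon on each threshold keeps constant feature columns from being split
by floating-point error.  Wake runs of at most 20 s (configurable) are then
relabelled as microarousals.

## Numerical choices

- EM is a batched 1-D implementation: many independent samples (and all
  restarts of each) advance through the E/M steps as one ndarray
  computation, which is what makes 200 × 200 Monte-Carlo refits and
  bootstrap loops affordable on one CPU.  Initialisation is a hard split of
  the sorted sample — the median first, then random interior quantiles (20
  restarts for data fits, 10 for Monte-Carlo refits); tolerance 1e-8 on the
  log-likelihood; variance floor 1e-6 against component collapse; "long"
  is re-assigned to the larger mean after fitting (label-switching guard).
  A sample with (near-)zero variance raises an error.
- Curve fits use the bin midpoint as the x-coordinate.  A failed
  logarithmic fit falls back to linear with a warning.
- `k_long` is clamped to [0, 1] at evaluation (the printed model clamps
  only the top; the bottom clamp keeps the weight a probability);
  evaluated sigmas are floored at 1e-3.
- Evaluating the curves beyond the fitted range (`REM_pre > 240 s`) warns
  but proceeds.
- The refractory quantile uses the standard normal quantile routine, never
  a hard-coded z value.

## The synthetic ground truth

The generator emulates the statistical structure the analysis assumes:
REM episode durations follow a near-exponential truncated gamma (shape 1.3,
scale 65 s, range 2.5–240 s; mean ≈ 85 s), which also populates all eight
30 s bins densely enough for stable per-bin estimation.  Given `REM_pre`,
the component is Bernoulli in `k_long(REM_pre)` and `ln|N|` Gaussian within
the component.  The fixture curves are anchored to the reported magnitudes
of the light-phase model: short mode near ln(85 s) and drifting slowly
down, long mode rising ln(420 s) → ln(1100 s), `k_long` from ≈ 0.6 at the
first bin to 1 at 150 s, `sigma_long` from ≈ 0.7 to ≈ 0.35.  Under these
defaults roughly 20% of generated cycles are sequential and the refractory
threshold is 2.2–2.9 × `REM_pre` over mid-range durations.  Wake episodes
(zero-inflated geometric count; lognormal durations truncated above the MA
threshold) are inserted at uniform positions in the interval;
microarousal bouts are carved out of interior NREM runs so they always
count into `|N|`.  Signals are sums of band-limited Gaussian noise scaled
by per-state amplitude templates (NREM delta-dominated, REM
theta-dominated with silent EMG, wake EMG/gamma-dominated), with
Hann-enveloped 10–15.5 Hz wave packets (0.5–1.5 s) injected into NREM at
2 per minute as annotated spindles.

What the generator does *not* emulate: 1/f spectral backgrounds and
artifacts, gradual state transitions, circadian drift, animal-to-animal
heterogeneity, and any dependence of `REM_post` on accumulated propensity
(episode durations are drawn i.i.d.).  Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions, not
staging or detection performance on real recordings.

## Known limitations

- The two-stage procedure (per-bin EM, then curve fits at bin midpoints)
  extrapolates the fitted log curves below the first bin midpoint (15 s)
  down to the domain minimum.  That extrapolation amplifies per-bin
  sampling noise roughly three-fold, so sup-norm recovery of `mu_long` and
  `k_long` near the domain floor is noticeably seed-dependent at 5,000
  cycles; the seeded closure checks in the test-suite document the scale of
  this effect.  Interior recovery (between the first and last midpoints) is
  much tighter.
- With only one ln|N| value per cycle and 30 s bins, within-bin curvature
  of the parameter curves is absorbed into the bin estimate; the midpoint
  convention is unbiased only for gently curved parameter functions.
- The Lilliefors correction re-estimates parameters per replicate with
  fewer EM restarts (10) than the data fit (20); with the strong component
  separation typical of these data the restart count does not measurably
  change the null calibration.
- Bootstrap comparisons resample cycles, not recordings; dependence between
  cycles of one animal is outside the synthetic model.
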