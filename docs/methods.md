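# Methods

`fetalbiom` estimates fetal biometrics — head circumference (HC),
biparietal diameter (BPD), abdominal circumference (AC), femur length (FL)
and transcerebellar diameter (TCD) — by aggregating automatic per-frame
measurements across an entire 20-week ultrasound examination instead of
relying on a handful of operator-selected frames. This note records the
model, the numerical choices, and what the synthetic test world does and
does not establish.

## Measurement model

Per-frame measurements of a biometric during one scan are modelled as a
two-component contamination mixture:

    D_o = P_t · N(mu, sigma²) + (1 − P_t) · U(a, b)

Correctly classified frames yield values scattered around the true
biometric value `mu` with spread `sigma` (caliper/landmark noise);
misclassified planes and failed extractions yield essentially arbitrary
values, modelled as uniform over the biological limits `(a, b)`. `P_t` is
the proportion of valid measurements. The uniform component has no
parameters worth tracking, so `(a, b)` stay fixed for a scan.

## Streaming estimation

Each accepted measurement `x_i` is scored with the normalized Bayes
posterior that it came from the Gaussian branch,

    p_i = P(T | x_i) = N(x_i; mu, sigma²) · P_t
          / [ N(x_i; mu, sigma²) · P_t + (1 − P_t) / (b − a) ],

and the running parameters are updated by weighted cumulative averages:
`P_t` moves with unit weight per frame; `mu` and `sigma²` move with weight
`p_i`, so an outlier influences the estimate only in proportion to its
(tiny) posterior probability of being genuine. The variance update uses
the *previous* mean in its squared deviation, exactly as the recurrence is
defined; the difference from using the refreshed mean is O(1/W) and
vanishes with data. The reported standard error is
`sigma_hat = sigma / sqrt(W_sigma2)` — the Gaussian spread divided by the
effective number of genuine measurements absorbed — and the 95% credible
interval is `mu ± 2·sigma_hat`.

The update is O(1) per frame in double precision with no early stopping;
on one CPU it processes tens of thousands of measurements per second,
comfortably above video frame rates.

### Priors

| parameter | default | meaning |
|---|---|---|
| `P_t0` | 0.75 | prior valid-measurement proportion; must be strictly inside (0, 1) — the recurrence cannot leave a boundary |
| `W_0` | 10 | prior weight on `P_t0`; trades convergence speed against early oscillation |
| `mu_0` | p50 at GA | chart median at the scan's gestational age |
| `sigma_0` | (p97 − p3)/4 | ±2·sigma_0 spans the chart's normal band at that GA |
| `W_mu0`, `W_sigma2_0` | 1 | one pseudo-measurement of prior belief each |
| `(a, b)` | p3(GA−3 w), p97(GA+3 w) | plausibility window; doubles as the uniform support |

The prior weights are design choices (no published values exist): `W_0=10`
damps early `P_t` oscillation without materially delaying convergence, and
unit weights on `mu`/`sigma²` let a handful of real measurements overwhelm
the chart prior. `W_mu` and `W_sigma2` receive identical increments and
therefore stay equal when initialized equally; they are kept as separate
state fields so unequal priors remain possible.

### Known behaviour of the credible interval

Because the posterior weights feed back on the running mean (measurements
near the current estimate count slightly more), the empirical spread of
the final estimate runs a few percent above `sigma/sqrt(n)` while the
down-weighting of tail values biases the `sigma²` estimate a few percent
low. The two effects partially cancel: measured coverage of
`mu ± 2·sigma_hat` over replicate pure-Gaussian streams is 93–95%, and the
RMS difference between independent replicate estimates is 1.3–1.6× the
mean reported standard error (theory for an exact standard error: √2).

## Pre-estimator gates

Gates run in a fixed order — confidence, frozen-frame, degenerate
geometry, plausibility — so the attributed rejection reason is
deterministic when several would fire:

- **Confidence**: only frames classified as a biometric-bearing standard
  plane with confidence strictly greater than 0.95 proceed.
- **Frozen frames**: a frame in which more than 95% of pixels are
  unchanged from its predecessor is a paused/annotation frame and is
  dropped. "Unchanged" is exact equality by default (clean 8-bit
  captures); an absolute intensity tolerance is configurable for
  compressed recordings.
- **Degenerate geometry**: heatmaps with fewer than two distinct maxima,
  or whose best-fit conic is not a real ellipse, contribute nothing.
- **Plausibility**: a measurement below the 3rd centile at GA−3 weeks or
  above the 97th centile at GA+3 weeks is anatomically implausible.
  Boundary values are accepted (the rejection conditions are read as
  strict inequalities).

## Geometry extraction

Linear biometrics (FL, TCD) are the Euclidean distance between the two
highest heatmap maxima. Peaks are found after light Gaussian smoothing
(sigma = 1 px, suppressing plateau ties) with a minimum separation of
10 px, then refined to sub-pixel positions by a local intensity centroid
on the raw map.

Circumferences (HC, AC) come from a direct least-squares conic fit
(Halir–Flusser stable formulation, ellipse constraint built into the
eigenproblem) to the heatmap pixels above half the maximum intensity,
weighted by intensity. No installed library offers a weighted direct
ellipse fit, so it is implemented here and validated against rendered
ground truth (axes within 2%, angle within 2°, rotation-equivariant).
The perimeter uses Ramanujan's second approximation by default
(relative error < 1e-9 at fetal-head eccentricities; validated against
the exact elliptic integral); Ramanujan's first approximation and the
naive `pi(A+B)` are selectable, and the formula name is recorded in every
report. BPD is read directly off the HC ellipse as twice the semi-minor
axis. All coordinates are 0-based (row, col); pixel lengths convert to mm
by multiplication with the calibrated pixel size (isotropic pixels
assumed).

## Scale-bar calibration

The on-screen ruler has major ticks every 50 mm. Along the scan line
crossing them, slowly varying background is removed by subtracting a 1-D
Gaussian smoothing (sigma = 3 px, reflect boundary) and clipping at zero;
the raw autocorrelation `R(n) = sum_i X'_i X'_{i+n}` of the result peaks
at the tick pitch, and the pixel size is `L_x = d_bar / pitch`. Using the
largest tick spacing minimizes the one-lag quantization error
`d_bar·(1/p − 1/(p+1))`. The machine "dialect" (scan-line position,
orientation, tick spacing) is configuration; the line is chosen to cross
only the long major ticks, as the shorter 10/5 mm minor ticks would
otherwise produce the first autocorrelation peak.

Three detection guards make the first-peak rule robust without altering
the filter or the autocorrelation:

1. **Noise-floor suppression.** Sensor noise surviving the high-pass adds
   a broadband pedestal to the autocorrelation that can exceed a large
   pitch's few-tick peak. Ticks are sparse, so the filtered profile's 90th
   percentile estimates the noise scale (a zero-clipped Gaussian has its
   90th percentile at ~1.28 sigma); subtracting 3 noise-sigma and clipping
   at zero leaves the tick spikes. Clean profiles are mostly exact zeros
   after the high-pass and pass through unchanged.
2. **Peak validity.** Candidate lags are limited to half the profile (two
   full periods must fit), and a candidate must show harmonic support —
   correlation energy at twice the detected lag — which uncorrelated
   spike pairs lack.
3. **Comb consistency.** The number of surviving spike clusters must be
   commensurate with the detected pitch (at least half of
   `profile length / pitch`), rejecting accidentally periodic noise
   survivors. A noise draw whose survivors happen to be evenly spaced is
   formally periodic and undetectable in principle; the guard makes this
   vanishingly rare rather than impossible.

With these guards, every integer pitch from 15 to 200 px is recovered
exactly on clean renders, and the failure rate at amplitude SNR 5 is 2%
(the tolerance is 5%). Sub-pixel refinement by parabolic interpolation is
available but off by default (the method is defined on integer lags).

## Offline mixture fit

Pooled demeaned residuals (each scan's final estimate subtracted from its
own measurements) are fitted by expectation-maximization for
`(P_t, mu, sigma)` with the uniform bounds fixed from the plausibility
window, mirroring the streaming estimator's fixed nuisance. EM uses 10
restarts by default (one from a deterministic moment-based start), a
convergence threshold of |Δ log-likelihood| < 1e-8, and a sigma floor of
1e-3 mm against the degenerate single-point-spike likelihood singularity.
The fit reports the sup-distance between the empirical and fitted CDFs
for model-adequacy overlays. At n = 5000 with a simulation truth of
P_t = 0.79, sigma = 1.8 mm (a realistic femur-length operating point),
median recovery errors are within (0.03, 0.1 mm, 0.1 mm).

## Synthetic world

All tests run against generated inputs, since real screening recordings
are confidential:

- **Streams** draw each frame from the contamination mixture at defaults
  mirroring a realistic femur acquisition (truth 34 mm at 20 weeks,
  sigma = 1.8 mm, P_t = 0.8, 600 frames at 30 fps, pixel size
  0.35 mm/px), with configurable background-frame and low-confidence
  fractions and exact per-frame ground-truth labels.
- **Scale bars** render major ticks at a known integer pitch plus shorter,
  dimmer minor ticks at one-fifth and one-tenth of it, with optional
  Gaussian noise and bright clutter blobs emulating anatomy near the bar.
- **Heatmaps** place Gaussian blobs at known endpoints, or a
  Gaussian-profile ridge along a known ellipse, as the measurement
  networks are trained to emit.

Every generator is a pure function of (parameters, seed). The bundled
centile table is **synthetic and non-clinical**: quadratic-in-GA medians
anchored at plausible 20-week values with fixed-fraction p3/p97 bands. It
exists so the pipeline runs without licensed growth charts; clinical use
would inject a real reference via the same CSV interface.

What green tests establish: the estimator's calibration, robustness and
convergence under its own model assumptions; exact geometric and
calibration recovery on idealized renders. What they do not establish:
performance on real ultrasound appearance (speckle, shadowing, probe
pressure), real classifier confidence distributions, non-uniform outlier
structure, or drift of the true value within a scan (the model assumes a
single stationary truth per biometric).

One test-design note: the contamination-robustness check places the truth
at 30 mm rather than the chart median, because the uniform nuisance
window is nearly centred on the median — there the naive mean barely
shifts under symmetric contamination and the comparison ratio would be
noise over noise. An off-centre truth gives the naive mean a measurable
shift (~0.9 mm) against which the estimator's shift (~0.06 mm) is
compared.

## Limitations

- The posterior is normalized over the two mixture branches; the
  alternative odds-ratio reading of the scoring rule is unbounded and
  contradicts its description as a probability, so it is not offered.
- `sigma_hat` is not an exact frequentist standard error (see "Known
  behaviour" above); intervals are calibrated to within ~2 points of
  nominal in the tested regimes, not asymptotically exact.
- The estimator is order-dependent in its exact arithmetic (shuffled
  replays agree statistically, not bit-for-bit).
- Scale-bar reading assumes the dialect's scan line actually crosses the
  major ticks; locating the bar in an arbitrary vendor UI is out of
  scope.
- Isotropic pixels are assumed; anisotropic displays would need separate
  row/column calibration.
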