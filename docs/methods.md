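# Methods

`bedtherm` estimates the wrist distal skin temperature (DST) during sleep
from a five-sensor temperature strip embedded just below a smart-bed
mattress surface. This note describes the model, the synthetic data the
package is validated on, the numerical choices, and what the tests do and
do not demonstrate.

## The estimation algorithm

**Inputs.** Each strip sensor T1..T5 samples at ~1 Hz with a 0.1 °C
quantum. Samples are aggregated to per-minute means over half-open windows
[60(n−1), 60n) seconds (1-based minute index *n*), giving T1(n)..T5(n).

**Top-3 selection.** The five per-minute values are sorted descending and
the top three, V1(n) ≥ V2(n) ≥ V3(n), are kept. Warm sensors are the ones
most likely in contact with the body, so this step compensates for lateral
position changes without knowing the sleeper's location. Ties break toward
the smaller sensor index.

**Stage one.** A gradient boosted tree (XGBoost, squared-error objective)
maps (V1, V2, V3) → X(n), a first per-minute DST estimate. Training pairs
pool all valid minutes across all training sessions.

**Stage two.** Because consecutive DST values are strongly autocorrelated,
a random forest maps the rolling window (X(n), X(n−1), …, X(n−4)) → Y(n),
the final estimate. Y(n) exists only where five *consecutive* valid
stage-one estimates are available: the first possible index is n = 5, and a
gap in valid minutes suppresses output until four minutes after the gap
ends. Truncating a session after minute n provably leaves Y(5..n)
unchanged (no use of future samples).

**Sequential training.** The boosted tree is fitted first; its predictions
on the *same* training sessions form the stage-two design matrix; the
forest is then fitted on complete windows against the reference. Both
stages are seeded and single-threaded, so training is reproducible.

**Reference series.** The wrist channel (4 Hz, 0.02 °C quantum) is smoothed
with robust LOWESS at full rate and then reduced to one sample per minute
by taking per-minute means of the smoothed values (mean-based subsampling
avoids aliasing; skin temperature varies slowly, so the 1/min rate is
adequate). LOWESS parameters: `frac` = 0.05 of the session (floored so the
local window spans at least 10 minutes of samples), 3 robustifying
iterations, and a `delta` of 30 s (nearby fit points are linearly
interpolated), which keeps full-rate smoothing O(minutes) rather than
O(samples²).

**Known smoother edge case.** On *exactly* noise-free, unquantized input
the robust iterations degenerate: residuals are identically zero, the MAD
scale collapses, and outliers are returned unsmoothed. Real and simulated
wrist data are quantized (0.02 °C), which keeps the residual scale positive
and restores robust downweighting; the tests exercise the quantized case.

## Quality criteria

A minute is flagged, in priority order: `null_invalid` (any null sample),
`negative_invalid` (any sample < 0 °C), `oscillation_invalid` (intra-minute
range above a 2.0 °C threshold — "large oscillations indicate electronic
issues"; the threshold is configurable), `missing` (fewer than 50 % of the
nominal samples), `bed_absent` (less than 50 % overlap with bed-presence
intervals; out-of-bed data are discarded regardless of quality), else
`valid`. The strip is pooled: a minute is valid only if all five sensors
are valid. A session enters training only when **both** the pooled strip
and the wrist reference have at least 80 % valid minutes (inclusive
boundary). The 80 % criterion is computed over pooled strip minutes; a
per-sensor reading of the rule would be more permissive.

## Accuracy statistics

Per session, over the m minutes where both the reference S(n) and the
estimate exist (the estimate is LOWESS-smoothed first, with the same
parameters as the reference):

- bias = mean(S − Y); SD_d = sample standard deviation of the differences
  with the m−1 denominator; limits of agreement LoA = bias ∓ 1.96·SD_d.
  (The printed form of this formula elsewhere uses 1/N and 1/(N−5)
  prefactors for N−4 terms; this package deliberately uses the standard
  m / m−1 convention — the discrepancy is negligible for session-length m.)
- R² = 1 − SS_res/SS_tot with SS_tot about mean(S). Undefined (distinct
  error) for constant S or fewer than two pairs.

Sessions average unweighted to fold level, folds average unweighted to
grand means. Cross-validation is subject-blocked: each participant's
nights are an indivisible block, folds are mutually exclusive and
collectively exhaustive with sizes differing by at most one, and
train/validation subject disjointness is asserted programmatically.

## Hyperparameters

Search space — boosted tree: estimators ∈ {100, 200, 300}, depth ∈
{3, 5, 7, 9, 15}, learning rate ~ U(0, 1); forest: estimators ∈ [10, 300],
depth ∈ [1, 30] *or* unbounded, min-samples-split ∈ [2, 20]. The default
configuration (300 trees / depth 3 / rate 0.031; 300 trees / unbounded /
split 2) is the optimum reported for the real-data study; it is used as the
package default without any claim of optimality for synthetic data.

`tune_hyperparams` is a compact sequential model-based (TPE-style)
sampler written for this package: after 8 random startup trials, candidate
configurations are drawn from the prior and ranked by a Parzen density
ratio (best quartile vs rest, per dimension; Gaussian kernels for numeric
dimensions, add-one counts for categorical ones). The objective is the MSE
of Y against S on an inner 75/25 *subject-level* split of the tuning
sessions, honouring the subject-blocking philosophy. The tuning subset is
drawn at the subject level (20 % of subjects by default in the CLI).

## The synthetic study

No recordings from the motivating study are available, so the package
ships a simulator that generates the statistical structure the estimator
assumes:

- **Latent physiology.** Distal temperature rises by `distal_rise`
  (default 1.0 °C; proximal 0.5 °C) after sleep onset as a saturating
  exponential with time constant `rise_timescale` (default 15 min, so the
  rise reaches ~90 % within 30–40 min — consistent with the sleep-onset
  vasodilation literature). Onset follows bed entry (or lights-off in the
  lab) by a per-subject habitual latency (default 20 min, SD 5 across
  subjects, SD 3 night-to-night).
- **Slow fluctuation.** On top of the rise, a two-sinusoid mixture
  (periods 90 and 40 min, random phases per night) with standard deviation
  `fluctuation_amplitude` emulates sleep-cycle-scale drifts. The default
  ties the amplitude to 2 × `noise_sd`, so the noise-free limit is also
  fluctuation-free and the latent trajectory is exactly monotone during
  the rise.
- **Strip contact model.** Sensor i reads
  c_i·skin + (1 − c_i)·ambient + noise, quantized to 0.1 °C at a jittered
  ~1 Hz clock (±5 % interval jitter). Per night, three sensors are "under
  the body" (c ~ U(0.93, 1.0)) and two are not (c ~ U(0.15, 0.55)); posture
  shifts (Poisson, 1/h) permute and jitter the couplings, which makes top-3
  selection non-trivial. Ambient is constant (default 24 °C); a dynamic
  micro-environment model is an open engineering choice, not emulated.
- **Reference channels.** Wrist = latent + noise at 4 Hz/0.02 °C (home
  sessions); foot and proximal at 1/30 s with the 0.0625 °C iButton-style
  quantum (lab sessions; labs carry a lights-off event and no wrist,
  mirroring reference devices not worn under polysomnography).
- **Artifacts.** Null samples (NaN), negative samples, per-minute
  oscillation bursts on one random sensor, and bed-absence holes during
  which strip sensors relax to ambient. Defaults (10⁻⁴ null/sample,
  5·10⁻⁵ negative/sample, 0.005 oscillation/minute, one 2–8 min absence)
  contaminate a realistic few percent of minutes so most — not all —
  sessions pass the 80 % gate. Injection counts are exact by construction.
- **Subjects.** Stable baseline offsets (SD 0.3 °C) and habitual latencies;
  demographics drawn uniformly over realistic adult spans.

**Calibration.** The reference synthetic study (`default_study`) uses 20
home subjects × 5 nights plus 18 lab subjects × 2 nights of 240-minute
sessions, with `noise_sd` = 0.15 °C. These conditions were fixed once so
that the pipeline's synthetic recovery sits inside the plausibility
envelope of the real-data study (grand R² ≈ 0.9, |bias| ≪ 0.05 °C, LoA
well within ±1 °C) — the synthetic task is *easier* than reality, and
passing it shows correctness of the machinery, not field accuracy. The
240-minute session length is a deliberate problem-size choice.

**What the simulator does not emulate.** Real beds add ambient drift,
partner heat, bedding changes, device drop-outs with structure, and skin
temperature dynamics far richer than a rise plus two sinusoids. Passing
synthetic recovery therefore demonstrates that preprocessing, training,
validation and verification are wired correctly and leak-free — not that
the accuracy numbers transfer to any real mattress.

## Verification (lights-off change curves)

For each lab session the model (trained on all home sessions) estimates
DST from the strip alone; the estimate (LOWESS-smoothed, as everywhere
downstream) and the measured foot temperature are each reduced to change
curves — value minus the value at the lights-off minute, minutes 0–60 —
grand-averaged across sessions, and the two mean curves are correlated
(Pearson, two-sided t-based p over the 61 points). The 61 curve points are
strongly autocorrelated, so the p-value is optimistic; it is reported
as-is and should be read qualitatively. Sessions whose lights-off minute
lacks a valid estimate are skipped and counted.

In the noise-free limit the foot curve is exactly monotone. The estimated
curve is monotone only up to the resolution floor: a piecewise-constant
tree ensemble fed 0.1 °C-quantized inputs wiggles by a few hundredths of a
degree, so monotonicity is asserted within 0.05 °C (half the strip
quantum).

## Numerical and design choices

- Minute convention: 1-based, half-open [60(n−1), 60n) s windows.
- Null samples are NaN throughout; they void a minute's validity but not
  its sample-count (presence and validity are separate criteria).
- Quantization is round-to-nearest-multiple; equality checks use 1e-9.
- Stage-two window order is (X(n), …, X(n−4)); the order is
  representational only — forests are insensitive to feature order.
- Learning curves subsample *training subjects* per fraction; at fraction
  1.0 folds and model seeds coincide with `run_cv`, so the two agree
  exactly under the same seed.
- Fold partition, model seeds, simulator clocks and artifact draws all
  derive from a single user seed; every artifact is reproducible from
  (config, seed) alone, byte-identically for serialized output.
- Invalid minutes are discarded, never imputed.

## Limitations

- The two-stage model smooths aggressively; rapid reference excursions are
  underestimated (visible as larger errors at sharp reference deviations).
- Accuracy conditional on sleep stage is out of scope (no sleep staging).
- The distal-to-proximal gradient, a better sleep-onset predictor than DST
  alone, is not estimated.
- Real device drivers, bed firmware and pressure-signal processing are out
  of scope; streams enter via the CSV/Parquet + manifest schema.
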