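# Methods

This note documents the models behind `napinsight`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Task and behavioural model

The simulated task is a two-alternative random-dot classification with
nine 100-trial blocks. Motion direction (two diagonals) determines the
correct response throughout; five coherence levels (5/23/41/59/76%)
modulate difficulty, with the noisiest level over-represented (30 per 100
trials vs 10/20/20/20 in blocks 3–9). Block 1 is pure 100% coherence,
block 2 uses only the three easiest levels. From trial 351 the stimulus
colour becomes perfectly predictive of the correct response (orange ↔
NW/SE, purple ↔ NE/SW — the mapping is fixed across simulated subjects,
since counterbalancing does not affect any statistic computed here). The
nap separates trials 400 and 401; block 9 is performed under explicit
colour instruction.

An agent's probability correct on trial *t* is a lapse-contaminated
mixture of a motion strategy and a colour strategy,

    p(t) = (1 − λ) [ (1 − w(t)) p_motion(c) + w(t) p_colour ] + λ/2 ,

with logistic weight `w(t) = 1 / (1 + exp(−m (t − t_s)))` for insight
agents after colour onset and `w ≡ 0` otherwise. Reaction times are
log-normal, with the mean interpolating between pre- and post-switch
levels (767 → 527 ms) under the same weight.

### Default calibration

The cohort defaults are calibrated once against the canonical behavioural
profile of this task family and then frozen:

* `p_motion` — effective accuracy (including the default lapse λ = 0.03)
  of 56% at 5% coherence and 92% at 76% coherence, monotone in between,
  ceiling at full coherence;
* `p_colour = 0.97` — post-switch accuracy approaches ceiling, consistent
  with near-ceiling instructed-block performance;
* switch centres `t_s ~ N(510, 80)` truncated to [405, 650] (delayed,
  variable insight onset, mean near block 5);
* slopes `m ~ lognormal(ln 0.075, 0.3)` per trial. At this slope the
  switch-aligned accuracy profile, aligned at the generating switch
  centre and averaged over the 15 low-coherence trials before/after,
  reproduces window means of ≈ 0.62 / ≈ 0.88 — a ≈ 25-point jump within
  15 high-noise trials.

### Change-point fitting and a known alignment bias

The sigmoid is fit to the binary 5%-coherence series by Bernoulli maximum
likelihood (not least squares on smoothed accuracy): candidate switch
centres every 10 trials are scored with heuristic asymptotes and a small
slope grid, and the five best candidates are refined with bounded
L-BFGS-B (bounds: probabilities in [0, 1], slope in [0, 10], t_s within
the fitted range; ties broken toward the smallest t_s). The returned
optimum is never worse than any grid start.

Change-point MLE on binary data overfits the switch location: the fitted
slope frequently runs to its bound, locking t̂_s onto the boundary
between an error-dense and a success-dense run. Consequently, windows
adjacent to the *fitted* switch are selection-biased (accuracy just
before t̂_s is pulled down, just after pulled up) by roughly +0.10–0.15
in the jump statistic, regardless of the generating parameters. Summaries
meant to describe the generative switch profile should therefore align at
known (simulated) switch centres; summaries aligned at fitted centres are
reported as-is but carry this bias. The switch *classification* is
unaffected — it uses block-8 accuracy, far from the boundary.

Estimator properties under the default calibration (recomputed by the
test suite): median |t̂_s − t_s| ≈ 15–20 trials at the default gentle
slopes and < 15 at moderate slopes (m = 0.5); classifier sensitivity and
specificity ≥ 0.95.

### Inclusion rules

Two exclusion rules mirror standard practice for this design: (1)
subjects below 80% accuracy on the three easiest coherences in block 3 —
the last fully rule-free block, since the colour rule starts mid-block 4
— are excluded as non-learners; (2) subjects whose fitted switch centre
precedes the nap boundary *and* whose pre-nap high-noise accuracy already
exceeds the 85% insight criterion are excluded as pre-nap switchers.

## Hypnograms and EEG synthesis

Hypnograms are 40 epochs of 30 s. Wake-group naps are all W; N1 naps
descend after a geometric latency into N1 episodes with brief awakenings
and never reach N2; N2 naps descend W → N1 → N2 with a sustained N2 run
(≥ 2 min by default, matching the usual minimum-duration criterion).

EEG is synthesized per 30-s epoch by frequency-domain shaping: complex
Gaussian Fourier coefficients are scaled so the expected one-sided
periodogram equals the target density

    log10 P(f) = b − x log10 f + Σ_k h_k exp(−(f − c_k)² / 2σ_k²) ,

i.e. the oscillatory peaks are Gaussian in log-power, which makes the
composite spectrum exact in expectation and round-trip recovery tests
well-posed. Below 1 Hz the density plateaus at its 1-Hz value: real EEG
spectra plateau at low frequencies, and without the plateau the diverging
sub-1-Hz power-law energy leaks through the 6-s analysis taper into the
lowest fitted bins and biases exponent recovery steep (up to +0.4 at
x = 2.5). Epochs are joined with 0.1-s cosine ramps.

Stage defaults: exponents x = 1.37 (W), 1.47 (N1), 1.79 (N2), 2.1 (N3) —
slopes −x steepen with sleep depth — with alpha peaks in W/N1 (10 and
9 Hz) and a 13.5-Hz spindle peak in N2. Per subject, a N(0, 0.25)
idiosyncratic exponent offset is added (0.25 spans the between-subject
spread implied by typical group SEMs), plus a mean-preserving insight
contrast: insight subjects are steeper than their group's non-insight
subjects by 0.25 (the canonical insight/no-insight slope difference)
*centred within group*, so group-mean slopes stay at the stage defaults.
A plain additive insight effect would drag the group means away from the
stage values, making the two calibrations mutually inconsistent.

What the generator does **not** emulate: morphologically realistic
spindles/K-complexes (peaks are stationary within an epoch, not bursts),
EOG/EMG channels, REM, artifacts, volume conduction or spatial
correlation between channels (channels are independent realizations of
the same target spectrum), and within-stage drift of the aperiodic state.
Passing tests therefore demonstrate correctness of the estimators under
the stated spectral model, not robustness to real-data artifacts.

## Spectral estimation

Recordings are segmented into 6-s epochs with 50% overlap (399 epochs for
a 20-min nap; stage-restricted variants use only windows fully inside a
contiguous run of target-stage 30-s epochs). Each epoch is Hanning-
tapered, zero-padded from 1200 to 2000 samples so the FFT grid contains
exact 0.2-Hz multiples (6-s epochs natively give a 1/6-Hz grid; padding
honours both the 6-s epoch length and the 0.2-Hz resolution — whether
the original analyses padded or used a different epoch length is not
determinable, and the padding is configurable), normalized by window
power, averaged, and restricted to 1–45 Hz.

The decomposition is the standard two-stage procedure: (1) a robust
aperiodic fit in log10–log10 space — initial fit, clip negative residuals
to zero, refit on points at or below the 2.5th residual percentile, which
discounts oscillatory bumps; (2) iterative Gaussian peak extraction on the
flattened spectrum (max 3 peaks, minimum height 0.3 log10 units — the
"3 dB" criterion read as 0.3 bel — relative threshold 2 SD, full widths
within 0.5–12 Hz), followed by a joint refinement of all peaks; (3) a
final aperiodic refit on the peak-subtracted spectrum. The knee is fixed
at 0 throughout, so the log-log slope equals −x. On noiseless peak-free
model input the fit reduces to log-log linear regression to machine
precision; on simulated 20-min recordings exponent recovery is unbiased
to ≈ 0.01 across x ∈ [0.5, 2.5] and agrees with an independent Theil–Sen
robust regression within 0.05.

Flattened (aperiodic-corrected) spectra are evaluated on 1–20 Hz; band
summaries average the flattened values over inclusive bands (delta 1–4,
alpha 5.8–11.3, spindle 11.5–15.2 Hz).

## Cluster-based permutation inference

Element statistics are Welch t (two groups; two-sided threshold at the
per-element parametric critical value of `cluster_alpha`, sign-separated
clusters) or one-way F (three groups). Clusters connect supra-threshold
elements across spatial channel neighbours (Euclidean distance ≤ radius
on the 2-D montage; default radius 0.85 keeps left/right homologues
adjacent without completing the graph) and across adjacent frequency bins
within a channel; no diagonal channel-and-frequency hops. Channel-only
data are treated as a single bin. Cluster mass is the sum of statistics;
significance comes from the permutation null of the maximum |mass| over
relabelings, with the (+1)/(+1) correction so p is never zero. For small
cohorts an exact mode enumerates all distinct assignments. Family-wise
type-I error at nominal 0.05 measures ≈ 0.04 over 200 null simulations on
the 8-channel montage. No multiple-testing correction is applied across
the per-channel model ladder (the ladder and the cluster test are
separate analyses; noted in output metadata).

## Logistic models

The model ladder per channel — `insight ~ 1`, `~ 1 + stage`,
`~ 1 + stage + slope`, `~ 1 + slope` — uses treatment coding with Wake as
the reference level, fit by IRLS maximum likelihood (statsmodels GLM,
relative tolerance 1e-10, max 100 iterations). Reported per fit:
coefficients with Wald z tests, log-likelihood, `AIC = −2LL + 2k` with k
counting all parameters including the intercept, and adjusted McFadden
`R² = 1 − (LL − k)/LL_null`. Likelihood-ratio tests use the chi-square
with df equal to the parameter-count difference; for the saturated
one-factor stage model the coefficients and their standard errors equal
the closed-form log-odds-ratio expressions, which the tests verify.
Complete separation is flagged (diverging coefficients or a perfect 0/1
fit), not raised. Fisher's exact test uses the two-sided
point-probability convention (sum over tables no more probable than the
observed one), the convention required to reproduce standard reported
p-values; a zero margin returns p = 1 by convention.

## Determinism and problem sizes

One master seed drives everything; per-subject streams are derived by a
counter-based `SeedSequence` keyed by (seed, group, index), so enlarging
a cohort never reshuffles earlier subjects. Permutation tests take their
own seed. The test suite and acceptance script use cohorts of 8–28
subjects per group, 200 agents for behavioural operating
characteristics, 200 null simulations for permutation calibration, and
single-channel 20-min recordings where only one channel is analysed —
sizes chosen to keep Monte-Carlo error comfortably inside the asserted
tolerances.

## Known limitations

* The sigmoid midpoint is used as the switch point; a threshold-crossing
  definition would shift switch points later for gradual switches.
* The fitted-alignment selection bias described above is inherent to
  change-point MLE on binary data and affects any window statistic
  computed around the fitted switch.
* Whole-nap group-mean slopes for N1/N2 groups are flattened relative to
  the stage parameters because naps mix stages; the deepest-stage
  provenance is the one directly comparable to the stage parameters.
* The EDF writer targets the plain 16-bit EDF profile (1-s records, µV),
  not EDF+ annotations.
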