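# Methods

This note documents the statistical model behind `corticoflow`, the choices
made where the procedure admitted more than one reasonable reading, what the
synthetic-data generator does and does not emulate, and the problem sizes
used by the test suite.

## Single-trial response model

A directed connection is an ordered pair (stimulated bipolar electrode A,
recording bipolar electrode B). Each delivered pulse defines a trial: a
600 ms pre-stimulation window and a 500 ms post-stimulation window on B,
contiguous at the pulse onset T₀. All analysis windows operate on
preprocessed signals (see below) at 500 Hz.

**Magnitude.** The line length of a window of N samples,
LL = (Σ|xᵢ−xᵢ₋₁|/N)·(sf/1000), is waveform-agnostic and offset-invariant;
it is integrated over a 250 ms window chosen to contain both deflections of
a typical evoked response. The window starts at T₀ + 12 ms, after the
interpolated artifact span, so interpolated samples never contribute
(the start offset is configurable and echoed into output metadata, since
the alternative — starting at T₀ — is also defensible).

**Centroids.** Trials of one connection are clustered into two centroid
waveforms by rank-2 K-means under the correlation distance 1 − ρ:
assignment by highest Pearson correlation, centroid update by plain
averaging of member trials, 10 seeded restarts keeping the lowest-inertia
solution (the procedure has no canonical initialization; restarts plus a
fixed seed make it deterministic). Two centroids let a connection express
two contrasted response morphologies (e.g. opposite polarities) without
diluting either average.

**Connection-level test.** A connection is *effective* when the larger of
its two centroid line lengths reaches the 95th percentile of a surrogate
null. Each of 200 surrogate re-computations draws as many baseline epochs
as the connection has trials, runs the same K-means, and contributes both
centroid line lengths (2 × 200 pooled values). Re-computing the full
clustering on surrogates is essential: cluster selection inflates centroid
line length, and a null built from plain epoch averages would be badly
miscalibrated. Even so, the observed statistic is a maximum over two
centroids compared against the marginal surrogate distribution, so the test
is intrinsically mildly anti-conservative (Monte Carlo: ≈8–10% positives on
unconnected pairs instead of the nominal 5%); decisions across all probed
pairs are therefore Benjamini–Hochberg corrected in the pipeline output.
Surrogate p-values use the add-one estimator (1 + k)/(1 + n) and can never
be exactly zero.

**Trial-level test.** Each trial is scored by ±ρ²·LL: the Pearson
correlation with each centroid is maximized in ρ² over lags within ±10 ms,
and the score is sign(ρ)·ρ²·LL — the amount of line length attributable to
the expected waveform. The maximum over both centroids is taken (a trial
resembling either morphology counts as a response; the combination rule is
not prescribed elsewhere). The sign convention follows the ρ²-maximizing
lag. A trial is significant when its score reaches the 95th percentile of
400 identically scored baseline epochs, one-sided and uncorrected. Surrogate
epochs are sampled with replacement of onsets — a 5-min baseline cannot host
400 disjoint 250 ms epochs.

Because the threshold is a one-sided 95th percentile, the estimated
signaling probability has expectation P̂ = p·sensitivity + (1 − p)·0.05:
a 5% false-positive floor is part of the estimand. At the cohort-typical
hundreds of trials this floor dominates only for weakly connected pairs;
with very few trials (tens) the in-sample centroid fit additionally inflates
trial scores of the very trials that built the centroids, so small sessions
must be read through the FDR-corrected connection-level flags.

**Outliers.** Trials with LL above 4× the connection median are flagged —
an automated stand-in for the visual artifact/discharge review that an
analyst would perform; the default excludes them from both the probability
denominator and magnitude averages (configurable to flag-only, since
exclusion from only the magnitude is an equally faithful reading).

**Latency.** The signaling latency is the latency of the first local
extremum of the average response (significant trials when ≥5 are available)
within 500 ms, searched after the artifact span, gated by a line-length
elevation of the post-window over the pre-window (factor 1.25; pure-noise
averages sit at ≈1.0) and by peak prominence ≥2× the baseline SD of the
average trace. A prominence criterion alone admits small ripples riding on
the response flank once many trials are averaged, so a peak must also
deviate from the pre-stimulation level by the same threshold.

## Connection-level quantities

- **P** = significant responses / delivered stimulations; undefined (not 0)
  without stimulations.
- **DI** = (P_AB − P_BA)/max(P_AB, P_BA); antisymmetric; undefined when both
  probabilities are zero (0 would assert bidirectionality of a silent pair).
- **Classes**: local (≤25 mm, same hemisphere and region), long-range
  short-latency (>25 mm, ≤65 ms), long-range long-latency (>25 mm, >65 ms).
  The 65 ms threshold is the 95th percentile of within-region latencies
  (`parcellation.latency_threshold`), with 65 ms as fallback. A connection's
  own directed latency is used when the two directions disagree. Pairs
  within 25 mm but across regions or hemispheres are classified by latency.
- **Magnitude** = LL of the pointwise average of ≥5 significant trials
  (fewer → undefined; no baseline subtraction since LL ignores offsets).
- **ExI** = trapezoidal area under normalized magnitude vs normalized
  intensity (0 at 0.2 mA, 1 at 12 mA). Magnitudes are normalized to the
  connection's maximal complete-level wake LL; sleep curves reuse the wake
  anchor so state contrasts compare like with like. Levels with <5 trials
  are incomplete and excluded; ≥2 complete levels are required; the
  trapezoid runs over the available levels without interpolation, and gaps
  are visible in the reported level table. Significance: 200 surrogate
  curves built from baseline epochs with matched trial counts, 95th
  percentile.

## Parcellation

Regions are Louvain communities of the inter-areal connection-incidence
matrix at resolution 2.0. The matrix is symmetrized by arithmetic mean (the
incidence is directional in principle), not thresholded, and clustered over
20 seeded restarts keeping the best modularity; the graph is built over
integer node indices because set iteration over string labels depends on the
process hash seed and would break cross-run determinism. Selected areas
(amygdala, hippocampus) are removed before clustering and re-attached as
singleton regions. A ten-name region list is shipped for labeling synthetic
scenarios; deriving the real atlas partition requires external data and is
out of scope.

## Group-level statistics

- **Probability model**: binomial GLM
  logit(P) = β₀ + β₁(Region_stim:Region_resp) + β₂·d, with the interaction
  coded as a single combined factor (reference cell = first pair
  alphabetically, matching the printed formula which has no main effects)
  and observations weighted by trial counts (P is a binomial proportion with
  known denominator, not a unit-weight fraction). McFadden pseudo-R² is
  reported against the intercept-only fit.
- **Directionality across participants**: probabilities averaged within
  participants first, then paired P_AB vs P_BA Wilcoxon signed-rank tests
  per region pair, Benjamini–Hochberg adjusted across pairs; pairs with <5
  participants are reported untested.
- **Class contrasts**: Kruskal–Wallis across the three classes for P and
  |DI|, post-hoc two-sided Mann–Whitney pairs FDR-adjusted within measure.
- **Sleep modulation**: percent change 100·(sleep − wake)/wake of magnitude
  and ExI on state-complete connections, averaged within
  participant × region pair, signed-rank tested across participants and
  FDR-adjusted within state and measure; probability agreement between
  states summarized by Pearson correlation and Bland–Altman mean bias;
  probability changes modelled with a mixed-effects linear model
  (stimulation region fixed, participant random intercept, REML — no
  estimator is canonical here, REML is the conventional default).
- All tests are two-sided except the surrogate-percentile tests, which are
  one-sided by construction.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the analysis relies on:

- **Background**: 1/f-power noise per channel plus a 50 Hz sinusoid with
  random channel phase (full sessions); the epoch-level generator emulates
  *preprocessed* data — band-limited 1/f noise flattened below 0.5 Hz,
  matching the pipeline high-pass. Crucially, each connection's trials and
  its surrogate baseline are cut from one continuous noise stream, exactly
  as surrogate testing against the same recording channel assumes;
  independent per-epoch noise would differ spectrally from a continuous
  baseline and miscalibrate the null.
- **Evoked response**: two Gaussian-windowed deflections of opposite
  polarity — a sharp negativity peaking at the connection latency L (width
  max(4, 0.2·L) ms) and a broad positivity near 2.5·L (width max(10, 0.5·L)
  ms, amplitude ratio 0.6) — so a 250 ms window captures both. Trial-to-
  trial variability: multiplicative lognormal amplitude jitter (σ = 0.3)
  and uniform ±5 ms latency jitter.
- **Probability and intensity**: a response occurs with probability
  p(state)·σ(slope·(I − midpoint)); the same logistic also scales amplitude,
  so response magnitude grows with intensity. Defaults midpoint 1 mA, slope
  3/mA make the 3 mA mapping intensity effectively saturating.
- **State dependence**: `state_gain` scales the evoked *amplitude* per
  state class (W/NREM/REM); per-state response probabilities can be given
  separately. Default gains are 1.0 everywhere; sleep scenarios set them
  explicitly.
- **Artifact**: an 8 ms square transient of 20× the noise SD at T₀ on all
  channels, decaying spatially with a 20 mm constant, so artifact
  interpolation is genuinely exercised.
- **Schedule**: per block, a 5-min stimulation-free baseline, a full map
  (each electrode 3–5×, 3 mA, randomized), and a stimulation–response block
  (14 intensities × 3, randomized) for selected electrodes;
  inter-stimulus intervals Gaussian 4.5 ± 0.2 s truncated at 3 s (epochs
  must not overlap; no floor is prescribed anywhere). The 14 intensity
  levels are fixed once in `SR_INTENSITIES_MA`, spanning 0.2–12 mA with
  denser coverage at the low end where the response sigmoid bends. Blocks
  repeat hourly by default; a smaller `block_interval_s` packs a denser
  demo session.

**What it does not emulate**: biophysical neural-mass dynamics, volume
conduction, seizure activity, non-stationary noise, electrode drift, or
imaging-chain uncertainties (coordinates and region labels are inputs).
Passing recovery tests therefore demonstrates the *statistical* correctness
of the chain under its own assumptions, not robustness to every artifact of
clinical recordings.

## Problem sizes and numerical choices

Monte Carlo studies in the test suite are sized for a single CPU while
keeping binomial error bands meaningful: null calibration uses 2000 trials
against a 400-surrogate null; probability recovery uses 50 connections × 300
trials (evoked amplitude 5× noise SD); directionality recovery 10 pairs ×
200 trials per direction; the sleep cohort 13 participants × 4 region
pairs × 2 connections × 50 trials per state (amplitude 12× noise SD,
response probability 0.9, NREM amplitude gain 0.75 on hippocampal
efferences, states interleaved as in the block-wise protocol), 20
replicates. With 50-trial state averages the line-length noise floor
attenuates a generative −25% magnitude change to ≈ −22% recovered; larger
sessions converge to the generative value.

Degenerate inputs are handled explicitly: fewer than two trials yield a
flagged duplicated centroid; zero-variance trials score 0; empty clusters
duplicate the surviving centroid; all-zero incidence matrices yield a
single trivial community with a warning; insufficient baselines raise an
error naming the requirement. Quantiles are linear-interpolation
percentiles throughout. Seeds propagate through `numpy` Generators;
identical configuration and seed reproduce every output bit-exactly.

## Known limitations

- The estimated signaling probability carries the one-sided 5% surrogate
  floor described above; comparisons of P̂ against a generative truth must
  account for it at low p.
- The connection-level max-over-centroids test is mildly anti-conservative
  before FDR correction (≈8–10% on null pairs).
- Sessions with tens of trials per connection inflate single-trial
  probabilities via the in-sample centroid fit; the clinical regime
  (hundreds of trials) is where trial-level probabilities are trustworthy.
- EDF export is not provided; sessions are stored as an uncompressed array
  container (`.npy` + JSON sidecar) next to BIDS-iEEG-like TSV tables.
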