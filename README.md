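# corticoflow

Single-trial mapping of directed cortico-cortical signal flow from repeated
single-pulse intracortical stimulation.

When one bipolar iEEG electrode (A) is stimulated with a brief current pulse,
a connected cortical site (B) may produce a cortico-cortical evoked potential
(CCEP). Classical effective-connectivity mapping averages many trials and asks
only *whether* a connection exists. `corticoflow` instead decides, for **every
single stimulation**, whether a response occurred, and from those decisions
derives:

- **Signaling probability** `P_AB` — the fraction of stimulations in A that
  evoke a statistically significant single-trial response in B;
- **Directionality index**
  `DI_AB = (P_AB − P_BA) / max(P_AB, P_BA)` ∈ [−1, 1] — +1 is a pure
  efference (A only sends), −1 a pure afference, 0 bidirectional signaling;
  |DI| = 0.5 already means a doubling of signaling in one direction;
- **Excitability index** `ExI` ∈ [0, 1] — the area under the
  stimulation–response curve (response magnitude, normalized to the maximal
  wake response, against stimulation intensity normalized over 0.2–12 mA);
- **Vigilance-state modulation** — changes of all of the above between
  wakefulness, NREM and REM sleep.

The single-trial decision uses the **line length** of the post-stimulation
window,

```
LL = ( Σᵢ |xᵢ − xᵢ₋₁| / N ) · (sf / 1000),
```

two centroid waveforms per connection (rank-2 K-means under a Pearson
correlation distance), and the compound score **±ρ²·LL** (LL weighted by the
maximal squared correlation with either centroid within ±10 ms lag, sign
preserved). Significance is assessed one-sidedly against surrogate nulls
drawn from non-stimulated baseline epochs of the same channel: 2 × 200
surrogate centroid re-computations at the connection level, 400 surrogate
epochs at the trial level, 200 surrogate curves for the ExI, each at the 95th
percentile.

Because clinical recordings cannot be bundled, the package ships a
first-class **synthetic session generator**: ground-truth directed networks
with per-connection response probability, latency, amplitude, sigmoidal
intensity dependence and state gains, embedded in 1/f background noise with
50 Hz line contamination and stimulation artifacts, delivered on the
block-wise clinical schedule (5-min baseline, full 3 mA map, 14-intensity
stimulation–response block). Every injection is recorded in a truth table, so
recovery of `P`, `DI`, latency, `ExI` and sleep effects can be tested
exactly.

## Worked example

Run the bundled demo — a six-electrode, two-region network with two strong
local pairs, one asymmetric long-range pair (efference twice as probable as
the reverse direction), and unconnected pairs, probed in three protocol
blocks:

```bash
corticoflow run --seed 7 --out demo --hours 1 --block-interval 1200
```

This simulates the session, preprocesses it (12 ms artifact interpolation,
0.5–200 Hz zero-phase bandpass, 50 Hz notch + harmonics, robust rescaling,
resampling to 500 Hz), runs single-trial detection, and writes tidy tables.
The connections that survive the connection-level surrogate test with FDR
correction (`metrics/connections.csv`, `effective_fdr`):

```
stim_pair channel  n_stims  probability  latency_ms  magnitude  distance_mm connection_class
       e0      e1       15        0.933        26.0      0.164        8.824            local
       e0      e3       15        1.000        42.0      0.125       74.741       long_short
       e1      e0       15        0.933        24.0      0.170        8.824            local
       e3      e0       15        0.533        46.0      0.138       74.741       long_short
       e4      e5       15        1.000        20.0      0.105        7.799            local
```

These are exactly the five connections planted in the generator; the
latencies match the generative values (25, 45, 20 ms) within the ±5 ms trial
jitter. The directed pair table (`metrics/pairs.csv`) quantifies the planted
asymmetry of e0 ↔ e3 (generative probabilities 0.8 vs 0.4, i.e. a doubling,
DI = +0.5):

```
 a  b  p_ab  p_ba  di_ab
e0 e1 0.933 0.933  0.000
e0 e3 1.000 0.533  0.467
```

Note the small session: with only 15 trials per connection the single-trial
probabilities of *unconnected* pairs are inflated by the in-sample centroid
fit (the clinical protocol probes each connection hundreds of times, where
this vanishes) — which is why connection-level maps should be read through
the FDR-corrected effective flags, as above.

The stages are also available separately (`corticoflow simulate | preprocess
| detect | metrics | stats`), and `corticoflow parcellate` groups cortical
areas into regions by Louvain community detection (resolution 2.0) on a
connection-incidence matrix, keeping chosen structures (e.g. amygdala,
hippocampus) as their own singleton regions.

## Layout

| Module | Role |
| --- | --- |
| `corticoflow.synthetic_data` | ground-truth networks, schedules, session and epoch synthesis |
| `corticoflow.preprocess` | artifact interpolation, filtering, resampling, rescaling, epoching |
| `corticoflow.detection` | line length, centroids, surrogate nulls, single-trial tests, latency |
| `corticoflow.metrics` | signaling probability, DI, connection classes, magnitude, ExI |
| `corticoflow.parcellation` | Louvain region partition, latency threshold |
| `corticoflow.stats` | logistic probability model, directionality and class contrasts, sleep modulation |
| `corticoflow.io` / `pipeline` / `cli` | readers/writers, stage orchestration, `corticoflow` command |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
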