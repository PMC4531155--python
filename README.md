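# evokedio

Analysis of paired-pulse evoked multiunit responses and data-driven
input-output (I/O) modelling of a stimulated neural pathway.

When an afferent fiber tract is stimulated with pairs of electrical pulses,
the downstream cortical response depends on the stimulation parameters: the
inter-pulse interval (IPI) engages short-term synaptic facilitation — the
second response grows and arrives earlier for intermediate IPIs — and the
stimulus intensity recruits a larger afferent volley.  `evokedio` implements
the full chain needed to characterize and model this behaviour from
multielectrode multiunit recordings, plus a synthetic-data generator with a
known ground-truth circuit so every stage can be validated without any
recordings:

1. **Preprocessing** (`evokedio.preprocess`) — second-order elliptic
   bandpass (800 Hz–3 kHz, zero-phase), stimulation-artifact suppression by
   sliding local-polynomial subtraction, and precise-timing spike detection
   (peak-to-peak excursions within a 2 ms peak lifetime, ±9× the robust
   noise SD, 1 ms refractory).
2. **Response features** (`evokedio.features`) — peristimulus time
   histograms (2 ms bins, window [−10 ms, 2·IPI)), evoked spike counts per
   pulse (`count1`, `count2`, `count_total`) and first-spike latencies
   (`lat1`, `lat2`), with the reference-condition strength normalization
   that makes sessions comparable.
3. **Information analysis** (`evokedio.infotheory`) — plug-in mutual
   information MI(R; S) = H(R) − H(R|S) in bits and the coding fraction
   cf = MI/H(R), used to rank output features by how much they tell us
   about the stimulation parameter.
4. **I/O modelling** (`evokedio.iomodel`) — kernel regularized least
   squares: f(x) = Σᵢ aᵢ k(x, xᵢ) + b with linear or Gaussian RBF kernel
   (exp(−‖x − xᵢ‖²/σ)), coefficients from (K + λnI)a = y − b̄,
   hyperparameters by cross-validated grid search.  Spike-count prediction
   is scored as exact-match accuracy against the chance level of guessing
   among training values; latency prediction by nMSE = MSE/Var(y).
   `KRLSRegressor` is a scikit-learn compatible estimator.
5. **Orchestration** (`evokedio.pipeline`, `evokedio` CLI) — one-call runs
   from config to a reproducible report bundle, including rank-based group
   statistics (Kruskal–Wallis, pairwise rank-sum with Bonferroni).

## Worked example

Simulate one IPI-variation session (paired pulses at IPIs of 50/100/200/500
ms, 20 trials per condition, two channels) from the default ground-truth
circuit, then measure facilitation, rank features, and fit the I/O model:

```python
import numpy as np
from evokedio import synthdata as sd, features as ft, infotheory as it, iomodel as io

truth = sd.default_ground_truth()
protocol = sd.make_protocol("ipi_variation", n_trials_per_condition=20, seed=42)
spikes = sd.simulate_spike_responses(protocol, truth, n_channels=2, seed=42)
table = ft.per_trial_features(spikes, protocol, n_channels=2)

print(ft.facilitation_curve_from_features(table).round(3))

cf = it.rank_features([table], "ipi_ms").set_index("feature")["cf"]
print(cf.round(3))

x = table["ipi_ms"].to_numpy()
for kernel in ("rbf", "linear"):
    rep = io.cross_validated_evaluation(
        {0: (x, table["lat2"].to_numpy())}, kernel, task="latency", seed=42)
    print(kernel, "nMSE(lat2 | IPI) =", round(rep.per_channel[0], 3))
```

Output:

```
   ipi_ms   n  ratio     se
0    50.0  40  0.926  0.085
1   100.0  40  1.588  0.138
2   200.0  40  1.553  0.168
3   500.0  40  1.147  0.128
feature
count1         0.051
count2         0.111
lat1           0.038
lat2           0.214
count_total    0.105
Name: cf, dtype: float64
rbf nMSE(lat2 | IPI) = 0.642
linear nMSE(lat2 | IPI) = 1.048
```

The facilitation ratio (mean pulse-2 count / mean pulse-1 count) peaks near
the 100 ms IPI and decays back toward 1 at 500 ms, where the two responses
are independent.  Among the five output features, the pulse-2 first-spike
latency (`lat2`) carries the largest coding fraction about the IPI.  The
IPI → latency-2 dependency is nonlinear: the RBF kernel reaches an nMSE
well below 1 while the linear kernel does no better than predicting the
mean (nMSE ≈ 1).

The same session can be produced at the raw-trace level
(`sd.synthesize_raw_trace`, with spike templates, per-pulse artifact
transients and Gaussian noise) and pushed through the preprocessing chain;
the retained ground-truth spike times score the detector.

From the shell: `evokedio synth`, `evokedio preprocess`, `evokedio fit`,
`evokedio run --config config.yaml`.

## Layout

```
src/evokedio/
  synthdata.py    ground-truth circuit model, protocols, spikes, raw traces
  preprocess.py   bandpass, artifact subtraction, spike detection
  features.py     PSTH, counts, latencies, normalization
  infotheory.py   entropy, mutual information, coding fraction
  iomodel.py      KRLS estimator, model selection, accuracy/chance/nMSE
  pipeline.py     orchestration, group statistics, report bundle
  cli.py          click CLI (`evokedio`)
docs/methods.md   modelling assumptions, parameter choices, limitations
```
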