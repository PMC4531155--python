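# Methods notes

## The experiment being modelled

A paired-pulse stimulation experiment probes a pathway's short-term
dynamics: two identical pulses separated by an inter-pulse interval (IPI)
are delivered repeatedly (one pair every 5 s, i.e. 0.2 Hz) while a
multielectrode array records multiunit activity downstream.  Two protocols
are used: *IPI variation* (IPIs of 50, 100, 200 and 500 ms at a fixed
intensity, 75% of the maximal one) and *intensity variation* (a fixed
200 ms IPI while the normalized intensity ramps over (0, 1]).  The
response on each channel and trial is summarized by evoked spike counts in
the IPI-long window after each pulse and by the first-spike latency after
each pulse.

## Ground-truth circuit model (synthetic data)

The generator replaces recordings with draws from an explicit circuit
model, so every downstream stage can be scored against known truth.  Its
components, all configurable:

* **Recruitment** (`base_rate_curve`): expected pulse-1 count vs intensity,
  a Hill curve `max·i²/(i² + 0.4²)` with `max = 6` spikes — zero at zero
  intensity, saturating at full recruitment.  Values chosen to give a few
  evoked spikes per channel per pulse, typical of multiunit windows.
* **Facilitation** (`facilitation_curve`): multiplicative gain on the
  pulse-2 expected count vs IPI.  Default: an asymmetric log-Gaussian bump,
  gain 1.06 at 50 ms, 1.8 at 100 ms, 1.36 at 200 ms, 1.01 at 500 ms —
  facilitation engages above 50 ms, peaks at 100 ms and has vanished by
  500 ms, where the two responses of a pair are independent.  `validate()`
  enforces the unity-at-500, peak-at-100 and monotone-recruitment
  invariants.
* **Counts**: Poisson by default.  A variance-to-mean dispersion parameter
  generalizes this: > 1 draws negative-binomial counts, < 1 draws
  sub-Poisson counts (rounded Gaussian with the requested variance), 0 is
  deterministic.  Only means are constrained by the phenomenon being
  emulated; the noise family is a modelling choice.
* **Latencies**: lognormal around the condition mean (median-parametrized,
  CV ≈ jitter/mean), truncated to (0, IPI) — positive and right-skewed,
  as evoked first-spike delays are.  The condition mean is 8 ms at full
  intensity, lengthened by 2 ms per unit of missing intensity, and
  shortened by 3 ms per unit of facilitation gain above 1 (facilitated
  volleys reach threshold earlier).  Jitter SD 1 ms.
* **Raw traces**: Gaussian noise + a biphasic 1.2 ms spike template per
  event (main negative peak aligned with the event time; shorter than the
  detector's 2 ms peak lifetime so detection is well posed) + a per-pulse
  stimulation transient `A·(1 − t/10 ms)⁴` (default amplitude 50× the
  template peak) — a stiff smooth artifact of the kind local-polynomial
  subtraction is designed for.

What the generator does **not** emulate: channel heterogeneity (channels
are exchangeable draws), bursting/refractory structure within a response
beyond ordered spike times, electrode drift, correlated noise across
channels, and field-potential components.  Passing tests therefore
demonstrate correctness of the analysis chain under the stated model, not
robustness to every property of real tissue.

## Preprocessing choices

* **Filter**: second-order elliptic bandpass 800 Hz–3 kHz.  Ripple is not
  part of the contract; 0.1 dB passband / 40 dB stopband is used.  The
  filter runs forward-backward (`sosfiltfilt`) so latency features inherit
  no group delay.
* **Artifact subtraction**: per pulse onset, a sliding least-squares
  polynomial (order 3, 151-sample window = 15.1 ms at 10 kHz) is fitted
  over a 40 ms correction window and subtracted; the first 1 ms is blanked
  (amplifier saturation region).  Implemented via Savitzky–Golay
  smoothing, which is exactly the sliding local LS polynomial fit.
* **Order of operations**: subtraction runs on the *raw* trace and the
  bandpass comes second.  Filtering first smears the artifact's sharp
  onset into in-band ringing that no low-order polynomial can track and
  that triggers false detections near every onset; on the raw trace the
  artifact is smooth, the polynomial removes almost all of it, and the
  filter then suppresses the smooth residual.  On the standard fixture
  this choice moves detection precision from ≈0.55 to 1.0.
* **Noise SD**: median absolute deviation / 0.6745 by default — the spikes
  themselves inflate the raw SD, the MAD ignores them.  Raw SD is
  selectable.
* **Detection**: consecutive local extrema closer than the 2 ms peak
  lifetime form a candidate excursion; peak-to-peak amplitude must exceed
  9× the noise SD; the spike is stamped at the extremum of larger absolute
  amplitude (precise peak timing); a 1 ms refractory keeps the earlier of
  two close detections.  Detections are assigned to the trial whose window
  [onset − 10 ms, onset + 2·IPI) contains them.
* **Bad channels**: instead of visual exclusion, channels whose noise SD
  exceeds 3× the median channel SD are dropped automatically.

## Feature conventions

All windows are half-open; a spike exactly at the pulse-2 onset belongs to
pulse 2.  Silent trials contribute 0 to count averages but are excluded
from latency averages (a latency is undefined without a spike); in the
information analysis, missing latencies instead form an explicit symbol so
non-response carries information.  Condition aggregation is per-channel
trial means first, then across-channel means for "global" quantities; the
strength normalization divides by the global mean total strength at the
reference condition (maximal intensity, or the 500 ms IPI).

## Information estimates

Plug-in (maximum-likelihood) entropies in bits; MI = H(R) − Σ p(s)H(R|s).
No bias correction by default — plug-in MI is biased upward by roughly
(|R|−1)(|S|−1)/(2n ln 2), which matters for small samples; a Miller–Madow
correction is available behind a flag.  Latencies are discretized at 2 ms
(the PSTH resolution).  Coding fractions are asserted to lie in [0, 1] on
every computation.

## KRLS conventions

* Regularized system `(K + λnI)a = y − ȳ`: the `λn` scaling makes λ a
  per-sample quantity so grids transfer across dataset sizes; centering the
  outputs avoids penalizing the mean response, which is restored at
  prediction.
* RBF kernel `exp(−d²/σ)`: σ carries squared-distance units (no factor 2).
* Grids: λ ∈ 10⁻⁶…10² (9 log-spaced), σ ∈ median pairwise squared distance
  × 2⁻³…2³ (7 values).
* Model selection is nested: the outer 10-fold split (seeded shuffle,
  contiguous blocks) measures performance; hyperparameters are chosen by
  an inner 5-fold grid search run on the outer training set only, so no
  validation data leaks into selection.  Reported metrics are averaged
  over outer folds.
* Count prediction is regression + rounding to the nearest non-negative
  integer, scored as exact-match accuracy.  The chance level is
  1/#distinct training count values by default (guessing uniformly among
  the values available in training); a 1/max-count variant is selectable —
  the two coincide whenever every value 1..max occurs.
* Channels with fewer than 10 usable observations are excluded from
  evaluation.
* Degenerate cases: a singular system (λ = 0 with duplicated inputs) falls
  back to a pseudo-inverse with a warning; zero output variance makes nMSE
  undefined (NaN, warning); fewer observations than folds reduces the fold
  count with a warning.

## Problem sizes

Test and script workloads are sized for quick, repeatable runs: 20 trials
per condition and 1–2 channels for qualitative checks (repeated over 20
seeds for majority assertions), 500 trials per condition for facilitation
recovery (3 Monte-Carlo-SE tolerance), 200 injected spikes at SNR 12 for
detection scoring, and 100 × 10 s noise traces for the false-positive
bound.

## Known limitations

* The facilitation curve's exact values between the four standard IPIs are
  a free parametrization; only its structural invariants are meaningful.
* Plug-in MI values on 80-trial sessions carry small-sample bias; only
  comparisons between features of the same session are interpreted.
* The KRLS input is one-dimensional (IPI or intensity); multivariate
  stimulus descriptions would need only a kernel change but are untested.
* Detection is multiunit: no spike sorting, and overlapping spikes within
  one refractory period merge into one event by design.
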