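# Methods

This note documents the models, conventions, and design choices behind
`toddleracc`: what the synthetic-data generator emulates, how counts and
features are defined, and where genuinely open decisions were settled.

## 1. Synthetic signal model (`toddleracc.simulate`)

The generator emulates 30 Hz, ±6 g triaxial recordings from hip- and
wrist-worn devices while a toddler performs one of nine behaviors. Each
bout is built in a world frame and rotated into the device frame:

* **Oscillatory core** — a sum of harmonics (fundamental + up to two
  overtones, weights per behavior) for the vertical and fore–aft
  components, plus lateral sway at half the step frequency. Cadence and
  amplitude are redrawn per bout (log-normal jitter, CV 6% and 20%) and
  scaled per subject (CV 15%): no two walks, and no two caregivers, move
  identically. A slow seeded envelope (low-passed noise, ±20%) modulates
  amplitude within the bout.
* **Gravity** — a per-behavior trunk pitch rotates the 1 g static vector
  with the dynamics, so any static posture averages to 1 g vector
  magnitude. Crawling pitches the trunk ~90°: gravity leaves the vertical
  device axis while the large fore–aft rocking lands on it — reproducing
  the high vertical-axis counts of hands-and-knees locomotion.
* **Carried** — adult cadence (1.9 Hz), moderate amplitude, low-pass
  filtered at 3 Hz (the carrier's body smooths the transmitted gait), plus
  an unsmoothed per-bout "fidget" term at toddler cadence whose amplitude
  is drawn half-normal: most carried bouts are spectrally smooth, some are
  contaminated by the child's own wiggling. The fidget term is what keeps
  carried-vs-ambulation from being trivially separable.
* **Ride-on toy** — a per-bout two-mode mixture: vigorous upper-body
  bouncing vs. quiet feet-propulsion.
* **Stand / sit / stroller** — zero oscillation amplitude; the dynamic
  component is Gaussian sensor noise (SD 12–20 mg).
* **Wrist** — attenuated copy (gain 0.6) of the hip dynamic signal plus
  independent band-limited arm bursts gated second-by-second, scaled by a
  per-behavior arm-activity factor (toy play while sitting is busy; a
  stroller ride is not). Wrist data are therefore noisier than hip data.

Sessions concatenate scheduled bouts with 1-s seeded "transition"
segments, labeled as such so downstream label filters exercise their
exclusion path. All randomness flows from a single `SeedSequence`; the
same seed reproduces traces bit-for-bit, and hip/wrist calls with one
seed are sample-aligned.

Default per-behavior amplitudes and cadences were calibrated once so that
emulated hip vertical-axis count medians obey the orderings observed in
playroom recordings of toddlers — stand/sit/stroller ≪ walk < carried <
crawl, with running and bouncing most energetic — and so that the carried
median exceeds the walking median roughly threefold.

**What the generator does not emulate:** biomechanically realistic gait
(no double-support structure, impacts, or turning), device non-wear,
battery/temperature artifacts, posture drift within static bouts, or
inter-axis cross-talk. Passing tests show the analysis pipeline behaves
correctly on signals with the *statistical signatures* of these behaviors;
they do not certify performance on real recordings, where class overlap is
larger and labels are noisier.

### Coder-error model

`perturb_labels` jitters label boundaries (Gaussian SD in seconds, rounded
to whole seconds, validity repaired) and swaps each label with a fixed
confusable counterpart (e.g. stand ↔ transition) with a given probability,
emulating the disagreement pattern of independent video coders.

## 2. Activity counts (`toddleracc.counts`)

Commercial count algorithms are proprietary, so the package implements a
documented open analogue: per axis, a 4th-order Butterworth band-pass
(0.25–2.5 Hz) → rectification → dead-band (0.05 g) → clip (2.13 g) →
per-sample quantization (1/64 g per step) → epoch sum. Per-sample
quantization makes counts exactly additive across epoch boundaries and
monotone in in-band oscillation amplitude. Absolute values are on this
algorithm's own scale; every count-based conclusion in the package is
ordinal or arithmetic, never a comparison of absolute counts against
proprietary-software values.

Behavior count rates follow the labeled-interval convention: intervals are
half-open [start, end) at whole seconds; the first and last labeled second
are excluded (a 10:00:00–10:00:05 label contributes data from 10:00:01 to
10:00:04); counts are summed over a behavior's trimmed time, divided by
trimmed seconds, × 5. Use 1-s epochs for rates so epochs align with label
boundaries. Trailing partial epochs are dropped, not prorated.

Cut-point conversion scales a threshold by the epoch-length ratio and
rounds to the nearest integer — the only rule consistent with the three
published conversions (419/15 s → 140/5 s; 1756/min → 146/5 s; 3958/min →
330/5 s). The built-in toddler hip vertical set places MVPA at ≥140
counts/5 s; its light/sedentary boundary is set at 5 counts/5 s, the
ceiling observed for quiescent postures in toddler playroom data — a
package choice, since no toddler sedentary bound is published alongside
the MVPA bound.

## 3. Labels and agreement (`toddleracc.annotation`)

The label filter keeps the nine prescribed behaviors at ≥5 consecutive
seconds. Inter-coder agreement matches labels greedily by largest interval
overlap, requiring overlap >50% of the shorter label; matched pairs are
concordant when behaviors agree, and unmatched labels on either side count
toward the total as discordant. Reported percentages round to the nearest
integer. The >50%-overlap rule is one defensible reading of row-level
coding comparison; it is configurable (`min_overlap_frac`).

## 4. Window features (`toddleracc.features`)

Windows are non-overlapping 5-s segments (150 samples) tiled from the
start of each label's trimmed interval — by construction every window is
100% one behavior. Feature axes follow the conventional lettering: x =
horizontal (axis 2), y = vertical (axis 1), z = perpendicular (axis 3).

* **Time domain (30):** mean, SD, median, min, max, skewness, excess
  kurtosis per axis (21); mean, median, min, max, skewness, kurtosis of
  the per-sample vector magnitude (6); zero-lag Pearson correlation of
  each axis pair (3). SDs are population (ddof = 0). Skewness/kurtosis of
  an (effectively) constant signal are defined as 0, and correlation with
  a constant axis is 0, so no window produces missing values. The VM stat
  set deliberately omits SD to keep the 30-feature arithmetic exact; this
  is a documented open reading (see §7).
* **Frequency domain (48):** per axis, the magnitude spectrum of the
  mean-subtracted signal, DC bin excluded (gravity dominates DC), no
  taper; over it: mean, SD, median, min, max, and the spectral centroid
  (magnitude-weighted mean frequency, Σf·|S| / Σ|S|, 0 for a silent
  spectrum); plus the magnitudes of bins 1–10 (0.2–2.0 Hz at 5-s windows).
  Magnitude (not power, not normalized) spectra were chosen; scaling a
  window by c then scales every spectral magnitude by c, matching the
  time-domain spread features.

The batch extractor is vectorized across windows (a thousand windows take
well under a second on one core) and column order is canonical and stable.

## 5. Statistics (`toddleracc.stats`)

Count summaries report the median and linear-interpolation quartiles of
per-participant rates. Mann–Whitney tests are two-sided, exact for
combined n ≤ 20 without ties, tie-corrected normal approximation
otherwise. The sensitivity index uses the equal-weight pooled-variance
form d′ = |μ_A − μ_B| / √((σ²_A + σ²_B)/2) with sample (ddof = 1)
variances — the conventional signal-detection definition for two empirical
distributions; zero pooled variance yields 0 for equal means and +inf
otherwise. The feature ranking scores all 78 features and breaks d′ ties
alphabetically.

## 6. Classifier (`toddleracc.classifier`)

A random forest over the 78 features. Hyperparameters are chosen by grid
search with stratified 10-fold cross-validation over the entire data set;
the default grid is {trees: 100, 300} × {depth: none, 5, 10} × {min leaf:
1, 5}, visited smallest-model-first so ties resolve to the smallest model.
Whole-data-set tuning mirrors common practice in small activity-recognition
studies but leaks test windows into hyperparameter choice;
`loso_evaluate(..., nested=True)` provides the leakage-free alternative.
Evaluation is leave-one-subject-out: each participant's windows are held
out exactly once, metrics are computed on the pooled out-of-fold
predictions, and per-fold (per-subject) accuracies are reported because
pooled accuracy can exceed every individual subject's accuracy under class
imbalance. "Average" precision/recall are macro-averages over the two
classes. Feature importances are mean decrease in impurity from a final
fit on all data, normalized to sum to 1.

## 7. Open decisions and known limitations

* **Problem sizes.** The default synthetic study uses 21 subjects with
  ~4–6 min sessions (~550 windows, ~13–15% carried), chosen to mirror the
  scale and class imbalance of a playroom study while keeping the full
  battery fast; real sessions average ~15 min.
* **VM feature set.** Whether SD of vector magnitude belongs among the
  time-domain features is ambiguous in the source material; the enumerated
  30-feature list (without it) was followed and the alternative recorded.
* **d′ denominator.** Pooled-variance vs. average-SD denominators cannot
  be distinguished from the source; pooled variance was chosen.
* **Counts.** The open count algorithm approximates, not reproduces,
  proprietary counts; only orderings and ratios are meaningful.
* **Agreement unit.** Boundary-time disagreements may be counted
  differently by different row-matching conventions; the overlap rule is
  configurable.
* **Generator realism.** Synthetic separability is optimistic: on real
  data the carried class overlaps ambulation more heavily, and reported
  synthetic accuracies should be read as upper bounds demonstrating the
  pipeline, not field performance.
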