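# Methods

This note documents the models, numerical conventions and design choices
behind `cardiosleep`, in the spirit of a statistical package's model
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

The pipeline's substrate is a night of RR intervals: beat times (s) and
intervals (ms) with a per-beat validity flag. When the input is a raw
single-lead ECG, R peaks are detected with the classic derivative/energy
detector: band-pass 5–15 Hz (2nd-order Butterworth, zero-phase),
differentiation, squaring, 150-ms moving-window integration, adaptive
dual thresholds (running signal/noise peak estimates with a 0.25 mixing
fraction) and a 200-ms refractory period; accepted detections are refined
to the band-passed extremum within ±100 ms.

Artifact flagging marks beats invalid without deleting samples:

* interval > 2 s ("wide gap") or < 0.35 s ("narrow gap");
* *irregular adjacent gaps*: deviation of more than 20 % from the median
  of the 5 surrounding valid intervals. This rule is iterated to a fixed
  point (runs of ectopic-like beats are removed step by step), which makes
  `clean_rr` idempotent by construction. The 20 % tolerance is the common
  ectopic-beat heuristic and is configurable; no published definition of
  the rule exists to pin it down further.

Invalid beats are excluded from all feature computation; for spectral
features the gaps are bridged implicitly by the resampling spline.

If a recording opens with more than 5 min of wakefulness, everything
before the final 5 min of that wake run is cut off and the beat clock
shifted so epoch alignment is preserved.

Whole-recording screening applies the study inclusion rules: at least 5 h
of data; AHI < 5; objective sleep efficiency ≥ 75 % (defined here, in the
absence of a standard formula for this pipeline, as the fraction of
non-wake epochs between the first and last non-wake epoch); at most
45 min of leading and 30 min of trailing wakefulness; at most 25 % of the
data lost to noise. Rules whose metadata is absent are skipped and
reported as skipped rather than silently passed.

## Analysis windows

Epochs are 0-based and half-open: epoch *i* covers [30·i, 30·(i+1)) s.
Each epoch's feature window is the 4-min-30-s stretch centred on it.
In training mode a window is unusable when truncated at a record edge or
when it spans more than two distinct annotated stages; in inference mode
every window is used.

## HRV features

Twenty-three candidate features per window. Conventions fixed by this
package where the field has several:

* **Spectral.** The tachogram of valid beats is resampled with a cubic
  spline at 4 Hz and analysed with Welch's method (128-s Hann segments,
  50 % overlap). Bands: VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz;
  LFn = LF/(LF+HF) so LFn + HFn = 1 identically.
* **resf** is the spectral argmax in 0.15–0.5 Hz (the respiratory band);
  **strf** is the standard deviation of resf over five 90-s sub-windows
  sliding across the 270-s unit (the sub-windowing is unspecified in the
  method's sources; five half-overlapping sub-windows give each estimate
  ≥ 0.011 Hz resolution while sampling the whole unit).
* **coRR** correlates the valid-interval sequence with its second-order
  smoothed version, implemented as two passes of a centred 3-point moving
  average — the simplest smoother matching the description; configurable.
* **DFA** is order-1 over scales 4–64 beats (14 log-spaced scales,
  forward and backward segmentation). Following the method's own wording,
  α₁ is the *slope* and α₂ the *intercept* of a single
  log₁₀ F(n)–log₁₀ n regression; the conventional two-exponent variant
  (slopes over 4–11 and 11–64) is available via `dual_exponent=True`.
  Under this convention α₂ shifts by log₁₀ c when the signal is scaled by
  c, which the tests exploit.
* **Entropies.** Sample entropy: m = 2, r = 0.2·SD, Chebyshev distance,
  self-matches excluded, both template lengths built on the same n−m
  starts; constant input returns 0 by convention, an empty match count
  returns the missing marker. Fuzzy entropy: same m and r, Gaussian
  membership exp(−(d/r)²) on baseline-removed templates.
* **Poincaré.** Successive differences are treated as zero-mean, so
  SD1 = RMSSD/√2 holds as an exact identity and
  SD2² = 2·var(RR) − SD1² (population variance).
* **Irreversibility.** P₁ is the percentage of negative increments among
  the nonzero ones; G₁ the percentage of increment energy carried by the
  positive ones. Both are invariant under adding a constant to all
  intervals, and time reversal maps P₁ to 100 − P₁.
* **corr2** is the Pearson correlation of the sequence with itself
  shifted by two beats.

Every feature returns `nan` (the explicit missing marker) when its
precondition — minimum beat count or duration — fails; no feature raises
on short input.

### Contextual features

Twenty features relate each unit to its neighbourhood. The per-epoch
instantaneous-HR series is the window mean HR and the respiration series
the window resf (one value per unit). In the 3-min windows before ("a"
prefix) and after ("z" prefix) the unit, extrema are located on a
3-point-smoothed series (endpoints count as extrema, so a monotone window
has exactly one maximum and one minimum); t₁/t₂ are the two highest
maxima, b₁/b₂ the two lowest minima, and the four pairwise slopes per
signal are Δvalue/Δtime in s⁻¹, missing when the second extremum does not
exist. Level ratios compare the unit value to its centred one-hour mean
(`*_m1`) and the overnight mean (`*_ma`).

## Stage recognizers

For each stage the named features (defaults: W = coRR, HR, resf, α₂;
R = coRR, HR, resf, α₁, α₂, G₁; L = HR, resf, SE, α₂, P₁; D = resf, LF,
α₁, corr2) are median-imputed within the night (a column over 50 %
missing is an error), SE and α₂ are negated (their variation across
arousals opposes the other features), columns are z-scored within the
night and projected on the first principal component. The PC sign is
arbitrary, so loadings are oriented to make HR's loading (or the first
listed feature's) positive — the criteria are one-sided, so the
convention matters. F₁ is z-scored and smoothed with Savitzky–Golay
filters (order 2) at two frame lengths: **11 epochs** (≈5.5 min; tracks
epoch-scale variation) and **121 epochs** (≈60 min; spans the sleep-cycle
scale). Neither frame length is stated in the method's sources; these
defaults bracket the two time scales the construction requires and are
configurable.

The per-stage offsets k (k₁ < k₂ for the light-sleep band, fitted as a
symmetric band ±k) are chosen on a 41-point grid over [−2, 2] PC units by
maximising the mean of binary accuracy and Youden's index over the pooled
training epochs, ties broken toward the smaller |k|.

### Boundary-value processing

Near each crossing of SF₁ with the shifted trend, epochs are easily
mis-tagged. For each excursion of g = SF₁ − (BF₁ + k) above zero
(below, for the deep-sleep recognizer, with all signs mirrored), let H be
the excursion maximum and L the adjacent minimum outside it on each side
(searched within 40 epochs), and s the one-epoch difference of g at the
crossing. On the medial (inside) side of each crossing the threshold is
raised by a linear ramp of height c_h·(H−L) decaying to zero over
c_w·(H−L)/|s| epochs; where ramps from both crossings overlap the larger
applies; tags are then re-evaluated against the adjusted threshold. The
proportionality constants default to c_h = 0.25, c_w = 0.5 (unstated in
the sources; configurable), and c_h = 0 is an exact no-op. The band
recognizer is not adjusted, matching the construction's restriction to
the W, R and D detectors. Adjustment runs on the tags before fusion.

### Fusion

Three binary classifiers — wake+REM vs NREM ("WR/N"), W vs R, L vs D —
are RBF-kernel SVMs (C from a small inner grid search, γ = 'scale',
training subsampled to 4 000 epochs for tractability) on standardized,
median-imputed features: the union of the recognizer features plus the
top contextual features ranked by linear SVM-RFE (8 by default). Each
margin f is calibrated with Platt's sigmoid P = 1/(1 + exp(A·f + B)),
obtained as an (effectively unregularised) logistic fit on the training
margins; the explicit (A, B) pair is what the serialised model bundle
stores, alongside support vectors and dual coefficients, so bundles are
plain JSON and language-neutral.

Routing per epoch: one tag stands as-is; tags {W,R} or {L,D} are resolved
by the corresponding conditional classifier alone (the group probability
is deliberately not consulted); one tag from each group is resolved by
the WR/N classifier choosing the group, whose surviving tag wins; zero,
three or four tags fall back to the argmax of the four joint
probabilities. Ties in the argmax break in the order W, R, L, D.

### Post-hoc corrections

REM within the first 80 min after sleep onset (first non-wake epoch)
becomes W; deep sleep within 30 min before the final awakening (the
trailing contiguous wake run) becomes L. A single pass can move the very
landmarks the rules are defined against (converting an early REM epoch
to wake can shift sleep onset), so the pass is iterated to a fixed point;
this makes the operation idempotent by construction rather than by
accident. Convergence takes one or two passes in practice and is capped.

### Feature-combination search and useless-feature elimination

Combination search builds a provisional recognizer for every feature
combination of size 1–3 (PCA → dual smoothing → best offset on the grid)
and ranks combinations by the same accuracy/Youden score. A feature is
*useless for a stage* when it appears in the bottom quartile of the
ranking but never in the top quartile; the intersection of the four
per-stage useless sets is removed from the global pool. The quartile
cut-off is a package choice — the sources describe the rule only
qualitatively.

## Sleep-quality model

The hypnogram is reduced to architecture features. Definitions fixed
here: sleep onset = first non-wake epoch; sleep efficiency = non-wake
epochs / all epochs; wake bouts = maximal wake runs after onset;
`freq_WR_after_6h` = W-or-R epochs beyond the 6-h mark per hour of record
beyond it (missing for shorter nights); incubations in minutes from
record start (sleep) and from onset (REM). The *transition intensity*
codes W → 1, R → 0, L → 1, D → 1 and sums absolute differences of
neighbouring codes — implemented verbatim from its printed definition,
although that coding makes wake↔NREM transitions invisible; the plausibly
intended 1/0/−1 coding is available via `labeling="signed"` but is not
the default.

The classifier is a degree-3 polynomial-kernel SVM on the nine retained
features, standardized, with C selected by an inner grid search and
reported with stratified 5-fold cross-validation (per-class accuracy,
average accuracy, macro F1). SVM-RFE (explicit elimination loop over a
linear SVC, dropping the smallest squared weight each round) provides the
feature ranking machinery for both this model and the fusion classifiers.

## Synthetic data generator

The generator exists so the pipeline is testable end-to-end without
clinical recordings. It emulates:

* **Hypnograms**: a semi-Markov chain over {W, R, L, D} with geometric
  bout lengths (defaults: W 2, L 18, D 12, R 12 min) and transition
  weights that produce NREM/REM cycling on the ~90-min scale, after an
  opening wake bout (10 min).
* **RR series**: intervals laid down sequentially as stage mean + 0.1-Hz
  LF sinusoid + respiratory-frequency sinusoid + Gaussian jitter, with
  1 % of beats pushed outside the physiological range to exercise
  artifact flagging. Stage defaults (mean RR 800/860/950/1010 ms for
  W/R/L/D; LF amplitude 45/35/12/3 ms; respiratory amplitude
  10/16/22/8 ms at 0.30/0.34/0.26/0.21 Hz; jitter 25/20/10/15 ms) encode
  the qualitative contrasts the staging method relies on — faster heart
  rate and LF dominance in wake/REM, respiratory-band dominance in NREM,
  stage-specific respiratory frequency. They are documented choices, not
  claims of physiological truth.
* **Cohorts** with planted good/poor labels: poor sleepers' chains are
  biased into more wake (transition weights into W ×4, wake bouts ×2.5)
  and more fragmented sleep (L/D/R bout means ×0.5), yielding lower
  efficiency, more wake bouts and higher transition intensity.
  Questionnaire scores are drawn on the matching side of the good/poor
  threshold.

What the generator does **not** emulate: real ECG morphology and noise,
apnea events, inter-subject variability of HRV baselines beyond the
seeded randomness, circadian drift within stages, and the empirical joint
distribution of HRV features. Passing end-to-end tests therefore
demonstrates that the machinery recovers structure *of the kind the
method presumes* when it is present at realistic contrast — not clinical
performance on human data, which requires the restricted polysomnography
corpora the published benchmarks use.

## Problem sizes and determinism

The acceptance computation uses 40-subject cohorts of 8-h nights for the
staging block (20 training / 20 held-out nights, ≈38 000 epochs), an
80-subject hypnogram-level cohort for the quality block, 10 × 1000-point
series for the DFA calibration and 20 seeded runs for the SVM-RFE
recovery experiment — sizes at which the synthetic checks are stable
while a full run stays in the minutes range on one CPU. Every random
draw is derived from the single `--seed` argument; identical seeds give
byte-identical outputs.

## Known limitations

* The staging model's accuracy on synthetic cohorts says nothing
  quantitative about performance on the large clinical polysomnography
  corpora; no external benchmark is rerun here.
* The "irregular adjacent gaps" rule, the strf sub-windowing, the coRR
  smoother, the smoothing frame lengths, the boundary-adjustment
  constants and the useless-feature quartile are all under-specified in
  the method's sources; each is implemented with a documented,
  configurable default.
* The printed transition-intensity coding is honoured verbatim even
  though it blinds the statistic to wake↔NREM transitions.
* ECG support is a thin text-based import plus the built-in detector;
  EDF/WFDB binary formats are out of scope.
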