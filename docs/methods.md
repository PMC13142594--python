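# Methods

This note documents the statistical model behind `shortcut-audit`, the
detector definitions and their thresholds, what the synthetic benchmark
does and does not emulate, and the numerical choices a maintainer would
want to know about.

## Problem formulation

Let `E ∈ R^{n×d}` be embeddings extracted from a trained model, `Y` the
task labels and `A` a binary sensitive attribute (categorical attributes
are binarized explicitly; age-like attributes at a configurable cut,
default 60). Shortcut risk is framed as residual conditional dependence
`I(E; A | Y) > 0`: the embeddings remain separable by the attribute
beyond what the task explains. No direct conditional-mutual-information
estimator is attempted; instead a battery of practical detectors, each
sensitive to a different geometry of encoding, estimates the dependence
from its own angle, and evidence is combined by counting flags.

Every detector honors one contract: `detect(E, Y, A) → (s_m, τ_m,
flag)` with evidence score `s_m ∈ [0, 1]`, threshold `τ_m`, and `flag ⇔
s_m > τ_m`. Detectors that cannot run (single-class attribute, missing
second attribute, too few samples per fold/cell) return
`applicable=false` and leave the aggregation denominator.

## Detectors and thresholds

**Probe.** 5-fold stratified cross-validated logistic regression A ~ E
on pooled-standardized embeddings, scored by mean held-out balanced
accuracy. Flags when the accuracy clears *both* a fixed high-risk cut
(0.70) and the 95th percentile of a 100-permutation label-shuffle null.
The fixed cut dominates at audit scale; the permutation term guards
small-n audits. Localization: dimensions whose full-data refit
coefficient has robust z-score ≥ 3 (median/MAD across dimensions). The
classifier uses lbfgs with loose tolerance (1e-2, ≤100 iterations):
at audit scale the accuracy is indistinguishable from tight fits and
the permutation null needs hundreds of refits.

**Statistical.** Per-dimension Welch (unequal-variance) two-sample
t-tests, corrected across dimensions (Bonferroni default; Holm and
Benjamini–Hochberg available, delegated to statsmodels). Welch rather
than pooled variance keeps the test valid under 0.9 group imbalance.
Score `1 − min adjusted p`; localization = significant dimensions.
Zero-variance dimensions get p = 1 with a logged warning.

**Geometric.** Euclidean distance between group centroids of
standardized embeddings, tested by a label-permutation null (1000
permutations, add-one smoothing). Calibrated: empirical size ≤ 0.07 at
nominal 0.05 in the test suite. Per-dimension localization compares
each dimension's squared centroid difference against its own
permutation 99th percentile.

**Bias direction.** Normalized centroid-difference direction `w`;
score is the *in-sample* AUC of the projection `E·w` against A, flagged
at AUC ≥ 0.60. Estimating and evaluating on the same samples makes the
null AUC concentrate near `Φ(√(d/n)·c)` — about 0.69 at n=1000, d=128
and higher for larger d — so the detector flags on pure noise at audit
scale. This is deliberate: it reproduces the documented behavior of
uncalibrated direction methods, and the aggregation layer's adjusted
counts exclude it.

**Frequency.** Per-dimension comparison of extreme-activation
frequencies: counts above the pooled 95th percentile per group, tested
with a two-proportion z-test, Bonferroni-corrected. This statistic is
the package's embedding-level stand-in for frequency-based perturbation
analysis (reports label it as such). It is deliberately lower-powered
than the mean-shift t-test: at n=1000 its per-dimension power crosses
from ~0 at δ=0.2 to ~1 at δ=0.5, giving the sharp detection transition
the benchmark expects, while a full distributional test (e.g.
Kolmogorov–Smirnov) already fires at δ=0.2 and would duplicate the
statistical detector.

**SIS (sufficient input subsets).** Greedy forward selection of
dimensions: at each step the dimension maximizing the in-sample
accuracy of a least-squares linear scorer on the selected subset is
added (exact forward stepwise via Gram–Schmidt residualization; ties
break to the lowest index), stopping at accuracy ≥ 0.55 or 20
dimensions. In-sample greedy selection overfits enough that the target
is reached even on pure-noise embeddings at audit scale — the second
deliberately uncalibrated detector. The 0.55 target was frozen from a
one-time pilot on the null grid (d ∈ {128, 256, 512}, 10 seeds) where
greedy in-sample accuracy concentrates around 0.56–0.62; the pilot is
part of the design, not a per-run calibration. A consequence of the
early stop is that at large effect sizes the subset is very small, so
localization recall (and F1) against a 10-dimensional ground truth is
low even though detection is certain.

**HBAC (hierarchical bias-aware clustering).** Recursive bisecting
2-means on standardized embeddings (depth ≤ 5, clusters split only
above 2×50 samples). Each leaf's attribute composition is tested
against the global composition (two-proportion z, Bonferroni over
leaves). Score = positive part of the leaf-partition silhouette × the
largest significant composition gap, scaled by 0.5 — the silhouette
factor is the cluster-quality confidence normalization; the flag
threshold applies the same silhouette weighting to the minimum gap of
0.10, so flag ⇔ (significant leaf with gap > 0.10 and positive
silhouette). Localization: dimensions in the top decile of the flagged
leaf's centroid deviation.

**Demographic parity.** A linear task head Y ~ E is fit with 5-fold
stratified CV (shared by all fairness detectors); every sample gets one
held-out decision score. The DP gap is measured in its *strong* form:
the maximum positive-rate gap over all decision thresholds, i.e. the
Kolmogorov–Smirnov distance between the two groups' held-out score
distributions. For hard 0/1 predictions this reduces to the familiar
positive-rate gap. Flag at gap > 0.01 (strict parity). On
A-independent data the score-distribution gap concentrates around
0.04–0.08 at n=1000, so the detector always flags on null data — the
third deliberately uncalibrated method, kept so that aggregated and
adjusted counts mean what they say. The single-threshold hard-label gap
is also reported in the result details.

**Equalized odds.** Max of TPR and FPR gaps across groups on held-out
predictions. Calibrated, unlike DP: flags only when the gap exceeds
both 0.10 and the 95th percentile of a 200-permutation attribute-
shuffle null, so sampling noise does not fire it.

**Intersectional.** With ≥ 2 attributes, each intersection cell with ≥
20 samples (smaller cells merged out with a warning) is compared
against its complement on positive rate; flags only when the largest
intersectional gap exceeds both the tolerance and the largest
single-attribute gap — i.e. when the intersection adds information
beyond marginal disparity. Not applicable with a single attribute.

**GroupDRO.** Two linear task heads trained by deterministic full-batch
gradient descent (50 epochs, lr 0.1): ERM, and GroupDRO with
exponentiated-gradient group weights over the A-groups (step 0.1).
Flags when (a) the *peak* group-weight share over training exceeds 0.6
(once DRO equalizes losses the weights drift back toward uniform, so
the collapse signal is the trajectory maximum, not the final value) and
(b) DRO repairs the worst-group loss ERM incurs by more than 0.1.

**GCE.** A task head trained with generalized cross-entropy
`L_q(p) = (1 − p^q)/q` (q = 0.7), which down-weights hard examples so
the fit is dominated by the easiest predictive structure. Signal:
balanced accuracy of the head's held-out task predictions in predicting
A (symmetrized), flagged at ≥ 0.60 — but gated on the head having
actual task skill (held-out task balanced accuracy ≥ 0.55). Without the
gate, a head trained on unpredictable labels emits near-random
predictions whose incidental attribute alignment grows with the
attribute's encoding strength and would spuriously fire at large effect
sizes; random predictions carry no evidence of shortcut *reliance*.

**SSA.** The attribute is hidden for 90% of samples; a logistic head
trained on the labeled 10% pseudo-labels the rest. Flags when the
pseudo-labels are accurate (≥ 0.70 on the hidden portion — the
attribute is learnable from few labels) and the downstream task model's
error rate differs across pseudo-attribute groups by > 0.10.

The three learning-dynamics detectors and equalized odds read shortcut
evidence out of *task-prediction structure*. When Y is independent of E
(as in the synthetic benchmark) there is nothing for them to exploit
and they stay silent at every effect size; this is expected behavior,
not insensitivity.

## Aggregation

The applicable detectors' flags are counted: `R = agreement /
denominator`. Convergence bands generalize the HIGH ≥ 7/12 rule as a
fraction applied by ceiling to any denominator (so a 13-method audit
needs ≥ 8/13); MODERATE uses the 5/12 fraction, LOW means at least one
flag. The MODERATE band is this package's plumbing — reports always
print raw counts next to the level. Adjusted agreement recomputes both
numerator and denominator after removing {bias_direction, sis,
demographic_parity}; the exclusion list is config-exposed and echoed in
every report. Ceiling computations subtract 1e-9 before rounding so
that 7/12 × 12 does not float up to 8.

Per-detector seeds derive from the audit seed by a stable CRC-32 hash
of the method name, so adding a method never shifts another method's
random stream.

## Synthetic benchmark

`generate_synthetic` draws all d dimensions i.i.d. standard normal,
samples k (default 10) shortcut dimensions uniformly, and shifts group
1 by +δ/2 and group 0 by −δ/2 on those dimensions, so the per-dimension
Cohen's d equals δ exactly in population. The attribute is Bernoulli
with majority proportion `imbalance` (group 0 majority); Y is Bernoulli
(0.5) independent of both E and A, which makes every detection a pure
embedding–attribute signal. Four named child RNG streams (attribute,
embeddings, dims, labels) keep generation bit-reproducible and
extensible. Replicate seeds form the ladder base, base+1, ….

With k = 10 the probe's Bayes accuracy `Φ(δ√k/2)` crosses the 0.70 flag
cut between δ=0.2 (≈0.62) and δ=0.5 (≈0.79), which is what produces the
probe's sharp 0 → 1 detection transition at the benchmark scale.

What the generator does *not* emulate: correlated or multi-dimensional
shortcut structure beyond mean shifts (variance or higher-moment
differences), label-coupled shortcuts (Y ⊥ E always), non-Gaussian
marginals, and any image-level provenance. Consequently, passing
benchmarks show correct detector behavior under mean-shift encodings
with independent labels; they do not certify sensitivity to nonlinear
or distributed encodings in real embeddings, and the learning-dynamics
detectors are structurally silent here (their activity is exercised by
constructed label-coupled datasets in the unit tests instead).

Localization is scored as precision/recall/F1 of the detected dimension
set against the planted set; an empty detection against a nonempty
truth scores 0, empty against empty scores 1.

## Mitigation loop

All transforms preserve n and sample order. `mask_dimensions` replaces
listed dimensions by their pooled mean. `erase_bias_direction` projects
onto the orthogonal complement of the group centroid-difference
direction, recomputed each round (default 3); each extra round removes
roughly one more noise direction (~1/d of variance) once the rank-1
mean structure is gone. `adversarial_debias` trains a linear map
jointly with a task head and an adversary head; the map descends the
task loss while shrinking the group-mean separation along the
adversary's current direction — the statistic the adversary exploits —
because ascending the adversary's cross-entropy directly has a
vanishing gradient once the adversary converges. `contrastive_debias`
learns a linear map pulling same-task cross-group pairs together with a
margin hinge pushing different-task pairs apart (2000 sampled pairs,
margin 1.0). `last_layer_retrain` refits the task head on a
(Y, A)-balanced subsample and changes the head, not the embeddings.

Two behaviors worth knowing. First, transforms that zero the *sample*
group-mean difference exactly (erasure, adversarial) can push a
cross-validated probe slightly *below* chance: conditioned on a zero
pooled difference, the training folds' empirical direction
anti-correlates with the test fold. Below-chance probe accuracy after
mitigation is an over-removal artifact, not residual signal. Second,
erasure removes rank-1 mean structure only; when the attribute is
encoded with higher rank (multiple shift magnitudes, variance
differences), cluster-based detectors may legitimately keep flagging
after erasure — the re-audit asserts nothing beyond what it reruns, and
the tests only require that linear probe accuracy drops.

`mitigate_and_reaudit` runs the identical pipeline (same methods,
settings, seeds) before and after, and reports held-out downstream task
accuracy on both sides.

## Problem sizes and numerical choices

The benchmark and the reproduction script run at n=1000, d=128, k=10
with 10 replicate seeds per cell — the scale at which all reported
detection rates, F1 values and FPRs are defined; the uncalibrated-trio
FPR check additionally runs d ∈ {256, 512}. The full 12-method suite
takes ~2.5 s per dataset on one CPU (the probe's 100-permutation null
dominates). Geometric permutations are vectorized as a single
(permutations × n) · (n × d) product. Degenerate inputs (constant
dimensions, zero-variance groups, coincident centroids, empty cells)
return not-applicable results or p = 1 rather than raising, except
where the input violates the dataset contract outright. Flag thresholds
on score scales are nudged by 1e-12 so that boundary equality (e.g.
accuracy exactly at the cut) counts as specified without floating-point
surprises.

## Known limitations

- Thresholds (probe 0.70, bias-direction AUC 0.60, SIS 0.55, HBAC gap
  0.10, DP 0.01) are defaults chosen for the audit scale above and are
  all config-exposed; other scales may need recalibration.
- Binary attributes only, after explicit binarization; multi-level
  attributes require a user-supplied level map (one-vs-rest audits can
  be run per level). Missing attribute values drop rows, never imputed.
- The geometric detector's in-sample standardization makes it
  anticonservative in very high dimension relative to n; like the
  uncalibrated trio it is best read inside the convergence aggregate.
- The frequency detector is a named stand-in (see above), not a
  spectral method.
- Linear heads throughout; nonlinear probes and deep mitigation maps
  are out of scope.
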