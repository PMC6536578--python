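# Methods

This note documents the models, estimators and numerical conventions behind
`chemosig`, the defaults that shape its output, and what the synthetic
benchmarks do and do not demonstrate.

## Dose-response model and IC50 estimation

Viability plates are modelled (and simulated) as a Hill curve on top of a
fluorescence window: fraction viability `v(c) = 1 / (1 + (c/IC50)^h)` with
Hill slope `h > 0`, and well signal `blank + (control − blank)·v·(1 + ε)`
with multiplicative Gaussian noise `ε ~ N(0, cv)`. Multiplicative
(CV-parameterised) noise matches the mean-proportional error of plate
fluorimetry; simulated readouts that would go negative are clamped at zero
and the clamp count is reported on the dataset. Normalisation
`(treated − blank) / (control − blank)` makes the viability scale invariant
to detector gain and offset, which is tested as a property.

Two IC50 estimators:

* **Log-linear interpolation (default).** The adjacent dose pair bracketing
  mean viability 0.5 is interpolated on the log10-dose axis; with several
  crossings (non-monotone noisy curves) the lowest-dose crossing is used, a
  deterministic and conservative choice. Curves entirely above or below 0.5
  are censored (`above_max` / `below_min`) rather than extrapolated. This is
  the most assumption-free reading of "IC50 from the dose-response curve"
  and needs no optimiser.
* **Four-parameter logistic (opt-in).** Least squares on
  `v(c) = bottom + (top − bottom)/(1 + (c/IC50)^h)` with loose bounds
  (top ∈ [0.3, 3], bottom ∈ [−1, 0.7], h ∈ [0.05, 20]) and the
  interpolation estimate as the IC50 start value. Non-convergence falls back
  to interpolation with a flag in the diagnostics instead of failing the
  plate.

On the default simulated plate design (8 geometric doses 0.1–300 µM, six
replicates, 5% CV) interpolation recovers the true IC50 with a median
relative error of a few percent; both estimators agree within 5% on
noiseless curves for h ∈ [0.5, 3].

**Degree of resistance** is `IC50(derivative)/IC50(parental)`, reported
rounded half-up to two decimals (presentation convention) while the
qualitative call is made on the unrounded ratio. The call thresholds — ≤ 0.5
collateral-sensitive, ≥ 2.0 cross-resistant — are not a community standard;
they encode the usual qualitative language ("two-fold resistance", "half the
IC50") and are configurable. Censored IC50s are refused with instructions to
widen the dose range: a ratio against a bound would be directional, not
numeric.

## Correlation ranking and signature selection

Each gene row is correlated with the per-line log10(IC50) by the Pearson
product-moment coefficient using pairwise-complete observations; genes with
fewer than three usable values or zero variance are excluded and counted.
Computation is a vectorised masked two-pass formula; tests cross-check it
against direct summation and `scipy.stats.pearsonr`. The log10 scale for the
response is deliberate: potencies are log-normally distributed across lines,
and correlating on the log scale keeps a single very resistant line from
dominating.

Selection keeps up to `k = 20` genes per direction passing `|r| ≥ 0.50`,
ranked by signed r (two separate lists, not one |r| ranking), ties broken by
gene identifier for determinism. At n = 47 lines the null probability of
`|r| ≥ 0.50` is ≈ 3.4 × 10⁻⁴ (r² ~ Beta(½, (n−2)/2) under the null), so a
2000-gene null panel contributes < 1 expected false gene — the threshold is
what makes a recovered 40-gene signature signal rather than selection noise,
and the generator's null tail is tested against that analytic value.

The expression matrix is treated as already normalised (the simulator emits
z-scale values); no platform-specific preprocessing is attempted.

## Ward clustering

Cell lines are objects, signature genes features, z-scored per gene by
default (clustered-image-map convention; raw-scale clustering is a flag).
Agglomeration follows Ward's minimum-variance criterion on Euclidean
distances via the Lance–Williams recurrence (`scipy` linkage, "ward"), under
the convention where two singletons merge at their Euclidean distance, i.e.
heights are `√(2·ΔESS)`. Tests verify, by exhaustive evaluation of every
candidate merge's within-cluster sum-of-squares increase for n ≤ 7, that the
implementation's merge sequence and heights equal the direct definition, and
that heights never invert (Ward is reducible, so the nearest-neighbor-chain
order cannot produce inversions). Exact merge ties are resolved by the
linkage algorithm's traversal order; on continuous data ties have
probability zero.

The k-cluster partition is defined by removing the k − 1 highest merges
(implemented by union-find over the first n − k linkage rows, so tie
behaviour is exactly the linkage order), and clusters are numbered 1..k by
first appearance along the dendrogram leaf order so partition files,
contingency tables and the exported Newick tree cross-reference. Branch
lengths in the Newick export are parent height minus child height; k
defaults to 4 and no automatic k selection is offered — choosing k from the
dendrogram is left to the analyst.

## Median dichotomy and the predictability test

Lines are labelled sensitive when log10(IC50) < M (the panel median) and
resistant otherwise; ties at M go to "resistant" by default (the ≥ rule,
configurable) and the choice is explicit because with an odd panel one line
sits exactly at M. The k × 2 contingency table is tested with
`X² = Σ (O−E)²/E`, no continuity correction, df = k − 1, upper-tail p from
the χ² distribution. Because k = 4 over ~47 lines routinely yields expected
counts below 5, a fixed-margin Monte-Carlo p-value — permuting the
sensitive/resistant labels over lines, add-one corrected
`(1 + #{X²* ≥ X²})/(1 + B)` — is added automatically whenever
`min(E) < 5`, with B = 10000 by default.

### Selection circularity and what "calibrated" means here

The full chain selects genes *by* their correlation with the response and
then asks whether clusters built on those genes associate with the response.
Under the null this is anti-conservative by construction: conditioning the
features on the outcome guarantees spurious association. Empirically, null
panels pushed through the full chain reject far above the nominal level
whenever any gene clears the threshold. The calibration benchmark therefore
measures the size of the Monte-Carlo chi-square test itself, with the
clustering built on a response-independent gene subset of the same null
panels: there the rejection rate is 5% within binomial error (1000 panels).
Passing that benchmark validates the test, not the selection step; a
signature "validated" by re-using the selection data should always be read
with this circularity in mind, and the planted-signature power benchmark
(where real signal exists) is the complementary check that the chain finds
structure when structure is there.

## Synthetic panels

`generate_panel` draws a response `z ~ N(1.5, 0.4)` in log10(µM) per line
(IC50s spanning roughly 8–120 µM, a realistic potency window for a
moderately active compound) and plants positive genes as
`x = r·z* + √(1−r²)·ε` against the population-standardised response `z*`
(negative genes use −r), so the population correlation is exactly ±r with no
post-hoc rescaling; null genes are iid standard normal. Defaults — 47 lines,
2000 null + 20 + 20 planted genes at |r| = 0.7 — are the panel geometry the
downstream claims are benchmarked under. A separate grouped generator plants
cell-line clusters (Gaussian centroids with shift ≫ noise) to validate
partition recovery.

What the simulator does *not* emulate: tissue-of-origin covariance between
lines, gene–gene correlation beyond the shared response factor, batch or
probe-level artifacts, and heavy-tailed expression noise. Benchmarks passing
on these panels show the estimators and tests are correct under their stated
model, not that a real 47-line screen will yield a 40-gene signature.

## Problem sizes and determinism

Benchmarks run at: 100 panels for signature recovery, 50 for end-to-end
power (1999 Monte-Carlo permutations each), 1000 null panels for calibration
(499 permutations each — enough to resolve p < 0.05), 200 plates for IC50
recovery; sizes chosen to pin the Monte-Carlo error well below each
acceptance margin while staying cheap on one core. All randomness flows from
`numpy.random.default_rng` seeds carried in the configs; the pipeline writes
no timestamps, sorts JSON keys and fixes float formatting, so a config +
seed reproduces every artifact byte-for-byte (tested).

## Known limitations

* Interpolated IC50s cannot leave the tested dose range; steep curves with
  a single bracketing interval inherit that interval's log-linear bias.
* The 4PL fit reports the curve midpoint; with partial plateaus (top/bottom
  poorly constrained) the midpoint and the absolute-50% crossing differ.
* Pairwise-complete correlation uses a different effective n per gene;
  no per-gene p-values or multiple-testing correction are produced because
  selection is by the |r| threshold rule.
* Ward tie-breaking is inherited from the linkage traversal; data with
  exactly duplicated lines may order ties differently than a smallest-index
  rule.
* The chi-square/Monte-Carlo test conditions on the partition; it does not
  account for the signature-selection step (see the circularity note).
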