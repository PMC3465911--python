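# Methods

## Dissimilarity representation

Objects of any type are represented by their distances to an ordered set of
prototypes Π = {P_1 … P_p} drawn from the dataset: phi(X) = [d(X, P_1), …,
d(X, P_p)]. The distance d must be symmetric with d(X, X) = 0 but is *not*
required to be metric; the projected space always carries the Euclidean
metric, so downstream learners operate on a true metric space even when d
violates the triangle inequality. Registered distances: correlation
distance 1 − r(a, b) (bounded in [0, 2], rejected for constant vectors, the
convention for volumetric data) and Euclidean distance (tabular and binary
sources, including the batch-encoding source).

Prototypes are selected by farthest-first traversal: the first uniformly at
random (seeded), each next one the unselected object maximizing the **sum**
of distances to the already selected set. The classical k-center variant
(maximize the **minimum** distance) is available via
`fft_select(..., criterion="maxmin")`; the sum criterion is the default
because it is the variant this workflow is defined with. Ties resolve to
the lowest dataset index, making selection bit-reproducible from (dataset
order, seed).

Embedding faithfulness is the Pearson correlation r between d(X, X′) and
‖phi(X) − phi(X′)‖ over all unordered pairs (population covariance; a
seeded subsample beyond a 50 000-pair cap keeps the cost quadratic-bounded).
`select_num_prototypes` returns the smallest grid value reaching r ≥ 0.85
(the working default; the full (p, r) curve is returned alongside), falling
back to the argmax when the threshold is unattainable. In the experiment
pipeline p defaults to 40 per source.

Inside cross-validation, prototypes are selected **per fold from training
recordings only**. Selecting them once globally would leak test information
into the representation; the leakage-free reading is the default and the
global variant is available explicitly (`prototypes="global"`) for
comparison. The prototype audit (which recording ids served as prototypes
in each fold) is part of every result row.

## Batch-effect model and encoding

Two batch levels are modelled: acquisition site and subject identity
(subjects may contribute several recordings). Each recording is encoded as
a binary vector of length S + N — site block first — with exactly two ones.
The encoding depends only on (site, subject), is injective across
(site, subject) pairs, and uses first-appearance roster order so positions
are deterministic. Treated as a data source ("batch-effect source"), this
vector lets the classifier — and hence the independence test — reveal how
much apparent class signal is reachable from batch membership alone.

## Cross-validation schemes

* `recording_kfold` — stratified k-fold over recordings (k = 10 default).
  Class counts per fold differ by at most one from proportionality.
  Subjects and sites may straddle train/test *by design*: this is the
  biased baseline.
* `subject_kfold` — stratified k-fold over subjects. Train = all
  recordings of training subjects; test = exactly one recording per test
  subject, drawn uniformly (seeded) when the plan is built, removing
  dependence between test examples. Subject stratification by class is
  retained for comparability with the recording-level scheme and recorded
  in the plan metadata.
* `leave_one_site_out` — one fold per site, one recording per test
  subject. No subject and no site straddles train/test.

A class with fewer members than k fails loudly rather than silently merging
folds. Plans serialize to JSON and are validated by an invariant audit
(disjointness at the appropriate levels, ≤ 1 test recording per subject).

## Classifier stage

Extremely randomized trees (scikit-learn `ExtraTreesClassifier`), 500 trees
by default, `max_features="sqrt"`, fixed seed. The family is insensitive to
monotone feature rescaling, so dissimilarity features need no
normalisation. The algorithm, tree count and seed are recorded in every
result row so reported numbers are attributable. No hyperparameter search
is performed (out of scope).

## Bayesian test of independence

For a c×c confusion matrix y (rows = true class, columns = predicted,
m = Σy), the test compares the unrestricted multinomial model (H1) against
the independence model θ_ij = α_i β_j (H0), both with uniform Dirichlet
default priors. H1 carries an intrinsic prior: a mixture of Dirichlet
posteriors over hypothetical training tables x of size t, weighted by the
null prior predictive of x, which concentrates the alternative prior
around the null and makes the Bayes factor well calibrated. Marginalizing
in closed form gives, for square tables,

    B10(y, t) = Γ(t + c²) / Γ(t + m + c²) · Γ(m + c)² / Γ(t + c)²
                · Σ_x  t!/Πx_ij! · Π_i r_i(x)! Π_j c_j(x)!
                       / (Π_i r_i(y)! Π_j c_j(y)!)
                       · Π_ij (x_ij + y_ij)! / x_ij!
                · ((t + 1)/2)^((c−1)²/2)

with r_i, c_j row/column sums, the sum running over all c×c tables x with
grand total t. The reported statistic is ln B10(y) = min over t ∈ {0..m} —
the most conservative member of the intrinsic-prior family. At t = 0 the
intrinsic construction reduces to the default-prior Bayes factor.

The trailing ((t+1)/2)^((c−1)²/2) term — exponent equal to half the test's
degrees of freedom — is a calibration factor identified when validating
this implementation against published reference values of the statistic on
the same confusion matrices; with it, reference rows whose minimum sits at
t = 0 are matched exactly (to the printed precision) and rows minimized at
large t agree closely. Only c = 2 is exercised by validation;
`calibrated=False` disables the factor.

### Monte Carlo evaluation

The sum over x is estimated by importance sampling with M draws (default
1000; the acceptance script uses 3000). All factorials are evaluated via
log-gamma and the average via log-sum-exp; nothing is ever exponentiated on
the natural scale. Two proposals are available:

* `"reference"` — x ~ Multinomial(t, θ̂), θ̂_ij = (y_ij + 1)/(m + c²), the
  defining form of the approximation. Its weights grow heavy-tailed as t
  approaches m, where the estimator can underestimate the sum badly (a
  log-sum-exp of underdispersed weights is biased low).
* `"mixture"` (default for t ≥ 30) — half the draws from the reference
  proposal, half from Multinomial(t, q) with q centred on the integer mode
  of the summand (found by hill climbing). The mixture density is used in
  the weights, so the estimator remains unbiased for the sum while the
  variance collapses: at M = 1000 it tracks exact dynamic-programming
  evaluations of the sum to within ±0.05 across the full t range, where
  the reference proposal can be off by several nats.

A delta-method standard error of the log estimate is available
(`return_se=True`). The t = 0 case is computed exactly (single term).

### Scan over t

For m ≤ 200 the scan is exhaustive. Above that, a coarse grid (~40 points,
denser near 0 where weak-evidence curves attain their minimum) is refined
by repeated bisection around the running minimizer until the bracketing
points are within 2 of each other, verifying the minimum is locally stable.
The full evaluated curve, the minimizing t*, M and the seed are part of the
result object.

## Synthetic data generator

Feature vector of recording r of subject j (class y_j) at site s:

    x_r = δ·y_j·u + u_s + v_j + ε_r

with u the all-ones direction (or a seeded sparse subset via
`sparse_fraction`), u_s ~ N(0, σ²_site I), v_j ~ N(0, σ²_subj I),
ε_r ~ N(0, σ²_ε I). Class labels are Bernoulli per subject with per-site
prevalence; recordings per subject are uniform on 1..k_max. Defaults — 8
sites × 30 subjects, prevalence 0.38, k_max 3, 40 features, σ_site 1.0,
σ_subj 0.5, σ_ε 1.0 — mirror the clustered, class-unbalanced structure of
pooled multi-site cohorts (hundreds of subjects across ~8 sites, 62%/38%
class split, 1–6 recordings per subject) at a size where a full
cross-validated experiment runs in seconds. `generate_volumes` embeds the
same features into seeded voxel positions of 3D volumes (background zero),
so the volumetric preprocessing path can be tested round-trip.

What the generator does *not* emulate: spatial autocorrelation and brain
geometry, realistic fMRI time series, motion artefacts, site differences in
covariance (site effects are mean shifts only), and label noise. Passing
tests therefore demonstrate the *logic* of the workflow — leakage, batch
confounding, evidence calibration — not performance on real acquisitions.

## Volume preprocessing

Structural-style maps: Gaussian smoothing ("3-voxel" parameter interpreted
as FWHM in voxel units, σ = 3/2.3548, reflect padding), 2×2×2 block-mean
downsampling (ceil sizes; partial blocks averaged over available voxels),
then a group mask retaining voxels non-zero in ≥ 5% of volumes (inclusive
boundary; built on the downsampled volumes), then row-major flattening of
retained voxels. fMRI-derived maps use the same mask rule without
smoothing/downsampling; "no activity across 95% of subjects" and "non-zero
in at least 5%" are treated as the same retention rule. Phenotypic and
motion tables are z-scored with the population (divide-by-n) deviation;
constant columns map to zeros rather than NaN.

## Numerical and design choices

* Population covariance throughout (z-scores, Pearson r).
* FFT ties → lowest index; argmax over floats relies on exact equality of
  tied distances, which holds for the mirrored-point constructions used in
  validation.
* Confusion-matrix convention: rows = true, columns = predicted; binary
  tables map (TP, TN, FP, FN) to [[TN, FP], [FN, TP]] with class 1 = patient.
* Both aggregate accuracy (trace/m of the summed matrix) and mean-over-fold
  accuracy are reported; they differ when fold sizes differ.
* Multi-source runs concatenate per-source dissimilarity blocks in declared
  order; the order is recorded in the report sidecar.
* Every stochastic step (cohort generation, fold assignment, per-subject
  test-recording choice, prototype seed, tree ensemble, Monte Carlo) is
  controlled by an explicit seed, and end-to-end runs are bit-reproducible
  from the seed tuple.

## Known limitations

* The calibration factor of the Bayes factor is validated only for 2×2
  tables; c > 2 is supported by the contracts but the calibration exponent
  (c−1)²/2 is an untested extrapolation there.
* The t-scan's coarse-to-fine refinement assumes the per-t curve is
  unimodal up to Monte Carlo noise; all observed curves are, but a
  pathological multimodal curve could in principle hide a lower minimum
  between coarse grid points.
* `leave_one_site_out` requires every site to contain at least one subject
  of each class for the classifier stage to be trainable on the complement;
  degenerate single-class sites fail loudly at the classifier.
* The generator's site effects are homoscedastic mean shifts; real site
  differences also change covariance and scale.
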