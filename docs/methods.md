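# Methods

`cvsig` implements an integrative analysis linking perturbation
transcriptomics signatures to cell viability: consensus signature
construction, signature–viability matching, ridge cell-viability-signature
(CVS) models with cross-screen transfer, de-confounded mechanism-of-action
(MoA) similarity, screen-wide toxicity classification, and
consensus-signature drug-sensitivity machine learning.  Every stage is
exercisable end-to-end on a synthetic-data generator with planted ground
truth, so the whole pipeline is testable without any external download.

## The model

The central object is a *cell viability signature*: a direction in
landmark-gene expression space along which perturbation signatures move when
the perturbed cells die or stop proliferating, largely independently of the
perturbing agent (compound or shRNA).  Operationally the CVS is the
coefficient vector β of a ridge regression

    y = X β + b,        minimize ‖y − Xβ − b‖² + α‖β‖²,  α = 1.0

where X holds replicate-collapsed differential-expression z-scores
(instances × landmark genes) and y the matched viability outcome.  Two
viability metrics coexist and are deliberately **not** rescaled to each
other: fraction viability from compound screens (≈1 for inert treatments)
and shRNA abundance log fold change from pooled knockdown screens (≈0 for
non-essential genes, negative for essential ones).  Because evaluation uses
only the Pearson correlation between predicted and observed viability, a
model trained on one metric can be scored on the other; the cross-metric,
cross-screen transfer is the substantive claim the pipeline tests.

Features are not standardized before the ridge fit: landmark z-scores are
already on a shared scale.  The intercept is fitted and unpenalized.

### MODZ consensus

Signatures of the same condition, or all signatures of one compound, are
collapsed by a moderated z-score: compute the pairwise Spearman correlation
matrix of the members, set the diagonal to 0 *first*, then clamp negative
entries to 0.01, take row sums as weights, normalize to sum 1, and average.
The clamping order matters only in documentation — a negative diagonal
cannot occur — but the code applies it exactly in that order.  Pathological
cases: a single member passes through with weight 1; a constant member has
undefined Spearman correlations, which are treated as the clamp value 0.01
with a warning; an all-anticorrelated group degenerates to equal weights.

### Matching

A viability record (cell line, perturbagen, dose) is paired, per signature
measurement time, with the signature instance of the same cell and
perturbagen whose dose is nearest on the log10 scale, accepted iff
|Δ log10 dose| < 0.2 (strict; ≈1.5-fold).  shRNA records match on the exact
(cell, perturbagen) key.  One viability value may serve signatures at
several times — the viability assay has a single time point while
expression is profiled repeatedly — and the matched dataset is split by
time afterwards.  Ties in |Δ log10| break by lower signature dose, then
lexicographic instance id, making matching deterministic and
order-independent.

### Validation

Random sub-sampling: 20 iterations; within-dataset runs fit on a random
half and score the disjoint half; across-dataset runs fit on a random half
of the training set and score **all** of the test set.  Iteration *i* uses
seed + *i*.  The across-dataset training half is resampled every iteration
(the spread of transfer estimates is part of the result).

### De-confounding MoA similarity

Cell death inflates the pairwise similarity of signatures from unrelated
toxic compounds, confounding similarity-based MoA discovery.  The module
measures this with pair groups (nontoxic pairs sharing an MoA label vs
toxic pairs with disjoint labels vs all remaining pairs, in any-cell and
same-cell scopes), where "toxic" comes from a 2-component Gaussian mixture
on viability values: the nontoxic component is the one with the larger
mean, and the threshold is its mean − 2 SD (≈0.8 when the nontoxic mode is
N(1.0, 0.1²)).  Two removal strategies are provided: dropping the *n* genes
with the largest |Pearson r| to viability — with the statistics computed on
the *shRNA* screen while similarity is computed on the *compound* screen,
so no information leaks from the data being de-confounded — and per-gene
residualization of expression on viability.  MoA prediction is evaluated by
ROC/PR over consensus-signature pair similarities, with structure
(Tanimoto) and sensitivity-profile similarities as comparators and a
z-normalize-then-sum fusion rule.

### Screen-wide toxicity and the external benchmark

A fitted CVS model applied to a chemical screen yields per-instance
predictions; per compound, the minimum and maximum prediction at the
compound's own highest tested dose separate general toxicity (both extremes
low) from selective toxicity (only the minimum low).  Default thresholds
−3 / 1.5 are on the shRNA log-fold-change scale (5th/95th percentiles of
that screen's viability values) and only apply to predictions of
LFC-trained models; a percentile mode computes thresholds from any supplied
vector.  The external benchmark mimics discovery screens that report a
sensitivity concentration capped at the maximal tested concentration:
delta = metric − max tested (log10), delta < 0 ⇔ effective; per (cell,
compound) the *lowest* prediction is the target score for ROC analysis.

### Drug-sensitivity machine learning

Random-forest regression (50 trees) predicts per (cell, drug) sensitivity
(AUC; ln IC50 accepted) from concatenated cell features (tissue one-hot +
weighted-gene-set activities over per-gene-standardized baseline
expression, Z_gc = (E_gc − μ_g)/σ_g) and one drug-feature variant
(nominal-target one-hot, targeted-pathway one-hot, fingerprint bits, or
PCA scores of MODZ consensus signatures, ≤40 components at 95% explained
variance).  Drugs split 50/50 under three schemes: random; shared target
(every test drug has a same-target train partner); different target (no
target spans folds, via connected components of the shares-a-target
graph).  The consensus PCA is fit on training-fold drugs only — fitting on
all drugs would leak fold information through the projection.  Performance
is the per-cell Pearson correlation on test drugs, averaged over cells,
across 20 resampled runs; cells with fewer than 3 test drugs are excluded
from a run's average, and constant predictions (e.g. all-zero one-hots for
unseen targets) leave r undefined rather than faked.

## The synthetic world

`synthetic_data` plants every latent the analysis is supposed to recover:

* a unit-norm loading vector **w** supported on 30% of the G = 300 genes —
  the true CVS.  Death moves compound signatures by −g(τ)·κ·f·**w**
  (κ = 3.0; f the logistic kill fraction) and shRNA signatures by
  g(τ)·LFC·κ′·**w** (LFC ≤ 0), so both screens share one axis and transfer
  is true in the world and falsifiable by the model;
* MoA vectors m_k (orthogonalized against **w**, amplitude 1.0) shared by a
  class, plus a per-drug idiosyncratic component (amplitude 1.5) standing
  in for off-target profiles.  Without the idiosyncratic term, within-class
  consensus similarity saturates and MoA prediction is trivially perfect;
  real drug classes are heterogeneous, and the chosen 1.0/1.5 split keeps
  consensus MoA ROC well away from both 0.5 and 1.0;
* per-cell offset vectors (per-gene SD 0.15), reused in baseline
  expression, small enough that the leading principal component of the
  signatures is the viability axis rather than cell identity;
* logistic dose–response with width 0.3 log10 units over doses
  {0.37, 1.1, 3.3, 10} μM; fraction viability 1 − f + noise (SD 0.05)
  clipped at 0, recorded at a single assay time.  By default potency is a
  class property (classes 0..K/2−1 potent near 1 μM, the rest inert near
  300 μM).  `toxicity_spanning_config` instead draws every drug's log10
  IC50 from N(0.9, 1.25²), so toxicity spans classes — the regime in which
  cell death genuinely confounds MoA similarity, used by the de-confounding
  analyses;
* time maturation g(τ) = 0.2/0.5/1.0 at 3/6/24 h (1.0 at all shRNA times),
  reproducing the weakness of early-time viability prediction;
* shRNA essentiality (40% essential, depletion depth ≈ N(2.0, 0.6²),
  clipped ≥0), a knockdown dip of 2.0 z-units at the target gene, LFC noise
  SD 0.1;
* baseline latents: per-cell CVS propensity ρ_c entering baseline
  expression as ρ_c·**w**; doubling time 40 − 5ρ_c + tissue effect + noise;
  GLDS offsets correlated 0.5 with ρ_c; a sensitivity table
  AUC = 0.7 + GLDS_c − 0.3·toxicity(p) + 0.08·affinity(c, class(p)) + noise
  (SD 0.05), where toxicity(p) is the mean top-dose kill fraction;
* TF regulons partially aligned with **w** whose planted mean essentiality
  is proportional to that alignment, plus decoy gene sets; ECFP-like
  fingerprints as per-class prototype bits with per-drug flips (p = 0.05).

All randomness derives from per-entity sub-streams of one seed
(`SeedSequence(seed, spawn_key=...)`), so adding entities does not shuffle
existing draws and a fixed seed fixes every downstream number.

Sign conventions worth stating once: death lowers expression along +**w**
in both screens, so the per-gene correlation between expression and
viability is sign-aligned with **w**, the signed-weight score of the
planted axis on those statistics is strongly *positive*, the ridge β is
aligned with +**w**, and the projection of signatures on **w** correlates
*positively* with viability.  The PC1 orientation rule (loading points
toward the mean signature of the lowest-viability decile) therefore yields
a *negative* PC1–viability Spearman correlation.

### What the generator does and does not emulate

It reproduces the statistical skeleton the analysis relies on — a shared
viability axis, class-structured MoA components, cell offsets, dose
response, two unrescaled viability metrics, time maturation, and
baseline/sensitivity couplings — at desk scale (300 genes, 12 cells, 60
compounds, 150 shRNAs; thousands of matched pairs rather than tens of
thousands).  It does not emulate gene-regulatory structure, realistic
chemistry, batch/plate effects, probe-level noise, off-target shRNA seed
effects, or tissue ontology.  Passing tests therefore demonstrate that the
*procedures* recover planted structure under the assumed generative model,
not that real screens satisfy those assumptions.

## Numerical choices

* Spearman ties: average ranks throughout.
* Ridge solver: direct (Cholesky) for determinism; row order cannot affect
  the solution.
* Zero-variance genes: correlation statistics record r = 0 with a flag;
  z-normalization maps constant genes to 0 (0/0 guarded).
* Silhouette: direct implementation of (b − a)/max(a, b) with Euclidean
  distances; singleton clusters score 0.
* GLDS: two-way additive least squares with sum-to-zero constraints on
  both factors; cell effects are identified only up to the absorbed
  intercept (any common shift of the table leaves them unchanged).
* Gaussian-mixture threshold: 2 components, 10 restarts, seeded;
  degenerate fits (components within half the larger SD, or near-constant
  input) fall back to the fixed 0.8 threshold with a warning.
* Similarity fusion normalization: z-score of off-diagonal entries.
* ROC/PR: threshold sweep with tied scores grouped, trapezoidal AUCs; the
  ROC AUC equals the tie-aware concordance (U-statistic) probability.
* FDR: Benjamini–Hochberg.
* Gene-removal ties (equal |r|): broken by gene id.

## Problem sizes

Tests and the reproduction script run the default 300 × 12 × 60 × 150
world: matched datasets of 2 880 compound and 1 800 shRNA rows per time
point, 20-iteration validations, 1 770 consensus drug pairs, and 20-run
random-forest comparisons.  The full test suite completes in a couple of
minutes on one CPU; the reproduction script in well under a minute.

## Known limitations

* The CVS here is strictly linear; saturation of death transcriptional
  programs is not modelled.
* The generator's MoA classes are balanced and disjoint; real target
  annotations overlap and are long-tailed, which weakens both
  shared-target splitting and pair-group definitions in ways the synthetic
  tests cannot probe.
* The permutation set-score is a stand-in for external enrichment engines;
  equivalence with any particular published enrichment statistic is not
  claimed, and gene-level statistics are exported in ranked TSV form for
  those tools instead.
* One-hot drug features give constant predictions for fully unseen
  targets, leaving per-cell correlations undefined; reports record these
  as missing rather than zero, which slightly flatters one-hot features in
  averages (only defined runs contribute).
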