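# Methods

This note documents the statistical models behind `pneumobiome`, the
defaults they ship with, and what the synthetic-data tests do and do
not demonstrate about real cohorts.

## Problem setting

The package analyzes the relationship between rectal microbiota
composition and systemic innate-immune function in a hospital cohort
design: patients sampled at admission (e.g. for community-acquired
pneumonia, CAP) and again one month later, plus a control group.  The
microbiota observation is a genus-level 16S count table; immune
function is a panel of cytokine and degranulation-product
concentrations measured after *ex vivo* stimulation of monocytes and
neutrophils (or in serum).  Upstream read processing (ASV inference,
taxonomy, tree building, decontamination) is out of scope: the package
starts from the count table, a rooted genus-level phylogeny, clinical
metadata and the analyte panel.

## Community metrics

**Alpha diversity.**  Shannon index H = −Σ pⱼ ln pⱼ in nats (the vegan
convention) and observed richness (taxa with non-zero counts).  Both
are computed on unrarefied counts by default; rarefaction is applied
separately where the mixture model requires it (below).

**Rarefaction** subsamples each sample without replacement to a common
depth (multivariate hypergeometric), dropping samples below the target
depth.  The default target is the minimum retained depth after a
1000-read floor; both floor and target are configurable.

**UniFrac.**  Beta diversity is weighted or unweighted UniFrac over
the supplied phylogeny, computed through scikit-bio.  Weighted UniFrac
defaults to the normalized [0, 1] variant, with the raw branch-length
weighted variant behind a flag; normalization is a monotone rescaling
per pair and does not change PCoA or PERMANOVA rank behavior, so
either choice supports the same inferences.

**PCoA** is classical metric scaling: eigendecomposition of the
Gower-centered squared-distance matrix, coordinates scaled by
√eigenvalue.  Negative eigenvalues (UniFrac matrices are generally
non-Euclidean) are discarded without Lingoes/Cailliez correction;
variance proportions are taken over the positive part of the spectrum,
and a warning flag is set when the most negative eigenvalue exceeds 5%
of the largest positive one.  This is the simplest defensible
treatment and matches how the ordination is consumed downstream (a
fixed number of leading axes).

## Dirichlet-multinomial mixture clustering

Each community cluster k is a Dirichlet distribution over taxon
proportions with parameters α_k > 0; counts are multinomial given the
proportions, so the per-cluster marginal is Dirichlet-multinomial
(DM).  The mixture is fit by EM:

* E-step: responsibilities ∝ π_k · DM(x_i | α_k), evaluated via
  log-gamma throughout.
* M-step: π_k = mean responsibility; α_k by responsibility-weighted
  fixed-point iteration on the digamma stationarity condition, a
  lower-bound ascent, so the observed-data log-likelihood is monotone
  non-decreasing across EM iterations (asserted in tests to 1e-8
  relative slack).

Clustering operates on genus-level rarefied counts by convention.
Initialization is a k-means split of relative-abundance profiles plus
uniform jitter; 5 random restarts by default (local optima are the
main failure mode of DM mixtures).  A component whose weight falls
below 1/(10n) is re-seeded from the worst-fit samples (logged).
Convergence tolerance 1e-6 relative log-likelihood, max 500
iterations; non-convergence is flagged on the result rather than
raised.  Hard labels are argmax responsibilities with ties broken
toward the lower component index.

**Model selection** uses a Laplace approximation of the negative log
model evidence, evaluated in the log α parameterization (positivity by
construction):

−log Z ≈ −[log p(data | α*) + log p(α*) + (d/2) ln 2π − ½ ln det H]

with d = K·T free Dirichlet parameters (T taxa), H the Hessian of the
negative log posterior at the EM mode, and a weakly-informative
N(0, 10²) prior on each log α entry.  The Hessian is evaluated with
responsibilities frozen at their converged values, which makes it
block-diagonal across components and analytic (digamma/trigamma
terms); mixture weights enter as plug-in estimates.  A block that is
not positive definite falls back to its diagonal with a warning.
Lower evidence is better; `select_k` takes the minimum over seeds per
K and the argmin over K.

**Robustness** follows a leave-one-group-out design: samples are
randomly split into 10 groups; for each group the mixture is refit on
the remaining ~90%, and every held-in sample's refit label is compared
with its full-data label after optimal (Hungarian) label matching.
Each sample is therefore re-clustered n_folds − 1 = 9 times: 115
samples yield 1035 held-in assignment events and 84 yield 756, an
arithmetic identity of the design that the tests check exactly.

## PERMANOVA

Distance-based variance partitioning follows McArdle–Anderson: with
G = −½ J D² J the Gower-centered inner-product matrix and H the hat
matrix of a design block, the block's sum of squares is tr(HG).
Sequential mode attributes SS in term order (term + residual R² sum to
1 exactly); marginal mode tests each term given all others.  Pseudo-F
compares per-df explained SS to residual SS; significance permutes
sample labels (rows and columns of G jointly) with the add-one
convention p = (1 + #{F* ≥ F}) / (1 + n_perm), so p is never 0 and
never below 1/(n_perm + 1).  For small n an exhaustive mode enumerates
all n! − 1 non-identity permutations, which makes the reported p equal
to exact enumeration over distinct relabelings.  Zero-SS terms are
assigned F = 0 and a zero residual (perfect fit) yields F = ∞ so the
degenerate noiseless case behaves correctly.  Default 9999
permutations for covariate partitions.

The confounder-adjusted community test uses marginal mode (the disease
term tested given age, sex, comorbidities and prior antibiotics);
single-covariate partitions fit each covariate alone.

## Cytokine variance explained

The community is summarized by the first 4 principal coordinates of
the (weighted UniFrac) distance matrix.  Per analyte, the
one-dimensional Euclidean distance matrix of the analyte values is
submitted to a sequential PERMANOVA with the 4 ordered coordinate
vectors as terms (999 permutations), and the R² of axes with p < 0.2
is summed; the result is reported as a percentage.  For 1-D Euclidean
distances G = ỹỹᵀ is rank one, so each axis R² coincides with its OLS
increment (verified to 1e-8 in tests), and the permutation loop uses
quadratic forms in the permuted response — algebraically identical to
permuting G and much faster.  Permutations shuffle the response;
axes stay fixed.  Constant or all-missing analytes return 0 with a
flag.  The statistic is non-decreasing in the inclusion threshold and
returns the full 4-axis R² sum at alpha = 1.

Two properties matter for interpretation.  First, the per-axis
inclusion rate under the null equals the threshold (0.2) by
construction — the statistic is calibrated but not unbiased: included
axes are selected for large R², so small-cohort estimates are inflated
by roughly the null axis R² scale 1/(n−1) per included axis.  Second,
comparisons between conditions (e.g. admission vs follow-up) are
therefore made at matched n wherever possible, via the rank-sum (or
signed-rank, if paired) test on per-analyte percentages.

## Group comparisons and butyrate scoring

Cluster-wise analyte comparisons use the two-sided Wilcoxon rank-sum
test (exact null for combined n ≤ 25 without ties, tie-corrected
normal approximation otherwise).  Covariate adjustment fits a linear
model of the (rank-transformed by default; log or identity
configurable) response on cluster + age + sex and reports the partial
F-test p for the cluster term next to the unadjusted p.  No
multiple-testing correction is applied by default (uncorrected p <
0.05 convention); Benjamini–Hochberg is available but off.

The butyrate-producer score is the per-sample summed relative
abundance over a configurable reference list of butyrate-producing
genera (the packaged default list of 17 genera is editable text;
studies should substitute their own list).  The score depends only on
proportions, hence is sequencing-depth invariant.  Associations with
analytes use Spearman correlation with average-rank ties; the
two-sided p is an exact permutation enumeration for n ≤ 9 pairs and
the t approximation otherwise.

## Analyte censoring

Values above an analyte's upper limit of quantification are set to the
upper limit; values below the lower detection limit are set to half
the lower limit.  The operation is idempotent and preserves panel
shape; missing values remain missing (never silently zero).  Numeric
limits are study-specific configuration — no defaults are assumed.

## Synthetic cohort generator

The generator is first-class, tested code that provides ground truth
for every downstream stage.  It emulates:

* **Two metacommunities.**  "Undisrupted" (component A): Dirichlet
  weight spread over Bacteroides-like commensals and butyrate
  producers (α ≈ 2–3 on ~22 genera) → high Shannon diversity and high
  butyrate score.  "Disrupted" (component B): weight concentrated on 5
  peptococci-like genera (α = 8 each, near-zero elsewhere) → low
  diversity, low butyrate mass.  The ~100× odds separation on dominant
  genera is a documented constant chosen so the mixture is cleanly
  identifiable at the default depth; it makes recovery tests sharp but
  is far easier than borderline real cohorts.
* **Design.**  Default 60 admission patients (half disrupted), a
  seeded 40-patient follow-up subset (patients keep their component),
  and 50 controls drawn from component A — 150 samples over 50 genera.
  Read depths are lognormal with median 10,000 (sd 0.35 on the log).
* **Timepoint-dependent coupling.**  Analyte panels (20 analytes
  mirroring a monocyte/neutrophil stimulation panel) are linear
  functions of the standardized leading PCoA axes plus unit Gaussian
  noise.  Admission coupling is zero; month coupling defaults to
  per-analyte explained-variance fractions spanning 0–15%, bracketing
  the weak-coupling regime rather than reproducing any particular
  cohort.  Values are shifted by a 4-total-sd baseline and clipped at
  the assay floor of 0 (clipped fraction logged; negligible at the
  defaults).
* **Clinical metadata** with plausible prevalences (elderly patients,
  more comorbidity and prior antibiotics in the disease group) — used
  for interface exercise and confounder-adjustment tests, not fit to
  any cohort.

One global seed is split into per-stage substreams
(`numpy.random.SeedSequence.spawn`), so each stage is individually
reproducible and the whole cohort is byte-identical across reruns.

What passing tests do **not** show: real 16S data have compositional
artifacts, contamination, taxonomic misassignment, overdispersion
beyond DM, covariate-correlated missingness and far weaker cluster
separation.  Recovery at the default separation demonstrates
correctness of the machinery, not expected performance on borderline
communities.

## Simulation sizes used by the checks

The statistical acceptance checks run at sizes chosen to make the
Monte Carlo error small relative to the tolerance being asserted while
keeping the default suite in the minutes range:

* DMM recovery and fold concordance: the default 150-sample cohort,
  10 selection runs.
* Null variance explained: 100 replicate datasets of n = 200 with 30
  independent analytes, 999 permutations — at this n the null
  inflation per included axis (~1.6/(n−1)) keeps the median below 1%.
* Signal recovery: n = 200, 30 analytes at 50% true explained
  variance, after a noiseless fully-explained baseline.
* PERMANOVA: exact enumeration at n = 6; 200 null replicates at
  n = 20 with 199 permutations for type-I calibration.

## Known limitations

* The Laplace evidence treats mixture weights as plug-in values and
  freezes responsibilities in the Hessian; this is the standard
  approximation for DM mixtures but not a full marginal likelihood.
* PCoA discards the negative eigenvalue mass rather than correcting
  for it.
* The variance-explained statistic inherits the upward selection bias
  discussed above; cross-timepoint comparisons at very different n
  should be read cautiously.
* Missing analyte values are dropped pairwise throughout; there is no
  imputation.
* The exact Spearman permutation enumerates n! orderings and is
  restricted to n ≤ 9.
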