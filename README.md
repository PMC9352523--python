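# pneumobiome

Analysis pipeline linking rectal microbiota composition to
innate-immune cytokine responses in hospitalized-pneumonia cohorts:
alpha diversity and UniFrac/PCoA ordination, PERMANOVA variance
partitioning, unsupervised Dirichlet-multinomial mixture (DMM)
clustering with Laplace-approximation model selection and
leave-one-group-out robustness, and a per-analyte
microbiota-variance-explained statistic — plus a synthetic cohort
generator with known ground truth so every stage has recovery tests.

It is written for microbiome researchers working with genus-level 16S
count tables, a rooted phylogeny, clinical metadata and Luminex-style
analyte panels.

## The statistics at the core

**DMM clustering.**  Each metacommunity k is a Dirichlet distribution
over taxon proportions (parameters α_k > 0) and counts are multinomial
draws, so clusters have Dirichlet-multinomial marginals.  Fitting is
EM with responsibility-weighted digamma fixed-point updates for α.
The number of clusters is chosen by minimizing a Laplace approximation
of the negative log model evidence in the log α parameterization:

    −log Z ≈ −[log p(x|α*) + log p(α*) + (d/2)·ln 2π − ½·ln det H]

Robustness uses 10-fold re-clustering: refit on 90% of samples, and
compare every held-in sample's label (after optimal matching) with the
full-data clustering; n samples yield exactly 9n held-in comparisons.

**PERMANOVA.**  Distance variance is partitioned over covariates via
the Gower-centered matrix G = −½JD²J; a term's SS is tr(HG), pseudo-F
is tested by permutation with p = (1+#{F* ≥ F})/(1+n_perm), with exact
enumeration available at small n.  Sequential term R² plus residual R²
sum to 1 exactly.

**Variance explained.**  The community is reduced to the first 4
principal coordinates of the weighted UniFrac matrix; per analyte a
sequential PERMANOVA of the 1-D analyte distance matrix on those axes
is run and the R² of axes with permutation p < 0.2 is summed.  For
1-D Euclidean distances this equals the OLS R² contribution of each
axis.

## Worked example

```python
import numpy as np
from pneumobiome.cohort import CohortConfig, generate_cohort
from pneumobiome.diversity import default_rarefaction_depth, rarefy, unifrac
from pneumobiome import dmm
from pneumobiome.association import cytokine_variance_explained

cohort = generate_cohort(CohortConfig(seed=42))   # 150 samples, 50 genera
adm = cohort.counts["admission"]

rare = rarefy(adm, default_rarefaction_depth(adm), seed=42)
best_k, evidence = dmm.select_k(rare, range(1, 4), seeds=3)
print("best K:", best_k)
print("negative log evidence:", {k: round(v, 1) for k, v in evidence.items()})

model = dmm.fit_dmm(rare, best_k, seed=42)
labels = dmm.hard_assignment(model)
print("cluster sizes:", np.bincount(labels.labels)[1:].tolist())

conc = dmm.reclustering_concordance(rare, best_k, n_folds=10, seed=42)
print(f"concordance: {conc.concordance_pct:.1f}% "
      f"({conc.n_discordant}/{conc.n_assignments} discordant)")

d = unifrac(cohort.counts["month"], cohort.tree)
res = cytokine_variance_explained(d, cohort.responses["month"], seed=42)
print(f"median explained at month: {res.explained_pct.median():.1f}%  "
      f"(max {res.explained_pct.max():.1f}%)")
```

Output:

```
best K: 2
negative log evidence: {1: 14436.0, 2: 13040.8, 3: 13157.1}
cluster sizes: [30, 30]
concordance: 100.0% (0/540 discordant)
median explained at month: 11.1%  (max 31.2%)
```

Reading it: the Laplace evidence (lower is better) picks two
metacommunities, matching how the cohort was generated (half of the 60
admission patients draw from a disrupted, low-diversity community);
the 10-fold refits never move a sample between clusters (540 = 60 × 9
held-in comparisons); and at the follow-up timepoint — where the
generator couples analytes to the community ordination — the median
analyte has ~11% of its variance attributable to the leading UniFrac
axes.  At admission the same statistic is near zero by construction.

## Command line

```
pneumobiome simulate  --config cohort.yaml --seed 0 --out data/
pneumobiome diversity --table data/counts_admission.tsv --metric shannon --out shannon.tsv
pneumobiome diversity --table data/counts_admission.tsv --tree data/tree.nwk \
                      --metric unifrac-w --out dist.tsv
pneumobiome permanova --dist dist.tsv --meta data/metadata.csv \
                      --terms group,age,sex --perms 9999 --out permanova.tsv
pneumobiome dmm fit   --table data/counts_admission.tsv --k 1..5 --out model.json
pneumobiome dmm stability --table data/counts_admission.tsv --k 2 --folds 10
pneumobiome varexp    --dist dist.tsv --panel data/panel_month.csv \
                      --analytes data/analytes_month.csv --out varexp.tsv
pneumobiome correlate --table data/counts_month.tsv --panel data/panel_month.csv \
                      --analytes data/analytes_month.csv --out corr.tsv
pneumobiome run-all   --config run.yaml --out results/
```

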