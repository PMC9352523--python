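# Full-pipeline configuration (see pneumobiome.pipeline.RunConfig).
out_dir: results/run
seed: 0
simulate:            # cohort overrides; omit for the 150-sample default
  n_admission: 60
  n_month: 40
  n_controls: 50
rarefaction_floor: 1000
unifrac_weighted: true
unifrac_normalized: true
k_range: [1, 2, 3, 4]
dmm_seeds: 3
n_folds: 10
n_axes: 4
varexp_alpha: 0.2
varexp_perm: 999
permanova_perm: 9999
permanova_terms: [group, age, sex, prior_antibiotics]
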