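# plscorr

Two-block partial least squares (PLS) correlation analysis for
brain–behavior data, with resampling inference and a synthetic cohort
generator for end-to-end testing.

The pipeline: age-residualize the brain block, z-score both blocks, correlate
every brain column with every behavior column, and decompose the resulting
cross-correlation matrix by SVD into latent variables (LVs). Each LV pairs a
brain weight pattern, a behavior weight pattern, and a singular value whose
squared share is the covariance explained. Inference covers:

- **permutation tests** on the singular values (behavior rows shuffled,
  preprocessing re-applied, add-one p-values);
- **bootstrap resampling** for feature reliability — bootstrap ratios
  (weight / bootstrap SE, reliable at |BSR| > 1.96) and percentile intervals
  for loadings (reliable when the interval excludes zero);
- **cross-validation** with repeated random 75/25 splits (100 by default):
  preprocessing and decomposition fit on train only, held-out subjects
  projected, out-of-sample score correlation reported per split, with an
  optional permutation p-value for the mean.

Downstream clinical utilities: Welch t and chi-square cohort descriptives,
diagnostic-subtype contrasts on LV scores, and the partial correlation of
baseline LV scores with follow-up severity controlling for baseline severity.
The synthetic module plants a sparse low-rank cross-block covariance in a
cohort shaped like the study sample (91 ED = 61 EDr + 30 EDbp, 48 HC, 65
brain ROIs, 38 behavior measures, follow-up for 72 ED subjects) and returns
the ground truth for recovery benchmarking.

## Command line

```bash
# generate a synthetic cohort (three CSVs + ground-truth sidecar)
pls synth --seed 1 --out data/

# full analysis: preprocess -> SVD -> permutation/bootstrap/CV -> clinical
pls run --brain data/brain.csv --behavior data/behavior.csv \
        --meta data/metadata.csv --out-dir results/ --seed 1

# markdown report from a results directory
pls report results/

# individual clinical analyses
pls descriptives --brain ... --behavior ... --meta ... --out desc.csv
pls subtypes     --brain ... --behavior ... --meta ... --lv 1 --out sub.csv
pls prospective  --brain ... --behavior ... --meta ... --lv 1 --score-type brain
```

Inputs are comma-separated UTF-8 text with a header row; the first column of
every file is `subject_id`. The metadata file needs columns `age`, `group`
(ED/HC), `subtype` (EDr/EDbp, blank for HC), `ede_baseline`, `ede_followup`
(blank if missing). Analysis knobs (permutation/bootstrap/split counts, seed,
BSR threshold, analysis group, …) live in a YAML config passed via
`--config`; defaults are in `plscorr.AnalysisConfig`.

## Library use

```python
from plscorr import (AnalysisConfig, SyntheticSpec, generate_dataset,
                     fit_preprocess, cross_correlation, decompose, run_inference)

ds, truth = generate_dataset(SyntheticSpec(seed=0))
ed = ds.ed_subset()
Zx, Zy, model = fit_preprocess(ed)
dec = decompose(cross_correlation(Zx, Zy), Zx, Zy,
                roi_names=ed.roi_names, behavior_names=ed.behavior_names)
inf = run_inference(ed, dec, AnalysisConfig(n_permutations=999, n_bootstraps=500,
                                            n_cv_null=0, seed=0))
```

## Notes

- Permutation p-values compare sorted singular values rank-for-rank by
  default. Procrustes-rotating the permuted structure onto the observed LVs
  is available (`rotate_permutation`) but is strongly anticonservative under
  a true null and therefore off.
- Bootstrap draws are aligned to the original decomposition by a
  signed-permutation match (sign + order), not a free orthogonal rotation:
  free rotation deflates bootstrap SEs and inflates false-positive
  reliability flags. `bootstrap_align="rotation"` restores the free rotation
  if wanted.
- All resampling derives from independent child streams of one seed;
  identical config + seed reproduces every output byte-for-byte.
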