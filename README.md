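# faskel

Single-subject classification and voxelwise group inference on skeletonized
white-matter fractional-anisotropy (FA) maps.

## What this is for

In diffusion-tensor imaging studies of psychiatric disorders, each subject's
white matter is summarized by an FA image projected onto a common tract
skeleton (FA > 0.2). Two complementary questions are asked of such data:

1. **Can individual patients be told apart from matched controls?**
   A linear support vector machine (SVM) on the skeleton voxels,
   `min (1/2)||w||² + C Σᵢ max(0, 1 − yᵢ(w·xᵢ + b))` with C = 1, is
   evaluated by *matched-pair leave-two-out cross-validation*: each fold
   holds out one patient and their age/sex-matched control, so a cohort of
   n pairs yields exactly n folds. Accuracy is the number of correctly
   classified test subjects over all subjects, and its significance is the
   proportion of label permutations whose rerun cross-validation beats the
   observed value. The SVM weight vector, rendered back onto the skeleton,
   maps which regions drive the decision, and Platt scaling
   `p(f) = 1/(1 + exp(Af + B))` turns decision values into posteriors that
   can be correlated with clinical variables (PANSS symptom scores,
   chlorpromazine-equivalent dose). Kernel ridge regression
   (`α = (K + λI)⁻¹y`) tests whether those clinical variables are
   predictable from the FA pattern itself.
2. **Where does FA differ between groups?** A voxelwise two-sample t map is
   enhanced with threshold-free cluster enhancement,
   `TFCE(v) = Σ_h e_v(h)^E · h^H · dh` (E = 0.5, H = 2), and family-wise
   error is controlled at p < 0.05 by the permutation distribution of the
   image-wide maximum enhanced statistic.

Because matched DTI cohorts are rarely shareable, the package ships a
synthetic-cohort generator with known ground truth — a connected thinned
skeleton, matched pairs, a contiguous FA reduction in patients, and clinical
scores with controllable coupling to the images — so the entire chain is
testable end to end and recovery can be scored against the true effect mask.

Audience: methods researchers and students who need a transparent,
dependency-light reference implementation of this analysis chain, not a
replacement for FSL/TBSS tooling on real data.

## Worked example

```python
from faskel import (CohortSpec, generate_skeleton_template, generate_cohort,
                    run_lto_cv, permutation_test)

template = generate_skeleton_template((20, 20, 20), fill_fraction=0.1, seed=1)
cohort = generate_cohort(template, CohortSpec(n_pairs=40, seed=7))

report = run_lto_cv(cohort)
print(report.percent("accuracy"), report.percent("sensitivity"),
      report.percent("specificity"))
res = permutation_test(cohort, n_perm=200, seed=7, add_one=True)
print(round(res.p_value, 4))
```

prints

```
97.5 95.0 100.0
0.005
```

40 matched pairs with a 0.05 FA reduction over 20% of an 800-voxel skeleton
(noise SD 0.02) are almost perfectly separable: 78 of 80 subjects are
classified correctly out of fold, and none of the 200 label permutations
reaches the observed accuracy (add-one p = 1/201 ≈ 0.005).

The same pipeline is scriptable from the shell:

```bash
faskel simulate   --config config.yaml
faskel classify   --config config.yaml
faskel clinical   --config config.yaml
faskel groupstats --config config.yaml
faskel report     --config config.yaml
```

See `faskel <cmd> --help`; every run writes a JSON manifest with the exact
parameters and seeds used.

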