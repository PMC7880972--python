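# t1liver

Whole-liver T1-map histogram/texture analysis for stratifying the risk of
advanced fibrosis in fatty liver disease — reimplemented as a fully
synthetic, testable pipeline:

1. **synthetic** — liver-shaped phantoms (correlated T1 fields, vessels,
   B1 gradient, forward-simulated SPGR magnitude pairs, auto-placed seed
   points) and clinical cohorts with a known latent risk label.
2. **t1map** — B1-corrected variable-flip-angle T1 fitting (exact
   two-point DESPOT1-style linearisation; invalid voxels flagged).
3. **segment** — seeded random-walker segmentation on the 6-connected
   voxel graph, manual mask refinement, mask propagation to the T1 grid.
4. **features** — 8 histogram parameters plus 4 texture parameters
   (entropy, contrast, diff-entropy, diff-variance) from a pooled
   symmetric 3D gray-level co-occurrence matrix over 13 unit offsets.
5. **clinical** — NFS and FIB-4 scores, LSM reliability rule, and the
   two-step (blood test first line, elastography second line)
   low / intermediate / high stratification.
6. **stats** — Shapiro-Wilk-gated univariate comparison, stepwise binary
   logistic regression, ROC with maximal-Youden cutoffs and DeLong
   variance, paired DeLong AUC comparison, Hosmer-Lemeshow calibration,
   and two-way mixed-model ICC.
7. **pipeline** — orchestration with a config hash manifest, stage
   caching, and report tables (univariate / ROC / DeLong / model).

## CLI

Every stage is exposed under one entry point:

```sh
t1liver simulate-phantom --config phantom.json --out phantom_dir/
t1liver simulate-cohort  --config cohort.json  --out cohort.csv
t1liver fit-t1   --low spgr_low.nii.gz --high spgr_high.nii.gz \
                 --b1 b1_map.nii.gz --tr 4.61 --flips 3 15 --out t1.nii.gz
t1liver segment  --image spgr_high.nii.gz --seeds seeds.csv --out mask.nii.gz
t1liver extract  --t1 t1.nii.gz --mask mask.nii.gz --out feats.csv
t1liver stratify --cohort cohort.csv --out risk.csv
t1liver analyze  --features feats.csv --risk risk.csv --out report/
t1liver run      --config run.json --out run_dir/
```

Volumes are NIfTI-1; seeds are CSV of 0-based `x,y,z,label` voxel indices
(label 1 = foreground); cohorts/features/risk are CSV; reports are
CSV + JSON.

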