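# dcx — resting-state degree centrality and expertise classification

`dcx` is a tested re-implementation of a resting-state fMRI analysis used
to ask whether domain-specific visual expertise (the model system:
radiology interns vs. matched controls, 22 per group) reshapes intrinsic
brain network hubs. It covers the full chain from BOLD time series to the
published-style outputs:

1. **Temporal preprocessing** — dropping the first volumes, Friston-24
   head-motion and global/WM/CSF nuisance regression, linear detrending,
   and an ideal (DFT-mask) 0.01–0.08 Hz bandpass; optional isotropic
   Gaussian smoothing.
2. **Degree centrality (DC)** — for every voxel (or ROI) *i*,

   `DC(i) = Σ_{j≠i}  w(r_ij) · [ r_ij > 0.2 ]`

   where `r_ij` is the Pearson correlation of the two time series and the
   default edge weight is the Fisher transform `w(r) = atanh(r)` (raw-`r`
   and binary-count variants are available). Each subject's map is
   divided by its whole-brain mean and averaged within the parcels of an
   atlas (~246 regions), giving one DC feature vector per subject.
3. **Classification** — two-stage feature selection (per-feature
   two-sample *t* filter at p < 0.05, then contribution-guided recursive
   feature elimination scored by leave-one-out SVM accuracy) feeding a
   soft-margin linear SVM, evaluated by nested leave-one-out
   cross-validation with accuracy, sensitivity, specificity, ROC and a
   pair-counting AUC. Positive SVM weights mean higher DC in the
   expertise group.
4. **Statistics** — Mann–Whitney U behavioral group comparisons and
   per-ROI Pearson DC–behavior correlations with Benjamini–Hochberg FDR.

Because the original imaging data are not publicly deposited, the package
ships a first-class **synthetic cohort generator**: a modular Gaussian
vector-AR(1) process whose group correlation matrices carry planted,
signed node-level ("degree") effects at seven designated ROIs, plus
behavioral scores whose expertise measure is coupled to a designated
fusiform-analog ROI's DC. Every downstream stage is tested against this
generator; see `docs/methods.md` for the model and its limits.

## Worked example

```python
from dcx import SimConfig, simulate_cohort, nested_evaluate, default_planted_effects
from dcx.config import RunConfig
from dcx.pipeline import cohort_features

sim = SimConfig(n_per_group=22, n_rois=50, n_modules=5,
                planted_effects=default_planted_effects(50, magnitude=0.12), seed=42)
cohort = simulate_cohort(sim)
feats = cohort_features(cohort, RunConfig())
rep = nested_evaluate(feats.values.to_numpy(), feats.binary_labels("expertise"),
                      feature_names=feats.roi_names)
print(rep.accuracy_pct, rep.sensitivity_pct, rep.specificity_pct, rep.auc)
```

prints `100.0 100.0 100.0 1.0`: with moderate planted effects
(correlation deltas of ±0.12 at 7 of 50 ROIs) the nested LOOCV separates
the groups perfectly. The descriptive consensus-weight table recovers all
seven planted regions with the planted signs (positive weight = higher DC
in the expertise group):

```
SFG_R_7_6 -0.36   OrG_R_6_4 -0.32   FuG_L_3_3 +0.31   SFG_L_7_7 +0.26
MFG_L_7_7 -0.23   PhG_L_6_1 -0.22   PhG_R_6_4 -0.15   (+ 6 noise ROIs, |w| ≤ 0.15)
```

and the behavioral expertise score separates the groups
(`Mann–Whitney U = 484, p = 1.4e-08`).

The same analysis runs from the shell:

```bash
dcx run-all --seed 42 --out out/          # simulate + preprocess + DC + classify + stats
dcx simulate --seed 7 --out sim/ --mode voxel   # write NIfTI + TSV cohort artifacts
dcx classify --features out/features.tsv --labels out/participants.tsv --out report.json
```

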