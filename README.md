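# locrad

Local first-order parametric-map radiomics and two-group lesion
discrimination, built for the problem of telling locally recurrent
rectal cancer (LRRC) apart from post-treatment scar on CT and FDG-PET.
After rectal-cancer surgery, recurrence and fibrotic scar look alike
even to expert readers; the quantitative signature of recurrence is
*local* tissue inhomogeneity, which plain whole-ROI statistics miss.

`locrad` is a library for researchers reproducing or extending this
style of analysis: it turns a masked 3D lesion volume into texture
features and runs the complete univariate discrimination study, and it
ships a calibrated synthetic phantom generator so every stage can be
exercised and validated without patient data.

## Method

For a lesion ROI in a volume *f* with voxel values in HU (CT) or SUV
(PET):

1. **Local maps.** Every in-ROI voxel *v* gets a square in-plane window
   W(v) whose pixel side is the smallest odd integer covering a fixed
   physical extent (5 mm CT, 10 mm PET, floor 3 px). Twelve first-order
   statistics of {f(u) : u in W(v)} — mean, median, kurtosis, skewness,
   entropy, uniformity, IQR, CV, SD, MAD, and the mean/median of the
   last decile — yield 12 parametric maps on the ROI support.
2. **Aggregation.** The pooled all-slice distribution of each map is
   summarised with the same 12 statistics: 144 features keyed
   `<MAP>-<STAT>`, e.g. `S-MAD` = MAD of the local-skewness map,
   `K-M90th` = median of the last decile of the local-kurtosis map.
3. **Discrimination.** Features are z-scored; an L1-penalized binomial
   model with 5-fold-CV penalty choice at minimum weighted deviance
   (samples weighted by class prior) screens the table; surviving
   features are ranked by two-sided Wilcoxon rank-sum p with
   Holm-Bonferroni adjustment and reported with group variances, ROC
   AUC with a stratified bootstrap 95% CI, and the Youden operating
   point: sensitivity SN, specificity SP, informedness
   I = SN + SP − 1.

See `docs/methods.md` for conventions, the phantom texture model, and
known limitations.

## Worked example

```sh
python examples/04_discrimination_study.py
```

runs the full study on a 30 vs 30 phantom cohort with a strong planted
heterogeneity effect and prints (abridged):

```
modality CT: 30 LRRC vs 30 NO LRRC
LASSO selected 15 of 144 features

 Rank        RF   AUC    SN    SP     I     p  p (Holm)
    1       U-S 0.957 0.933 0.867 0.800 0.000     0.000
    2     S-MAD 0.887 0.600 1.000 0.600 0.000     0.000
    ...
```

`S-MAD` — the dispersion of local skewness, the feature this analysis
style singles out for recurrent tissue — ranks near the top (here
second, AUC 0.887, Holm-significant): recurrence phantoms mix regions
of mostly-higher and mostly-lower local values, so their local-skewness
map spreads while scar phantoms stay tight. I is always exactly
SN + SP − 1 for the reported Youden point. Other
examples cover ROI proposal by fractional-SUVmax thresholding (01),
parametric maps (02), cohort feature tables (03), and null-cohort
behaviour (05).

The same stages are scriptable from a shell:

```sh
locrad generate --out cohort/ --modality PET --n-pos 33 --n-neg 24 --effect 1 --seed 7
locrad extract --manifest cohort/manifest.csv --modality PET --out features.csv
locrad discriminate --features features.csv --out run/ --seed 7
```

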