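# echodsi

Multiparametric ("disease-specific imaging") characterization of breast
lesions in ultrasound. Conventional B-mode reading of breast lesions is
qualitative; this package extracts quantitative biophysical features from the
raw echo data within a segmented lesion, combines them into a single
malignancy score, and renders the score as a per-pixel probability-of-
malignancy color overlay on the B-mode image. It is written for quantitative-
ultrasound researchers who have beamformed RF frames and lesion contours and
want a reproducible, testable analysis chain — including a seeded synthetic
RF cohort generator so the whole pipeline runs without patient data.

## The analysis

From an RF frame (samples × scanlines, with sampling/center frequency and
pixel pitches) and a lesion contour, nine candidate features are computed:

| feature | source | what it measures |
|---|---|---|
| H-scan color level, STD | attenuation-corrected RF | local spectral content via a 256-filter Gaussian matched-filter bank (peaks 5.2–12.4 MHz); proxies effective scatterer scale |
| boundary shape dA/A | contour | convex-hull area excess `(hull − A)/A`; boundary spiculation |
| B-scan intensity, STD | log-compressed envelope | lesion echogenicity and texture |
| boundary intensity, STD | log-compressed envelope | texture over inner+outer margin bands (erosion/dilation with a disk, total band width 10% of the lesion length) |
| Burr λ, b | envelope | speckle amplitude statistics under the Burr law `P(A) = 2A(b−1)/(λ²[(A/λ)²+1]^b)` |

The default selected subset {H-scan color level, dA/A, B-scan STD, boundary
STD, Burr b} is combined, after per-feature standardization, by three
scalar scores:

* **PC1** — first principal component, oriented malignant-positive;
* **projection** — inner product with the unit benign→malignant centroid
  direction;
* **SVM distance** — signed decision value of a Gaussian-kernel SVM
  (`sign · distance`; sign = predicted class −1/+1, magnitude = confidence),
  hyperparameters chosen by seeded 5-fold cross-validation.

A score is clipped between training percentiles and mapped linearly to a
probability of malignancy; within the lesion, the H-scan color level (the
only localized feature) is substituted per pixel, the map is median+Gaussian
smoothed, and the result is blended over B-mode with a light-blue→red
colormap. Evaluation follows a repeated-splits protocol: five seeded
stratified 70/30 train/test partitions, AUC with DeLong 95% CI, operating
metrics at a training-frozen Youden threshold, per-feature one-way ANOVA,
and lesion-size-threshold stratification (strictly `area > A` for A = 0.0,
0.1, …, 1.0 cm²). See `docs/methods.md` for assumptions and numerical
choices.

## Worked example

```python
from echodsi import CohortSpec, DSIModel, generate_cohort, roc_auc
from echodsi.evaluation import SplitPlan, evaluate_cohort
from echodsi.features import SELECTED_FEATURES, cohort_feature_table

cohort = generate_cohort(CohortSpec(n_benign=15, n_malignant=15, seed=42))
table = cohort_feature_table(cohort)
y = table["label"].to_numpy()

model = DSIModel(feature_names=list(SELECTED_FEATURES), seed=0)
model.fit(table[list(SELECTED_FEATURES)], y)
print(model.contributions_)
rep = evaluate_cohort(table, y, plan=SplitPlan(), seed=0)
print(rep.summary[rep.summary["set"] == "test"])
```

On this strong-effect synthetic cohort the feature table separates the
classes completely — the first rows look like

```
   case_id  label  hscan_color_level  boundary_shape  bscan_std  boundary_std  burr_b
benign_000     -1             84.623           0.038     28.640        31.341   2.592
benign_001     -1             95.547           0.030     26.989        30.819   2.897
```

(benign lesions: low color level ≈ 85–95 from their 8.5 MHz content, smooth
boundaries dA/A ≈ 0.03, Burr b ≈ 2.6–2.9; malignant lesions sit near color
level 140, dA/A ≈ 0.8, b ≈ 1.6). The PC1 contributions come out nearly even,

```
{'hscan_color_level': 0.203, 'boundary_shape': 0.200, 'bscan_std': 0.206,
 'boundary_std': 0.198, 'burr_b': 0.194}
```

because every feature separates the classes strongly, and all three combined
scores reach test AUC 1.000 ± 0.000 and accuracy 1.000 over the five splits
— the expected pattern when effect sizes are deliberately large. The
per-feature ANOVA prints `****` (p < 0.0001) for all nine features. The
selected SVM hyperparameters here are box 0.1, gamma 0.01 (the smoothest
plane that survives cross-validation).

A command-line interface mirrors the library:

```sh
echodsi simulate --config cohort.yaml --out cohort/ --seed 7
echodsi features --cohort cohort/ --out features.csv
echodsi train --features features.csv --scorer svm_distance --out model.json
echodsi bmode --in cohort/benign_000.h5 --alpha 1.0 --out bmode.png
echodsi evaluate --features features.csv --out report/ --by-size
```

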