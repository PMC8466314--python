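# compoct

**CT body composition at L3: U-Net ensemble segmentation, muscle and
adipose indices, and the survival analysis they feed.**

A single axial CT slice at the third lumbar vertebra (L3) predicts
whole-body muscle and fat mass, and two scalars derived from it carry
prognostic weight in oncology: the skeletal muscle index
SMI = muscle area / height² (cm²/m²) and the muscle attenuation
MA = mean muscle HU (low MA — *muscular hypodensity* — indicates fatty
muscle infiltration).  Measuring them by hand requires a trained
operator per slice, which is why automatic segmentation matters.

`compoct` implements the full measurement chain for researchers who
want to study, extend, or stress-test it without access to patient
data:

* **`compoct.phantom`** — synthetic L3 slices with pixel-perfect tissue
  labels: an elliptical torso with a subcutaneous fat ring, a
  10-compartment muscle layout (8 wall/paraspinal sectors + 2 psoas),
  visceral fat with bowel gas, and a vertebral body; muscle area and
  mean attenuation are controlled exactly.
* **`compoct.groundtruth`** — ROI contours gated by the tissue
  Hounsfield windows (muscle −29…+150 HU, fat −190…−30 HU).
* **`compoct.ensemble`** — twelve independent U-Nets (one per ROI,
  6 resolution levels, Adam at initial lr 10⁻³), the pooled muscle
  mask, and Dice-based evaluation.  The networks are implemented
  directly on numpy and train on one CPU core.
* **`compoct.bodycomp`** — SMI, MA, VAT/SAT indices; sarcopenia
  (SMI < 55 ♂ / 39 ♀), hypodensity (MA below the sex-specific 10th
  percentile; reference cutoffs 26.7/23.1 HU), BMI classes.
* **`compoct.cohortsim`** — calibrated synthetic survival cohorts
  (exponential proportional hazards, competing risks, administrative
  censoring) for parameter-recovery testing.
* **`compoct.survstats`** — Kaplan–Meier + log-rank, Cox (Efron ties),
  Aalen–Johansen cumulative incidence with Gray's test, χ²/t
  comparisons, ROC-AUC screening.
* **`compoct.io` / `compoct.cli`** — DICOM/NIfTI ingestion (HU via
  rescale slope/intercept), mask serialization, an end-to-end pipeline
  with a hashed manifest, and the `compoct` command-line tool.

## Worked example

Train a small ensemble on synthetic phantoms and measure one patient:

```python
from compoct import (PhantomSpec, UNetConfig, PatientMeta,
                     generate_dataset, make_ground_truth,
                     train_ensemble, predict_masks, dice,
                     compute_indices, classify)

data = generate_dataset(12, seed=1)                      # (slice, labels) pairs
pairs = [(s, make_ground_truth(s, lab)) for s, lab in data]
ens = train_ensemble(pairs[:10], UNetConfig(max_epochs=20, seed=0))

slc, labels = data[10]
pred = predict_masks(ens, slc)                           # 12 gated masks
truth = make_ground_truth(slc, labels)
print(f"pooled muscle Dice: {dice(pred.muscle, truth.muscle):.3f}")

meta = PatientMeta(sex="male", height_m=1.79, weight_kg=80, age_years=52)
bc = classify(compute_indices(slc, pred, meta), meta)
print(f"SMI {bc.smi:.1f} cm2/m2, MA {bc.ma_hu:.1f} HU, "
      f"sarcopenic={bc.sarcopenic}, hypodense={bc.hypodense}")
```

Output of this exact script (the training takes a few minutes on one
CPU core):

```
pooled muscle Dice: 0.995
SMI 41.8 cm2/m2, MA 22.1 HU, sarcopenic=True, hypodense=True
```

A Dice of 0.995 means predicted and reference muscle masks overlap on
~99.5 % of their pixels.  SMI 41.8 is below the 55 cm²/m² male
threshold, so this phantom "patient" is classified sarcopenic, and its
MA of 22.1 HU falls below the 26.7 HU male hypodensity cutoff, so it is
also flagged hypodense — this particular phantom was drawn with a low
target muscle attenuation.

The same flow from a shell:

```sh
compoct simulate --n 20 --seed 1 --out phantoms/
compoct train --data phantoms/ --out models/ --max-epochs 20
compoct segment --model models/ --in phantoms/phantom_000.nii.gz --out masks.json
compoct simulate-cohort --n 656 --seed 1 --out cohort.csv
compoct analyze --cohort cohort.csv --endpoint os --covariates hypodense,obese
```

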