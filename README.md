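# morphorec

Regression-based reconstruction of missing 3D landmarks in geometric
morphometrics, with a seeded damage-simulation framework for quantifying
how accurate those reconstructions are.

Paleontologists, anthropologists and forensic scientists routinely work
with fragmentary bones. Given a reference sample of *complete* specimens,
the RM method estimates a damaged specimen's missing landmark
coordinates by multiple linear regression: after generalized Procrustes
alignment (and bending-energy sliding of surface semilandmarks), the
coordinates of the missing landmarks are regressed on the coordinates of
all present landmarks across the reference sample, and the damaged
specimen — superimposed on the reference consensus via its present
landmarks — is completed with the regression's predictions.

`morphorec` implements that pipeline end to end for landmark data (TPS or
wide CSV input; no meshes required), together with the study design that
measures its accuracy on a 30-landmark zygomatic scheme (7 fixed
landmarks, 23 surface semilandmarks): landmarks of a *complete* target
are deleted according to a damage scenario, re-estimated from the
remaining specimens, and compared with the truth via the partial
Procrustes distance

d(X, Y) = min over rotations R of ‖ X/‖X‖ R − Y/‖Y‖ ‖,

both configurations centered and at unit centroid size. Each simulated
target yields two distances: d(true, predicted), and d(true, reference
consensus) — the error one would make using the mean shape as a
template. Two-sample t-tests compare the two per damage case; one-way
ANOVA plus Tukey HSD compare reconstruction error across cases.

A seeded synthetic-data generator (smooth low-rank factor covariance,
population mean offsets, rigid-motion/scale nuisance, digitization
noise) makes the full study reproducible without any external dataset;
see `docs/methods.md` for the generative model and all numerical
choices.

## Worked example

```python
import morphorec as mr

model = mr.default_population_model(seed=0)
dataset = mr.generate_dataset(model, seed=0)     # 150 specimens, 3 populations
report = mr.DamageStudy(dataset, n_targets=30).run(seed=0)
print(report.summary())
```

prints

```
Reconstruction accuracy study
==================================
Case 1: mean d(true, predicted) = 0.0158, mean d(true, mean shape) = 0.0616, t = -25.47, p = 9.95e-26
Case 2: mean d(true, predicted) = 0.0193, mean d(true, mean shape) = 0.0619, t = -17.56, p = 5.85e-21
Case 3: mean d(true, predicted) = 0.0314, mean d(true, mean shape) = 0.0624, t = -12.03, p = 6.82e-17
ANOVA across cases: F(2,87) = 50.49, p = 2.78e-15
Tukey Case 1 - Case 2: diff = -0.0035, p = 0.0851
Tukey Case 1 - Case 3: diff = -0.0156, p = 1.11e-14
Tukey Case 2 - Case 3: diff = -0.0121, p = 2.17e-10
```

Reading: in every damage case the regression completion is several times
closer to the true shape than the mean-shape template is (strongly
negative t), so the method genuinely exploits inter-landmark covariation
rather than shrinking to the average. Accuracy worsens as the damaged
region grows — the six-landmark body case (Case 3) is clearly separated
from the two small cases by Tukey HSD, while the 2- and 3-landmark cases
(Case 1 vs Case 2) perform alike.

The damage cases are named 1-based landmark sets; the defaults are
Case 1 = {1, 2} (incomplete temporal process), Case 2 = {4, 5, 7}
(damaged orbit), Case 3 = {16–21} (incomplete zygomatic body). Any
`CaseDefinition` works, and `population_filter="Italian"` restricts the
whole study to one subsample.

To reconstruct a single specimen:

```python
reference = dataset.drop("Italian_007")
aligned = mr.slide_semilandmarks(mr.gpa(reference))
results = mr.MissingLandmarkModel(aligned, missing_indices=(4, 5, 7)).fit()
completed, transform = results.impute(
    mr.DamagedConfiguration(dataset.get("Italian_007"), (4, 5, 7))
)
restored = transform.invert(completed.coords)   # back in specimen space
```

The same operations are available from the shell:

```
morphorec simulate --out data.csv --seed 42
morphorec impute --data data.csv --missing 4,5,7 --target Italian_007 --out completed.csv
morphorec run --data data.csv --n-targets 30 --seed 42 --out report/
```

`run` writes `records.csv` (one row per simulated reconstruction),
`stats.json` (t/ANOVA/Tukey), and the scatter/violin plot data as CSV.

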