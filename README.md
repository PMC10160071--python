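# ramantda

Topological machine learning for the classification of Raman spectra of
chondrogenic bone tumours — grading enchondroma (EC, benign) against the
three chondrosarcoma grades (CS G1–G3) from baseline-corrected spectra in
the 400–1800 cm⁻¹ fingerprint region.

## Who this is for

Researchers in biomedical spectroscopy / computational pathology who want
a reproducible, patient-aware pipeline that turns 1-D spectra into
topological descriptors and selects the best {vectorization, classifier}
pair, plus a synthetic-cohort generator so every stage can be exercised
and validated without access to clinical data.

## The method

1. **Embedding.** Each spectrum is treated as a planar point cloud: one
   point (wavenumber, intensity) ∈ ℝ² per spectral sample (an
   index-based embedding and min–max axis normalization are available as
   options).
2. **Persistent homology.** The Vietoris–Rips filtration grows balls of
   radius *r* around the points; a *k*-simplex enters when all pairwise
   distances among its vertices fall below the scale. The homology
   classes that appear and disappear form the persistence diagram
   PD = {(birth, death)} in dimensions 0 (connected components) and 1
   (loops). H₀ deaths equal the Euclidean minimum-spanning-tree edge
   lengths of the cloud; H₁ intervals are computed by GF(2) reduction of
   the triangle boundary matrix (the small-instance brute-force oracle
   in `persistence.brute_force_pd` validates both).
3. **Vectorization.** Four fixed-length representations: persistence
   image (PI, bandwidth σ ∈ {0.1, 1, 10}, resolution n ∈ {5, 10, 25}),
   persistence landscape (PL), persistence silhouette (PS) and Betti
   curve (BC), each with n ∈ {25, 50, 75, 100}; under four homology
   fusions: H₀ only, H₁ only, H₀+H₁ pooled ("fused"), H₀ and H₁
   concatenated ("concat").
4. **Classification.** RBF support vector classifier with
   C ∈ {1, 2, 3, 5, 10, 20}, a 100-tree random forest, and a ridge
   classifier (α = 1). The grid search reports, per validation run, the
   best accuracy and the achieving method, and the best single method by
   mean accuracy.
5. **Validation.** Leave-one-patient-out (LOPO) cross-validation is the
   primary scheme — all spectra of one patient are held out per run, so
   the classifier cannot score by re-identifying patients. Shuffled
   ten-fold CV and a static patient split are provided for comparison,
   together with a six-fold data-augmentation recipe (additive Gaussian
   noise at two levels, ±5 cm⁻¹ calibration shifts, and their
   combinations), a no-TDA ablation (raw spectra into the same
   classifiers) and an unsupervised evaluation over ten clustering
   algorithms scored by optimal cluster-to-label assignment.

## Worked example

Train a binary (benign vs malignant) model on a synthetic 400-spectrum,
10-patient cohort with a moderate patient effect and predict a held-out
cohort of ten new patients, one spectrum each:

```bash
ramantda simulate --out train_cohort --seed 1 --patient-effect 0.05
ramantda simulate --out test_cohort --cohort holdout --seed 1 --patient-effect 0.05
ramantda predict --train-manifest train_cohort/manifest.csv \
                 --test-manifest test_cohort/manifest.csv \
                 --labels binary_ec_vs_cs \
                 --method PS --fusion fused --classifier random_forest
```

which prints

```
predicted labels: [1, 1, 1, 1, 0, 1, 0, 1, 1, 0]
true labels:      [1, 1, 1, 1, 1, 1, 0, 1, 1, 0]
accuracy: 90.00%
confusion matrix (rows=true, cols=pred):
[[2 0]
 [1 7]]
```

The held-out cohort's grades are (1, 2, 2, 1, 1, 2, 0, 3, 3, 0), which
the benign-vs-malignant relabelling maps to (1, 1, 1, 1, 1, 1, 0, 1, 1,
0); the confusion matrix counts true classes in rows — both benign
patients are recognised and one malignant patient is missed (a false
negative, the clinically costly error). The same library calls are
available in Python via `ramantda.fit_full` / `FittedModel.predict`.

A full grid search under LOPO:

```bash
ramantda grid --manifest train_cohort/manifest.csv --scheme lopo \
              --labels binary_ec_vs_cs --out results_lopo
```

writes `best_per_run.csv` (best accuracy and method per held-out
patient), `best_per_run_summary.csv` (mean ± std per fusion) and
`best_single_method.csv`.

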