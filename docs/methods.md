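# Methods

## The model

A Raman spectrum restricted to the fingerprint region (400–1800 cm⁻¹,
closed interval) is embedded as a planar point cloud with one point
(wavenumber, intensity) per sample. The Vietoris–Rips filtration over
the Euclidean metric yields a persistence diagram in homology dimensions
0 and 1; a lower-star filtration was not used because it produces no
H₁ classes for a 1-D signal. The diagram is vectorized (persistence
image, landscape, silhouette, or Betti curve) under one of four homology
fusions, and the vector is classified. Model selection is a grid search
over {vectorization × parameters × fusion × classifier}, scored under a
patient-aware validation scheme.

The default embedding uses raw (wavenumber, intensity) coordinates. The
relative scaling of the two axes is physically arbitrary and materially
changes Vietoris–Rips distances, so a min–max normalization of each axis
to [0, 1] and an index-based abscissa are exposed as options
(`embed_spectrum(mode=..., normalize=...)`) and can be included in the
grid.

## Persistence computation

* **H₀.** The finite H₀ deaths of a VR filtration are exactly the edge
  lengths of a Euclidean minimum spanning tree; they are computed by
  Kruskal's algorithm with union–find. Kruskal is written out (rather
  than delegated to a sparse-graph MST routine) so that zero-length
  edges between coincident points survive as explicit (0, 0) bars; all
  H₀ births are 0 and one essential bar remains.
* **H₁.** Triangle boundary columns are reduced over GF(2) against edge
  rows in filtration order (diameter, with ties broken by index). The
  reduction is compiled with numba over bit-packed (uint64) columns.
  The filtration is truncated at the *enclosing radius*
  min_i max_j d(x_i, x_j): beyond it the complex is a cone over the
  enclosing point and H₁ vanishes, so every cycle born later dies at its
  birth scale. Consequently H₁ pairs with death = birth are dropped from
  the diagram. This is also the principled choice: the zero-persistence
  multiset depends on the arbitrary ordering of equal-diameter
  simplices, while the positive-persistence diagram is the well-defined
  persistence of the diameter filtration; and zero-length intervals are
  invisible to every vectorizer in this package.
* **Oracle.** `brute_force_pd` enumerates the full complex up to
  dimension 2, orders simplices by (diameter, dimension, vertex tuple)
  and runs the textbook left-to-right column reduction on Python sets.
  It shares no code with the production path and is limited to 12
  points; tests assert multiset equality on hundreds of random clouds.

## Vectorizations

All four methods consume finite intervals only and sample n equally
spaced grid points including both endpoints. Ranges are fitted on
training diagrams only — [min birth, max death] for BC/PL/PS, the birth
range and [0, max persistence] for PI — and frozen before transforming
validation or test diagrams; out-of-range intervals are clipped to the
fitted range. This prevents train/test leakage through the sampling
domain, which matters under LOPO where the held-out patient's diagrams
can exceed the training range.

* **Betti curve:** β(t) = #{(b, d) : b ≤ t < d} (half-open convention,
  so a bar does not count at its death scale).
* **Landscape:** λ_j(t) = j-th largest tent value,
  tent_(b,d)(t) = max(0, min(t−b, d−t)); k = 5 landscapes by default.
* **Silhouette:** φ(t) = Σ w_i tent_i(t) / Σ w_i with w_i = (d_i−b_i)^p,
  p = 1 by default; an all-zero-persistence diagram yields the zero
  vector rather than a division error.
* **Image:** intervals map to (birth, persistence); each contributes a
  unit-mass isotropic Gaussian of bandwidth σ weighted linearly by
  persistence (0 at persistence 0, 1 at the fitted maximum — the
  weighting originally recommended for persistence images). Pixel
  values integrate the density by the midpoint rule × pixel area; the
  mass identity in the tests therefore holds to high accuracy once the
  pixel pitch is below σ, and the test tolerance (10⁻³) is set
  accordingly.

A fusion block with no finite training interval anywhere gets a unit
placeholder range and vectorizes to zeros; fitting fails only when *no*
block contains any interval. Degenerate fitted ranges (max ≤ min, e.g.
all-H₀ births) are widened by one unit.

## Classifiers and reporting

SVC uses the RBF kernel with one-vs-one multiclass (the library
default); the forest fixes 100 trees; "ridge regression" as a classifier
is the standard construction — labels one-hot encoded to ±1, linear
ridge fit with α = 1, prediction by argmax — i.e. scikit-learn's
`RidgeClassifier`. Per-run "best" tables take the maximum over methods
with ties broken by a canonical ordering (vectorization name, parameters,
classifier); mean ± std rows use the population standard deviation over
runs. A method that fails to fit on some run (e.g. an H₁ fusion on a
cohort without loops) is logged and excluded from the argmax rather than
scored 0.

Ten-fold cross-validation is shuffled but not stratified; the shuffle
seed is exposed. The static split trains on patients 1, 3, 5, 6, 8, 10
(1-based positions in cohort order) and tests on the rest.

Clustering accuracy uses the optimal one-to-one assignment of clusters
to classes on the contingency table (Hungarian algorithm); unmatched
clusters contribute zero, and a single-cluster outcome — flagged
degenerate — scores the majority-class frequency.

## Synthetic cohorts

The generator emulates baseline-corrected tissue spectra: each class is
a sum of Lorentzian lines (Gaussian optional) on a low-order polynomial
baseline. The four default profiles share eight bands at 856, 937,
1003, 1090, 1245, 1302, 1450 and 1660 cm⁻¹ with amplitude trends
monotone in grade (collagen-associated bands decreasing, phenylalanine
and nucleic-acid bands increasing with malignancy), so adjacent grades
differ least — matching the clinical observation that neighbouring
grades are hardest to distinguish. Intensities are in arbitrary units
with band heights of order 100–300 over a baseline of order 30.

Patient identity is modelled by effects drawn once per patient: a
multiplicative per-peak amplitude jitter (relative std
`patient_effect_std`, default 0.12), a global intensity scale (half that
relative std) and a per-band center offset (std 1.5 cm⁻¹). Per-spectrum
variation is additive white Gaussian noise (std 4 a.u.). With the
defaults, the patient effect is comparable to the between-class
amplitude contrast while within-patient noise is small — the regime in
which patient-naive ten-fold CV is optimistic and LOPO fold accuracies
are heterogeneous (folds whose training set contains a single patient of
the test class degrade sharply). That qualitative behaviour, not any
specific accuracy value, is what the pipeline tests assert on the
default cohort.

Two fixed cohort designs are provided: `study_cohort` (10 patients with
spectrum counts 32, 31, 37, 24, 38, 38, 50, 50, 49, 51 and grade labels
0, 0, 0, 1, 1, 1, 2, 2, 3, 3 — 400 spectra, EC = 25%) and
`holdout_cohort` (10 new patients, one spectrum each, grades
1, 2, 2, 1, 1, 2, 0, 3, 3, 0, drawn from a disjoint seed stream standing
in for a different acquisition session). `separable_cohort` keeps the
study composition but scales class amplitude deviations by 3 and lowers
the patient effect to 0.05: the well-separated regime used by the
recovery benchmark, where the best binary (EC vs CS) LOPO mean accuracy
is expected to exceed 0.9.

The default generation grid samples every 14 cm⁻¹ (101 points per
spectrum), enough to resolve the ≥ 25 cm⁻¹-wide bands the profiles use
while keeping the H₁ boundary reduction (quadratic in edges, cubic in
points) fast enough for cohort-scale studies; tests of pipeline
mechanics use coarser grids since they exercise bookkeeping, not
spectral realism. What the generator does **not** emulate: fluorescence
background and its correction residuals, cosmic-ray spikes, detector
shot-noise statistics, wavenumber-dependent instrument response, or
vendor differences between acquisition systems. Passing tests on
synthetic cohorts therefore demonstrate the pipeline's correctness and
its patient-aware behaviour, not clinical-grade accuracy on real
spectra.

## Augmentation

Five variants per spectrum (plus the original, a six-fold expansion):
small additive Gaussian noise (std = max(spectrum)/1000), unit-std
noise, a calibration shift uniform in [−5, 5] cm⁻¹, and the two
noise+shift combinations. The shift is continuous along the wavenumber
axis, implemented by linear re-interpolation onto the original grid with
boundary-value fill — chosen over integer-sample shifts because
calibration error is not quantized to the sampling step. One RNG stream
is derived per (spectrum, variant), so results are independent of
processing order, and max(spectrum) is taken per spectrum within the
analyzed range.

## Numerical choices and limitations

* Diagram comparisons in tests use multiset equality to 10⁻⁹ after
  sorting intervals.
* The brute-force oracle is O(n⁶) in the worst case and capped at 12
  points; the production H₁ path handles a few hundred points per cloud
  comfortably but is not intended for thousands (use coarser resampling
  first).
* Homology above dimension 1, non-Euclidean metrics, and filtrations
  other than Vietoris–Rips are out of scope.
* The acceptance script's grid runs use the reduced method grid (one
  resolution per vectorization, PI at σ = 1, SVC C ∈ {1, 10} plus the
  forest) and the H₀ and fused fusions: these are representative
  problem sizes chosen for routine desk-scale reproduction; the full
  grid is available through `default_method_grid` / `--full-grid`.
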