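"""Patient-aware model selection for topological spectrum classification.

The pipeline: spectra -> planar point clouds -> Vietoris-Rips persistence
diagrams -> vectorizations (PI/PL/PS/BC under four homology fusions) ->
classifier grid (RBF SVC over C, random forest, ridge classifier),
evaluated under one of three validation schemes:

* leave-one-patient-out (LOPO): one run per patient, all of that
  patient's spectra held out — the honest scheme when several spectra
  share a patient;
* shuffled ten-fold cross-validation, which ignores patient boundaries
  and therefore measures patient re-identification as much as class
  structure;
* a static split by patient position (train on patients 1, 3, 5, 6, 8,
  10; test on the rest).

For every (run, method) the vectorization sampling range and the
classifier are fitted on the training indices only.  Reporting follows
the two customary table shapes: the best accuracy per run (optionally
per homology fusion) with a mean +/- population-std row, and the best
single method by mean accuracy across runs.

The module also hosts the no-TDA ablation (raw interpolated intensity
vectors into the same classifier grid) and the unsupervised evaluation
(ten clustering algorithms scored by optimal one-to-one cluster-to-label
assignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn import cluster as skcluster
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import RidgeClassifier
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .io import RamanSpectrum, SpectraDataset, restrict_range
from .persistence import PersistenceDiagram, embed_spectrum, vietoris_rips_pd
from .vectorize import (
    CURVE_RESOLUTION_GRID,
    FUSIONS,
    PI_RESOLUTION_GRID,
    PI_SIGMA_GRID,
    VectorizationConfig,
    fit_value_range,
    vectorize,
)

__all__ = [
    "ClassifierSpec",
    "MethodSpec",
    "GridResult",
    "SVC_C_GRID",
    "default_classifier_grid",
    "default_method_grid",
    "reduced_method_grid",
    "compute_diagrams",
    "lopo_splits",
    "kfold_splits",
    "static_split",
    "run_grid",
    "accuracy",
    "confusion_matrix",
    "best_per_run",
    "best_per_run_summary",
    "best_single_method",
    "classify_without_tda",
    "cluster_eval",
    "FittedModel",
    "fit_full",
    "CLUSTER_ALGORITHMS",
]

logger = logging.getLogger("ramantda")

#: Regularization grid of the RBF support vector classifier.
SVC_C_GRID = (1.0, 2.0, 3.0, 5.0, 10.0, 20.0)
#: Static-split training patients, as 1-based positions in patient order.
STATIC_TRAIN_PATIENTS = (1, 3, 5, 6, 8, 10)


# ---------------------------------------------------------------------------
# Method grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier of the grid: RBF SVC, random forest, or ridge."""

    kind: str = "svc_rbf"
    C: float = 1.0
    n_trees: int = 100
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("svc_rbf", "random_forest", "ridge"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.C <= 0 or self.n_trees < 1 or self.alpha <= 0:
            raise ValueError("invalid classifier parameters")

    def build(self, seed: int = 0):
        """Instantiate the scikit-learn estimator."""
        if self.kind == "svc_rbf":
            return SVC(kernel="rbf", C=self.C, random_state=seed)
        if self.kind == "random_forest":
            return RandomForestClassifier(n_estimators=self.n_trees, random_state=seed)
        # ridge classification: labels one-hot encoded to +/-1, linear
        # ridge fit, prediction by argmax — RidgeClassifier's construction
        return RidgeClassifier(alpha=self.alpha)

    def key(self) -> tuple:
        return (self.kind, self.C if self.kind == "svc_rbf" else 0.0)

    def label(self) -> str:
        if self.kind == "svc_rbf":
            return f"SVC(C={self.C:g})"
        if self.kind == "random_forest":
            return f"RFC({self.n_trees})"
        return f"Ridge(alpha={self.alpha:g})"


@dataclass(frozen=True)
class MethodSpec:
    """A (vectorization, classifier) pair; vectorization=None means raw spectra."""

    vectorization: VectorizationConfig | None
    classifier: ClassifierSpec

    def key(self) -> tuple:
        vkey = ("raw",) if self.vectorization is None else self.vectorization.key()
        return (vkey, self.classifier.key())

    @property
    def fusion(self) -> str:
        return "raw" if self.vectorization is None else self.vectorization.fusion

    def label(self) -> str:
        v = "raw" if self.vectorization is None else self.vectorization.label()
        return f"{v} + {self.classifier.label()}"


def default_classifier_grid() -> list[ClassifierSpec]:
    """RBF SVC over the C grid, a 100-tree forest, and ridge with alpha=1."""
    grid = [ClassifierSpec("svc_rbf", C=c) for c in SVC_C_GRID]
    grid.append(ClassifierSpec("random_forest"))
    grid.append(ClassifierSpec("ridge"))
    return grid


def _vector_configs(fusions: Sequence[str], reduced: bool) -> list[VectorizationConfig]:
    configs = []
    for fusion in fusions:
        if reduced:
            configs += [
                VectorizationConfig("PI", resolution=10, sigma=1.0, fusion=fusion),
                VectorizationConfig("PL", resolution=25, fusion=fusion),
                VectorizationConfig("PS", resolution=25, fusion=fusion),
                VectorizationConfig("BC", resolution=25, fusion=fusion),
            ]
            continue
        for sigma in PI_SIGMA_GRID:
            for n in PI_RESOLUTION_GRID:
                configs.append(VectorizationConfig("PI", resolution=n, sigma=sigma, fusion=fusion))
        for method in ("PL", "PS", "BC"):
            for n in CURVE_RESOLUTION_GRID:
                configs.append(VectorizationConfig(method, resolution=n, fusion=fusion))
    return configs


def default_method_grid(fusions: Sequence[str] = FUSIONS) -> list[MethodSpec]:
    """The full search grid: every vectorization x fusion x classifier."""
    clfs = default_classifier_grid()
    return [MethodSpec(v, c) for v in _vector_configs(fusions, reduced=False) for c in clfs]


def reduced_method_grid(
    fusions: Sequence[str] = FUSIONS,
    classifiers: Sequence[ClassifierSpec] | None = None,
) -> list[MethodSpec]:
    """A small representative grid (one resolution per method) for quick runs."""
    if classifiers is None:
        classifiers = [ClassifierSpec("svc_rbf", C=1.0), ClassifierSpec("svc_rbf", C=10.0),
                       ClassifierSpec("random_forest")]
    return [MethodSpec(v, c) for v in _vector_configs(fusions, reduced=True) for c in classifiers]


# ---------------------------------------------------------------------------
# Diagrams for a whole cohort
# ---------------------------------------------------------------------------

def compute_diagrams(
    dataset: SpectraDataset,
    mode: str = "wavenumber_intensity",
    normalize: bool = False,
    restrict: tuple[float, float] | None = (400.0, 1800.0),
) -> list[PersistenceDiagram]:
    """Restrict, embed and compute the VR diagram of every spectrum."""
    out = []
    for s in dataset:
        if restrict is not None:
            s = restrict_range(s, *restrict)
        out.append(vietoris_rips_pd(embed_spectrum(s, mode=mode, normalize=normalize)))
    return out


# ---------------------------------------------------------------------------
# Validation splits
# ---------------------------------------------------------------------------

def lopo_splits(dataset: SpectraDataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-patient-out: one (train, test) split per patient, in order."""
    patients = dataset.patient_order
    if len(patients) < 2:
        raise ValueError("LOPO needs at least 2 patients")
    pid = np.asarray(dataset.patient_ids)
    splits = []
    for p in patients:
        test = np.flatnonzero(pid == p)
        train = np.flatnonzero(pid != p)
        splits.append((train, test))
    return splits


def kfold_splits(dataset: SpectraDataset, k: int = 10, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition that ignores patient boundaries."""
    n = len(dataset)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.arange(n))]


def static_split(
    dataset: SpectraDataset,
    train_patients: Sequence[int] = STATIC_TRAIN_PATIENTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Split by 1-based patient positions; listed patients train, rest test."""
    patients = dataset.patient_order
    for p in train_patients:
        if not 1 <= p <= len(patients):
            raise KeyError(f"patient position {p} outside 1..{len(patients)}")
    train_ids = {patients[p - 1] for p in train_patients}
    pid = np.asarray(dataset.patient_ids)
    train = np.flatnonzero(np.isin(pid, sorted(train_ids)))
    test = np.flatnonzero(~np.isin(pid, sorted(train_ids)))
    if test.size == 0 or train.size == 0:
        raise ValueError("static split leaves an empty train or test set")
    return train, test


# ---------------------------------------------------------------------------
# Elementary metrics
# ---------------------------------------------------------------------------

def accuracy(pred: Sequence[int], true: Sequence[int]) -> float:
    """Fraction of positions where pred equals true."""
    p, t = np.asarray(pred), np.asarray(true)
    if p.shape != t.shape or p.size == 0:
        raise ValueError(f"shape mismatch or empty: {p.shape} vs {t.shape}")
    return float(np.mean(p == t))


def confusion_matrix(pred: Sequence[int], true: Sequence[int], n_labels: int) -> np.ndarray:
    """Counts with entry (i, j) = #{true == i and pred == j}."""
    p, t = np.asarray(pred, dtype=int), np.asarray(true, dtype=int)
    if p.shape != t.shape:
        raise ValueError("pred and true must have the same shape")
    if p.size and (min(p.min(), t.min()) < 0 or max(p.max(), t.max()) >= n_labels):
        raise ValueError(f"labels outside [0, {n_labels})")
    cm = np.zeros((n_labels, n_labels), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass
class GridResult:
    """Accuracy per (run, method) under one validation scheme."""

    scheme: str
    methods: list[MethodSpec]
    accuracies: dict[tuple[int, tuple], float] = field(default_factory=dict)
    n_runs: int = 0

    def accuracy_of(self, run: int, method: MethodSpec) -> float | None:
        return self.accuracies.get((run, method.key()))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: run, fusion, method label, accuracy."""
        rows = []
        by_key = {m.key(): m for m in self.methods}
        for (run, key), acc in self.accuracies.items():
            m = by_key[key]
            rows.append({"run": run, "fusion": m.fusion, "method": m.label(), "accuracy": acc})
        return pd.DataFrame(rows).sort_values(["run", "fusion", "method"]).reset_index(drop=True)


def _method_order_key(m: MethodSpec) -> tuple:
    # canonical tie-break: vectorization name, parameters, then classifier
    return m.key()


def run_grid(
    diagrams: Sequence[PersistenceDiagram],
    labels: Sequence[int],
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    methods: Sequence[MethodSpec],
    seed: int = 0,
    scheme: str = "custom",
) -> GridResult:
    """Fit and score every method on every split.

    Per split, the sampling range of each distinct vectorization config
    is fitted on the training diagrams only; train and test diagrams are
    then transformed under the frozen config and each classifier is fit
    on the training vectors.  A method that fails to fit is logged and
    recorded as missing rather than crashing the grid.
    """
    if not methods:
        raise ValueError("methods must be nonempty")
    y = np.asarray(labels, dtype=int)
    if len(y) != len(diagrams):
        raise ValueError("labels and diagrams are not aligned")
    result = GridResult(scheme=scheme, methods=list(methods), n_runs=len(splits))
    by_vconfig: dict[tuple, list[MethodSpec]] = {}
    for m in methods:
        if m.vectorization is None:
            raise ValueError("run_grid expects vectorization methods; use classify_without_tda")
        by_vconfig.setdefault(m.vectorization.key(), []).append(m)
    vconfigs = {m.vectorization.key(): m.vectorization for m in methods}
    for run, (train, test) in enumerate(splits):
        for vkey, group in by_vconfig.items():
            vconfig = vconfigs[vkey]
            try:
                fitted = fit_value_range([diagrams[i] for i in train], vconfig)
                X = np.vstack([
                    vectorize(diagrams[i], fitted).values
                    for i in np.concatenate([train, test])
                ])
                Xtr, Xte = X[: len(train)], X[len(train):]
            except Exception as exc:  # noqa: BLE001 — record, don't crash the grid
                for m in group:
                    logger.warning("run %d: %s failed to vectorize: %s", run, m.label(), exc)
                continue
            for m in group:
                try:
                    clf = m.classifier.build(seed)
                    clf.fit(Xtr, y[train])
                    acc = accuracy(clf.predict(Xte), y[test])
                except Exception as exc:  # noqa: BLE001
                    logger.warning("run %d: %s failed to fit: %s", run, m.label(), exc)
                    continue
                result.accuracies[(run, m.key())] = acc
    return result


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def best_per_run(result: GridResult, by_fusion: bool = True) -> pd.DataFrame:
    """Best accuracy per run (and fusion), with the achieving method.

    Ties go to the first method in canonical order (vectorization name,
    parameters, classifier).
    """
    groups: dict[str, list[MethodSpec]] = {}
    for m in sorted(result.methods, key=_method_order_key):
        groups.setdefault(m.fusion if by_fusion else "all", []).append(m)
    rows = []
    for run in range(result.n_runs):
        for fusion, ms in groups.items():
            scored = [(result.accuracy_of(run, m), m) for m in ms
                      if result.accuracy_of(run, m) is not None]
            if not scored:
                continue
            best_acc = max(a for a, _ in scored)
            best_m = next(m for a, m in scored if a == best_acc)
            rows.append({"run": run, "fusion": fusion,
                         "accuracy": best_acc, "method": best_m.label()})
    return pd.DataFrame(rows)


def best_per_run_summary(per_run: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- population std of the per-run best accuracies, per fusion."""
    return (
        per_run.groupby("fusion")["accuracy"]
        .agg(mean="mean", std=lambda s: float(np.std(s, ddof=0)))
        .reset_index()
    )


def best_single_method(result: GridResult, by_fusion: bool = True) -> pd.DataFrame:
    """The method with the highest mean accuracy across runs, per fusion."""
    rows = []
    groups: dict[str, list[MethodSpec]] = {}
    for m in sorted(result.methods, key=_method_order_key):
        groups.setdefault(m.fusion if by_fusion else "all", []).append(m)
    for fusion, ms in groups.items():
        best = None
        for m in ms:
            accs = [result.accuracy_of(run, m) for run in range(result.n_runs)]
            accs = [a for a in accs if a is not None]
            if not accs:
                continue
            mean = float(np.mean(accs))
            if best is None or mean > best[0]:
                best = (mean, m)
        if best is not None:
            rows.append({"fusion": fusion, "accuracy": best[0], "method": best[1].label()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ablation: classify the raw spectra
# ---------------------------------------------------------------------------

def _common_grid_matrix(dataset: SpectraDataset) -> np.ndarray:
    """Intensities interpolated onto the first spectrum's wavenumber grid."""
    ref = dataset[0].wavenumbers
    rows = []
    for s in dataset:
        if s.wavenumbers.shape == ref.shape and np.allclose(s.wavenumbers, ref):
            rows.append(s.intensities)
        else:
            rows.append(np.interp(ref, s.wavenumbers, s.intensities))
    return np.vstack(rows)


def classify_without_tda(
    dataset: SpectraDataset,
    labels: Sequence[int],
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    classifiers: Sequence[ClassifierSpec] | None = None,
    seed: int = 0,
    scheme: str = "no_tda",
) -> GridResult:
    """Feed raw (interpolated) intensity vectors to the classifier grid."""
    clfs = default_classifier_grid() if classifiers is None else list(classifiers)
    X = _common_grid_matrix(dataset)
    y = np.asarray(labels, dtype=int)
    methods = [MethodSpec(None, c) for c in clfs]
    result = GridResult(scheme=scheme, methods=methods, n_runs=len(splits))
    for run, (train, test) in enumerate(splits):
        for m in methods:
            try:
                clf = m.classifier.build(seed)
                clf.fit(X[train], y[train])
                result.accuracies[(run, m.key())] = accuracy(clf.predict(X[test]), y[test])
            except Exception as exc:  # noqa: BLE001
                logger.warning("run %d: %s failed: %s", run, m.label(), exc)
    return result


# ---------------------------------------------------------------------------
# Unsupervised evaluation
# ---------------------------------------------------------------------------

CLUSTER_ALGORITHMS = (
    "affinity_propagation", "agglomerative", "birch", "dbscan", "kmeans",
    "minibatch_kmeans", "mean_shift", "optics", "spectral", "gaussian_mixture",
)


@dataclass(frozen=True)
class ClusterEvalResult:
    accuracy: float
    n_clusters: int
    degenerate: bool  # single cluster: accuracy is just the majority frequency


def _build_clusterer(name: str, k: int, seed: int):
    if name == "affinity_propagation":
        return skcluster.AffinityPropagation(random_state=seed)
    if name == "agglomerative":
        return skcluster.AgglomerativeClustering(n_clusters=k)
    if name == "birch":
        return skcluster.Birch(n_clusters=k)
    if name == "dbscan":
        return skcluster.DBSCAN()
    if name == "kmeans":
        return skcluster.KMeans(n_clusters=k, random_state=seed, n_init=10)
    if name == "minibatch_kmeans":
        return skcluster.MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=10)
    if name == "mean_shift":
        return skcluster.MeanShift()
    if name == "optics":
        return skcluster.OPTICS(min_samples=5)
    if name == "spectral":
        return skcluster.SpectralClustering(n_clusters=k, random_state=seed,
                                            assign_labels="discretize")
    if name == "gaussian_mixture":
        return GaussianMixture(n_components=k, random_state=seed)
    raise ValueError(f"unknown clustering algorithm {name!r}")


def assignment_accuracy(cluster_labels: Sequence[int], true_labels: Sequence[int]) -> float:
    """Accuracy under the optimal one-to-one cluster-to-label assignment.

    The contingency table is solved by the Hungarian algorithm; clusters
    beyond the number of classes (or vice versa) stay unmatched and
    contribute zero.
    """
    c = np.asarray(cluster_labels)
    t = np.asarray(true_labels)
    if c.shape != t.shape or c.size == 0:
        raise ValueError("label vectors must be nonempty and aligned")
    cvals, cinv = np.unique(c, return_inverse=True)
    tvals, tinv = np.unique(t, return_inverse=True)
    cont = np.zeros((cvals.size, tvals.size), dtype=int)
    np.add.at(cont, (cinv, tinv), 1)
    rows, cols = linear_sum_assignment(cont, maximize=True)
    return float(cont[rows, cols].sum()) / c.size


def cluster_eval(
    features: np.ndarray,
    true_labels: Sequence[int],
    algorithms: Sequence[str] = CLUSTER_ALGORITHMS,
    seed: int = 0,
) -> dict[str, ClusterEvalResult]:
    """Cluster the feature vectors and score against the true labels.

    Algorithms that take a cluster count receive k = number of distinct
    true labels.  Noise points from density-based algorithms count as
    one extra (unmatched) cluster.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a nonempty 2-D array")
    y = np.asarray(true_labels, dtype=int)
    k = int(np.unique(y).size)
    out: dict[str, ClusterEvalResult] = {}
    for name in algorithms:
        model = _build_clusterer(name, k, seed)
        if name == "gaussian_mixture":
            pred = model.fit(X).predict(X)
        else:
            pred = model.fit_predict(X)
        n_clusters = int(np.unique(pred).size)
        degenerate = n_clusters <= 1
        if degenerate:
            logger.warning("%s produced a single cluster; accuracy is the majority frequency", name)
        out[name] = ClusterEvalResult(
            accuracy=assignment_accuracy(pred, y),
            n_clusters=n_clusters,
            degenerate=degenerate,
        )
    return out


# ---------------------------------------------------------------------------
# Final-model fitting for held-out prediction
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A method fitted on a full cohort, reusable on new diagrams."""

    method: MethodSpec
    fitted_vectorization: VectorizationConfig
    classifier: object

    def predict(self, diagrams: Sequence[PersistenceDiagram]) -> np.ndarray:
        X = np.vstack([vectorize(d, self.fitted_vectorization).values for d in diagrams])
        return np.asarray(self.classifier.predict(X), dtype=int)


def fit_full(
    diagrams: Sequence[PersistenceDiagram],
    labels: Sequence[int],
    method: MethodSpec,
    seed: int = 0,
) -> FittedModel:
    """Fit one method on an entire labelled cohort (no held-out split)."""
    if method.vectorization is None:
        raise ValueError("fit_full needs a vectorization method")
    fitted = fit_value_range(diagrams, method.vectorization)
    X = np.vstack([vectorize(d, fitted).values for d in diagrams])
    clf = method.classifier.build(seed)
    clf.fit(X, np.asarray(labels, dtype=int))
    return FittedModel(method=method, fitted_vectorization=fitted, classifier=clf)
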