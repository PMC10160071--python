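"""Fixed-length vectorizations of persistence diagrams.

Four representations are provided, each sampling a functional summary of
the finite (birth, death) intervals on a grid fitted to training data:

* Betti curve (BC): beta(t) = #{(b, d) : b <= t < d}.
* Persistence landscape (PL): lambda_j(t) = j-th largest tent value,
  where tent_(b,d)(t) = max(0, min(t - b, d - t)).
* Persistence silhouette (PS): persistence-weighted average tent,
  phi(t) = sum_i (d_i - b_i)^p tent_i(t) / sum_i (d_i - b_i)^p.
* Persistence image (PI): intervals mapped to (birth, persistence),
  smoothed by a unit-mass isotropic Gaussian of bandwidth sigma,
  weighted linearly by persistence, and integrated over an n x n pixel
  grid (midpoint rule).

Homology dimensions are combined by one of four fusion strategies: only
H0, only H1, all intervals pooled ("fused"), or H0 and H1 vectorized
separately and concatenated ("concat").

Sampling ranges are fitted on training diagrams only and frozen in the
config before transforming held-out diagrams; out-of-range intervals are
clipped to the fitted range, never an error.  This keeps patient-aware
validation free of train/test leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .persistence import PersistenceDiagram

__all__ = [
    "VectorizationConfig",
    "FeatureVector",
    "betti_curve",
    "persistence_landscape",
    "persistence_silhouette",
    "persistence_image",
    "vectorize",
    "fit_value_range",
    "PI_SIGMA_GRID",
    "PI_RESOLUTION_GRID",
    "CURVE_RESOLUTION_GRID",
    "FUSIONS",
]

#: Grid-search values for the persistence-image bandwidth.
PI_SIGMA_GRID = (0.1, 1.0, 10.0)
#: Grid-search values for the persistence-image resolution (n x n pixels).
PI_RESOLUTION_GRID = (5, 10, 25)
#: Grid-search values for the BC/PL/PS sampling resolution.
CURVE_RESOLUTION_GRID = (25, 50, 75, 100)

FUSIONS = ("H0", "H1", "fused", "concat")
METHODS = ("PI", "PL", "PS", "BC")


@dataclass(frozen=True)
class VectorizationConfig:
    """One point of the vectorization grid.

    ``value_range`` is ``None`` until fitted; after
    :func:`fit_value_range` it holds one entry per fusion block —
    ``(tmin, tmax)`` for BC/PL/PS, ``((bmin, bmax), (pmin, pmax))`` for
    PI.
    """

    method: str = "BC"
    resolution: int = 50
    sigma: float = 1.0
    landscape_count: int = 5
    silhouette_power: float = 1.0
    fusion: str = "concat"
    value_range: tuple | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.fusion not in FUSIONS:
            raise ValueError(f"fusion must be one of {FUSIONS}")
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.landscape_count < 1:
            raise ValueError("landscape_count must be >= 1")
        if self.silhouette_power <= 0:
            raise ValueError("silhouette_power must be > 0")

    @property
    def blocks(self) -> tuple[str, ...]:
        """Homology blocks vectorized under this fusion strategy."""
        return {
            "H0": ("h0",), "H1": ("h1",), "fused": ("all",), "concat": ("h0", "h1"),
        }[self.fusion]

    @property
    def block_length(self) -> int:
        n = self.resolution
        if self.method == "PI":
            return n * n
        if self.method == "PL":
            return self.landscape_count * n
        return n

    @property
    def vector_length(self) -> int:
        return len(self.blocks) * self.block_length

    def key(self) -> tuple:
        """Canonical ordering key (method, params, fusion)."""
        return (self.method, self.resolution, self.sigma,
                self.landscape_count, self.silhouette_power, self.fusion)

    def label(self) -> str:
        extra = f", sigma={self.sigma:g}" if self.method == "PI" else ""
        return f"{self.method}(n={self.resolution}{extra}) [{self.fusion}]"


@dataclass(frozen=True)
class FeatureVector:
    """A vectorized diagram together with the config that produced it."""

    values: np.ndarray
    config: VectorizationConfig

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite entries")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# Elementary vectorizers on plain (m, 2) interval arrays
# ---------------------------------------------------------------------------

def _as_intervals(intervals) -> np.ndarray:
    arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
    return arr


def _check_range(value_range) -> tuple[float, float]:
    tmin, tmax = float(value_range[0]), float(value_range[1])
    if not tmin < tmax:
        raise ValueError(f"empty sampling range ({tmin}, {tmax})")
    return tmin, tmax


def _clip(arr: np.ndarray, tmin: float, tmax: float) -> np.ndarray:
    return np.clip(arr, tmin, tmax)


def betti_curve(intervals, n: int, value_range) -> np.ndarray:
    """beta(t_i) = number of intervals with b <= t_i < d, at n grid points."""
    tmin, tmax = _check_range(value_range)
    arr = _as_intervals(intervals)
    t = np.linspace(tmin, tmax, n)
    if arr.size == 0:
        return np.zeros(n)
    arr = _clip(arr, tmin, tmax)
    b, d = arr[:, 0][:, None], arr[:, 1][:, None]
    return np.sum((b <= t[None, :]) & (t[None, :] < d), axis=0).astype(float)


def _tents(arr: np.ndarray, t: np.ndarray) -> np.ndarray:
    b, d = arr[:, 0][:, None], arr[:, 1][:, None]
    return np.maximum(0.0, np.minimum(t[None, :] - b, d - t[None, :]))


def persistence_landscape(intervals, n: int, k: int, value_range) -> np.ndarray:
    """Concatenated landscapes lambda_1..lambda_k, each at n grid points."""
    tmin, tmax = _check_range(value_range)
    arr = _as_intervals(intervals)
    t = np.linspace(tmin, tmax, n)
    if arr.size == 0:
        return np.zeros(k * n)
    tents = _tents(_clip(arr, tmin, tmax), t)
    if tents.shape[0] < k:
        tents = np.vstack([tents, np.zeros((k - tents.shape[0], n))])
    top = -np.sort(-tents, axis=0)[:k]
    return top.ravel()


def persistence_silhouette(intervals, n: int, p: float, value_range) -> np.ndarray:
    """Power-weighted average tent function at n grid points."""
    tmin, tmax = _check_range(value_range)
    arr = _as_intervals(intervals)
    t = np.linspace(tmin, tmax, n)
    if arr.size == 0:
        return np.zeros(n)
    arr = _clip(arr, tmin, tmax)
    w = (arr[:, 1] - arr[:, 0]) ** p
    total = w.sum()
    if total == 0:
        return np.zeros(n)
    return (w @ _tents(arr, t)) / total


def persistence_image(intervals, sigma: float, n: int, range_b, range_p) -> np.ndarray:
    """Flattened n x n persistence image.

    Each interval contributes a unit-mass Gaussian at (birth,
    persistence), weighted linearly by persistence (0 at persistence 0, 1
    at the top of the fitted persistence range); pixel values are the
    midpoint-rule integral of the weighted density over each pixel.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    bmin, bmax = _check_range(range_b)
    pmin, pmax = _check_range(range_p)
    arr = _as_intervals(intervals)
    if arr.size == 0:
        return np.zeros(n * n)
    b = _clip(arr[:, 0], bmin, bmax)
    pers = _clip(arr[:, 1] - arr[:, 0], pmin, pmax)
    weight = pers / pmax if pmax > 0 else np.zeros_like(pers)
    hb, hp = (bmax - bmin) / n, (pmax - pmin) / n
    cb = bmin + (np.arange(n) + 0.5) * hb
    cp = pmin + (np.arange(n) + 0.5) * hp
    # image[i, j]: i indexes persistence rows, j birth columns
    gb = np.exp(-0.5 * ((cb[None, :] - b[:, None]) / sigma) ** 2)
    gp = np.exp(-0.5 * ((cp[None, :] - pers[:, None]) / sigma) ** 2)
    norm = 1.0 / (2.0 * np.pi * sigma * sigma)
    img = np.einsum("m,mi,mj->ij", weight * norm, gp, gb) * hb * hp
    return img.ravel()


# ---------------------------------------------------------------------------
# Diagram-level interface with fusion and fitted ranges
# ---------------------------------------------------------------------------

def _block_intervals(diagram: PersistenceDiagram, block: str) -> np.ndarray:
    if block == "h0":
        return diagram.h0
    if block == "h1":
        return diagram.h1
    return np.vstack([diagram.h0, diagram.h1])


def _vectorize_block(intervals: np.ndarray, config: VectorizationConfig, rng) -> np.ndarray:
    n = config.resolution
    if config.method == "BC":
        return betti_curve(intervals, n, rng)
    if config.method == "PL":
        return persistence_landscape(intervals, n, config.landscape_count, rng)
    if config.method == "PS":
        return persistence_silhouette(intervals, n, config.silhouette_power, rng)
    return persistence_image(intervals, config.sigma, n, rng[0], rng[1])


def vectorize(diagram: PersistenceDiagram, config: VectorizationConfig) -> FeatureVector:
    """Vectorize one diagram under a fitted configuration."""
    if config.value_range is None:
        raise RuntimeError("value_range not fitted; call fit_value_range on training diagrams first")
    parts = [
        _vectorize_block(_block_intervals(diagram, block), config, rng)
        for block, rng in zip(config.blocks, config.value_range)
    ]
    return FeatureVector(np.concatenate(parts), config)


def fit_value_range(
    diagrams: Iterable[PersistenceDiagram], config: VectorizationConfig
) -> VectorizationConfig:
    """Fit the sampling range(s) on training diagrams and freeze them.

    BC/PL/PS blocks get [min finite birth, max finite death]; PI blocks
    get the birth range and [0, max persistence].  A block with no finite
    training interval anywhere gets a unit placeholder range (its vectors
    are all-zero); if *no* block has any interval the fit fails.
    """
    diagrams = list(diagrams)
    if not diagrams:
        raise ValueError("cannot fit value range on an empty diagram collection")
    ranges = []
    any_intervals = False
    for block in config.blocks:
        stacks = [iv for d in diagrams if (iv := _block_intervals(d, block)).size]
        if not stacks:
            ranges.append(((0.0, 1.0), (0.0, 1.0)) if config.method == "PI" else (0.0, 1.0))
            continue
        any_intervals = True
        allint = np.vstack(stacks)
        if config.method == "PI":
            bmin, bmax = float(allint[:, 0].min()), float(allint[:, 0].max())
            pmax = float((allint[:, 1] - allint[:, 0]).max())
            if bmax <= bmin:
                bmax = bmin + 1.0
            if pmax <= 0.0:
                pmax = 1.0
            ranges.append(((bmin, bmax), (0.0, pmax)))
        else:
            tmin, tmax = float(allint[:, 0].min()), float(allint[:, 1].max())
            if tmax <= tmin:
                tmax = tmin + 1.0
            ranges.append((tmin, tmax))
    if not any_intervals:
        raise ValueError("no finite intervals in any training diagram; cannot fit")
    return replace(config, value_range=tuple(ranges))
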