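"""Vietoris-Rips persistent homology of planar embeddings of spectra.

A spectrum is embedded as a point cloud in R^2 (one point per spectral
sample) and filtered by the Vietoris-Rips complex under the Euclidean
metric: a simplex enters the filtration when all pairwise distances among
its vertices fall below the current scale.  The module computes the
dimension-0 and dimension-1 persistence diagrams.

Two independent code paths are provided:

* :func:`vietoris_rips_pd` — the production path.  H0 comes from the
  Euclidean minimum spanning tree (Kruskal); H1 from GF(2) reduction of
  the triangle boundary matrix, compiled with numba over bit-packed
  columns and truncated at the enclosing radius (beyond which the VR
  complex is a cone, hence contractible).
* :func:`brute_force_pd` — a small-instance oracle that enumerates the
  full complex up to dimension 2 and runs the textbook column reduction
  in pure Python.  It shares no code with the production path and backs
  the correctness tests.

Convention: H1 pairs with death == birth are omitted (they are invisible
to every downstream vectorization and their multiset is an artifact of
tie-breaking); zero-length H0 bars from coincident points are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist, squareform

from .io import RamanSpectrum

__all__ = [
    "PersistenceDiagram",
    "embed_spectrum",
    "vietoris_rips_pd",
    "brute_force_pd",
]

BRUTE_FORCE_MAX_POINTS = 12


# ---------------------------------------------------------------------------
# Diagram container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death) intervals in homology dimensions 0 and 1.

    ``h0`` and ``h1`` hold the *finite* intervals as (m, 2) float arrays;
    ``n_essential_h0`` counts the bars with death = +inf (one for a
    connected filtration).  VR filtrations on planar clouds carry no
    essential H1.
    """

    h0: np.ndarray
    h1: np.ndarray
    n_essential_h0: int = 1

    def __post_init__(self) -> None:
        for name in ("h0", "h1"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1, 2)
            if arr.size and np.any(arr[:, 1] < arr[:, 0]):
                raise ValueError(f"{name}: interval with death < birth")
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    def intervals(self, dim: int) -> np.ndarray:
        """Finite intervals of one homology dimension as an (m, 2) array."""
        if dim == 0:
            return self.h0
        if dim == 1:
            return self.h1
        raise ValueError(f"dim must be 0 or 1, got {dim}")

    @property
    def n_points(self) -> int:
        """Number of points of the underlying cloud (H0 bar count)."""
        return len(self.h0) + self.n_essential_h0

    def to_array(self) -> np.ndarray:
        """Stack as rows (birth, death, dim) with inf for essential bars."""
        rows = [np.column_stack([self.h0, np.zeros(len(self.h0))])]
        rows.append(np.array([[0.0, np.inf, 0.0]] * self.n_essential_h0).reshape(-1, 3))
        rows.append(np.column_stack([self.h1, np.ones(len(self.h1))]))
        return np.vstack(rows)


def _sorted_pairs(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr, dtype=float).reshape(-1, 2)
    return a[np.lexsort((a[:, 1], a[:, 0]))]


def diagrams_close(a: PersistenceDiagram, b: PersistenceDiagram, tol: float = 1e-9) -> bool:
    """Multiset equality of two diagrams up to ``tol``, per dimension."""
    if a.n_essential_h0 != b.n_essential_h0:
        return False
    for dim in (0, 1):
        ia, ib = _sorted_pairs(a.intervals(dim)), _sorted_pairs(b.intervals(dim))
        if ia.shape != ib.shape:
            return False
        if ia.size and not np.allclose(ia, ib, atol=tol, rtol=0.0):
            return False
    return True


# ---------------------------------------------------------------------------
# Spectrum -> point cloud
# ---------------------------------------------------------------------------

def embed_spectrum(
    spectrum: RamanSpectrum,
    mode: str = "wavenumber_intensity",
    normalize: bool = False,
) -> np.ndarray:
    """Embed a spectrum as an (n, 2) planar point cloud.

    ``wavenumber_intensity`` uses (wavenumber, intensity) coordinates;
    ``index_intensity`` uses (sample index, intensity).  With
    ``normalize`` each coordinate is min-max scaled to [0, 1] before any
    distance is computed, which removes the (arbitrary) relative scaling
    of the two axes.
    """
    if mode == "wavenumber_intensity":
        x = spectrum.wavenumbers.astype(float)
    elif mode == "index_intensity":
        x = np.arange(len(spectrum), dtype=float)
    else:
        raise ValueError(f"unknown embedding mode {mode!r}")
    y = spectrum.intensities.astype(float)
    cloud = np.column_stack([x, y])
    if normalize:
        span = cloud.max(axis=0) - cloud.min(axis=0)
        span[span == 0] = 1.0
        cloud = (cloud - cloud.min(axis=0)) / span
    return cloud


def _validate_cloud(cloud: np.ndarray) -> np.ndarray:
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("point cloud must be a nonempty (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point cloud contains non-finite coordinates")
    return pts


# ---------------------------------------------------------------------------
# H0: Kruskal minimum spanning tree
# ---------------------------------------------------------------------------

def _mst_edge_lengths(dmat: np.ndarray) -> np.ndarray:
    """Kruskal MST edge weights of a complete graph given its distance matrix.

    Written out rather than delegated so that zero-length edges between
    coincident points are kept as explicit 0-weight bars.
    """
    n = dmat.shape[0]
    if n == 1:
        return np.empty(0)
    iu, ju = np.triu_indices(n, k=1)
    w = dmat[iu, ju]
    order = np.argsort(w, kind="stable")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = []
    for e in order:
        a, b = find(int(iu[e])), find(int(ju[e]))
        if a != b:
            parent[a] = b
            out.append(w[e])
            if len(out) == n - 1:
                break
    return np.asarray(out)


# ---------------------------------------------------------------------------
# H1: boundary-matrix reduction over GF(2), bit-packed, numba-compiled
# ---------------------------------------------------------------------------

@njit(cache=True)
def _reduce_h1(tri_edges, tri_diam, edge_w, n_edges, n_pairs_needed):  # pragma: no cover
    """Reduce triangle boundary columns against edge rows.

    ``tri_edges`` holds, per triangle in filtration order, the ranks of
    its three boundary edges in the edge filtration order.  Columns are
    bit-packed into uint64 words; the pivot of each fully reduced column
    pairs an edge (cycle birth) with the triangle (cycle death).  Stops
    once every independent cycle has been paired.
    """
    nw = (n_edges + 63) // 64
    max_cols = n_pairs_needed if n_pairs_needed > 0 else 1
    cols = np.zeros((max_cols, nw), dtype=np.uint64)
    pivot_col = np.full(n_edges, -1, dtype=np.int64)
    births = np.empty(max_cols, dtype=np.float64)
    deaths = np.empty(max_cols, dtype=np.float64)
    npairs = 0
    work = np.zeros(nw, dtype=np.uint64)
    for t in range(tri_edges.shape[0]):
        if npairs == n_pairs_needed:
            break
        for w in range(nw):
            work[w] = np.uint64(0)
        for k in range(3):
            e = tri_edges[t, k]
            work[e >> 6] ^= np.uint64(1) << np.uint64(e & 63)
        while True:
            # locate the pivot: highest set bit
            p = -1
            for w in range(nw - 1, -1, -1):
                if work[w] != np.uint64(0):
                    v = work[w]
                    b = 0
                    while v > np.uint64(1):
                        v >>= np.uint64(1)
                        b += 1
                    p = (w << 6) + b
                    break
            if p < 0:
                break  # column vanished: the triangle creates a 2-cycle
            c = pivot_col[p]
            if c == -1:
                for w in range(nw):
                    cols[npairs, w] = work[w]
                pivot_col[p] = npairs
                births[npairs] = edge_w[p]
                deaths[npairs] = tri_diam[t]
                npairs += 1
                break
            for w in range(nw):
                work[w] ^= cols[c, w]
    return births[:npairs], deaths[:npairs]


def _triangles_within(dmat: np.ndarray, threshold: float):
    """Enumerate triangles (i<j<k) with diameter <= threshold, vectorized per i."""
    n = dmat.shape[0]
    tri_idx = []
    tri_diam = []
    within = dmat <= threshold
    for i in range(n - 2):
        # candidate partners of i
        js = np.flatnonzero(within[i, i + 1:]) + i + 1
        if js.size < 2:
            continue
        sub = dmat[np.ix_(js, js)]
        ok = np.triu(within[np.ix_(js, js)], k=1)
        jj, kk = np.nonzero(ok)
        if jj.size == 0:
            continue
        d = np.maximum(sub[jj, kk], np.maximum(dmat[i, js[jj]], dmat[i, js[kk]]))
        keep = d <= threshold
        jj, kk, d = jj[keep], kk[keep], d[keep]
        tri_idx.append(np.column_stack([np.full(jj.size, i), js[jj], js[kk]]))
        tri_diam.append(d)
    if not tri_idx:
        return np.empty((0, 3), dtype=np.int64), np.empty(0)
    return np.vstack(tri_idx).astype(np.int64), np.concatenate(tri_diam)


def _h1_intervals(dmat: np.ndarray) -> np.ndarray:
    """Positive-persistence H1 intervals of the VR filtration."""
    n = dmat.shape[0]
    if n < 4:
        # fewer than 4 points: any cycle dies at its birth (triangle fills
        # the moment its last edge appears), so H1 is empty
        return np.empty((0, 2))
    # enclosing radius: past it the complex is a cone, H1 vanishes
    np.fill_diagonal(dmat, 0.0)
    r_enc = np.min(np.max(dmat, axis=1))
    iu, ju = np.triu_indices(n, k=1)
    w = dmat[iu, ju]
    keep = w <= r_enc
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.argsort(w, kind="stable")
    iu, ju, w = iu[order], ju[order], w[order]
    n_edges = w.size
    # rank lookup for edge (i, j), i < j
    rank = np.full(n * n, -1, dtype=np.int64)
    rank[iu * n + ju] = np.arange(n_edges)
    n_pos = n_edges - (n - 1)  # edges that create cycles
    if n_pos <= 0:
        return np.empty((0, 2))
    tri, tdiam = _triangles_within(dmat, r_enc)
    torder = np.argsort(tdiam, kind="stable")
    tri, tdiam = tri[torder], tdiam[torder]
    te = np.column_stack([
        rank[tri[:, 0] * n + tri[:, 1]],
        rank[tri[:, 0] * n + tri[:, 2]],
        rank[tri[:, 1] * n + tri[:, 2]],
    ])
    births, deaths = _reduce_h1(te, tdiam, w, n_edges, n_pos)
    pos = deaths > births
    return np.column_stack([births[pos], deaths[pos]])


def vietoris_rips_pd(cloud: np.ndarray, max_dim: int = 1) -> PersistenceDiagram:
    """Vietoris-Rips persistence diagram (H0 and H1) of a planar cloud.

    Finite H0 deaths are exactly the Euclidean MST edge lengths, plus one
    essential bar for the surviving component.  H1 intervals come from
    the GF(2) boundary reduction truncated at the enclosing radius.
    """
    pts = _validate_cloud(cloud)
    if max_dim not in (0, 1):
        raise ValueError("max_dim must be 0 or 1")
    n = pts.shape[0]
    if n == 1:
        return PersistenceDiagram(np.empty((0, 2)), np.empty((0, 2)))
    dmat = squareform(pdist(pts))
    mst = np.sort(_mst_edge_lengths(dmat))
    h0 = np.column_stack([np.zeros(mst.size), mst])
    if max_dim == 0:
        return PersistenceDiagram(h0, np.empty((0, 2)))
    h1 = _h1_intervals(dmat)
    return PersistenceDiagram(h0, h1)


# ---------------------------------------------------------------------------
# Brute-force oracle: full complex, textbook reduction (independent path)
# ---------------------------------------------------------------------------

def brute_force_pd(cloud: np.ndarray) -> PersistenceDiagram:
    """Oracle diagram by explicit simplex enumeration and column reduction.

    Builds the entire VR complex up to dimension 2 (all vertices, edges
    and triangles), orders simplices by (diameter, dimension, vertex
    tuple), and reduces the full boundary matrix over GF(2) with the
    standard left-to-right algorithm on Python sets.  Quadratic-to-cubic
    and intended for clouds of at most ``BRUTE_FORCE_MAX_POINTS`` points.
    """
    pts = _validate_cloud(cloud)
    n = pts.shape[0]
    if n > BRUTE_FORCE_MAX_POINTS:
        raise ValueError(f"brute-force oracle limited to {BRUTE_FORCE_MAX_POINTS} points, got {n}")
    d = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))

    def diam(simplex: tuple[int, ...]) -> float:
        if len(simplex) == 1:
            return 0.0
        return max(d[a, b] for a, b in combinations(simplex, 2))

    simplices = [(i,) for i in range(n)]
    simplices += list(combinations(range(n), 2))
    simplices += list(combinations(range(n), 3))
    simplices.sort(key=lambda s: (diam(s), len(s), s))
    index = {s: i for i, s in enumerate(simplices)}

    columns: list[set[int]] = []
    for s in simplices:
        if len(s) == 1:
            columns.append(set())
        else:
            columns.append({index[f] for f in combinations(s, len(s) - 1)})

    low_of: dict[int, int] = {}  # pivot row -> column index
    pairs: list[tuple[int, int]] = []  # (birth simplex idx, death simplex idx)
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            if low not in low_of:
                low_of[low] = j
                pairs.append((low, j))
                break
            col ^= columns[low_of[low]]

    paired = {b for b, _ in pairs} | {dd for _, dd in pairs}
    h0, h1 = [], []
    n_essential_h0 = 0
    for b, dd in pairs:
        dim = len(simplices[b]) - 1
        birth, death = diam(simplices[b]), diam(simplices[dd])
        if dim == 0:
            h0.append((birth, death))
        elif dim == 1 and death > birth:
            h1.append((birth, death))
    for j, s in enumerate(simplices):
        if j not in paired and len(s) == 1:
            n_essential_h0 += 1
    return PersistenceDiagram(
        np.asarray(h0).reshape(-1, 2), np.asarray(h1).reshape(-1, 2),
        n_essential_h0=n_essential_h0,
    )
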