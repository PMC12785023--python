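"""Hierarchical single-linkage segmentation of pixel spectra.

Pixels are clustered by agglomerative hierarchical cluster analysis (HCA)
with Euclidean distance and single (nearest-neighbor) linkage, the classic
MSI segmentation recipe.  Cutting the hierarchy into k classes is computed
exactly through the minimum-spanning-tree (MST) equivalence: the single-
linkage partition into k clusters equals the connected components left
after removing the k-1 largest MST edges.

Determinism under tied merge distances is guaranteed by a fixed rule:
tied candidate edges are processed in lexicographic (pixel-index pair)
order, which reproduces naive agglomeration with the same tie-break.
There is no randomness anywhere; two runs on the same cube are identical
down to the rendered PNG bytes.

Labels are re-indexed by descending cluster size, ties broken by the
smallest member pixel in row-major grid order, so cluster colors are
stable across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist

from .datacube import NO_TISSUE, LabelMap, MSIDataCube

__all__ = [
    "SegmentationResult",
    "DominantPeak",
    "ClusteringError",
    "hca_segment",
    "hca_segment_multi",
    "cluster_mean_spectra",
    "dominant_mz",
]


class ClusteringError(ValueError):
    pass


@dataclass
class SegmentationResult:
    """A k-class segmentation of a cube plus per-cluster summaries."""

    label_map: LabelMap
    k: int
    metric: str
    linkage: str
    mean_spectra: np.ndarray      # (k, n_bins) arithmetic means
    cluster_sizes: np.ndarray     # (k,) pixel counts, descending
    window: str | None = None     # mass-window label, e.g. "800-1000"
    mode: str | None = None       # ionization mode


@dataclass(frozen=True)
class DominantPeak:
    """The tallest bin of a cluster's mean spectrum."""

    label: int
    mz: float
    intensity: float


# ---------------------------------------------------------------------------
# exact single-linkage cut
# ---------------------------------------------------------------------------

def _condensed_to_pair(m: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Invert condensed-distance indices to (i, j) pairs with i < j."""
    m = np.asarray(m, dtype=np.float64)
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8 * m)) / 2).astype(np.intp)
    # guard against float rounding at row boundaries
    row_start = i * (b - i) // 2
    over = m < row_start
    i[over] -= 1
    row_start = i * (b - i) // 2
    j = (m - row_start).astype(np.intp) + i + 1
    return i, j


class _UnionFind:
    __slots__ = ("parent", "n_components")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.n_components = n

    def find(self, a: int) -> int:
        p = self.parent
        root = a
        while p[root] != root:
            root = p[root]
        while p[a] != root:
            p[a], a = root, p[a]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        self.n_components -= 1
        return True


def _mst_edges(X: np.ndarray):
    """MST of the complete Euclidean graph over rows of X.

    Distances are shifted by +1 before the sparse-graph MST so that
    exact-duplicate rows (distance zero) keep their edges; the shift is a
    monotone transform and leaves the MST unchanged.
    """
    from scipy.spatial.distance import squareform

    D = pdist(np.ascontiguousarray(X, dtype=np.float64))
    n = X.shape[0]
    dm = squareform(D) + 1.0
    np.fill_diagonal(dm, 0.0)
    mst = minimum_spanning_tree(csr_matrix(dm)).tocoo()
    return mst.row, mst.col, mst.data - 1.0, D


def _cut_partition(n: int, mi, mj, mw, D, k: int) -> np.ndarray:
    """Connected components after the n-k smallest merges, ties lexicographic."""
    if k == 1:
        return np.zeros(n, dtype=np.intp)
    if k == n:
        return np.arange(n, dtype=np.intp)
    keep = n - k
    order = np.argsort(mw, kind="stable")
    w_sorted = mw[order]
    h_keep, h_next = w_sorted[keep - 1], w_sorted[keep]

    if h_keep < h_next:
        sel = order[:keep]
        ei, ej = mi[sel], mj[sel]
        g = csr_matrix((np.ones(keep), (ei, ej)), shape=(n, n))
        _, labels = connected_components(g, directed=False)
        return labels.astype(np.intp)

    # a plateau of tied distances straddles the cut: take every edge strictly
    # below the plateau, then admit plateau edges (from ALL pairs, not just
    # the MST) in lexicographic (i, j) order until k components remain
    h = h_keep
    below = mw < h
    uf = _UnionFind(n)
    for a, b in zip(mi[below], mj[below]):
        uf.union(int(a), int(b))
    plateau_idx = np.flatnonzero(D == h)
    pi, pj = _condensed_to_pair(plateau_idx, n)
    lex = np.lexsort((pj, pi))
    for a, b in zip(pi[lex], pj[lex]):
        if uf.n_components == k:
            break
        uf.union(int(a), int(b))
    if uf.n_components != k:
        raise ClusteringError(f"could not realize {k} clusters")  # pragma: no cover
    roots = np.array([uf.find(i) for i in range(n)], dtype=np.intp)
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def _canonical_labels(raw: np.ndarray, ranks: np.ndarray, k: int) -> np.ndarray:
    """Re-index labels by descending size, ties by smallest row-major pixel."""
    sizes = np.bincount(raw, minlength=k)
    first_rank = np.full(k, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first_rank, raw, ranks)
    order = np.lexsort((first_rank, -sizes))
    remap = np.empty(k, dtype=np.intp)
    remap[order] = np.arange(k)
    return remap[raw]


def _build_result(cube: MSIDataCube, labels: np.ndarray, k: int) -> SegmentationResult:
    grid = np.full((cube.height, cube.width), NO_TISSUE, dtype=np.int32)
    grid[cube.pixel_coords[:, 1], cube.pixel_coords[:, 0]] = labels
    label_map = LabelMap(cube.width, cube.height, grid, k)
    means, sizes = cluster_mean_spectra(cube, label_map)
    window = None
    mz = cube.mz_axis
    if mz.size:
        window = f"{mz.min():g}..{mz.max():g}"
    return SegmentationResult(
        label_map=label_map, k=k, metric="euclidean", linkage="single",
        mean_spectra=means, cluster_sizes=sizes, window=window, mode=cube.mode,
    )


def hca_segment_multi(cube: MSIDataCube, ks) -> dict[int, SegmentationResult]:
    """Segment one cube at several cluster counts, sharing the MST.

    The distance computation and MST dominate the cost; cutting at each k
    is cheap, so requesting k in {2, 10} together costs barely more than
    one segmentation.
    """
    n = cube.n_pixels
    ks = sorted(set(int(k) for k in ks))
    if ks[0] < 1:
        raise ClusteringError("k must be >= 1")
    if ks[-1] > n:
        raise ClusteringError(f"k={ks[-1]} exceeds the {n} available pixels")
    X = cube.intensities.astype(np.float64)
    mi, mj, mw, D = _mst_edges(X)
    # duplicate spectra appear as zero-weight MST edges; the number of
    # distinct spectra bounds the achievable cluster count
    n_distinct = n - int((mw == 0).sum())
    if ks[-1] > n_distinct:
        raise ClusteringError(
            f"only {n_distinct} distinct spectra: at most {n_distinct} clusters achievable"
        )
    ranks = cube.row_major_rank()
    out = {}
    for k in ks:
        raw = _cut_partition(n, mi, mj, mw, D, k)
        labels = _canonical_labels(raw, ranks, k)
        out[k] = _build_result(cube, labels, k)
    return out


def hca_segment(cube: MSIDataCube, k: int) -> SegmentationResult:
    """Exact Euclidean single-linkage segmentation into k classes."""
    return hca_segment_multi(cube, [k])[k]


# ---------------------------------------------------------------------------
# per-cluster summaries
# ---------------------------------------------------------------------------

def cluster_mean_spectra(cube: MSIDataCube, label_map: LabelMap):
    """Arithmetic mean spectrum and pixel count of every cluster.

    Returns ``(means, sizes)`` with ``means`` of shape (k, n_bins).  The
    weighted recomposition ``sum_c sizes[c] * means[c]`` equals the total
    intensity sum over pixels (conservation).
    """
    labels = label_map.labels[cube.pixel_coords[:, 1], cube.pixel_coords[:, 0]]
    if np.any(labels == NO_TISSUE):
        raise ValueError("label map marks NO_TISSUE at a cube pixel")
    k = label_map.k
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):
        missing = int(np.flatnonzero(sizes == 0)[0])
        raise ValueError(f"label {missing} has no member pixels in the cube")
    X = cube.intensities.astype(np.float64)
    sums = np.zeros((k, X.shape[1]))
    np.add.at(sums, labels, X)
    return sums / sizes[:, None], sizes


def dominant_mz(mean_spectrum: np.ndarray, mz_axis: np.ndarray,
                label: int = 0) -> DominantPeak:
    """Bin center of the global maximum of a mean spectrum; ties -> lowest m/z."""
    v = np.asarray(mean_spectrum, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty spectrum has no dominant peak")
    if not np.any(v > 0):
        raise ValueError("all-zero spectrum has no dominant peak")
    i = int(np.argmax(v))  # argmax returns the first (lowest-m/z) maximum
    return DominantPeak(label=label, mz=float(mz_axis[i]), intensity=float(v[i]))
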