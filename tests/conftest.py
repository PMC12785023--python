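import numpy as np
import pytest

from msimargin import MSIDataCube


@pytest.fixture
def tiny_cube() -> MSIDataCube:
    """2x2 cube with 3 bins, handmade values."""
    return MSIDataCube(
        width=2, height=2,
        pixel_coords=[(0, 0), (1, 0), (0, 1), (1, 1)],
        mz_axis=[250.05, 465.95, 885.75],
        intensities=[[1.0, 0.0, 1.0],
                     [3.0, 0.0, 3.0],
                     [0.5, 2.0, 0.5],
                     [1.0, 4.0, 1.0]],
        mode="negative",
    )


def random_cube(rng: np.random.Generator, n_max: int = 200, bins_max: int = 20,
                n_min: int = 12) -> MSIDataCube:
    """A random rectangular-ish cube for clustering tests."""
    n = int(rng.integers(n_min, n_max + 1))
    n_bins = int(rng.integers(2, bins_max + 1))
    width = int(np.ceil(np.sqrt(n)))
    height = int(np.ceil(n / width))
    grid = [(x, y) for y in range(height) for x in range(width)][:n]
    mz = np.sort(200 + rng.random(n_bins) * 800)
    while np.any(np.diff(mz) <= 0):  # pragma: no cover - vanishing probability
        mz = np.sort(200 + rng.random(n_bins) * 800)
    inten = rng.random((n, n_bins)).astype(np.float32) * 100
    return MSIDataCube(width=width, height=height, pixel_coords=grid,
                       mz_axis=mz, intensities=inten, mode="negative")


def naive_single_linkage(X: np.ndarray, k: int) -> list:
    """Naive O(n^3) agglomerative single linkage, independent oracle.

    Maintains the full cluster-distance matrix; at each step merges the
    pair at minimal distance, ties broken by the lexicographically
    smallest realizing pixel pair.  Returns the partition as a set of
    frozensets of pixel indices.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    # independent distance computation (not scipy.pdist)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    INF = np.inf
    cd = D.copy()
    np.fill_diagonal(cd, INF)
    ri = np.tile(np.arange(n), (n, 1))      # realizing pair (row index i)
    rj = ri.T.copy()
    # keep realizing pairs ordered (i < j)
    swap = ri > rj
    ri[swap], rj[swap] = rj[swap], ri[swap].copy()
    members = {c: {c} for c in range(n)}
    active = np.ones(n, dtype=bool)

    while len(members) > k:
        m = np.where(active[:, None] & active[None, :], cd, INF)
        dmin = m.min()
        ii, jj = np.nonzero(m == dmin)
        cand = sorted(zip(ri[ii, jj], rj[ii, jj], ii, jj))
        _, _, a, b = cand[0]
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        # merge b into a with single-linkage (elementwise min) update
        closer = cd[b] < cd[a]
        tie = (cd[b] == cd[a]) & ~np.isinf(cd[a])
        lex_b = (ri[b] < ri[a]) | ((ri[b] == ri[a]) & (rj[b] < rj[a]))
        take_b = closer | (tie & lex_b)
        cd[a, take_b] = cd[b, take_b]
        ri[a, take_b] = ri[b, take_b]
        rj[a, take_b] = rj[b, take_b]
        cd[:, a] = cd[a]
        ri[:, a] = ri[a]
        rj[:, a] = rj[a]
        cd[a, a] = INF
        active[b] = False
        members[a] |= members.pop(b)
    return {frozenset(v) for v in members.values()}


def partition_of_labels(labels: np.ndarray) -> set:
    labels = np.asarray(labels)
    return {frozenset(np.flatnonzero(labels == c).tolist())
            for c in np.unique(labels)}
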