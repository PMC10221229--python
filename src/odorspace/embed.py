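"""Fingerprints, 3D UMAP embedding, and clustering of odorant space.

Molecules are encoded as 1024-bit extended-connectivity fingerprints
(ECFP, radius 2 by default), embedded into three dimensions with UMAP
(Jaccard metric, appropriate for binary vectors), and partitioned on the
embedding coordinates with k-means and a self-organizing map (SOM).  The
number of clusters is selected with the elbow curve (within-cluster sum
of squares) and a Kelley-style penalty score adapted to flat partitions.

Cluster indices are 1-based throughout, matching the "SOM16-Cl-2"
naming convention of the reports this module feeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from odorspace.dataset import OdorDataset


@dataclass
class FingerprintMatrix:
    ids: list[str]
    bits: np.ndarray  # (n_molecules, n_bits) uint8 in {0,1}
    radius: int = 2

    def __post_init__(self) -> None:
        if self.bits.shape[0] != len(self.ids):
            raise ValueError("fingerprint row count does not match id count")


@dataclass
class Embedding3D:
    ids: list[str]
    coords: np.ndarray  # (n_molecules, 3)
    umap_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.ids), 3):
            raise ValueError("embedding must be (n_molecules, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")


@dataclass
class ClusterAssignment:
    """A flat partition of the embedded molecules.

    ``level`` is the requested cluster count (grid size for SOM); SOM may
    leave units empty, so ``effective_clusters`` <= level.  Labels are
    1-based cluster indices.
    """

    method: str  # "kmeans" | "som"
    level: int
    labels: dict[str, int]
    grid: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("kmeans", "som"):
            raise ValueError(f"unknown clustering method {self.method!r}")

    @property
    def effective_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.labels.items() if c == cluster]

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.labels.values()))


@dataclass
class ClusterSelectionReport:
    k_range: list[int]
    wss: dict[int, float]
    kelley_penalty: dict[int, float]
    k_optimal: int


def compute_fingerprints(dataset: OdorDataset, n_bits: int = 1024,
                         radius: int = 2) -> FingerprintMatrix:
    """ECFP bit-vector fingerprints; deterministic and atom-order invariant."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = np.zeros((len(dataset), n_bits), dtype=np.uint8)
    for i, rec in enumerate(dataset.records):
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise ValueError(f"record {rec.id}: invalid structure {rec.smiles!r}")
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1
    return FingerprintMatrix(ids=dataset.ids, bits=rows, radius=radius)


def tanimoto_matrix(fps: FingerprintMatrix) -> np.ndarray:
    """Pairwise Tanimoto similarity of binary fingerprints."""
    x = fps.bits.astype(np.float64)
    inter = x @ x.T
    pop = x.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def embed_umap(fps: FingerprintMatrix, seed: int = 0, n_neighbors: int = 15,
               min_dist: float = 0.1, metric: str = "jaccard") -> Embedding3D:
    """Reduce fingerprints to 3D with UMAP; reproducible for a fixed seed."""
    import umap  # deferred: numba compilation makes this import expensive

    n = fps.bits.shape[0]
    if n < 5:
        raise ValueError(f"too few molecules ({n}) for a 3D embedding")
    reducer = umap.UMAP(n_components=3, n_neighbors=min(n_neighbors, n - 1),
                        min_dist=min_dist, metric=metric, random_state=seed)
    coords = reducer.fit_transform(fps.bits)
    params = {"n_neighbors": int(min(n_neighbors, n - 1)), "min_dist": min_dist,
              "metric": metric, "seed": seed}
    return Embedding3D(ids=list(fps.ids), coords=np.asarray(coords, dtype=np.float64),
                       umap_params=params)


def cluster_kmeans(emb: Embedding3D, k: int, seed: int = 0,
                   n_restarts: int = 10) -> ClusterAssignment:
    """k-means on the embedding coordinates, best of ``n_restarts`` by WSS."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(emb.ids):
        raise ValueError("k exceeds the number of molecules")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(emb.coords)
    return ClusterAssignment(method="kmeans", level=k,
                             labels={i: int(l) + 1 for i, l in zip(emb.ids, labels)})


def kmeans_wss(emb: Embedding3D, k: int, seed: int = 0, n_restarts: int = 10) -> float:
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(emb.coords)
    return float(km.inertia_)


# ---------------------------------------------------------------------------
# Self-organizing map

def _som_train(data: np.ndarray, rows: int, cols: int, epochs: int,
               seed: int, lr0: float = 0.5, lr1: float = 0.01) -> np.ndarray:
    """Train a rectangular SOM; returns unit weights of shape (rows*cols, dim).

    Online Kohonen updates with a Gaussian grid neighborhood whose radius
    and the learning rate both decay linearly over epochs.
    """
    rng = np.random.default_rng(seed)
    n, dim = data.shape
    lo, hi = data.min(axis=0), data.max(axis=0)
    weights = rng.uniform(lo, hi, size=(rows * cols, dim))
    grid = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=np.float64)
    sigma0 = max(rows, cols) / 2.0
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = lr0 + (lr1 - lr0) * frac
        sigma = max(sigma0 * (1.0 - frac), 0.5)
        order = rng.permutation(n)
        for idx in order:
            x = data[idx]
            bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            d2 = ((grid - grid[bmu]) ** 2).sum(axis=1)
            h = np.exp(-d2 / (2.0 * sigma * sigma))
            weights += (lr * h)[:, None] * (x - weights)
    return weights


def quantization_error(data: np.ndarray, weights: np.ndarray) -> float:
    d = np.sqrt(((data[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())


def cluster_som(emb: Embedding3D, grid_rows: int, grid_cols: int,
                epochs: int = 500, seed: int = 0) -> ClusterAssignment:
    """Assign each molecule to its best-matching SOM unit (1-based, row-major).

    Empty units are permitted, so the number of effective clusters can be
    smaller than the grid size.
    """
    if grid_rows * grid_cols < 2:
        raise ValueError("SOM grid must contain at least 2 units")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    data = emb.coords
    rng = np.random.default_rng(seed)
    lo, hi = data.min(axis=0), data.max(axis=0)
    init_weights = rng.uniform(lo, hi, size=(grid_rows * grid_cols, data.shape[1]))
    weights = _som_train(data, grid_rows, grid_cols, epochs, seed)
    if quantization_error(data, weights) > quantization_error(data, init_weights):
        raise RuntimeError("SOM training failed to reduce quantization error")
    d = ((data[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
    bmu = d.argmin(axis=1)
    return ClusterAssignment(method="som", level=grid_rows * grid_cols,
                             grid=(grid_rows, grid_cols),
                             labels={i: int(b) + 1 for i, b in zip(emb.ids, bmu)})


# ---------------------------------------------------------------------------
# Cluster-count selection

def _partition_spread(coords: np.ndarray, labels: np.ndarray) -> float | None:
    """Mean over clusters (size >= 2) of the mean pairwise member distance."""
    spreads = []
    for c in np.unique(labels):
        pts = coords[labels == c]
        if len(pts) >= 2:
            spreads.append(pdist(pts).mean())
    return float(np.mean(spreads)) if spreads else None


def select_cluster_count(emb: Embedding3D, k_range: list[int] | range,
                         seed: int = 0, n_restarts: int = 10) -> ClusterSelectionReport:
    """Elbow WSS plus a Kelley-style penalty over flat k-means partitions.

    The per-k spread (mean within-cluster pairwise distance, clusters of
    size >= 2) is min-max scaled onto [1, len(k_range) - 1]; the penalty is
    scaled spread + k and the optimum is its argmin (ties -> smallest k).
    A k whose partition is all singletons has no defined spread and is
    excluded from the penalty ranking.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    if ks[0] < 2:
        raise ValueError("each k must be >= 2")
    wss: dict[int, float] = {}
    spreads: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(emb.coords)
        wss[k] = float(km.inertia_)
        s = _partition_spread(emb.coords, labels)
        if s is not None:
            spreads[k] = s
    if not spreads:
        raise ValueError("no k in k_range yields a cluster of size >= 2")
    vals = np.array([spreads[k] for k in sorted(spreads)])
    smin, smax = vals.min(), vals.max()
    hi = max(len(ks) - 1, 1)
    penalty: dict[int, float] = {}
    for k, s in spreads.items():
        norm = 1.0 if smax == smin else 1.0 + (s - smin) / (smax - smin) * (hi - 1)
        penalty[k] = norm + k
    k_optimal = min(penalty, key=lambda k: (penalty[k], k))
    return ClusterSelectionReport(k_range=ks, wss=wss, kelley_penalty=penalty,
                                  k_optimal=k_optimal)


# ---------------------------------------------------------------------------
# Small exact oracle used by the test-suite (exhaustive k-means optimum)

def exhaustive_min_wss(coords: np.ndarray, k: int) -> float:
    """Exact minimum WSS over all partitions into at most k non-empty parts.

    Exponential; intended for <= 10 points only.
    """
    n = len(coords)
    if n > 12:
        raise ValueError("exhaustive search limited to small instances")
    best = np.inf

    def wss_of(parts: list[list[int]]) -> float:
        tot = 0.0
        for part in parts:
            pts = coords[part]
            tot += ((pts - pts.mean(axis=0)) ** 2).sum()
        return tot

    def rec(i: int, parts: list[list[int]]):
        nonlocal best
        if i == n:
            if parts:
                best = min(best, wss_of(parts))
            return
        for part in parts:
            part.append(i)
            rec(i + 1, parts)
            part.pop()
        if len(parts) < k:
            parts.append([i])
            rec(i + 1, parts)
            parts.pop()

    rec(0, [])
    return float(best)
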