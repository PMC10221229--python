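"""Fingerprints, UMAP embedding, k-means / SOM clustering, cluster-count selection."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from odorspace.dataset import OdorDataset, OdorantRecord
from odorspace.embed import (
    ClusterAssignment,
    Embedding3D,
    cluster_kmeans,
    cluster_som,
    compute_fingerprints,
    embed_umap,
    exhaustive_min_wss,
    kmeans_wss,
    select_cluster_count,
    tanimoto_matrix,
)


def _mini_dataset(smiles: dict[str, str]) -> OdorDataset:
    recs = [OdorantRecord(id=k, name=k, smiles=v, notes=frozenset({"x"}))
            for k, v in smiles.items()]
    return OdorDataset(recs, min_note_occurrence=1)


def _blob_embedding(rng, centers, n_per=10, spread=0.05) -> Embedding3D:
    pts, ids = [], []
    for ci, c in enumerate(centers):
        for j in range(n_per):
            pts.append(np.asarray(c) + rng.normal(0, spread, 3))
            ids.append(f"b{ci}-{j}")
    return Embedding3D(ids=ids, coords=np.array(pts))


class TestFingerprints:
    def test_vanillin_has_set_bits(self):
        ds = _mini_dataset({"V": "COc1cc(C=O)ccc1O"})
        fps = compute_fingerprints(ds)
        assert fps.bits.shape == (1, 1024)
        assert fps.bits.sum() >= 1
        assert set(np.unique(fps.bits)) <= {0, 1}

    def test_smiles_spelling_invariance(self):
        ds = _mini_dataset({"a": "OC(=O)c1ccccc1", "b": "c1ccccc1C(O)=O"})
        fps = compute_fingerprints(ds)
        assert np.array_equal(fps.bits[0], fps.bits[1])

    def test_vanillin_vs_ethyl_acetate_dissimilar(self):
        ds = _mini_dataset({"V": "COc1cc(C=O)ccc1O", "EA": "CCOC(C)=O"})
        sim = tanimoto_matrix(compute_fingerprints(ds))
        assert sim[0, 1] < 0.3


class TestUmap:
    def test_shape_determinism_and_recorded_params(self, small_synthetic):
        ds, labels = small_synthetic
        fps = compute_fingerprints(ds)
        emb1 = embed_umap(fps, seed=3)
        emb2 = embed_umap(fps, seed=3)
        assert emb1.coords.shape == (len(ds), 3)
        assert np.all(np.isfinite(emb1.coords))
        assert np.allclose(emb1.coords, emb2.coords)
        assert emb1.umap_params["metric"] == "jaccard"

    def test_families_are_compact_in_embedding(self, small_synthetic):
        ds, labels = small_synthetic
        emb = embed_umap(compute_fingerprints(ds), seed=3)
        fam = np.array([labels[i] for i in emb.ids])
        core = fam != "background"
        d = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=2)
        same = (fam[:, None] == fam[None, :]) & ~np.eye(len(fam), dtype=bool)
        mask = core[:, None] & core[None, :]
        assert d[same & mask].mean() < d[~same & mask].mean()

    def test_too_few_molecules_rejected(self):
        ds = _mini_dataset({"a": "CCO", "b": "CCC"})
        with pytest.raises(ValueError, match="too few"):
            embed_umap(compute_fingerprints(ds))


class TestKMeans:
    def test_k1_single_cluster(self, rng):
        emb = _blob_embedding(rng, [(0, 0, 0)], n_per=8)
        asg = cluster_kmeans(emb, 1)
        assert set(asg.labels.values()) == {1}

    def test_k_equals_n_gives_zero_wss(self, rng):
        emb = _blob_embedding(rng, [(0, 0, 0)], n_per=6)
        assert kmeans_wss(emb, 6) == pytest.approx(0.0, abs=1e-12)

    def test_two_blobs_recovered(self, rng):
        emb = _blob_embedding(rng, [(0, 0, 0), (10, 0, 0)], n_per=5)
        asg = cluster_kmeans(emb, 2, seed=0)
        first = {asg.labels[i] for i in emb.ids[:5]}
        second = {asg.labels[i] for i in emb.ids[5:]}
        assert len(first) == len(second) == 1 and first != second

    def test_best_of_restarts_matches_exhaustive_minimum(self, rng):
        """On tiny instances k-means must reach the global WSS optimum."""
        for k in (2, 3):
            coords = rng.normal(0, 1, size=(8, 3))
            emb = Embedding3D(ids=[f"p{i}" for i in range(8)], coords=coords)
            assert kmeans_wss(emb, k, n_restarts=30) == pytest.approx(
                exhaustive_min_wss(coords, k), rel=1e-6)

    def test_invalid_k(self, rng):
        emb = _blob_embedding(rng, [(0, 0, 0)], n_per=4)
        with pytest.raises(ValueError):
            cluster_kmeans(emb, 0)
        with pytest.raises(ValueError):
            cluster_kmeans(emb, 99)


class TestSom:
    def test_grid_bounds_label_count(self, rng):
        emb = _blob_embedding(rng, [(0, 0, 0), (5, 5, 5)], n_per=20, spread=1.0)
        asg = cluster_som(emb, 4, 4, epochs=50, seed=0)
        assert asg.effective_clusters <= 16
        assert set(asg.labels) == set(emb.ids)

    def test_single_point_degenerate(self):
        emb = Embedding3D(ids=["only"], coords=np.zeros((1, 3)))
        asg = cluster_som(emb, 1, 2, epochs=5, seed=0)
        assert len(set(asg.labels.values())) == 1

    def test_two_blobs_agree_with_kmeans(self, rng):
        emb = _blob_embedding(rng, [(0, 0, 0), (10, 0, 0)], n_per=10)
        som = cluster_som(emb, 2, 1, epochs=100, seed=0)
        km = cluster_kmeans(emb, 2, seed=0)
        ids = emb.ids
        ari = adjusted_rand_score([som.labels[i] for i in ids],
                                  [km.labels[i] for i in ids])
        assert ari == pytest.approx(1.0)

    def test_deterministic(self, rng):
        emb = _blob_embedding(rng, [(0, 0, 0), (3, 3, 3)], n_per=10, spread=0.5)
        a = cluster_som(emb, 3, 3, epochs=30, seed=5)
        b = cluster_som(emb, 3, 3, epochs=30, seed=5)
        assert a.labels == b.labels

    def test_zero_epochs_rejected(self, rng):
        emb = _blob_embedding(rng, [(0, 0, 0)], n_per=4)
        with pytest.raises(ValueError):
            cluster_som(emb, 2, 2, epochs=0)


class TestClusterCountSelection:
    def test_four_planted_blobs_give_k4(self, rng):
        centers = [(0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, 10)]
        emb = _blob_embedding(rng, centers, n_per=12, spread=0.3)
        rep = select_cluster_count(emb, range(2, 11), seed=0)
        assert rep.k_optimal == 4
        # WSS elbow: non-increasing in k
        ks = rep.k_range
        assert all(rep.wss[a] >= rep.wss[b] - 1e-9 for a, b in zip(ks, ks[1:]))

    def test_single_blob_never_selects_many_clusters(self, rng):
        # one Gaussian blob: the +k term dominates once the spread term
        # flattens, so the penalty rises through the tail and the optimum
        # stays at the very low end of the range
        emb = _blob_embedding(rng, [(0, 0, 0)], n_per=30, spread=1.0)
        rep = select_cluster_count(emb, range(2, 8), seed=0)
        pens = [rep.kelley_penalty[k] for k in rep.k_range]
        tail = pens[2:]
        assert all(a < b for a, b in zip(tail, tail[1:]))
        assert rep.k_optimal <= 3

    def test_duplicated_points_keep_same_optimum(self, rng):
        centers = [(0, 0, 0), (8, 0, 0), (0, 8, 0)]
        emb = _blob_embedding(rng, centers, n_per=8, spread=0.3)
        dup = Embedding3D(ids=emb.ids + [f"{i}+" for i in emb.ids],
                          coords=np.vstack([emb.coords, emb.coords]))
        a = select_cluster_count(emb, range(2, 8), seed=0)
        b = select_cluster_count(dup, range(2, 8), seed=0)
        assert a.k_optimal == b.k_optimal == 3

    def test_invalid_ranges(self, rng):
        emb = _blob_embedding(rng, [(0, 0, 0)], n_per=5)
        with pytest.raises(ValueError):
            select_cluster_count(emb, [])
        with pytest.raises(ValueError):
            select_cluster_count(emb, [1, 2])


def test_assignment_validation():
    with pytest.raises(ValueError, match="method"):
        ClusterAssignment(method="dbscan", level=2, labels={"a": 1})
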