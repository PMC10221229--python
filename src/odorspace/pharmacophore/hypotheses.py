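"""Common-feature pharmacophore hypothesis search.

A hypothesis is a rigid arrangement of >= 3 typed feature points (A/H/R)
that a required fraction of the input molecules can present in at least
one conformer, each within a geometric tolerance (feature RMSD after
least-squares superposition, default 2 A).

Search: every conformer of every molecule contributes candidate feature
subsets (size ``min_features``..``max_features``).  Candidates are grouped
by kind signature and compared through their sorted interfeature distance
vectors: two candidates are compatible when every corresponding distance
agrees within the tolerance (a 1 A-binned key is used to deduplicate, the
decision itself uses the real distances).  A candidate key presented by
enough molecules seeds a hypothesis: the reference subset comes from the
molecule with the fewest conformers, every other molecule is aligned by
its best type-preserving rigid superposition, and molecules within the
RMSD tolerance count as matched.

The score is transparent (the commercial ranking score of the original
workflow is proprietary):

    score = 0.4 * matched_fraction
          + 0.4 * (1 - mean_rmsd / tolerance)
          + 0.2 * (n_features - min_features + 1) / 4

i.e. coverage, geometric tightness, and feature richness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from odorspace.pharmacophore.conformers import ConformerEnsemble
from odorspace.pharmacophore.features import FeaturePoint, perceive_features

DEFAULT_SCORE_WEIGHTS = (0.4, 0.4, 0.2)


@dataclass
class PharmacophoreHypothesis:
    features: list[FeaturePoint]
    tolerance: float
    matched: dict[str, float]  # molecule id -> feature RMSD (A)
    score: float
    reference_molecule: str
    reference_conformer: int
    partial: dict[str, float] = field(default_factory=dict)  # sub-threshold audit

    def __post_init__(self) -> None:
        if len(self.features) < 3:
            raise ValueError("a hypothesis needs at least 3 features")

    @property
    def signature(self) -> str:
        return "".join(sorted(f.kind for f in self.features))

    @property
    def positions(self) -> np.ndarray:
        return np.array([f.xyz for f in self.features])

    @property
    def feature_labels(self) -> list[str]:
        """Labels "A1", "A2", "H3", ... : kind-sorted, 1-based positions."""
        order = sorted(range(len(self.features)), key=lambda i: self.features[i].kind)
        labels = [""] * len(self.features)
        for rank, i in enumerate(order, start=1):
            labels[i] = f"{self.features[i].kind}{rank}"
        return labels

    @property
    def distance_matrix(self) -> np.ndarray:
        pos = self.positions
        return np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)

    def feature_distance(self, label_a: str, label_b: str) -> float:
        labels = self.feature_labels
        return float(self.distance_matrix[labels.index(label_a), labels.index(label_b)])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "signature": self.signature,
            "tolerance": self.tolerance,
            "score": self.score,
            "reference_molecule": self.reference_molecule,
            "reference_conformer": self.reference_conformer,
            "matched": self.matched,
            "partial": self.partial,
            "features": [
                {"label": lab, "kind": f.kind, "position": list(f.position),
                 "source_atoms": list(f.source_atoms)}
                for lab, f in zip(self.feature_labels, self.features)
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def interfeature_distances(h: PharmacophoreHypothesis) -> list[tuple[str, str, float]]:
    """All pairwise feature distances, labeled "A1"/"H3"-style."""
    labels = h.feature_labels
    dm = h.distance_matrix
    out = []
    for i, j in combinations(range(len(labels)), 2):
        a, b = sorted((labels[i], labels[j]))
        out.append((a, b, float(dm[labels.index(a), labels.index(b)])))
    return sorted(out)


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between paired point sets under rigid rotation+translation."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    e = np.array([1.0, 1.0, d])
    ssd = (p ** 2).sum() + (q ** 2).sum() - 2.0 * (s * e).sum()
    return math.sqrt(max(ssd, 0.0) / len(p))


def best_typed_superposition(kinds_a: list[str], pos_a: np.ndarray,
                             kinds_b: list[str], pos_b: np.ndarray) -> float | None:
    """Min RMSD over kind-preserving bijections of two equal-size feature sets."""
    if sorted(kinds_a) != sorted(kinds_b):
        return None
    by_kind_b: dict[str, list[int]] = {}
    for i, k in enumerate(kinds_b):
        by_kind_b.setdefault(k, []).append(i)
    kinds = sorted(by_kind_b)
    a_groups = [[i for i, k in enumerate(kinds_a) if k == kind] for kind in kinds]
    best = None
    perm_sets = [list(permutations(by_kind_b[kind])) for kind in kinds]

    def rec(gi: int, mapping: list[tuple[int, int]]):
        nonlocal best
        if gi == len(kinds):
            ia = [m[0] for m in mapping]
            ib = [m[1] for m in mapping]
            r = kabsch_rmsd(pos_a[ia], pos_b[ib])
            if best is None or r < best:
                best = r
            return
        for perm in perm_sets[gi]:
            rec(gi + 1, mapping + list(zip(a_groups[gi], perm)))

    rec(0, [])
    return best


@dataclass(frozen=True)
class _Candidate:
    mol_idx: int
    conf_id: int
    kinds: tuple[str, ...]       # sorted-by-kind order, aligned with positions
    positions: np.ndarray
    sorted_dists: np.ndarray     # sorted pairwise distances

    @property
    def signature(self) -> str:
        return "".join(self.kinds)

    @property
    def bin_key(self) -> tuple:
        return (self.signature, tuple(np.rint(self.sorted_dists).astype(int)))


def _enumerate_candidates(ensemble: ConformerEnsemble, mol_idx: int,
                          min_features: int, max_features: int,
                          aromatic_as_hydrophobic: bool,
                          feature_map: dict[int, list[FeaturePoint]] | None = None
                          ) -> list[_Candidate]:
    cands: list[_Candidate] = []
    conf_ids = sorted(feature_map) if feature_map is not None else ensemble.conformer_ids
    for cid in conf_ids:
        if feature_map is not None:
            feats = feature_map[cid]
        else:
            feats = perceive_features(ensemble.mol, cid,
                                      aromatic_as_hydrophobic=aromatic_as_hydrophobic)
        if len(feats) < min_features:
            continue
        for size in range(min_features, min(max_features, len(feats)) + 1):
            for combo in combinations(range(len(feats)), size):
                chosen = sorted((feats[i] for i in combo), key=lambda f: f.kind)
                pos = np.array([f.xyz for f in chosen])
                cands.append(_Candidate(
                    mol_idx=mol_idx, conf_id=cid,
                    kinds=tuple(f.kind for f in chosen), positions=pos,
                    sorted_dists=np.sort(pdist(pos)),
                ))
    return cands


def _compatible(a: _Candidate, b: _Candidate, tolerance: float) -> bool:
    return (a.kinds == b.kinds
            and bool(np.all(np.abs(a.sorted_dists - b.sorted_dists) <= tolerance)))


def find_common_pharmacophores(
    ensembles: list[ConformerEnsemble],
    min_features: int = 3,
    tolerance: float = 2.0,
    match_fraction: float = 0.5,
    max_hypotheses: int = 10,
    max_features: int = 6,
    aromatic_as_hydrophobic: bool = False,
    feature_sets: list[dict[int, list[FeaturePoint]]] | None = None,
) -> list[PharmacophoreHypothesis]:
    """Ranked common-feature hypotheses over a set of conformer ensembles.

    With a single ensemble this degenerates to the molecule's own
    conformational-space pharmacophore.  Returns an empty list when no
    arrangement satisfies the constraints.  Ties in score are resolved
    toward more features, then lexicographic signature.

    ``feature_sets`` (one ``{conformer_id: [FeaturePoint, ...]}`` mapping
    per ensemble) bypasses structural feature perception; it exists for
    planted-geometry validation.
    """
    if not ensembles:
        raise ValueError("at least one conformer ensemble is required")
    if feature_sets is not None and len(feature_sets) != len(ensembles):
        raise ValueError("feature_sets must align with ensembles")
    n_mol = len(ensembles)
    need = max(1, math.ceil(match_fraction * n_mol))

    per_mol: list[list[_Candidate]] = [
        _enumerate_candidates(ens, i, min_features, max_features, aromatic_as_hydrophobic,
                              feature_sets[i] if feature_sets is not None else None)
        for i, ens in enumerate(ensembles)
    ]
    # deduplicate per molecule by binned key (keeps the lowest-energy conformer's
    # representative; candidates are enumerated in energy-ladder order)
    dedup: list[dict[tuple, _Candidate]] = []
    for cands in per_mol:
        keyed: dict[tuple, _Candidate] = {}
        for c in cands:
            keyed.setdefault(c.bin_key, c)
        dedup.append(keyed)

    # reference molecule preference: fewest conformers, then input order
    ref_order = sorted(range(n_mol), key=lambda i: (ensembles[i].n_conformers, i))

    hypotheses: list[PharmacophoreHypothesis] = []
    seen_keys: set[tuple] = set()
    for ref_idx in ref_order:
        for key, ref_cand in sorted(dedup[ref_idx].items()):
            if key in seen_keys:
                continue
            support = [m for m in range(n_mol)
                       if any(_compatible(ref_cand, c, tolerance)
                              for c in dedup[m].values())]
            if len(support) < need:
                continue
            seen_keys.add(key)
            matched: dict[str, float] = {ensembles[ref_idx].molecule_id: 0.0}
            partial: dict[str, float] = {}
            rmsds = [0.0]
            for m in range(n_mol):
                if m == ref_idx:
                    continue
                best: float | None = None
                for c in per_mol[m]:
                    if not _compatible(ref_cand, c, tolerance):
                        continue
                    r = best_typed_superposition(list(ref_cand.kinds), ref_cand.positions,
                                                 list(c.kinds), c.positions)
                    if r is not None and (best is None or r < best):
                        best = r
                if best is None:
                    continue
                if best <= tolerance:
                    matched[ensembles[m].molecule_id] = best
                    rmsds.append(best)
                else:
                    partial[ensembles[m].molecule_id] = best
            if len(matched) < need:
                continue
            n_feat = len(ref_cand.kinds)
            w_cov, w_geo, w_rich = DEFAULT_SCORE_WEIGHTS
            score = (w_cov * len(matched) / n_mol
                     + w_geo * (1.0 - float(np.mean(rmsds)) / tolerance)
                     + w_rich * (n_feat - min_features + 1) / 4.0)
            center = ref_cand.positions.mean(axis=0)
            feats = [FeaturePoint(kind, tuple(xyz - center), ())
                     for kind, xyz in zip(ref_cand.kinds, ref_cand.positions)]
            hypotheses.append(PharmacophoreHypothesis(
                features=feats, tolerance=tolerance, matched=matched, score=score,
                reference_molecule=ensembles[ref_idx].molecule_id,
                reference_conformer=ref_cand.conf_id, partial=partial))

    # score rounded so that float-epsilon jitter (e.g. after a rigid motion of
    # all inputs) cannot reorder genuinely tied hypotheses; residual ties fall
    # through to feature count, signature, then the distance geometry itself
    hypotheses.sort(key=lambda h: (
        -round(h.score, 9), -len(h.features), h.signature,
        tuple(np.round(np.sort(pdist(h.positions)), 6))))
    return hypotheses[:max_hypotheses]
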