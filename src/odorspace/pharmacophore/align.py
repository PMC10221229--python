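"""Pairwise alignment of pharmacophore hypotheses.

Two hypotheses are compared by searching every kind-preserving pairing of
at least three features (one hypothesis acting as the template), rigidly
superposing each pairing by least squares, and keeping the minimum-RMSD
pairing.  The comparison is declared a failure — no alignment, mirroring
a "-" entry in a comparison table — when no pairing of size >= 3 exists
or the best RMSD exceeds the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

from odorspace.pharmacophore.hypotheses import PharmacophoreHypothesis, kabsch_rmsd


@dataclass
class HypothesisAlignment:
    reference_id: str
    other_id: str
    feature_mapping: list[tuple[str, str]]  # (reference label, other label)
    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray


class AlignmentFailure(Exception):
    """No acceptable type-preserving feature pairing exists."""

    def __init__(self, reference_id: str, other_id: str, reason: str):
        super().__init__(f"{reference_id} vs {other_id}: {reason}")
        self.reference_id = reference_id
        self.other_id = other_id
        self.reason = reason


def _rigid_transform(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R q + t - p||."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, pc - r @ qc


def align_hypotheses(reference: PharmacophoreHypothesis,
                     other: PharmacophoreHypothesis,
                     rmsd_cutoff: float = 2.0,
                     r_as_h: bool = False,
                     reference_id: str = "reference",
                     other_id: str = "other") -> HypothesisAlignment:
    """Best type-preserving superposition of two hypotheses.

    ``r_as_h`` lets aromatic-ring features pair with hydrophobic features
    (both re-typed to H for the pairing search).  Raises
    :class:`AlignmentFailure` when no pairing of >= 3 features exists or
    the minimum RMSD exceeds ``rmsd_cutoff``.
    """
    def kinds_of(h: PharmacophoreHypothesis) -> list[str]:
        ks = [f.kind for f in h.features]
        return ["H" if (r_as_h and k == "R") else k for k in ks]

    ka, kb = kinds_of(reference), kinds_of(other)
    pa, pb = reference.positions, other.positions
    la, lb = reference.feature_labels, other.feature_labels

    best: tuple[float, list[tuple[int, int]]] | None = None
    na, nb = len(ka), len(kb)
    for size in range(3, min(na, nb) + 1):
        for sub_a in combinations(range(na), size):
            kinds_a = sorted(ka[i] for i in sub_a)
            for sub_b in combinations(range(nb), size):
                if sorted(kb[i] for i in sub_b) != kinds_a:
                    continue
                # kind-preserving bijections between the two subsets
                by_kind_b: dict[str, list[int]] = {}
                for i in sub_b:
                    by_kind_b.setdefault(kb[i], []).append(i)
                groups_a = {}
                for i in sub_a:
                    groups_a.setdefault(ka[i], []).append(i)
                kinds = sorted(groups_a)
                perm_sets = [list(permutations(by_kind_b[k])) for k in kinds]

                def rec(gi: int, mapping: list[tuple[int, int]]):
                    nonlocal best
                    if gi == len(kinds):
                        ia = [m[0] for m in mapping]
                        ib = [m[1] for m in mapping]
                        r = kabsch_rmsd(pa[ia], pb[ib])
                        if best is None or r < best[0]:
                            best = (r, list(mapping))
                        return
                    for perm in perm_sets[gi]:
                        rec(gi + 1, mapping + list(zip(groups_a[kinds[gi]], perm)))

                rec(0, [])

    if best is None:
        raise AlignmentFailure(reference_id, other_id,
                               "no type-preserving pairing of >= 3 features")
    rmsd, mapping = best
    if rmsd > rmsd_cutoff:
        raise AlignmentFailure(
            reference_id, other_id,
            f"best pairing RMSD {rmsd:.3f} A exceeds cutoff {rmsd_cutoff} A")
    ia = [m[0] for m in mapping]
    ib = [m[1] for m in mapping]
    rot, trans = _rigid_transform(pa[ia], pb[ib])
    return HypothesisAlignment(
        reference_id=reference_id, other_id=other_id,
        feature_mapping=[(la[i], lb[j]) for i, j in mapping],
        rmsd=float(rmsd), rotation=rot, translation=trans)
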