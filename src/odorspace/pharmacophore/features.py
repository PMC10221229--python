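"""Pharmacophore feature perception.

Three feature kinds are perceived on a 3D conformer:

* ``A`` — hydrogen-bond acceptor, placed on the acceptor atom nucleus.
  Acceptors are matched by an editable SMARTS pattern file (carbonyl,
  ether/ester/hydroxyl oxygens, basic nitrogens).  Donor features are
  deliberately not emitted: every donor of interest here is also an
  acceptor, so the acceptor feature subsumes them.
* ``H`` — hydrophobic group, placed at the heavy-atom centroid of a
  contiguous group of non-polar carbons (carbons with no heteroatom
  neighbor).  Groups need >= 2 atoms, except single terminal methyls,
  which count as minimal hydrophobic clusters.
* ``R`` — aromatic ring, placed at the ring centroid, with the ring-plane
  normal attached.  The ``aromatic_as_hydrophobic`` option re-types every
  R into an H (ring treated as a hydrophobic disc), matching one modelling
  convention for receptor-unknown targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem

FEATURE_KINDS = ("A", "H", "R")


@dataclass(frozen=True)
class FeaturePoint:
    kind: str
    position: tuple[float, float, float]
    source_atoms: tuple[int, ...]
    ring_normal: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite feature position")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=np.float64)


def _default_pattern_path() -> Path:
    return Path(str(resources.files("odorspace.fixtures").joinpath("feature_patterns.smarts")))


def load_acceptor_patterns(path: str | Path | None = None) -> list[Chem.Mol]:
    """Parse the tab-separated SMARTS pattern file (acceptor patterns only)."""
    path = Path(path) if path is not None else _default_pattern_path()
    patterns: list[Chem.Mol] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, smarts = line.split("\t")[:2]
        if kind != "A":
            continue
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in pattern file: {smarts!r}")
        patterns.append(patt)
    return patterns


_PATTERN_CACHE: list[Chem.Mol] | None = None


def _acceptor_atoms(mol: Chem.Mol) -> list[int]:
    global _PATTERN_CACHE
    if _PATTERN_CACHE is None:
        _PATTERN_CACHE = load_acceptor_patterns()
    atoms: set[int] = set()
    for patt in _PATTERN_CACHE:
        for match in mol.GetSubstructMatches(patt):
            atoms.add(match[0])  # pattern convention: acceptor atom first
    return sorted(atoms)


def _hydrophobic_groups(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Connected groups of non-polar carbons; singleton terminal methyls kept."""
    candidate = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if all(nb.GetAtomicNum() in (1, 6) for nb in atom.GetNeighbors()):
            candidate.add(atom.GetIdx())
    # connected components within the candidate set
    groups: list[tuple[int, ...]] = []
    todo = set(candidate)
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            a = frontier.pop()
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                i = nb.GetIdx()
                if i in todo:
                    todo.discard(i)
                    comp.add(i)
                    frontier.append(i)
        if len(comp) >= 2:
            groups.append(tuple(sorted(comp)))
        else:
            atom = mol.GetAtomWithIdx(next(iter(comp)))
            if atom.GetDegree() == 1:  # terminal methyl cluster
                groups.append(tuple(comp))
    return sorted(groups)


def _aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(tuple(sorted(ring)))
    return sorted(rings)


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    return normal / np.linalg.norm(normal)


def perceive_features(mol: Chem.Mol, conf_id: int = -1,
                      aromatic_as_hydrophobic: bool = False) -> list[FeaturePoint]:
    """Perceive A/H/R features on one conformer of a molecule.

    Returns an empty list (valid, but flagged to the logger) when the
    molecule carries no feature at all.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()

    feats: list[FeaturePoint] = []
    for idx in _acceptor_atoms(mol):
        feats.append(FeaturePoint("A", tuple(pos[idx]), (idx,)))
    for group in _hydrophobic_groups(mol):
        centroid = pos[list(group)].mean(axis=0)
        feats.append(FeaturePoint("H", tuple(centroid), group))
    for ring in _aromatic_rings(mol):
        coords = pos[list(ring)]
        kind = "H" if aromatic_as_hydrophobic else "R"
        normal = None if aromatic_as_hydrophobic else tuple(_ring_normal(coords))
        feats.append(FeaturePoint(kind, tuple(coords.mean(axis=0)), ring,
                                  ring_normal=normal))
    return feats
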