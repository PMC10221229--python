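"""Conformer-ensemble generation.

Each molecule is represented by an ensemble of force-field-minimized
conformers: up to a target count (default 50), retained within an energy
window above the ensemble minimum (default 21 kJ/mol) and deduplicated at
0.5 A heavy-atom RMSD.  Distance-geometry embedding (ETKDG) with a fixed
seed makes ensembles reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign

KCAL_TO_KJ = 4.184


class EmbeddingError(RuntimeError):
    pass


@dataclass
class ConformerEnsemble:
    """A molecule plus its retained 3D conformers and relative energies (kJ/mol)."""

    molecule_id: str
    mol: Chem.Mol  # heavy-atom molecule carrying the retained conformers
    energies: list[float]  # relative to the ensemble minimum, aligned with conformers

    def __post_init__(self) -> None:
        n = self.mol.GetNumConformers()
        if n < 1:
            raise ValueError(f"{self.molecule_id}: ensemble has no conformer")
        if len(self.energies) != n:
            raise ValueError(f"{self.molecule_id}: energy list does not match conformers")
        if min(self.energies) < -1e-9:
            raise ValueError(f"{self.molecule_id}: relative energies must be >= 0")

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    @property
    def conformer_ids(self) -> list[int]:
        return [c.GetId() for c in self.mol.GetConformers()]


def generate_conformers(smiles_or_mol: str | Chem.Mol, molecule_id: str = "",
                        target_count: int = 50, energy_window_kj: float = 21.0,
                        seed: int = 0, dedup_rmsd: float = 0.5) -> ConformerEnsemble:
    """Generate a minimized, energy-filtered, deduplicated conformer ensemble."""
    if isinstance(smiles_or_mol, str):
        mol = Chem.MolFromSmiles(smiles_or_mol)
        if mol is None:
            raise ValueError(f"unparsable SMILES {smiles_or_mol!r}")
        molecule_id = molecule_id or smiles_or_mol
    else:
        mol = Chem.Mol(smiles_or_mol)
        molecule_id = molecule_id or Chem.MolToSmiles(mol)
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    params.numThreads = 1
    conf_ids = list(AllChem.EmbedMultipleConfs(molh, numConfs=target_count, params=params))
    if not conf_ids:
        raise EmbeddingError(f"conformer embedding failed for {molecule_id}")

    results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=2000)
    energies: dict[int, float] = {}
    for cid, (converged, energy) in zip(conf_ids, results):
        if converged == 0:  # 0 = converged
            energies[cid] = energy * KCAL_TO_KJ
    if not energies:
        raise EmbeddingError(f"force-field minimization failed for {molecule_id}")
    e_min = min(energies.values())

    # energy filter, then greedy dedup from the bottom of the energy ladder
    ladder = sorted(energies, key=lambda c: energies[c])
    molh_noH = Chem.RemoveHs(molh)
    kept: list[int] = []
    for cid in ladder:
        rel = energies[cid] - e_min
        if rel > energy_window_kj:
            continue
        duplicate = False
        for kid in kept:
            probe = Chem.Mol(molh_noH)  # GetBestRMS aligns in place; protect kept confs
            if rdMolAlign.GetBestRMS(probe, molh_noH, prbId=cid, refId=kid) < dedup_rmsd:
                duplicate = True
                break
        if not duplicate:
            kept.append(cid)

    out = Chem.Mol(molh_noH)
    out.RemoveAllConformers()
    new_energies = []
    for cid in kept:
        conf = Chem.Conformer(molh_noH.GetConformer(cid))
        out.AddConformer(conf, assignId=True)
        new_energies.append(energies[cid] - e_min)
    return ConformerEnsemble(molecule_id=molecule_id, mol=out, energies=new_energies)
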