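#!/usr/bin/env python
"""Pairwise alignment of the pharmacophore hypotheses.

Compares the single-molecule ("-c") and subset ("-s") hypotheses of the
key components (V, IA, F, WL) in pairs: least-squares superposition of
the best type-preserving feature pairing (>= 3 features, 2 A cutoff).
Failures are reported as "-", reproducing the masking-vs-blending
contrast: the WL/IA hypotheses overlay well, the blending-mixture
phenolics do not, or not at all.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from odorspace.pharmacophore import AlignmentFailure, align_hypotheses
from odorspace.pharmacophore.features import FeaturePoint
from odorspace.pharmacophore.hypotheses import PharmacophoreHypothesis

OUT = Path(__file__).resolve().parents[1] / "results"

PAIRS = [
    ("hyp_V_c", "hyp_IA_c"), ("hyp_V_c", "hyp_F_c"), ("hyp_IA_c", "hyp_F_c"),
    ("hyp_WL_c", "hyp_IA_c"),
    ("hyp_V_s", "hyp_IA_s"), ("hyp_V_s", "hyp_F_s"), ("hyp_IA_s", "hyp_F_s"),
    ("hyp_WL_s", "hyp_IA_s"),
    ("hyp_V_c", "hyp_V_s"), ("hyp_IA_c", "hyp_IA_s"), ("hyp_F_c", "hyp_F_s"),
    ("hyp_WL_c", "hyp_WL_s"),
]


def load(name: str) -> PharmacophoreHypothesis | None:
    path = OUT / f"{name}.json"
    if not path.exists():
        return None
    data = json.loads(path.read_text())
    feats = [FeaturePoint(f["kind"], tuple(f["position"]), tuple(f["source_atoms"]))
             for f in data["features"]]
    return PharmacophoreHypothesis(
        features=feats, tolerance=data["tolerance"], matched=data["matched"],
        score=data["score"], reference_molecule=data["reference_molecule"],
        reference_conformer=data["reference_conformer"])


def main() -> None:
    rows = []
    for a, b in PAIRS:
        ha, hb = load(a), load(b)
        label_a, label_b = a.replace("_", "-"), b.replace("_", "-")
        if ha is None or hb is None:
            rows.append((label_a, label_b, "-", "hypothesis unavailable"))
            continue
        try:
            res = align_hypotheses(ha, hb, reference_id=a, other_id=b)
            rows.append((label_a, label_b, f"{res.rmsd:.4f}", ""))
        except AlignmentFailure as exc:
            rows.append((label_a, label_b, "-", exc.reason))
    with (OUT / "hypothesis_alignments.csv").open("w") as fh:
        fh.write("reference,other,rmsd,comment\n")
        for row in rows:
            fh.write(",".join(row) + "\n")
    width = max(len(f"{a}  vs  {b}") for a, b, *_ in rows)
    print("pairwise hypothesis alignment (feature RMSD, A; '-' = failure)")
    for a, b, rmsd, comment in rows:
        print(f"  {f'{a}  vs  {b}':<{width}}  {rmsd:>7}  {comment}")


if __name__ == "__main__":
    main()
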