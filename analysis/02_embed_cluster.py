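#!/usr/bin/env python
"""Fingerprint, embed, and cluster the odorant database.

1024-bit ECFP fingerprints -> 3D UMAP (Jaccard metric) -> cluster-count
selection (elbow WSS + Kelley penalty) -> k-means and SOM partitions at
levels 4 / 9 / 16 (SOM grids 2x2, 3x3, 4x4).  Reports where the seven
planted mixture components land and how well the SOM recovers the
generating families.

Reads results/dataset.csv + families.csv; writes embedding, assignment
and selection tables under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
from sklearn.metrics import adjusted_rand_score

from odorspace.dataset import read_odorant_table
from odorspace.embed import (cluster_kmeans, cluster_som, compute_fingerprints,
                             embed_umap, select_cluster_count)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results"
COMPONENTS = ("V", "IA", "F", "EA", "bI", "bD", "WL")
LEVELS = {4: (2, 2), 9: (3, 3), 16: (4, 4)}


def main() -> None:
    ds = read_odorant_table(OUT / "dataset.csv")
    families = dict(line.strip().split(",") for line in
                    (OUT / "families.csv").read_text().splitlines()[1:])

    fps = compute_fingerprints(ds)
    emb = embed_umap(fps, seed=SEED)
    with (OUT / "embedding.csv").open("w") as fh:
        fh.write("id,x,y,z\n")
        for rid, row in zip(emb.ids, emb.coords):
            fh.write(f"{rid},{row[0]:.6f},{row[1]:.6f},{row[2]:.6f}\n")

    report = select_cluster_count(emb, range(2, 11), seed=SEED)
    with (OUT / "cluster_selection.csv").open("w") as fh:
        fh.write("k,wss,kelley_penalty\n")
        for k in report.k_range:
            fh.write(f"{k},{report.wss[k]:.4f},{report.kelley_penalty[k]:.4f}\n")
    print(f"Kelley penalty optimum: k = {report.k_optimal} "
          f"(four families were planted)")

    rows = {c: {} for c in COMPONENTS}
    for level, grid in LEVELS.items():
        km = cluster_kmeans(emb, level, seed=SEED)
        som = cluster_som(emb, *grid, seed=SEED)
        for name, asg in ((f"kmeans{level}", km), (f"som{level}", som)):
            with (OUT / f"assignment_{name}.csv").open("w") as fh:
                fh.write("id,method,level,cluster\n")
                for rid in emb.ids:
                    fh.write(f"{rid},{asg.method},{level},{asg.labels[rid]}\n")
            for c in COMPONENTS:
                rows[c][name] = asg.labels.get(c, "-")
        print(f"L{level}: SOM uses {som.effective_clusters}/{level} units "
              f"(empty units are allowed), k-means {km.effective_clusters}/{level}")
        truth = np.array([families.get(i, "planted") for i in emb.ids])
        core = np.isin(truth, ["esters", "vanilloids", "lactones", "ionones"])
        lab = np.array([som.labels[i] for i in emb.ids])
        print(f"     SOM vs families ARI (family molecules): "
              f"{adjusted_rand_score(truth[core], lab[core]):.3f}")

    with (OUT / "component_clusters.csv").open("w") as fh:
        cols = [f"{m}{l}" for l in LEVELS for m in ("kmeans", "som")]
        fh.write("component," + ",".join(cols) + "\n")
        for c in COMPONENTS:
            fh.write(c + "," + ",".join(str(rows[c][col]) for col in cols) + "\n")
    print("component cluster membership -> results/component_clusters.csv")


if __name__ == "__main__":
    main()
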