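#!/usr/bin/env python
"""Odor-note profiles and co-occurrence structure of the SOM clusters.

For the finest SOM partition: per-cluster %ON / %OM profiles over the 25
most frequent notes (radar-chart tables) and relative co-occurrence
heatmap tables, whole-dataset and restricted to the clusters hosting the
mixture components.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from odorspace.dataset import read_odorant_table
from odorspace.stats import (cooccurrence, export_heatmap_tables,
                             export_profile_tables, note_profiles,
                             top_frequent_notes)

OUT = Path(__file__).resolve().parents[1] / "results"
COMPONENTS = ("V", "IA", "F", "EA", "bI", "bD", "WL")


def read_assignment(path):
    from odorspace.embed import ClusterAssignment
    labels = {}
    method, level = "som", 16
    for line in Path(path).read_text().splitlines()[1:]:
        rid, method, level, c = line.split(",")
        labels[rid] = int(c)
    return ClusterAssignment(method=method, level=int(level), labels=labels)


def main() -> None:
    ds = read_odorant_table(OUT / "dataset.csv")
    asg = read_assignment(OUT / "assignment_som16.csv")

    notes = top_frequent_notes(ds, min(25, len(ds.vocabulary)))
    stats = note_profiles(ds, asg, notes)
    export_profile_tables(stats, OUT / "profiles_som16.csv")

    by = {(s.note, s.cluster): s for s in stats}
    print("cluster hosting each mixture component, with its most typical note")
    for comp in COMPONENTS:
        cl = asg.labels[comp]
        best = max((s for s in stats if s.cluster == cl), key=lambda s: s.pct_OM)
        print(f"  {comp:>3} -> SOM16-Cl-{cl}: top note {best.note!r} "
              f"(%OM {best.pct_OM:.0f}, %ON {best.pct_ON:.0f})")

    cooc = cooccurrence(ds, notes)
    export_heatmap_tables(cooc, OUT / "cooccurrence_all.csv")
    for comp in ("WL", "IA"):
        cl = asg.labels[comp]
        restricted = cooccurrence(ds, notes, restrict_to=(asg, cl))
        export_heatmap_tables(restricted, OUT / f"cooccurrence_cl{cl}_{comp}.csv")
    print("profile and co-occurrence tables written under results/")


if __name__ == "__main__":
    main()
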