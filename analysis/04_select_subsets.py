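#!/usr/bin/env python
"""Select odor-profile subsets around each planted mixture component.

Within the SOM cluster hosting each component: keep cluster members with
>= 3 notes in common and <= 2 noncommon notes, refine by smallest
%noncommon then highest %common, cap at 10.  Writes the full audit to
results/subset_selection.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from odorspace.dataset import read_odorant_table
from odorspace.selection import select_subset

OUT = Path(__file__).resolve().parents[1] / "results"
COMPONENTS = ("V", "IA", "F", "EA", "bI", "bD", "WL")


def main() -> None:
    from odorspace.embed import ClusterAssignment
    labels = {}
    for line in (OUT / "assignment_som16.csv").read_text().splitlines()[1:]:
        rid, _, _, c = line.split(",")
        labels[rid] = int(c)
    asg = ClusterAssignment(method="som", level=16, labels=labels)

    ds = read_odorant_table(OUT / "dataset.csv")
    rows = []
    for comp in COMPONENTS:
        cl = asg.labels[comp]
        members = [ds.get(i) for i in asg.members(cl) if i in ds]
        res = select_subset(members, ds.get(comp), cap=10,
                            vocabulary=ds.vocabulary, cluster=cl)
        print(f"{comp}-s (SOM16-Cl-{cl}): {len(res.selected_ids)} molecules "
              f"(reference + {len(res.selected_ids) - 1} selected of "
              f"{len(members) - 1} candidates)")
        for sim, verdict in res.audit:
            rows.append((comp, cl, sim.candidate_id, sim.n_common, sim.n_noncommon,
                         f"{sim.pct_common:.1f}", f"{sim.pct_noncommon:.1f}", verdict))
    with (OUT / "subset_selection.csv").open("w") as fh:
        fh.write("reference,cluster,candidate,n_common,n_noncommon,"
                 "pct_common,pct_noncommon,verdict\n")
        for row in rows:
            fh.write(",".join(str(x) for x in row) + "\n")
    print("full audit -> results/subset_selection.csv")


if __name__ == "__main__":
    main()
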