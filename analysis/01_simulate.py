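#!/usr/bin/env python
"""Generate the synthetic odorant database used by the downstream analyses.

Emulates the statistical shape of a curated structure-odor database:
four structural families (esters, vanilloid phenolics, lactones,
ionone-like terpenoids) with family-typical odor-note distributions plus
an unstructured background, 2-5 notes per molecule, and a vocabulary
pruned to notes with >= 5 occurrences.  The seven real mixture components
are planted into the dataset so the later stages can locate them.

Writes results/dataset.csv and results/families.csv.
"""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from odorspace.dataset import write_odorant_table
from odorspace.synthetic import default_config, generate_dataset, plant_mixture_components

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ds, families = generate_dataset(default_config(seed=SEED))
    ds = plant_mixture_components(ds)
    write_odorant_table(ds, OUT / "dataset.csv")
    with (OUT / "families.csv").open("w") as fh:
        fh.write("id,family\n")
        for rid, fam in sorted(families.items()):
            fh.write(f"{rid},{fam}\n")

    occ = ds.note_occurrences()
    print(f"dataset: {len(ds)} molecules "
          f"({Counter(families.values()).most_common()}), "
          f"{len(ds.vocabulary)} vocabulary notes (threshold "
          f"{ds.min_note_occurrence})")
    print(f"most frequent notes: {occ.most_common(5)}")
    print(f"wrote {OUT/'dataset.csv'} and {OUT/'families.csv'}")


if __name__ == "__main__":
    main()
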