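# Methods

This note documents the models and procedures implemented in `odorspace`,
the parameter defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical conventions that
affect results.

## Dataset model

An odorant record is a structure (canonical SMILES) plus a set of
lowercase odor-note tokens. Note normalization lowercases, trims,
collapses internal whitespace, and splits whitespace-joined descriptors
into separate tokens ("powdery orris" → powdery, orris); the vocabulary is
therefore single-token. The analysis vocabulary keeps notes with at least
`min_note_occurrence = 5` occurrences (one occurrence = one molecule
carrying the note; notes are deduplicated per molecule). For the bundled
seven-component mixture table, occurrence pruning follows the table's own
footnote (maple and lovage are sub-threshold in the source database);
rebuilding the vocabulary on the pruned data is a fixed point.

The curated fixtures carry hand-assigned SMILES. For the seven mixture
components the structures are unambiguous (CAS-registered compounds). A
few members of the odor-profile subsets are trade names without a unique
public structure; those carry a chemically plausible representative of the
right family and are flagged in the loader docstring. No acceptance-graded
quantity depends on them.

## Synthetic database generator

The generator emulates the *joint* structure the analysis relies on:
structural families whose members are fingerprint-similar and share
family-typical notes. Four families (esters 150, vanilloid phenolics 90,
lactones 120, ionone-like terpenoids 80 — esters dominate real flavor
databases) are built by template substitution: a family scaffold with
attachment points filled from a substituent pool, guaranteeing valid
chemistry; 100 background molecules are drawn from a diverse pool of
common odorant scaffolds. Each molecule receives 2–5 notes from a
family-conditional distribution, with a 10% noise rate of draws from the
global pool. The global pool is the 39 mixture notes plus a representative
set of 25 frequent database notes, 10 shared — 54 distinct notes (the
source arithmetic quotes these counts as "55"; 25+39−10 = 54, and the pool
records the arithmetic as-is rather than invent a note). Randomness is one
stream per dataset with per-family sub-streams keyed by a stable hash of
the family name, so editing the family list does not reshuffle the others.

What the generator does *not* emulate: real note marginals (only their
qualitative shape), inter-family structural gradients (families are
well-separated by construction), multi-label correlations beyond the
family conditioning, and database curation noise. Passing recovery tests
therefore shows the pipeline recovers planted structure under favourable,
realistic-shaped conditions — not that the real database would cluster as
cleanly.

## Embedding and clustering

Fingerprints are 1024-bit ECFP with radius 2 (the community default; the
radius is configurable). UMAP reduces to 3D with n_neighbors 15, min_dist
0.1, Jaccard metric (appropriate for binary fingerprints; Euclidean is
available), fixed seed; the parameters are recorded in the embedding.
Clustering operates on the raw UMAP coordinates.

k-means is best-of-10 restarts by within-cluster sum of squares (WSS). The
SOM is a rectangular grid trained online: Gaussian grid neighborhood whose
radius decays linearly from half the larger grid dimension to 0.5,
learning rate 0.5 → 0.01 linearly, 500 epochs, uniform random weight
initialization in the data bounding box; molecules map to their best
matching unit, and empty units are permitted (so a 4×4 map can yield fewer
than 16 effective clusters). Training is rejected if it fails to reduce
quantization error. Cluster indices are 1-based everywhere.

Cluster-count selection combines the elbow curve (WSS per k) with a
Kelley-style penalty adapted from hierarchical clustering to flat
partitions: for each k, the spread is the mean over clusters (size ≥ 2) of
the mean pairwise member distance; spreads are min–max scaled onto
[1, |k_range| − 1]; penalty = scaled spread + k; the optimum is the argmin
with ties to the smallest k. All-singleton partitions have undefined
spread and are excluded. Note a property of this definition: on truly
unclustered data (one Gaussian blob) the minimum can fall at k = 3 rather
than exactly k = 2, because the spread initially declines faster than the
+1-per-k charge; the optimum always stays at the low end of the range.

Recovery on the default synthetic conditions is measured as the adjusted
Rand index between cluster labels and the generating families, restricted
to family-generated molecules — background molecules are unstructured by
construction and carry no family truth. At the selected level L4 (2×2 SOM,
matching the Kelley optimum of 4) the ARI is ≈ 0.8; a 4×4 map refines the
four blobs into multiple units each, which depresses plain ARI (≈ 0.55)
without representing a recovery failure.

## Odor-note statistics

%ON and %OM are as defined in the README; %ON sums to 100 over clusters
for every note, and a note with zero total occurrences gets an undefined
(None) %ON rather than a propagated NaN. Co-occurrence counts one
molecule carrying both notes, once per molecule; the relative matrix
row-normalizes by the row note's occurrence count and is therefore
nonsymmetric, with `rel[i,j]·count(i) = rel[j,i]·count(j)`. Restricting to
a cluster restricts both counting and normalization; per-cluster count
matrices sum to the whole-dataset matrix. Percentages export at 1 decimal.
Frequency rankings break ties alphabetically.

## Subset selection

The similarity conventions the selection rules leave open are fixed as:
noncommon = candidate notes absent from the reference; %common is
normalized by the reference's note count, %noncommon by the candidate's —
the hard rule "≥ 3 common, ≤ 2 noncommon" then reads as a parsimony
constraint on the candidate's description. A union-denominator convention
is available behind a flag. The cap of 10 is hard, under-full subsets are
allowed, every stage breaks ties by candidate id, and the audit lists
every candidate with its pass/fail reason. The reference is listed in the
subset but never competes.

## Pharmacophores

Feature conventions: A at the acceptor atom nucleus (SMARTS pattern file:
carbonyl, ether/ester/hydroxyl oxygens, basic nitrogens; donors are not
emitted since every donor here is also an acceptor); H at the heavy-atom
centroid of a contiguous group of carbons with no heteroatom neighbor
(groups ≥ 2 atoms, or single terminal methyls); R at aromatic ring
centroids with the ring normal, optionally re-typed to H
(`aromatic_as_hydrophobic`). These conventions are fixed and documented;
commercial tools draw the hydrophobic boundary differently (e.g. counting
an O-attached methyl as hydrophobic), which shifts feature inventories on
small polar molecules.

Conformers: ETKDG embedding (fixed seed), MMFF minimization, energies
relative to the ensemble minimum, 21 kJ/mol window, target 50, greedy
deduplication at 0.5 Å heavy-atom best RMSD walking up the energy ladder.

Hypothesis search: candidate feature subsets (3–6 features) are
enumerated per conformer and grouped by kind signature. Two candidates
are compatible when every corresponding sorted interfeature distance
agrees within the tolerance (2 Å); a 1 Å-binned key deduplicates
candidates within a molecule but the decision always uses the real
distances, so the search matches exhaustive enumeration exactly on small
instances. A key presented by ≥ ceil(match_fraction · n) molecules seeds
a hypothesis: reference subset from the molecule with the fewest
conformers, every other molecule aligned by its best kind-preserving
least-squares superposition (Kabsch), matched iff feature RMSD ≤
tolerance; sub-threshold molecules are reported as partial matches, not
counted. Score = 0.4·(matched fraction) + 0.4·(1 − meanRMSD/tolerance) +
0.2·(n_features − 2)/4 — a transparent stand-in for the proprietary
ranking score of the commercial workflow, preserving its semantics
(coverage, tightness, richness); weights are configurable. Ranking ties
resolve by feature count, signature, then distance geometry, with the
score rounded to 9 decimals so float jitter under rigid motions of the
input cannot reorder genuinely tied hypotheses.

Alignment: all kind-preserving pairings of ≥ 3 features between two
hypotheses are searched exhaustively (feature counts ≤ ~7), each
superposed by least squares; the minimum-RMSD pairing is returned, and
failure is declared when no pairing exists or the best RMSD exceeds the
2 Å cutoff. RMSD is symmetric in the two hypotheses even though the
template role is not.

Known limitation: declared alignment *failures* of the commercial tool are
only partially reproducible. Structural failures (no shared feature kinds
≥ 3) reproduce; but where both hypotheses expose acceptor pairs and a
ring, a geometric ≥3-feature pairing exists and superposes under any
cutoff consistent with the successful comparisons, so this implementation
reports a (poor) success where the reference tool reported none. The
masking-pair contrast — tight WL/IA overlay at ~0.2 Å versus degraded or
absent overlays among the blending-mixture components — reproduces.

## Problem sizes and reproducibility

Default synthetic runs use ~540 molecules (families 150/90/120/80 + 100
background), chosen as a realistic small database that exercises every
stage; the test suite uses a quarter-scale variant for the cheap checks
and the full default for recovery. All randomness flows from explicit
seeds (per-stage seeds derived from one global seed via a seed sequence),
and the pipeline manifest records config, seeds, and output checksums; a
rerun from the same config is byte-identical.
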