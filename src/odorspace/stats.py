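"""Per-cluster odor-note profiles and note co-occurrence statistics.

Two relative measures describe how a note distributes over a clustering:

    %ON = 100 * (occurrences of the note in the cluster)
              / (occurrences of the note in the whole dataset)

    %OM = 100 * (occurrences of the note in the cluster)
              / (number of molecules in the cluster)

An "occurrence" is one molecule carrying the note (notes are
deduplicated per molecule), so %ON sums to 100 over clusters for every
note and %OM is the within-cluster prevalence of the note.

Co-occurrence of two notes means one molecule carrying both.  The
symmetric matrix holds raw pair counts (diagonal = note occurrence
counts); the nonsymmetric relative matrix row-normalizes each pair count
by the row note's occurrence count, expressing "what share of note i's
occurrences come with note j".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from odorspace.dataset import OdorDataset
from odorspace.embed import ClusterAssignment


@dataclass(frozen=True)
class NoteClusterStats:
    note: str
    cluster: int
    n_in_cluster: int
    n_total: int
    cluster_size: int
    pct_ON: float | None  # None when the note never occurs (undefined)
    pct_OM: float


def note_profiles(dataset: OdorDataset, assignment: ClusterAssignment,
                  notes: Iterable[str] | None = None) -> list[NoteClusterStats]:
    """%ON / %OM per (note, non-empty cluster); zero counts reported as 0.

    Notes absent from the dataset altogether get ``pct_ON=None`` (the
    ratio is undefined) rather than a propagated NaN.
    """
    notes = sorted(notes) if notes is not None else sorted(dataset.vocabulary)
    unknown = set(notes) - set(dataset.vocabulary)
    if unknown:
        raise ValueError(f"notes outside the vocabulary: {sorted(unknown)}")
    missing = set(dataset.ids) - set(assignment.labels)
    if missing:
        raise ValueError(f"assignment does not cover records: {sorted(missing)[:5]}")

    totals = dataset.note_occurrences(pruned=True)
    out: list[NoteClusterStats] = []
    for cluster in assignment.clusters:
        member_ids = assignment.members(cluster)
        members = [dataset.get(i) for i in member_ids if i in dataset]
        size = len(members)
        if size == 0:
            continue
        for note in notes:
            n_in = sum(1 for m in members if note in m.pruned_notes(dataset.vocabulary))
            n_tot = totals.get(note, 0)
            pct_on = 100.0 * n_in / n_tot if n_tot > 0 else None
            out.append(NoteClusterStats(note=note, cluster=cluster, n_in_cluster=n_in,
                                        n_total=n_tot, cluster_size=size,
                                        pct_ON=pct_on, pct_OM=100.0 * n_in / size))
    return out


@dataclass
class CoocMatrices:
    notes: list[str]
    counts: np.ndarray    # symmetric int matrix; diagonal = occurrence counts
    relative: np.ndarray  # relative[i, j] = 100 * counts[i, j] / counts[i, i]; NaN rows undefined

    def count(self, a: str, b: str) -> int:
        return int(self.counts[self.notes.index(a), self.notes.index(b)])

    def rel(self, a: str, b: str) -> float:
        return float(self.relative[self.notes.index(a), self.notes.index(b)])


def cooccurrence(dataset: OdorDataset, notes: Sequence[str] | None = None,
                 restrict_to: tuple[ClusterAssignment, int] | None = None) -> CoocMatrices:
    """Symmetric pair counts and the row-normalized relative matrix.

    ``restrict_to=(assignment, cluster)`` confines both counting and
    normalization to that cluster's molecules.  A note with zero
    occurrences in the restriction gets a NaN (undefined) relative row.
    """
    note_list = sorted(notes) if notes is not None else sorted(dataset.vocabulary)
    if not note_list:
        raise ValueError("note set must be non-empty")
    idx = {n: i for i, n in enumerate(note_list)}
    records = dataset.records
    if restrict_to is not None:
        assignment, cluster = restrict_to
        keep = set(assignment.members(cluster))
        records = [r for r in records if r.id in keep]

    m = len(note_list)
    counts = np.zeros((m, m), dtype=np.int64)
    for rec in records:
        present = sorted(idx[n] for n in rec.pruned_notes(dataset.vocabulary) if n in idx)
        for a_pos, i in enumerate(present):
            counts[i, i] += 1
            for j in present[a_pos + 1:]:
                counts[i, j] += 1
                counts[j, i] += 1
    diag = np.diag(counts).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = 100.0 * counts / diag[:, None]
    relative[diag == 0, :] = np.nan
    return CoocMatrices(notes=note_list, counts=counts, relative=relative)


def top_frequent_notes(dataset: OdorDataset, k: int = 25) -> list[str]:
    """The k most frequent vocabulary notes; ties broken alphabetically."""
    occ = dataset.note_occurrences(pruned=True)
    if k > len(dataset.vocabulary):
        raise ValueError(f"k={k} exceeds vocabulary size {len(dataset.vocabulary)}")
    ranked = sorted(dataset.vocabulary, key=lambda n: (-occ.get(n, 0), n))
    return ranked[:k]


# ---------------------------------------------------------------------------
# Table exports (radar / heatmap data as plain CSV, 1 decimal place)

def profile_frame(stats: Sequence[NoteClusterStats]) -> pd.DataFrame:
    rows = [{
        "note": s.note, "cluster": s.cluster, "n_in_cluster": s.n_in_cluster,
        "n_total": s.n_total, "cluster_size": s.cluster_size,
        "pct_ON": float("nan") if s.pct_ON is None else round(s.pct_ON, 1),
        "pct_OM": round(s.pct_OM, 1),
    } for s in stats]
    return pd.DataFrame(rows)


def export_profile_tables(stats: Sequence[NoteClusterStats], path: str | Path) -> None:
    """Radar-ready long-format CSV of %ON / %OM values."""
    profile_frame(stats).to_csv(path, index=False)


def export_heatmap_tables(cooc: CoocMatrices, path: str | Path) -> None:
    """Heatmap-ready CSV of the relative co-occurrence matrix (plus counts)."""
    path = Path(path)
    rel = pd.DataFrame(np.round(cooc.relative, 1), index=cooc.notes, columns=cooc.notes)
    rel.to_csv(path, index_label="note")
    cnt = pd.DataFrame(cooc.counts, index=cooc.notes, columns=cooc.notes)
    cnt.to_csv(path.with_name(path.stem + "_counts" + path.suffix), index_label="note")
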