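"""Core domain types for odorant datasets.

An odorant is a volatile molecule described by a set of verbal odor notes
("fruity", "coconut", ...).  A dataset couples a collection of such records
with a note vocabulary: the notes retained for analysis are those occurring
at least ``min_note_occurrence`` times (default 5) across the source
database, so that rare idiosyncratic descriptors do not dominate
per-cluster statistics.

The module also bundles two curated fixtures: the seven components of the
"red cordial" (RC) blending mixture and the whiskey-lactone/isoamyl-acetate
(WL/IA) masking mixture together with their odor notes and RC proportions,
and the per-cluster odor-profile subsets used for pharmacophore modelling.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Notes flagged in the curated mixture table as occurring fewer than five
#: times in the full source database; they are dropped from vocabularies
#: built with the bundled external counts.
TABLE1_RARE_NOTES = frozenset({"maple", "lovage"})


class ConfigurationError(ValueError):
    """A required column or configuration item is missing."""


class EmptyDatasetError(ValueError):
    """The input contained no usable records."""


def normalize_note(raw: str) -> list[str]:
    """Normalize one raw note string into canonical note tokens.

    Lowercases, strips, collapses internal whitespace, and splits
    whitespace-joined descriptors into separate notes ("Powdery orris" ->
    ["powdery", "orris"]): the vocabulary is single-token by construction.
    """
    cleaned = " ".join(raw.strip().lower().split())
    return cleaned.split() if cleaned else []


def normalize_notes(raw_notes: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for raw in raw_notes:
        out.update(normalize_note(raw))
    return out


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string; raises ValueError on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class OdorantRecord:
    """One odorant: structure, identity, and its set of odor notes."""

    id: str
    name: str
    smiles: str
    notes: frozenset[str]
    cas: str | None = None

    def __post_init__(self) -> None:
        if not self.notes:
            raise ValueError(f"record {self.id!r} has no odor notes")

    def pruned_notes(self, vocabulary: frozenset[str] | set[str]) -> frozenset[str]:
        return frozenset(self.notes & set(vocabulary))


def common_notes(a: OdorantRecord, b: OdorantRecord) -> frozenset[str]:
    """Notes shared by two odorants (symmetric set intersection)."""
    return a.notes & b.notes


def build_vocabulary(
    records: Sequence[OdorantRecord],
    min_occurrence: int = 5,
    external_counts: Mapping[str, int] | None = None,
) -> frozenset[str]:
    """Notes carried by at least ``min_occurrence`` records.

    When ``external_counts`` is given (occurrence counts from a larger
    source database, e.g. the curated mixture table whose footnote flags
    rare notes), the threshold is applied to those counts instead of the
    counts within ``records``.
    """
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be >= 1")
    counts: Mapping[str, int]
    if external_counts is None:
        counter: Counter[str] = Counter()
        for rec in records:
            counter.update(rec.notes)
        counts = counter
    else:
        counts = external_counts
    all_notes = set().union(*(rec.notes for rec in records)) if records else set()
    vocab = frozenset(n for n in all_notes if counts.get(n, 0) >= min_occurrence)
    for rec in records:
        if rec.notes and not (rec.notes & vocab):
            logger.warning("record %s loses all notes under vocabulary pruning", rec.id)
    return vocab


@dataclass
class OdorDataset:
    """Ordered odorant records plus the retained note vocabulary."""

    records: list[OdorantRecord]
    vocabulary: frozenset[str] = field(default_factory=frozenset)
    min_note_occurrence: int = 5
    skipped_rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.vocabulary:
            self.vocabulary = build_vocabulary(self.records, self.min_note_occurrence)
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in dataset")
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def get(self, record_id: str) -> OdorantRecord:
        try:
            return self._by_id[record_id]
        except KeyError:
            raise LookupError(f"unknown record id: {record_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def pruned_notes(self, record_id: str) -> frozenset[str]:
        return self.get(record_id).pruned_notes(self.vocabulary)

    def note_occurrences(self, pruned: bool = True) -> Counter:
        """Occurrence count per note; one molecule carries a note at most once."""
        counter: Counter[str] = Counter()
        for rec in self.records:
            counter.update(rec.pruned_notes(self.vocabulary) if pruned else rec.notes)
        return counter


@dataclass(frozen=True)
class MixtureFixture:
    """A named odorant mixture: component record ids plus optional percentages."""

    name: str
    components: tuple[str, ...]
    proportions: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.proportions is not None:
            total = sum(self.proportions.values())
            if abs(total - 100.0) > 0.5:
                raise ValueError(f"mixture {self.name}: proportions sum to {total}, not 100")


def mixture_note_union(fixture: MixtureFixture, dataset: OdorDataset) -> frozenset[str]:
    """Union of the pruned note sets of a mixture's components."""
    out: set[str] = set()
    for cid in fixture.components:
        out |= dataset.pruned_notes(cid)
    return frozenset(out)


# ---------------------------------------------------------------------------
# I/O

REQUIRED_COLUMNS = ("id", "name", "smiles", "notes")


def read_odorant_table(
    path: str | Path,
    note_delimiter: str = ";",
    min_note_occurrence: int = 5,
    external_counts: Mapping[str, int] | None = None,
) -> OdorDataset:
    """Load an odorant CSV (id, name, cas, smiles, notes).

    Notes are split on ``note_delimiter``, normalized and deduplicated.
    Rows whose SMILES does not parse are skipped and reported in
    ``OdorDataset.skipped_rows`` (and logged), never silently dropped.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyDatasetError(f"{path}: empty file")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ConfigurationError(f"{path}: missing required column(s) {missing}")
        records: list[OdorantRecord] = []
        skipped: list[tuple[str, str]] = []
        for row in reader:
            rid = (row["id"] or "").strip()
            try:
                smiles = canonical_smiles(row["smiles"])
            except ValueError as exc:
                logger.warning("skipping row %r: %s", rid, exc)
                skipped.append((rid, str(exc)))
                continue
            notes = normalize_notes(row["notes"].split(note_delimiter))
            if not notes:
                logger.warning("skipping row %r: no odor notes", rid)
                skipped.append((rid, "no odor notes"))
                continue
            records.append(
                OdorantRecord(
                    id=rid,
                    name=(row.get("name") or "").strip(),
                    cas=(row.get("cas") or "").strip() or None,
                    smiles=smiles,
                    notes=frozenset(notes),
                )
            )
    if not records:
        raise EmptyDatasetError(f"{path}: no usable records")
    vocab = build_vocabulary(records, min_note_occurrence, external_counts)
    ds = OdorDataset(records, vocab, min_note_occurrence)
    ds.skipped_rows = skipped
    return ds


def write_odorant_table(dataset: OdorDataset, path: str | Path, note_delimiter: str = ";") -> None:
    """Write a dataset back to CSV; round-trips with :func:`read_odorant_table`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "cas", "smiles", "notes"])
        for rec in dataset.records:
            writer.writerow(
                [rec.id, rec.name, rec.cas or "", rec.smiles,
                 (note_delimiter + " ").join(sorted(rec.notes))]
            )


def read_odorant_sdf(path: str | Path, notes_property: str = "NOTES",
                     note_delimiter: str = ";", min_note_occurrence: int = 5) -> OdorDataset:
    """Load odorants from an SDF carrying notes in a text property."""
    records: list[OdorantRecord] = []
    skipped: list[tuple[str, str]] = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        name = ""
        if mol is None:
            skipped.append((f"sdf:{i}", "unparsable molecule block"))
            continue
        if mol.HasProp("_Name"):
            name = mol.GetProp("_Name")
        if not mol.HasProp(notes_property):
            skipped.append((name or f"sdf:{i}", f"missing {notes_property} property"))
            continue
        notes = normalize_notes(mol.GetProp(notes_property).split(note_delimiter))
        if not notes:
            skipped.append((name or f"sdf:{i}", "no odor notes"))
            continue
        records.append(
            OdorantRecord(id=name or f"sdf:{i}", name=name,
                          smiles=Chem.MolToSmiles(mol), notes=frozenset(notes))
        )
    if not records:
        raise EmptyDatasetError(f"{path}: no usable records")
    ds = OdorDataset(records, min_note_occurrence=min_note_occurrence)
    ds.skipped_rows = skipped
    return ds


# ---------------------------------------------------------------------------
# Bundled fixtures

def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("odorspace.fixtures").joinpath(name)))


def load_mixture_components(prune_rare: bool = True) -> OdorDataset:
    """The seven mixture components (curated table) as an OdorDataset.

    With ``prune_rare`` the vocabulary excludes the two notes the source
    table footnotes as having fewer than five occurrences in the full
    database (maple, lovage); all other notes are retained, mimicking a
    vocabulary built on the full-database counts.
    """
    ds = read_odorant_table(_fixture_path("table1.csv"), min_note_occurrence=1)
    if prune_rare:
        vocab = frozenset(n for n in ds.vocabulary if n not in TABLE1_RARE_NOTES)
        ds = OdorDataset(ds.records, vocab, min_note_occurrence=5)
    return ds


def rc_mixture() -> MixtureFixture:
    """The six-component red-cordial blending mixture with its proportions."""
    props = {"V": 41.8, "F": 41.8, "IA": 5.0, "bI": 4.3, "EA": 4.3, "bD": 2.8}
    return MixtureFixture("RC", ("V", "F", "IA", "bI", "EA", "bD"), props)


def wl_ia_mixture() -> MixtureFixture:
    """The binary whiskey-lactone / isoamyl-acetate masking mixture."""
    return MixtureFixture("WL/IA", ("WL", "IA"))


def load_profile_subsets() -> dict[str, dict]:
    """The curated per-cluster odor-profile subsets used for pharmacophore runs.

    Returns a mapping reference id -> {"cluster": str, "members": [(name, smiles), ...]}.
    Structures were curated from the published compound names; a few trade
    names lack a unique public structure and carry a representative
    structure of the same chemical family.
    """
    out: dict[str, dict] = {}
    with _fixture_path("table3.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            entry = out.setdefault(row["reference_id"], {"cluster": row["cluster"], "members": []})
            entry["members"].append((row["name"], canonical_smiles(row["smiles"])))
    return out
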