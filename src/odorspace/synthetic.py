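"""Synthetic odorant-database generator.

The real structure-odor databases couple structural families (esters,
vanilloid phenolics, lactones, ionone-like terpenoids, ...) with
family-typical odor vocabularies: esters smell fruity, lactones coconut,
vanilloids vanilla.  The generator reproduces exactly that joint structure
so the downstream stages (fingerprint clustering, per-cluster note
profiles, subset selection, pharmacophores) can be exercised and their
recovery of planted ground truth asserted, without any external download.

Molecules are built by template substitution -- a family scaffold with
attachment points filled from a substituent pool -- which guarantees valid,
family-coherent chemistry (no random molecular graphs).  Odor notes are
drawn per molecule (2-5 notes) from a family-conditional distribution,
with a configurable noise rate of draws from the global note pool.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from odorspace.dataset import (
    OdorantRecord,
    OdorDataset,
    build_vocabulary,
    canonical_smiles,
    load_mixture_components,
)

#: The global note pool: the 39 notes describing the mixture components
#: plus a representative set of 25 high-frequency database notes, 10 of
#: which overlap the mixture notes -- 54 distinct notes in total.  (The
#: source counts quote 25 + 39 with 10 shared as "55"; 25+39-10 = 54, and
#: the pool deliberately records the arithmetic as-is rather than invent
#: an extra note.)
MIXTURE_NOTES: tuple[str, ...] = (
    "sweet", "vanilla", "creamy", "chocolate", "fruity", "banana", "solvent",
    "pear", "berry", "raspberry", "ripe", "floral", "ethereal", "weedy",
    "green", "sharp", "brandy", "winey", "apple", "plum", "tea", "rose",
    "tobacco", "natural", "grape", "woody", "tropical", "violet", "dry",
    "powdery", "orris", "tonka", "coumarinic", "coconut", "toasted",
    "nutty", "celery", "burnt", "lactonic",
)

FREQUENT_NOTES: tuple[str, ...] = (
    # 10 shared with the mixture notes
    "fruity", "sweet", "floral", "green", "woody", "apple", "rose",
    "creamy", "berry", "tropical",
    # 15 frequent notes outside the mixture vocabulary
    "herbal", "minty", "spicy", "citrus", "fatty", "waxy", "oily",
    "caramellic", "pineapple", "earthy", "musty", "honey", "fresh",
    "sulfurous", "balsamic",
)

GLOBAL_NOTE_POOL: tuple[str, ...] = tuple(sorted(set(MIXTURE_NOTES) | set(FREQUENT_NOTES)))

_ALKYLS = ("C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC",
           "CC(C)", "CCC(C)", "CC(C)C", "CCC(C)C", "CC(C)CC", "CCCC(C)",
           "CC(C)(C)C", "Cc1ccccc1")

_VANILLOID_SUBS = ("C=O", "CC=O", "CCC=O", "C(C)=O", "CC(C)=O", "CCC(C)=O",
                   "C", "CC", "CCC", "CCCC", "CO", "CCO", "C=CC",
                   "COC(C)=O", "C(=O)OC", "C(=O)OCC")


@dataclass(frozen=True)
class FamilySpec:
    """One structural family: scaffolds, substituents, and its note habits."""

    name: str
    scaffold_smiles_templates: tuple[str, ...]
    substituent_pool: tuple[str, ...]
    note_distribution: Mapping[str, float]
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"family {self.name}: size must be >= 1")
        for p in self.note_distribution.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"family {self.name}: probabilities must lie in [0,1]")


@dataclass(frozen=True)
class GeneratorConfig:
    families: tuple[FamilySpec, ...]
    background_size: int = 100
    notes_per_molecule: tuple[int, int] = (2, 5)
    noise_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.notes_per_molecule[0] < 1:
            raise ValueError("notes_per_molecule minimum must be >= 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0,1]")


class GenerationError(RuntimeError):
    pass


def default_families(scale: float = 1.0) -> tuple[FamilySpec, ...]:
    """The default four families emulating the main structural areas.

    Sizes (esters 150, vanilloids 90, lactones 120, ionones 80) mirror the
    dominance of simple esters in flavor databases; ``scale`` multiplies
    all of them.
    """
    def n(base: int) -> int:
        return max(1, round(base * scale))

    return (
        FamilySpec(
            name="esters",
            scaffold_smiles_templates=("{r1}C(=O)O{r2}",),
            substituent_pool=_ALKYLS,
            note_distribution={
                "fruity": 0.9, "sweet": 0.55, "banana": 0.3, "pear": 0.3,
                "apple": 0.3, "green": 0.25, "ethereal": 0.2, "tropical": 0.2,
                "winey": 0.15, "brandy": 0.12, "pineapple": 0.2, "sharp": 0.1,
            },
            size=n(150),
        ),
        FamilySpec(
            name="vanilloids",
            scaffold_smiles_templates=("COc1cc({r1})ccc1O", "CCOc1cc({r1})ccc1O",
                                       "COc1cc({r1})ccc1OC", "COc1cc({r1})cc(C)c1O",
                                       "Oc1ccc({r1})cc1", "Oc1ccc({r1})cc1O"),
            substituent_pool=_VANILLOID_SUBS,
            note_distribution={
                "vanilla": 0.85, "sweet": 0.7, "creamy": 0.4, "chocolate": 0.25,
                "balsamic": 0.3, "spicy": 0.25, "powdery": 0.2, "honey": 0.15,
                "caramellic": 0.15,
            },
            size=n(90),
        ),
        FamilySpec(
            name="lactones",
            scaffold_smiles_templates=("{r1}C1CCC(=O)O1", "{r1}C1CCCC(=O)O1",
                                       "{r1}C1OC(=O)CC1C", "{r1}C1CCCCC(=O)O1",
                                       "{r1}C1CC(C)C(=O)O1", "{r1}C1CCC(C)C(=O)O1",
                                       "{r1}C1OC(=O)C(C)C1", "{r1}C1CC(CC)C(=O)O1"),
            substituent_pool=_ALKYLS,
            note_distribution={
                "coconut": 0.8, "lactonic": 0.7, "coumarinic": 0.35,
                "creamy": 0.35, "sweet": 0.4, "tonka": 0.2, "celery": 0.12,
                "fatty": 0.2, "oily": 0.15, "toasted": 0.1,
            },
            size=n(120),
        ),
        FamilySpec(
            name="ionones",
            scaffold_smiles_templates=("{r1}C(=O)/C=C/C1=C(C)CCCC1(C)C",
                                       "{r1}C(=O)/C=C/C1C(C)=CCCC1(C)C",
                                       "{r1}C(=O)C1=C(C)CCCC1(C)C",
                                       "{r1}C(=O)CCC1=C(C)CCCC1(C)C",
                                       "{r1}C(=O)/C=C/C1=C(C)CC(C)CC1(C)C",
                                       "{r1}C(O)/C=C/C1=C(C)CCCC1(C)C",
                                       "{r1}C(=O)CC1C(C)=CCCC1(C)C",
                                       "{r1}C(O)CC1=C(C)CCCC1(C)C"),
            substituent_pool=("C", "CC", "CCC", "CCCC", "CC(C)", "CCC(C)",
                              "CC(C)C", "CCCCC", "C=CC", "CCC(C)C"),
            note_distribution={
                "woody": 0.8, "floral": 0.65, "violet": 0.5, "fruity": 0.3,
                "orris": 0.25, "powdery": 0.25, "dry": 0.2, "berry": 0.2,
                "raspberry": 0.15, "tobacco": 0.1,
            },
            size=n(80),
        ),
    )


#: Diverse background structures sampled for the unstructured remainder:
#: alcohols, aldehydes, ketones, acids, phenols, ethers, terpenoids,
#: sulfur compounds and Maillard-type heterocycles.
_BACKGROUND_POOL: tuple[str, ...] = (
    "CCO", "CCCO", "CCCCO", "CCCCCO", "CCCCCCO", "CCCCCCCO", "CCCCCCCCO",
    "CC(C)CO", "CC(C)CCO", "CCC(C)O", "CC(O)CC", "CCCCCC(C)O", "CCCCCCC(C)O",
    "OCC1CCCO1", "OC1CCCCC1", "CC1CCCCC1O", "OCc1ccccc1", "OCCc1ccccc1",
    "CCCCC=O", "CCCCCC=O", "CCCCCCC=O", "CCCCCCCC=O", "CC(C)CC=O",
    "CC=CC=O", "C/C=C/CC=O", "CCCC/C=C/C=O", "c1ccccc1C=O", "CC(C)Cc1ccccc1C=O",
    "O=Cc1ccco1", "Cc1ccc(C=O)cc1", "COc1ccc(C=O)cc1", "O=CC1=CCCCC1",
    "CCCC(C)=O", "CCCCCC(C)=O", "CCCCCCC(C)=O", "CC(C)CCC(C)=O",
    "O=C1CCCCC1", "CC(=O)c1ccccc1", "CC(=O)C(C)=O", "CCC(=O)C(C)=O",
    "O=C1CCCC1", "CC1CCC(=O)CC1", "CC(C)C1CCC(C)CC1=O",
    "CCCCCC(=O)O", "CCCCCCCC(=O)O", "CC(C)CC(=O)O", "CCCCCCC(=O)O",
    "CC(C)=CCC(=O)O", "C/C=C/C(=O)O",
    "Oc1ccccc1", "Cc1ccc(O)cc1", "CCc1ccc(O)cc1", "CC(C)c1ccc(C)cc1O",
    "COc1ccccc1", "CCOc1ccccc1", "COc1ccc(C)cc1", "CCCCc1ccccc1",
    "CC(C)c1ccccc1", "Cc1ccccc1C", "Cc1ccc(C)cc1", "c1ccc2ccccc2c1",
    "Cc1cnc(C)cn1", "CCc1ncc(C)cn1", "CCc1cncc(C)n1", "Cc1cnccn1",
    "CCCc1cncc(C)n1", "Cc1ccco1", "CCc1ccco1", "Cc1ccc(C)o1", "c1ccsc1",
    "Cc1cccs1", "Cc1nccs1", "CCc1nccs1", "Cc1ccoc1C", "O=c1ccocc1",
    "CCS", "CCCS", "CCCCS", "CSSC", "CCSC", "CCSSCC", "SCC1CCCO1",
    "CC(C)=CCCC(C)=CCO", "CC(C)=CCCC(C)=CC=O", "CC(C)=CCCC(C)=CCOC(C)=O",
    "CC1=CCC(CC1)C(C)C", "CC1=CCC(CC1)C(C)(C)O", "CC1CCC(C(C)C)C(O)C1",
    "CC1=CCC2CC1C2(C)C", "CC(C)C1CCC(C)=CC1", "CC(C)=CCC/C(C)=C/CO",
    "C/C=C/c1ccccc1", "C=CCc1ccc(OC)cc1", "COc1ccc(/C=C/C)cc1",
    "CCCCC/C=C/C=O", "CCCCCCCCC=O", "CCCCCCCCCC=O", "OCCCCCC",
    "CC(=O)OCC(C)C", "N#Cc1ccccc1", "CCOC=O", "CCCCN", "Cc1ccncc1",
)


def _family_rng(seed: int, family_name: str) -> np.random.Generator:
    # sub-stream keyed by (dataset seed, stable hash of family name) so that
    # editing the family list does not reshuffle the other families
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(family_name.encode())]))


def _draw_notes(rng: np.random.Generator, spec_notes: Sequence[str],
                spec_probs: np.ndarray, n_range: tuple[int, int],
                noise_rate: float) -> frozenset[str]:
    n_notes = int(rng.integers(n_range[0], n_range[1] + 1))
    notes: set[str] = set()
    for _ in range(8 * n_notes):  # rejection loop; dedup can discard draws
        if len(notes) >= n_notes:
            break
        if noise_rate > 0 and rng.random() < noise_rate:
            notes.add(GLOBAL_NOTE_POOL[rng.integers(len(GLOBAL_NOTE_POOL))])
        else:
            notes.add(spec_notes[rng.choice(len(spec_notes), p=spec_probs)])
    return frozenset(notes)


def _build_family_molecule(rng: np.random.Generator, spec: FamilySpec) -> str:
    template = spec.scaffold_smiles_templates[rng.integers(len(spec.scaffold_smiles_templates))]
    subs = {}
    for i in (1, 2, 3):
        if "{r%d}" % i in template:
            subs[f"r{i}"] = spec.substituent_pool[rng.integers(len(spec.substituent_pool))]
    smiles = template.format(**subs)
    try:
        return canonical_smiles(smiles)
    except ValueError as exc:
        raise GenerationError(
            f"family {spec.name}: template {template!r} with {subs} "
            f"yields invalid chemistry"
        ) from exc


def generate_dataset(config: GeneratorConfig) -> tuple[OdorDataset, dict[str, str]]:
    """Generate a synthetic odorant dataset plus ground-truth family labels.

    Deterministic for a fixed ``config.seed``.  Duplicate structures within
    a family are regenerated (bounded retries) and any residual duplicates
    are dropped, so every record carries a distinct canonical SMILES.
    Returns ``(dataset, labels)`` with ``labels`` mapping record id ->
    generating family name ("background" for the unstructured remainder).
    """
    records: list[OdorantRecord] = []
    labels: dict[str, str] = {}
    seen_smiles: set[str] = set()

    for spec in config.families:
        rng = _family_rng(config.seed, spec.name)
        spec_notes = sorted(spec.note_distribution)
        probs = np.array([spec.note_distribution[n] for n in spec_notes], dtype=float)
        if probs.sum() <= 0:
            raise GenerationError(f"family {spec.name}: empty note distribution")
        probs /= probs.sum()
        made = 0
        for i in range(spec.size):
            smiles = None
            for _attempt in range(50):
                cand = _build_family_molecule(rng, spec)
                if cand not in seen_smiles:
                    smiles = cand
                    break
            if smiles is None:
                continue  # substituent pool exhausted; dedup by dropping
            seen_smiles.add(smiles)
            rid = f"{spec.name}-{made:04d}"
            notes = _draw_notes(rng, spec_notes, probs, config.notes_per_molecule,
                                config.noise_rate)
            records.append(OdorantRecord(id=rid, name=rid, smiles=smiles, notes=notes))
            labels[rid] = spec.name
            made += 1

    rng = _family_rng(config.seed, "background")
    made = 0
    for i in range(config.background_size):
        smiles = None
        for _attempt in range(50):
            cand = canonical_smiles(_BACKGROUND_POOL[rng.integers(len(_BACKGROUND_POOL))])
            if cand not in seen_smiles:
                smiles = cand
                break
        if smiles is None:
            continue
        seen_smiles.add(smiles)
        rid = f"background-{made:04d}"
        n_range = config.notes_per_molecule
        n_notes = int(rng.integers(n_range[0], n_range[1] + 1))
        idx = rng.choice(len(GLOBAL_NOTE_POOL), size=min(n_notes, len(GLOBAL_NOTE_POOL)),
                         replace=False)
        records.append(OdorantRecord(id=rid, name=rid, smiles=smiles,
                                     notes=frozenset(GLOBAL_NOTE_POOL[j] for j in idx)))
        labels[rid] = "background"
        made += 1

    if not records:
        raise GenerationError("empty generation: no family produced any molecule")
    ds = OdorDataset(records, min_note_occurrence=5)
    return ds, labels


def default_config(seed: int = 0, scale: float = 1.0,
                   background_size: int | None = None) -> GeneratorConfig:
    """Default generation conditions: 4 families (~440 molecules) + 100 background."""
    if background_size is None:
        background_size = max(1, round(100 * scale))
    return GeneratorConfig(families=default_families(scale),
                           background_size=background_size, seed=seed)


def plant_mixture_components(dataset: OdorDataset) -> OdorDataset:
    """Inject the seven curated mixture components into a dataset.

    Components already present (same id) are left untouched, so the
    operation is idempotent; a foreign record occupying a component id is
    kept and the component is injected under ``<id>-mix``.
    """
    components = load_mixture_components(prune_rare=False)
    records = list(dataset.records)
    existing = {r.id: r for r in records}
    for comp in components:
        if comp.id in existing:
            if existing[comp.id].smiles == comp.smiles:
                continue  # already planted
            comp = replace(comp, id=f"{comp.id}-mix")
            if comp.id in existing:
                continue
        records.append(comp)
        existing[comp.id] = comp
    # keep every component note analysable except the two footnoted rare ones
    from odorspace.dataset import TABLE1_RARE_NOTES

    comp_notes = frozenset(n for r in components for n in r.notes) - TABLE1_RARE_NOTES
    vocab = build_vocabulary(records, dataset.min_note_occurrence) | comp_notes
    out = OdorDataset(records, frozenset(vocab), dataset.min_note_occurrence)
    return out
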