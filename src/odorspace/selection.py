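"""Rule-based selection of odor-profile subsets.

Within a cluster, candidates whose odor profile resembles a reference
molecule are selected in three stages:

1. hard rule — at least 3 notes in common with the reference and at most
   2 notes not shared (the candidate's description must be close and
   parsimonious);
2. if more than ``cap`` survive, keep the smallest percentages of
   noncommon notes;
3. if still too many, keep the highest percentages of common notes.

"Noncommon" counts candidate notes absent from the reference;
%common is normalized by the reference's note count and %noncommon by the
candidate's (an alternative union-denominator convention is available via
``convention="union"``).  The reference itself is listed in the final
subset but never competes as a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from odorspace.dataset import OdorantRecord

CONVENTIONS = ("candidate", "union")


@dataclass(frozen=True)
class ProfileSimilarity:
    reference_id: str
    candidate_id: str
    n_common: int
    n_noncommon: int
    pct_common: float
    pct_noncommon: float


@dataclass
class SubsetResult:
    cluster: str | int
    reference_id: str
    selected_ids: list[str]
    audit: list[tuple[ProfileSimilarity, str]] = field(default_factory=list)


def profile_similarity(reference: OdorantRecord, candidate: OdorantRecord,
                       vocabulary: frozenset[str] | None = None,
                       convention: str = "candidate") -> ProfileSimilarity:
    """Note-overlap statistics between a reference and a candidate odorant."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    ref_notes = reference.pruned_notes(vocabulary) if vocabulary else reference.notes
    cand_notes = candidate.pruned_notes(vocabulary) if vocabulary else candidate.notes
    if not ref_notes or not cand_notes:
        raise ValueError(
            f"similarity undefined for empty note sets "
            f"({reference.id!r} vs {candidate.id!r})")
    common = cand_notes & ref_notes
    noncommon = cand_notes - ref_notes
    if convention == "candidate":
        pct_common = 100.0 * len(common) / len(ref_notes)
        pct_noncommon = 100.0 * len(noncommon) / len(cand_notes)
    else:  # union denominator for both percentages
        denom = len(cand_notes | ref_notes)
        pct_common = 100.0 * len(common) / denom
        pct_noncommon = 100.0 * len(noncommon) / denom
    return ProfileSimilarity(reference_id=reference.id, candidate_id=candidate.id,
                             n_common=len(common), n_noncommon=len(noncommon),
                             pct_common=pct_common, pct_noncommon=pct_noncommon)


def select_subset(cluster_members: list[OdorantRecord], reference: OdorantRecord,
                  cap: int = 10, min_common: int = 3, max_noncommon: int = 2,
                  vocabulary: frozenset[str] | None = None,
                  convention: str = "candidate",
                  cluster: str | int = "") -> SubsetResult:
    """Select up to ``cap`` cluster members profiled like the reference.

    Deterministic: every stage breaks ties by candidate id.  The returned
    ``selected_ids`` lists the reference first, then the selected
    candidates; the audit covers every non-reference cluster member with
    its pass/fail reason.
    """
    sims: list[ProfileSimilarity] = []
    audit: list[tuple[ProfileSimilarity, str]] = []
    for cand in sorted(cluster_members, key=lambda r: r.id):
        if cand.id == reference.id:
            continue
        sim = profile_similarity(reference, cand, vocabulary, convention)
        sims.append(sim)

    survivors = []
    for sim in sims:
        if sim.n_common < min_common:
            audit.append((sim, f"rejected: only {sim.n_common} common notes (< {min_common})"))
        elif sim.n_noncommon > max_noncommon:
            audit.append((sim, f"rejected: {sim.n_noncommon} noncommon notes (> {max_noncommon})"))
        else:
            survivors.append(sim)

    stage = {s.candidate_id: "selected: hard rule" for s in survivors}
    if len(survivors) > cap:
        # stage 2: ascending % noncommon; stage 3 (ties): descending % common;
        # residual ties broken by candidate id, then truncate to the cap
        survivors.sort(key=lambda s: (s.pct_noncommon, -s.pct_common, s.candidate_id))
        for s in survivors[cap:]:
            stage[s.candidate_id] = (
                f"rejected: refinement cut (pct_noncommon {s.pct_noncommon:.1f}, "
                f"pct_common {s.pct_common:.1f})")
        survivors = survivors[:cap]
        for s in survivors:
            stage[s.candidate_id] = "selected: refinement ranking"
    for s in sims:
        if s.candidate_id in stage:
            audit.append((s, stage[s.candidate_id]))
    audit.sort(key=lambda t: t[0].candidate_id)

    selected = [reference.id] + sorted(s.candidate_id for s in survivors)
    return SubsetResult(cluster=cluster, reference_id=reference.id,
                        selected_ids=selected, audit=audit)
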