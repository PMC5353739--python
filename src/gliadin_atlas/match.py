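"""Spot -> gene matching: the decision rule linking 2-DE gliadin spots to the
active genes whose products they contain.

Positive correspondence is based on the presence of unique peptides and on
coverage of the target protein by the observed peptides. Proteins whose
theoretical digests are indistinguishable under both enzymes (e.g. two genes
encoding 100% identical proteins) form an *equivalence group* and are matched
together or not at all.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .digest import (
    DEFAULT_ENZYMES,
    DigestParams,
    Enzyme,
    coverage,
    theoretical_peptide_set,
)
from .errors import InputError
from .records import ProteinRecord

EVIDENCE_UNIQUE = "unique_peptide"
EVIDENCE_COVERAGE = "max_coverage"
EVIDENCE_NMF = "NMF"  # no match found


@dataclass
class SpotObservation:
    spot_id: str
    enzyme_name: str
    peptides: list[str]


@dataclass
class MatchResult:
    spot_id: str
    matched_ids: list[str]
    evidence: str
    coverage: dict[str, float] = field(default_factory=dict)
    equivalence_group: bool = False

    def __post_init__(self) -> None:
        if (self.evidence == EVIDENCE_NMF) != (not self.matched_ids):
            raise InputError("evidence=NMF iff matched_ids is empty")


def equivalence_groups(
    db: list[ProteinRecord],
    enzymes: tuple[Enzyme, ...] = DEFAULT_ENZYMES,
    params: DigestParams | None = None,
) -> list[tuple[str, ...]]:
    """Partition the database into groups with identical theoretical peptide
    sets under both enzymes (sorted member tuples, deterministic order)."""
    params = params or DigestParams()
    by_set: dict[frozenset[str], list[str]] = {}
    for protein in db:
        by_set.setdefault(theoretical_peptide_set(protein, enzymes, params), []).append(
            protein.id
        )
    return sorted(tuple(sorted(m)) for m in by_set.values())


def match_spot(
    observations: list[SpotObservation],
    db: list[ProteinRecord],
    index: dict[str, set[str]],
    min_unique: int = 1,
    min_coverage: float = 0.1,
    enzymes: tuple[Enzyme, ...] = DEFAULT_ENZYMES,
    params: DigestParams | None = None,
    groups: list[tuple[str, ...]] | None = None,
) -> MatchResult:
    """Match one spot (its observations under both enzymes, pooled) to an
    equivalence group of proteins.

    1. Collapse the database into equivalence groups.
    2. If some group owns >= min_unique observed peptides unique to it, match
       that group (evidence=unique_peptide; ties broken by coverage).
    3. Otherwise match the candidate group (sharing >= 1 observed peptide) of
       maximal coverage if that coverage >= min_coverage (evidence=max_coverage).
    4. Otherwise: no match found.
    """
    if not observations:
        raise InputError("match_spot needs at least one observation")
    spot_id = observations[0].spot_id
    if any(o.spot_id != spot_id for o in observations):
        raise InputError("observations belong to different spots")
    observed = sorted({p for o in observations for p in o.peptides})
    if not observed:
        warnings.warn(f"spot {spot_id!r}: no observed peptides", stacklevel=2)
        return MatchResult(spot_id, [], EVIDENCE_NMF)

    params = params or DigestParams()
    if groups is None:
        groups = equivalence_groups(db, enzymes, params)
    proteins = {p.id: p for p in db}

    def group_coverage(group: tuple[str, ...]) -> float:
        return max(coverage(proteins[g], observed) for g in group)

    # step 2: group-unique observed peptides
    unique_counts: dict[tuple[str, ...], int] = {}
    for group in groups:
        members = set(group)
        n = sum(
            1
            for pep in observed
            if pep in index and index[pep] and index[pep] <= members
        )
        if n >= min_unique:
            unique_counts[group] = n
    if unique_counts:
        best = max(
            unique_counts,
            key=lambda g: (unique_counts[g], group_coverage(g), tuple(reversed(g))),
        )
        return MatchResult(
            spot_id=spot_id,
            matched_ids=list(best),
            evidence=EVIDENCE_UNIQUE,
            coverage={g: coverage(proteins[g], observed) for g in best},
            equivalence_group=len(best) > 1,
        )

    # step 3: maximal coverage among groups sharing at least one peptide
    candidates = [
        g for g in groups if any(pep in index and g[0] in index[pep] for pep in observed)
    ]
    scored = [(group_coverage(g), g) for g in candidates]
    scored.sort(key=lambda t: (-t[0], t[1]))
    if scored and scored[0][0] >= min_coverage:
        cov, best = scored[0]
        return MatchResult(
            spot_id=spot_id,
            matched_ids=list(best),
            evidence=EVIDENCE_COVERAGE,
            coverage={g: coverage(proteins[g], observed) for g in best},
            equivalence_group=len(best) > 1,
        )
    return MatchResult(spot_id, [], EVIDENCE_NMF)
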