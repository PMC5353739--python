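"""Gli-locus assignment from deletion-line evidence.

Bread wheat carries six compound gliadin loci (Gli-A1/B1/D1 on the group-1
short arms, Gli-A2/B2/D2 on the group-6 short arms). A 2-DE spot missing in
exactly one locus-deletion line is assigned to that locus; genes inherit loci
from their matched spots (SA evidence) and/or from PCR amplicon absence in the
deletion lines (PM evidence).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConflictError, InputError
from .match import MatchResult

GLI_LOCI = ("Gli-A1", "Gli-B1", "Gli-D1", "Gli-A2", "Gli-B2", "Gli-D2")

EVIDENCE_SA = "SA"
EVIDENCE_PM = "PM"
EVIDENCE_BOTH = "SA+PM"


@dataclass
class SpotPresenceMatrix:
    """Presence/absence of each spot in the wild type and the six deletion
    lines. ``line_locus`` maps each line to the locus it lacks (None for the
    wild type); ``mixture_spots`` are spots known to contain a mixture of
    gliadins and are excluded from assignment evidence."""

    present: pd.DataFrame  # spots x lines, boolean
    line_locus: dict[str, str | None]
    mixture_spots: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        wt = [l for l, loc in self.line_locus.items() if loc is None]
        if len(wt) != 1:
            raise InputError("exactly one wild-type line is required")
        self.wild_type = wt[0]
        missing = set(self.line_locus) - set(self.present.columns)
        if missing:
            raise InputError(f"lines missing from matrix: {sorted(missing)}")
        absent_wt = self.present.index[~self.present[self.wild_type].astype(bool)]
        if len(absent_wt):
            raise InputError(
                f"spots absent in wild type: {list(absent_wt)[:5]}"
            )

    @property
    def spots(self) -> list[str]:
        return list(self.present.index)

    @property
    def deletion_lines(self) -> list[str]:
        return [l for l in self.line_locus if self.line_locus[l] is not None]


@dataclass
class PcrEvidence:
    """Per-gene PCR amplicon presence across the wild type and deletion lines."""

    gene_id: str
    present: dict[str, bool]  # line -> amplicon present


@dataclass
class SpotAssignment:
    spot_id: str
    locus: str | None
    reason: str  # assigned | no_evidence | conflict | mixture


@dataclass
class GeneAssignment:
    gene_id: str
    locus: str | None
    evidence: str | None  # SA | PM | SA+PM | None
    matched_spots: list[str] = field(default_factory=list)


def assign_spot(spot_id: str, matrix: SpotPresenceMatrix) -> SpotAssignment:
    """Locus of the single deletion line lacking the spot, if unique."""
    if spot_id not in matrix.present.index:
        raise InputError(f"unknown spot {spot_id!r}")
    if not bool(matrix.present.loc[spot_id, matrix.wild_type]):
        raise InputError(f"spot {spot_id!r} absent in wild type")
    if spot_id in matrix.mixture_spots:
        return SpotAssignment(spot_id, None, "mixture")
    absent = [
        line
        for line in matrix.deletion_lines
        if not bool(matrix.present.loc[spot_id, line])
    ]
    if not absent:
        return SpotAssignment(spot_id, None, "no_evidence")
    if len(absent) > 1:
        return SpotAssignment(spot_id, None, "conflict")
    return SpotAssignment(spot_id, matrix.line_locus[absent[0]], "assigned")


def assign_all_spots(matrix: SpotPresenceMatrix) -> dict[str, SpotAssignment]:
    return {s: assign_spot(s, matrix) for s in matrix.spots}


def _pm_locus(pcr: PcrEvidence, line_locus: dict[str, str | None]) -> str | None:
    wt = [l for l, loc in line_locus.items() if loc is None][0]
    if not pcr.present.get(wt, False):
        raise InputError(f"gene {pcr.gene_id!r}: amplicon absent in wild type")
    absent = [
        line
        for line, loc in line_locus.items()
        if loc is not None and line in pcr.present and not pcr.present[line]
    ]
    if not absent:
        return None
    if len(absent) > 1:
        raise ConflictError(
            f"gene {pcr.gene_id!r}: amplicon absent in multiple lines {absent}"
        )
    return line_locus[absent[0]]


def assign_gene(
    gene_id: str,
    matches: list[MatchResult],
    spot_assignments: dict[str, SpotAssignment],
    pcr: PcrEvidence | None = None,
    line_locus: dict[str, str | None] | None = None,
) -> GeneAssignment:
    """Combine spot-assignment (SA) and PCR-mapping (PM) evidence for a gene.

    SA requires unanimity among the loci of matched, locus-assigned spots;
    SA/PM disagreement raises a ConflictError rather than prioritizing.
    """
    matched_spots = sorted(
        m.spot_id for m in matches if gene_id in m.matched_ids
    )
    sa_loci = []
    for spot in matched_spots:
        a = spot_assignments.get(spot)
        if a is not None and a.locus is not None:
            sa_loci.append(a.locus)
    sa_locus = None
    if sa_loci:
        if len(set(sa_loci)) > 1:
            raise ConflictError(
                f"gene {gene_id!r}: matched spots disagree on locus {sorted(set(sa_loci))}"
            )
        sa_locus = sa_loci[0]

    pm_locus = None
    if pcr is not None:
        if line_locus is None:
            raise InputError("PCR evidence requires the line->locus map")
        pm_locus = _pm_locus(pcr, line_locus)

    if sa_locus and pm_locus:
        if sa_locus != pm_locus:
            raise ConflictError(
                f"gene {gene_id!r}: SA locus {sa_locus} contradicts PM locus {pm_locus}"
            )
        return GeneAssignment(gene_id, sa_locus, EVIDENCE_BOTH, matched_spots)
    if sa_locus:
        return GeneAssignment(gene_id, sa_locus, EVIDENCE_SA, matched_spots)
    if pm_locus:
        return GeneAssignment(gene_id, pm_locus, EVIDENCE_PM, matched_spots)
    return GeneAssignment(gene_id, None, None, matched_spots)


def subgenome(locus: str) -> str:
    """A, B or D subgenome letter of a Gli locus name."""
    return locus.split("-")[1][0]


def summarize_loci(
    assignments: list[GeneAssignment], gene_types: dict[str, str] | None = None
) -> dict[str, pd.Series]:
    """Counts of assigned (accumulated) gliadins per locus, per subgenome and
    per type; the three groupings conserve the same total."""
    assigned = [a for a in assignments if a.locus is not None]
    by_locus = pd.Series(
        {loc: sum(1 for a in assigned if a.locus == loc) for loc in GLI_LOCI},
        dtype=int,
    )
    by_subgenome = pd.Series(
        {
            g: sum(1 for a in assigned if subgenome(a.locus) == g)
            for g in ("A", "B", "D")
        },
        dtype=int,
    )
    gene_types = gene_types or {}
    types = sorted({gene_types.get(a.gene_id, "unknown") for a in assigned})
    by_type = pd.Series(
        {
            t: sum(1 for a in assigned if gene_types.get(a.gene_id, "unknown") == t)
            for t in types
        },
        dtype=int,
    )
    return {"by_locus": by_locus, "by_subgenome": by_subgenome, "by_type": by_type}
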