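"""In-silico protease digestion and peptide-to-protein indexing.

Gliadin 2-DE spots are digested with chymotrypsin and thermolysin separately;
this module enumerates the theoretical peptides of each digest under a missed-
cleavage allowance and an MS/MS extraction mass window, and builds the
peptide -> parent-protein index used for uniqueness-based spot matching.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, InputError
from .masses import peptide_mass
from .records import ProteinRecord


@dataclass(frozen=True)
class Enzyme:
    name: str
    cut_side: str  # "C" (C-terminal to the residue) or "N"
    residues: frozenset[str]
    blocked_by_next_proline: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ConfigError(f"enzyme {self.name!r}: empty residue set")
        if self.cut_side not in ("C", "N"):
            raise ConfigError(f"enzyme {self.name!r}: cut_side must be C or N")

    def cleavage_boundaries(self, seq: str) -> list[int]:
        """0-based boundary indices (cut between seq[i-1] and seq[i])."""
        sites = []
        if self.cut_side == "C":
            for i in range(len(seq) - 1):
                if seq[i] in self.residues:
                    if self.blocked_by_next_proline and seq[i + 1] == "P":
                        continue
                    sites.append(i + 1)
        else:
            for i in range(1, len(seq)):
                if seq[i] in self.residues:
                    if self.blocked_by_next_proline and seq[i - 1] == "P":
                        continue
                    sites.append(i)
        return sorted(set(sites))


CHYMOTRYPSIN = Enzyme(
    "chymotrypsin", "C", frozenset("FYWL"), blocked_by_next_proline=True
)
THERMOLYSIN = Enzyme("thermolysin", "N", frozenset("AFILMV"))
DEFAULT_ENZYMES = (CHYMOTRYPSIN, THERMOLYSIN)


@dataclass
class DigestParams:
    """max_missed=2 and a 300-6000 Da window follow the MS/MS extraction
    settings used for the gliadin spot searches."""

    max_missed: int = 2
    mass_min_da: float = 300.0
    mass_max_da: float = 6000.0
    min_len_aa: int = 1

    def __post_init__(self) -> None:
        if self.max_missed < 0:
            raise ConfigError("max_missed must be >= 0")
        if self.mass_min_da >= self.mass_max_da:
            raise ConfigError("mass window must be increasing")


@dataclass
class TheoreticalPeptide:
    sequence: str
    parent_ids: set[str]
    spans: dict[str, list[tuple[int, int]]]  # parent id -> 1-based spans
    missed: int
    mass_da: float


def digest(
    protein: ProteinRecord, enzyme: Enzyme, params: DigestParams
) -> list[TheoreticalPeptide]:
    """All theoretical peptides of one protein under one enzyme, with up to
    ``max_missed`` internal missed cleavages, filtered to the mass window and
    minimum length; duplicates by sequence are collapsed with spans retained."""
    seq = protein.sequence
    bounds = [0] + enzyme.cleavage_boundaries(seq) + [len(seq)]
    by_seq: dict[str, TheoreticalPeptide] = {}
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + params.max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            pep = seq[start:end]
            if len(pep) < params.min_len_aa:
                continue
            mass = peptide_mass(pep)
            if not (params.mass_min_da <= mass <= params.mass_max_da):
                continue
            missed = j - i - 1
            entry = by_seq.get(pep)
            if entry is None:
                entry = TheoreticalPeptide(
                    sequence=pep,
                    parent_ids={protein.id},
                    spans={protein.id: []},
                    missed=missed,
                    mass_da=mass,
                )
                by_seq[pep] = entry
            entry.missed = min(entry.missed, missed)
            entry.spans[protein.id].append((start + 1, end))
    return sorted(by_seq.values(), key=lambda p: (p.spans[protein.id][0], p.sequence))


def theoretical_peptide_set(
    protein: ProteinRecord,
    enzymes: tuple[Enzyme, ...] = DEFAULT_ENZYMES,
    params: DigestParams | None = None,
) -> frozenset[str]:
    """Union of peptide sequences over all enzymes (used for equivalence
    grouping and spot simulation)."""
    params = params or DigestParams()
    peps: set[str] = set()
    for enzyme in enzymes:
        peps.update(p.sequence for p in digest(protein, enzyme, params))
    return frozenset(peps)


def build_peptide_index(
    db: list[ProteinRecord],
    enzymes: tuple[Enzyme, ...] = DEFAULT_ENZYMES,
    params: DigestParams | None = None,
) -> dict[str, set[str]]:
    """peptide sequence -> set of parent protein ids, pooled over enzymes.

    A peptide is *unique* iff its parent set has exactly one member.
    """
    if not db:
        raise InputError("empty protein database")
    ids = [p.id for p in db]
    if len(ids) != len(set(ids)):
        raise InputError("duplicate protein ids in database")
    params = params or DigestParams()
    index: dict[str, set[str]] = {}
    for protein in db:
        for pep in theoretical_peptide_set(protein, enzymes, params):
            index.setdefault(pep, set()).add(protein.id)
    return index


def coverage(protein: ProteinRecord, observed: list[str]) -> float:
    """Fraction of the protein covered by the union of all exact-substring
    placements of the observed peptides; peptides that do not occur contribute
    nothing."""
    seq = protein.sequence
    if not seq:
        return 0.0
    covered = bytearray(len(seq))
    for pep in observed:
        if not pep:
            continue
        start = seq.find(pep)
        while start != -1:
            covered[start : start + len(pep)] = b"\x01" * len(pep)
            start = seq.find(pep, start + 1)
    return sum(covered) / len(seq)
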