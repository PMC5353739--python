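"""Celiac-disease T-cell epitope scanning and per-protein summaries.

Epitope cores are 9-residue peptides presented on HLA-DQ molecules. Scanning
is exact overlapping substring search over the protein sequence: every start
position of every core is reported, so tandem-repeated epitopes (the 33-mer
situation) are counted once per occurrence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, InputError
from .records import AMINO_ACIDS, ProteinRecord

CATEGORY_ZERO = "zero"
CATEGORY_ONE_TO_TWO = "one_to_two"
CATEGORY_THREE_PLUS = "three_plus"

# The three immunodominant DQ2.5 alpha-gliadin epitopes carried by the
# canonical 33-mer peptide.
THIRTY_THREE_MER = "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF"
DQ25_GLIA_A1A = "PFPQPQLPY"
DQ25_GLIA_A1B = "PYPQPQLPY"
DQ25_GLIA_A2 = "PQPQLPYPQ"


@dataclass(frozen=True)
class Epitope:
    name: str
    core: str
    restriction: str = "DQ2.5"
    native_core: str | None = None

    def __post_init__(self) -> None:
        if len(self.core) != 9:
            raise InputError(f"epitope {self.name!r}: core must be 9 residues")
        if set(self.core) - AMINO_ACIDS:
            raise InputError(f"epitope {self.name!r}: invalid residues in core")


@dataclass
class EpitopePanel:
    epitopes: list[Epitope]
    scan_form: str = "native"  # native | deamidated
    q_e_equivalent: bool = False

    def __post_init__(self) -> None:
        # an empty panel is legal and scans to zero hits
        names = [e.name for e in self.epitopes]
        if len(names) != len(set(names)):
            raise ConfigError("epitope names must be unique")

    def scan_cores(self) -> list[tuple[str, str]]:
        out = []
        for e in self.epitopes:
            core = e.core
            if self.scan_form == "native" and e.native_core:
                core = e.native_core
            out.append((e.name, core))
        return out


@dataclass(frozen=True)
class EpitopeHit:
    protein_id: str
    epitope_name: str
    position: int  # 1-based start


@dataclass
class EpitopeSummary:
    protein_id: str
    per_epitope_copies: dict[str, int]
    total: int = 0
    distinct: int = 0
    category: str = CATEGORY_ZERO

    def __post_init__(self) -> None:
        self.total = sum(self.per_epitope_copies.values())
        self.distinct = sum(1 for c in self.per_epitope_copies.values() if c > 0)
        self.category = categorize(self.total)


def categorize(total: int) -> str:
    """Fixed epitope-load bins: 0 / 1-2 / >=3."""
    if total == 0:
        return CATEGORY_ZERO
    if total <= 2:
        return CATEGORY_ONE_TO_TWO
    return CATEGORY_THREE_PLUS


def _fold_qe(seq: str) -> str:
    return seq.replace("E", "Q")


def scan(protein: ProteinRecord, panel: EpitopePanel) -> list[EpitopeHit]:
    """Every (overlapping) exact occurrence of every panel core, ordered by
    position then epitope name."""
    seq = protein.sequence
    if panel.q_e_equivalent:
        seq = _fold_qe(seq)
    hits = []
    for name, core in panel.scan_cores():
        needle = _fold_qe(core) if panel.q_e_equivalent else core
        start = seq.find(needle)
        while start != -1:
            hits.append(EpitopeHit(protein.id, name, start + 1))
            start = seq.find(needle, start + 1)
    hits.sort(key=lambda h: (h.position, h.epitope_name))
    return hits


def summarize(
    hits: list[EpitopeHit], protein: ProteinRecord, panel: EpitopePanel
) -> EpitopeSummary:
    """Per-epitope copy counts and the 0 / 1-2 / >=3 category for one protein."""
    copies = {e.name: 0 for e in panel.epitopes}
    for h in hits:
        if h.protein_id != protein.id:
            raise InputError(f"hit for {h.protein_id!r} passed with {protein.id!r}")
        copies[h.epitope_name] += 1
    return EpitopeSummary(protein_id=protein.id, per_epitope_copies=copies)


def locus_summary(
    summaries: list[EpitopeSummary], gene_to_locus: dict[str, str]
) -> pd.DataFrame:
    """Per-locus aggregation: protein count, epitope-free count, total epitope
    copies. Proteins without an assignment are grouped under 'unassigned'."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "locus": gene_to_locus.get(s.protein_id, "unassigned"),
                "protein_id": s.protein_id,
                "total": s.total,
                "zero": s.total == 0,
            }
        )
    df = pd.DataFrame(rows, columns=["locus", "protein_id", "total", "zero"])
    if df.empty:
        return pd.DataFrame(
            columns=["n_proteins", "n_zero_epitope", "total_epitopes"]
        ).rename_axis("locus")
    out = df.groupby("locus").agg(
        n_proteins=("protein_id", "size"),
        n_zero_epitope=("zero", "sum"),
        total_epitopes=("total", "sum"),
    )
    out["n_zero_epitope"] = out["n_zero_epitope"].astype(int)
    return out


def default_panel() -> EpitopePanel:
    """Three published DQ2.5 alpha-epitope cores plus clearly labeled synthetic
    test epitopes (the full curated gliadin panel must be supplied by the user)."""
    return EpitopePanel(
        epitopes=[
            Epitope("DQ2.5-glia-a1a", DQ25_GLIA_A1A, "DQ2.5"),
            Epitope("DQ2.5-glia-a1b", DQ25_GLIA_A1B, "DQ2.5"),
            Epitope("DQ2.5-glia-a2", DQ25_GLIA_A2, "DQ2.5"),
            Epitope("SYN-glia-gA", "QTPFAQYQA", "DQ8"),
            Epitope("SYN-glia-gB", "FAQTYQAIP", "DQ8"),
            Epitope("SYN-glia-oA", "TIAQFPAYQ", "DQ8"),
        ]
    )
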