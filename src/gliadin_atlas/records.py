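"""Core sequence records and annotation containers.

Coordinates are 1-based inclusive throughout, on the precursor protein or on
the transcript, matching the convention used in the prolamin literature.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

GLIADIN_TYPES = ("alpha", "gamma", "delta", "omega")


@dataclass
class TranscriptRecord:
    """An oriented, full-length transcript (FLNC-read analogue)."""

    id: str
    sequence: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise InputError(
                f"transcript {self.id!r}: invalid nucleotide(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """A deduced protein, either the full precursor or the mature chain
    (precursor minus signal peptide)."""

    id: str
    sequence: str
    form: str = "precursor"  # "precursor" | "mature"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise InputError(
                f"protein {self.id!r}: invalid residue(s) {sorted(bad)}"
            )
        if self.form not in ("precursor", "mature"):
            raise InputError(f"protein {self.id!r}: unknown form {self.form!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def mature_sequence(self, signal_peptide_len: int) -> str:
        """Mature chain given the profile's signal-peptide length."""
        if self.form == "mature":
            return self.sequence
        if signal_peptide_len >= len(self.sequence):
            raise InputError(
                f"protein {self.id!r}: shorter than its signal peptide"
            )
        return self.sequence[signal_peptide_len:]


@dataclass
class CodingStatus:
    """Active/pseudogene call for a transcript.

    defect is one of none | premature_stop | frameshift | no_orf;
    orf_span is 1-based inclusive on the transcript, or None.
    """

    status: str
    defect: str
    orf_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.status not in ("active", "pseudogene"):
            raise InputError(f"unknown status {self.status!r}")
        if self.defect not in ("none", "premature_stop", "frameshift", "no_orf"):
            raise InputError(f"unknown defect {self.defect!r}")
        if (self.status == "active") != (self.defect == "none"):
            raise InputError("status=active iff defect=none")


@dataclass
class DomainMap:
    """Ordered, contiguous, full-coverage segmentation of a precursor."""

    segments: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise InputError("empty domain map")
        prev_end = 0
        for label, start, end in self.segments:
            if start != prev_end + 1 or end < start:
                raise InputError(
                    f"domain map not contiguous at segment {label!r} [{start},{end}]"
                )
            prev_end = end
        labels = [s[0] for s in self.segments]
        if len(labels) != len(set(labels)):
            raise InputError("duplicate domain labels")

    def span(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.segments:
            if lab == label:
                return start, end
        raise KeyError(label)

    def label_at(self, pos: int) -> str:
        for lab, start, end in self.segments:
            if start <= pos <= end:
                return lab
        raise KeyError(pos)

    @property
    def length(self) -> int:
        return self.segments[-1][2]


@dataclass
class GliadinAnnotation:
    """Per-protein classification record (one row of the annotation table)."""

    protein_id: str
    type: str = "unknown"
    type_score: float = 0.0
    subtype: str = "none"  # CT | CSTT | omega5 | omega12 | none
    nterm_label: str | None = None
    cys_total: int = 0
    cys_conserved: int = 0
    cys_extra_positions: list[int] = field(default_factory=list)
    domains: DomainMap | None = None
    mature_length: int = 0
    mature_mass_da: float = 0.0
    status: CodingStatus | None = None

    def __post_init__(self) -> None:
        if self.cys_total != self.cys_conserved + len(self.cys_extra_positions):
            raise InputError("cys_total must equal conserved + extras")
        if self.subtype in ("CT", "CSTT") and self.type != "alpha":
            raise InputError("CT/CSTT subtypes are alpha-only")
        if self.subtype in ("omega5", "omega12") and self.type != "omega":
            raise InputError("omega subtypes are omega-only")
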