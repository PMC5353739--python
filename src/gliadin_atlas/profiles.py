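"""Type profiles: the structural grammar of each gliadin type.

A profile bundles everything the classifier and segmenter need to know about
one gliadin type: the ordered domain grammar, the repeat motifs of the
repetitive region, the expected number of conserved cysteines and the domains
that host them, the mature-length band, and (for alpha/omega) the subtype
discriminators.

The alpha CT/CSTT tail signatures shipped here are synthetic placeholders
registered by the synthetic-data generator; users classifying real sequences
should derive signatures from their own alignment and override
``subtype_rules``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

# Synthetic C-terminal tail signatures for the two alpha subgroups (the real
# discriminating residues are not public; these keep the mechanism testable).
CT_SIGNATURE = "TTIAPFGIFG"
CSTT_SIGNATURE = "SNTAVQGSVQ"

ALPHA_MOTIFS = ("PQPQPFP", "QPQPYPQ")
GAMMA_MOTIFS = ("PQQPFPQ",)
DELTA_MOTIFS = ("FPQQTQQP",)
OMEGA5_MOTIFS = ("FPQQQ", "QQIPQQ")
OMEGA12_MOTIFS = ("PQQPFP",)


@dataclass
class TypeProfile:
    type: str
    domain_grammar: tuple[str, ...]
    expected_conserved_cys: int
    repeat_motifs: tuple[str, ...]
    motif_weights: tuple[float, ...] = ()
    signal_peptide_len: int = 20
    nterm_prefixes: tuple[str, ...] = ()
    mature_length_band: tuple[int, int] = (250, 460)
    conserved_cys_domains: tuple[str, ...] = ()
    subtype_rules: dict[str, str] = field(default_factory=dict)
    q_run_min: float = 0.8
    q_window: int = 8

    def __post_init__(self) -> None:
        if len(self.domain_grammar) != len(set(self.domain_grammar)):
            raise ConfigError("domain grammar labels must be unique")
        if self.expected_conserved_cys < 0:
            raise ConfigError("expected_conserved_cys must be >= 0")
        if not self.motif_weights:
            self.motif_weights = tuple(1.0 for _ in self.repeat_motifs)
        lo, hi = self.mature_length_band
        if lo >= hi:
            raise ConfigError("mature length band must be increasing")


def default_profiles() -> list[TypeProfile]:
    """The four built-in gliadin type profiles.

    Mature-length bands follow the published per-type protein-length ranges
    (alpha 282-325 aa, gamma 285-357 aa, delta ~327 aa, omega 359-439 aa) with
    a small margin for indel variation among homoeologs.
    """
    return [
        TypeProfile(
            type="alpha",
            domain_grammar=("SP", "RR", "PQR1", "UR1", "PQR2", "UR2"),
            expected_conserved_cys=6,
            repeat_motifs=ALPHA_MOTIFS,
            nterm_prefixes=("VRV",),
            mature_length_band=(275, 332),
            conserved_cys_domains=("UR1", "UR2"),
            subtype_rules={"CT": CT_SIGNATURE, "CSTT": CSTT_SIGNATURE},
        ),
        TypeProfile(
            type="gamma",
            domain_grammar=("SP", "NR", "RR", "PQR", "UR1", "UR2"),
            expected_conserved_cys=8,
            repeat_motifs=GAMMA_MOTIFS,
            nterm_prefixes=("NMQ",),
            mature_length_band=(278, 364),
            conserved_cys_domains=("UR1", "UR2"),
        ),
        TypeProfile(
            type="delta",
            domain_grammar=("SP", "NR", "RR", "UR"),
            expected_conserved_cys=8,
            repeat_motifs=DELTA_MOTIFS,
            nterm_prefixes=("RVQ",),
            mature_length_band=(300, 348),
            conserved_cys_domains=("UR",),
        ),
        TypeProfile(
            type="omega",
            domain_grammar=("SP", "NR", "RR"),
            expected_conserved_cys=0,
            repeat_motifs=OMEGA5_MOTIFS + OMEGA12_MOTIFS,
            nterm_prefixes=("SRL", "ARE", "ARQ", "KEL", "ARP"),
            mature_length_band=(352, 446),
            conserved_cys_domains=(),
        ),
    ]


def profile_by_type(profiles: list[TypeProfile], type_: str) -> TypeProfile:
    for p in profiles:
        if p.type == type_:
            return p
    raise ConfigError(f"no profile for type {type_!r}")


def generic_profile(profiles: list[TypeProfile] | None = None) -> TypeProfile:
    """A type-agnostic profile whose length band spans all types.

    Used to assess coding status of transcripts whose type is not yet known.
    """
    profiles = profiles or default_profiles()
    lo = min(p.mature_length_band[0] for p in profiles)
    hi = max(p.mature_length_band[1] for p in profiles)
    motifs: tuple[str, ...] = ()
    for p in profiles:
        motifs += p.repeat_motifs
    return TypeProfile(
        type="generic",
        domain_grammar=("SP", "RR"),
        expected_conserved_cys=0,
        repeat_motifs=motifs,
        mature_length_band=(lo, hi),
    )
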