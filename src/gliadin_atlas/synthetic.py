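"""Ground-truth-labeled synthetic gliadin corpora.

The generator emits a study-design corpus — 52 transcripts: 42 active (25 alpha
[13 CT / 12 CSTT], 11 gamma, 1 delta, 5 omega) plus 10 pseudogenes (7 alpha,
2 gamma, 1 omega disrupted by premature stops or frameshifts) — together with
epitope placements, two-enzyme spot observations, a deletion-line
presence/absence matrix, PCR evidence and developmental read counts, all
deterministic under a fixed seed.

Sequences follow each type's domain grammar (signal peptide, repeats,
polyglutamine runs, unique regions with conserved cysteines) but are openly
synthetic: repeat motifs, subtype tail signatures and most epitopes are
invented test sequences, not wheat biology.

Reverse translation uses a flat (uniform) codon table with three deterministic
exceptions (Y->TAC, N->AAC, D->GAC, and no A-ending codon before a cysteine)
that prevent spurious ATG start codons from forming across codon junctions,
so the longest ORF of every emitted transcript is its true CDS.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .align import pairwise_identity
from .digest import DEFAULT_ENZYMES, DigestParams, Enzyme, digest
from .epitopes import THIRTY_THREE_MER, Epitope, EpitopePanel, default_panel
from .errors import ConfigError
from .loci import PcrEvidence, SpotPresenceMatrix
from .match import SpotObservation
from .masses import peptide_mass
from .orf import STOP_CODONS, find_orfs
from .profiles import (
    CSTT_SIGNATURE,
    CT_SIGNATURE,
    TypeProfile,
    default_profiles,
    generic_profile,
    profile_by_type,
)
from .records import DomainMap, ProteinRecord, TranscriptRecord

SIGNAL_PEPTIDES = {
    "alpha": "MKTFLILALLAIVATTATIA",
    "gamma": "MKTLLILALLAIAATSATIA",
    "delta": "MKTFLILALLAISATTATIA",
    "omega": "MKTFLILALLAMVATTATIA",
}
NTERM_PREFIX = {"alpha": "VRVPV", "gamma": "NMQVD", "delta": "RVQLE"}
OMEGA_NTERM = {"omega5": "SRLL", "omega12": ("ARQL", "AREL", "KELQ", "ARPL")}

_UR_ALPHABET = "QPFLYSTIVA"
_SUB_ALPHABET = "PFLSTIVAY"  # substitution targets: no Q (polyQ safety), no C/M/W

UTR5 = "CTCTCTTCCTTCTCCTTCTCTTCCC"
UTR3 = "TAAGTAAGTAACTTCTTCCTTCTCC"  # early stop codons in all three frames

# flat codon table with junction-safe exceptions (see module docstring)
_CODONS = {
    "A": ("GCT", "GCC", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAC",),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC"),
    "I": ("ATT", "ATC"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAC",),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAC",),
}


# ---------------------------------------------------------------------------
# member plan (the default "study-design" composition)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MemberSpec:
    gene_id: str
    type: str
    subtype: str  # CT | CSTT | omega5 | omega12 | none
    locus: str
    status: str  # active | pseudogene
    defect_mode: str | None = None
    accumulated: bool = False
    extra_cys: int = 0
    epitope_plan: tuple[tuple[str, int], ...] = ()
    pcr: bool = False
    duplicate_of: str | None = None  # emit an identical protein (paralog pair)


def published_composition() -> list[MemberSpec]:
    """52 transcripts mirroring the published composition: counts per type,
    CT/CSTT split, loci, extra cysteines, NMF genes, epitope-load bins."""
    members: list[MemberSpec] = []
    alpha_two = (("DQ2.5-glia-a1a", 1), ("DQ2.5-glia-a1b", 1))
    for i in range(1, 26):
        locus = "Gli-A2" if i <= 8 else ("Gli-B2" if i <= 18 else "Gli-D2")
        subtype = "CSTT" if i in {8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19} else "CT"
        if i in {1, 2, 3, 4, 5, 6, 9, 10}:
            plan: tuple[tuple[str, int], ...] = alpha_two
        elif i in {20, 22, 23}:
            plan = (("33mer", 1),)
        elif i in {21, 24}:
            plan = (("DQ2.5-glia-a1a", 1), ("DQ2.5-glia-a2", 2))
        else:
            plan = ()
        members.append(
            MemberSpec(
                gene_id=f"Gli-a{i}",
                type="alpha",
                subtype=subtype,
                locus=locus,
                status="active",
                accumulated=i not in {7, 8, 18, 25},
                extra_cys=1 if i == 25 else 0,
                epitope_plan=plan,
                pcr=i in {1, 4, 5, 9, 10, 11, 16, 17, 20, 24, 7, 8, 18, 25},
            )
        )
    gamma_plan = (("SYN-glia-gA", 2), ("SYN-glia-gB", 2))
    for i in range(1, 12):
        locus = "Gli-A1" if i <= 3 else ("Gli-B1" if i <= 7 else "Gli-D1")
        members.append(
            MemberSpec(
                gene_id=f"Gli-g{i}",
                type="gamma",
                subtype="none",
                locus=locus,
                status="active",
                accumulated=True,
                extra_cys=1 if i in {5, 10} else 0,
                epitope_plan=gamma_plan,
                pcr=i in {1, 11},
                duplicate_of="Gli-g2" if i == 3 else None,
            )
        )
    members.append(
        MemberSpec("Gli-d1", "delta", "none", "Gli-D1", "active", accumulated=True)
    )
    omega_specs = [
        ("Gli-o1", "omega12", "Gli-A1", 0, False),
        ("Gli-o2", "omega12", "Gli-B1", 1, True),
        ("Gli-o3", "omega5", "Gli-B1", 0, False),
        ("Gli-o4", "omega12", "Gli-D1", 0, False),
        ("Gli-o5", "omega12", "Gli-D1", 1, False),
    ]
    omega_plan = (("SYN-glia-oA", 3),)
    for gid, subtype, locus, xc, pcr in omega_specs:
        members.append(
            MemberSpec(
                gene_id=gid,
                type="omega",
                subtype=subtype,
                locus=locus,
                status="active",
                accumulated=True,
                extra_cys=xc,
                epitope_plan=() if gid == "Gli-o3" else omega_plan,
                pcr=pcr,
            )
        )
    pseudo = [
        ("Gli-pa1", "alpha", "Gli-A2", "premature_stop"),
        ("Gli-pa2", "alpha", "Gli-A2", "frameshift"),
        ("Gli-pa3", "alpha", "Gli-B2", "premature_stop"),
        ("Gli-pa4", "alpha", "Gli-B2", "frameshift"),
        ("Gli-pa5", "alpha", "Gli-B2", "premature_stop"),
        ("Gli-pa6", "alpha", "Gli-D2", "frameshift"),
        ("Gli-pa7", "alpha", "Gli-D2", "premature_stop"),
        ("Gli-pg1", "gamma", "Gli-A1", "premature_stop"),
        ("Gli-pg2", "gamma", "Gli-D1", "frameshift"),
        ("Gli-po1", "omega", "Gli-B1", "frameshift"),
    ]
    for gid, type_, locus, mode in pseudo:
        members.append(
            MemberSpec(
                gene_id=gid,
                type=type_,
                subtype="omega12" if type_ == "omega" else ("CT" if type_ == "alpha" else "none"),
                locus=locus,
                status="pseudogene",
                defect_mode=mode,
            )
        )
    return members


@dataclass
class GeneratorConfig:
    seed: int = 7
    composition: list[MemberSpec] = field(default_factory=published_composition)
    family_identity: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.92, "gamma": 0.86, "omega": 0.82}
    )
    detection_prob: float = 0.8
    contaminant_rate: float = 0.02
    spots_per_protein: tuple[int, ...] = (1, 2, 3)
    spots_per_protein_weights: tuple[float, ...] = (0.25, 0.5, 0.25)
    n_mixture_spots: int = 2
    mass_band_da: tuple[float, float] = (28_000.0, 40_000.0)
    timepoints_daf: tuple[int, ...] = (0, 10, 15, 25)

    def __post_init__(self) -> None:
        if not 0 <= self.detection_prob <= 1:
            raise ConfigError("detection_prob must be in [0,1]")
        if self.contaminant_rate < 0:
            raise ConfigError("contaminant_rate must be >= 0")
        for spec in self.composition:
            if spec.status == "pseudogene" and spec.defect_mode is None:
                raise ConfigError(f"{spec.gene_id}: pseudogene needs a defect mode")


# ---------------------------------------------------------------------------
# skeleton construction
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = _UR_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _limit_q_runs(seq: str, max_run: int = 3) -> str:
    out = list(seq)
    run = 0
    for i, c in enumerate(out):
        run = run + 1 if c == "Q" else 0
        if run > max_run:
            out[i] = "S"
            run = 0
    return "".join(out)


def _no_edge_q(seq: str) -> str:
    out = list(seq)
    for i in (0, 1, -2, -1):
        if out[i] == "Q":
            out[i] = "S"
    return "".join(out)


def _unique_region(
    rng: np.random.Generator, n: int, n_cys: int
) -> tuple[str, list[int]]:
    """Random unique-region sequence with n_cys cysteines at spaced interior
    positions (0-based positions returned)."""
    seq = list(_no_edge_q(_limit_q_runs(_rand_seq(rng, n))))
    if n_cys:
        lo, hi = 3, n - 3
        step = max(2, (hi - lo) // max(n_cys, 1))
        positions = []
        for k in range(n_cys):
            base = lo + k * step
            pos = int(base + rng.integers(0, max(1, step - 2)))
            pos = min(pos, hi - 1)
            while pos in positions:
                pos += 1
            positions.append(pos)
        for pos in positions:
            seq[pos] = "C"
    else:
        positions = []
    return "".join(seq), sorted(positions)


def _repeat_tract(rng: np.random.Generator, motifs: tuple[str, ...], n: int) -> str:
    """A degenerate repeat tract: tandem motifs interrupted every ~30-45
    residues by an LT or TS dipeptide (real prolamin repeats carry scattered
    non-Q/P residues; at the nucleotide level these interruptions also place
    stop codons in the shifted reading registers, so frameshifts truncate
    translation the way they do in real pseudogenes)."""
    out = []
    total = 0
    while total < n:
        m = str(rng.choice(list(motifs)))
        out.append(m)
        total += len(m)
    tract = list("".join(out)[:n])
    pos = int(rng.integers(10, 30))
    toggle = bool(rng.integers(0, 2))
    while pos < n - 10:
        tract[pos : pos + 2] = "LT" if toggle else "TS"
        toggle = not toggle
        pos += int(rng.integers(28, 46))
    return "".join(tract)


def make_skeleton(
    type_: str,
    profile: TypeProfile,
    rng: np.random.Generator,
    subtype: str = "none",
) -> tuple[ProteinRecord, dict]:
    """A precursor skeleton of one gliadin type plus its ground truth
    (domain spans, conserved-cysteine positions, signature span; all 1-based
    precursor coordinates)."""
    sp = SIGNAL_PEPTIDES[type_]
    lo, hi = profile.mature_length_band
    # draw the mature length from the interior of the band so that family
    # indels cannot push members outside it
    T = int(rng.integers(lo + 9, hi - 9))
    if type_ == "alpha":
        q1 = int(rng.integers(10, 17))
        q2 = int(rng.integers(8, 15))
        u1, cys1 = _unique_region(rng, int(rng.integers(28, 37)), 3)
        body, cys2 = _unique_region(rng, int(rng.integers(62, 75)), 3)
        sig = CT_SIGNATURE if subtype != "CSTT" else CSTT_SIGNATURE
        tail = _no_edge_q(_limit_q_runs(_rand_seq(rng, 8)))
        u2 = body + sig + tail
        rr_len = T - q1 - q2 - len(u1) - len(u2) - len(NTERM_PREFIX["alpha"])
        if rr_len < 60:
            raise ConfigError("alpha skeleton: repetitive region too short")
        rr = NTERM_PREFIX["alpha"] + _repeat_tract(rng, profile.repeat_motifs, rr_len)
        mature = rr + "Q" * q1 + u1 + "Q" * q2 + u2
        n0 = len(sp)
        spans = {
            "SP": (1, n0),
            "RR": (n0 + 1, n0 + len(rr)),
            "PQR1": (n0 + len(rr) + 1, n0 + len(rr) + q1),
            "UR1": (n0 + len(rr) + q1 + 1, n0 + len(rr) + q1 + len(u1)),
            "PQR2": (
                n0 + len(rr) + q1 + len(u1) + 1,
                n0 + len(rr) + q1 + len(u1) + q2,
            ),
            "UR2": (n0 + len(rr) + q1 + len(u1) + q2 + 1, n0 + T),
        }
        ur1_off = spans["UR1"][0]
        ur2_off = spans["UR2"][0]
        cys_positions = [ur1_off + p for p in cys1] + [ur2_off + p for p in cys2]
        sig_start = ur2_off + len(body)
        truth = {
            "spans": spans,
            "cys": cys_positions,
            "signature_span": (sig_start, sig_start + len(sig) - 1),
        }
    elif type_ == "gamma":
        nr = NTERM_PREFIX["gamma"] + _no_edge_q(
            _limit_q_runs(_rand_seq(rng, int(rng.integers(4, 9))))
        )
        q1 = int(rng.integers(10, 17))
        ua, cysa = _unique_region(rng, int(rng.integers(36, 45)), 6)
        linker = _no_edge_q("".join(rng.choice(list("PFLSTIVA"), size=16)))
        ub, cysb = _unique_region(rng, int(rng.integers(26, 35)), 2)
        tail = _no_edge_q(_limit_q_runs(_rand_seq(rng, 10)))
        post = ua + linker + ub + tail
        rr_len = T - len(nr) - q1 - len(post)
        if rr_len < 60:
            raise ConfigError("gamma skeleton: repetitive region too short")
        rr = _repeat_tract(rng, profile.repeat_motifs, rr_len)
        mature = nr + rr + "Q" * q1 + post
        n0 = len(sp)
        post_off = n0 + len(nr) + rr_len + q1
        cys_positions = [post_off + 1 + p for p in cysa] + [
            post_off + len(ua) + 16 + 1 + p for p in cysb
        ]
        split = (cys_positions[5] + cys_positions[6] + 1) // 2
        spans = {
            "SP": (1, n0),
            "NR": (n0 + 1, n0 + len(nr)),
            "RR": (n0 + len(nr) + 1, n0 + len(nr) + rr_len),
            "PQR": (n0 + len(nr) + rr_len + 1, post_off),
            "UR1": (post_off + 1, split),
            "UR2": (split + 1, n0 + T),
        }
        truth = {"spans": spans, "cys": cys_positions, "signature_span": None}
    elif type_ == "delta":
        nr = NTERM_PREFIX["delta"] + _no_edge_q(
            _limit_q_runs(_rand_seq(rng, int(rng.integers(4, 8))))
        )
        ur_nominal = int(rng.integers(64, 76))
        rr_len = T - len(nr) - ur_nominal
        if rr_len < 60:
            raise ConfigError("delta skeleton: repetitive region too short")
        # end the tract on a whole motif so the RR/UR boundary is real
        rr_len -= rr_len % len(profile.repeat_motifs[0])
        ur, cys = _unique_region(rng, T - len(nr) - rr_len, 8)
        rr = _repeat_tract(rng, profile.repeat_motifs, rr_len)
        mature = nr + rr + ur
        n0 = len(sp)
        spans = {
            "SP": (1, n0),
            "NR": (n0 + 1, n0 + len(nr)),
            "RR": (n0 + len(nr) + 1, n0 + len(nr) + rr_len),
            "UR": (n0 + len(nr) + rr_len + 1, n0 + T),
        }
        truth = {
            "spans": spans,
            "cys": [spans["UR"][0] + p for p in cys],
            "signature_span": None,
        }
    elif type_ == "omega":
        if subtype == "omega5":
            prefix = OMEGA_NTERM["omega5"]
            motifs: tuple[str, ...] = ("FPQQQ", "QQIPQQ")
        else:
            choices = OMEGA_NTERM["omega12"]
            prefix = subtype if subtype in choices else str(rng.choice(list(choices)))
            motifs = ("PQQPFP",)
        nr = prefix + _no_edge_q(_limit_q_runs(_rand_seq(rng, int(rng.integers(4, 8)))))
        tail = _no_edge_q(_limit_q_runs(_rand_seq(rng, 8)))
        rr_len = T - len(nr) - len(tail)
        rr = _repeat_tract(rng, motifs, rr_len) + tail
        mature = nr + rr
        n0 = len(sp)
        spans = {
            "SP": (1, n0),
            "NR": (n0 + 1, n0 + len(nr)),
            "RR": (n0 + len(nr) + 1, n0 + T),
        }
        truth = {"spans": spans, "cys": [], "signature_span": None}
    else:
        raise ConfigError(f"unknown gliadin type {type_!r}")
    precursor = sp + mature
    if len(precursor) != len(sp) + T:
        raise ConfigError("skeleton length bookkeeping failed")
    return ProteinRecord(id=f"{type_}-skeleton", sequence=precursor), truth


# ---------------------------------------------------------------------------
# family divergence
# ---------------------------------------------------------------------------


def _protected_positions(truth: dict) -> set[int]:
    """0-based precursor positions that family mutation must not touch."""
    spans = truth["spans"]
    protected: set[int] = set()
    for label, (s, e) in spans.items():
        if label in ("SP", "NR") or label.startswith("PQR"):
            protected.update(range(s - 1, e))
        elif label.startswith("UR") or label == "RR":
            protected.update({s - 1, s, e - 2, e - 1})
    rr_s, _ = spans["RR"]
    protected.update(range(rr_s - 1, rr_s - 1 + 6))  # mature N-terminal label
    protected.update(p - 1 for p in truth["cys"])
    if truth.get("signature_span"):
        s, e = truth["signature_span"]
        protected.update(range(s - 1, e))
    return protected


def _shift_truth(truth: dict, pos0: int, delta: int) -> dict:
    """Shift all 1-based spans/positions strictly after 0-based ``pos0``."""
    spans = {}
    for label, (s, e) in truth["spans"].items():
        ns = s + delta if s - 1 > pos0 else s
        ne = e + delta if e - 1 >= pos0 else e
        spans[label] = (ns, ne)
    out = dict(truth)
    out["spans"] = spans
    out["cys"] = [p + delta if p - 1 > pos0 else p for p in truth["cys"]]
    if truth.get("signature_span"):
        s, e = truth["signature_span"]
        out["signature_span"] = (
            s + delta if s - 1 > pos0 else s,
            e + delta if e - 1 > pos0 else e,
        )
    return out


def _mutate_member(
    seq: str,
    truth: dict,
    rate: float,
    rng: np.random.Generator,
    allow_indels: bool = True,
) -> tuple[str, dict]:
    protected = _protected_positions(truth)
    mutable = [i for i in range(len(seq)) if i not in protected]
    k = int(round(rate * len(mutable)))
    out = list(seq)
    if k:
        for i in rng.choice(len(mutable), size=min(k, len(mutable)), replace=False):
            pos = mutable[int(i)]
            choices = [c for c in _SUB_ALPHABET if c != out[pos]]
            out[pos] = str(rng.choice(choices))
    new_truth = dict(truth)
    if allow_indels and rng.random() < 0.5:
        rr_s, rr_e = new_truth["spans"]["RR"]
        pos = int(rng.integers(rr_s + 8, rr_e - 12))  # 1-based, RR interior
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            ins = "".join(rng.choice(list("PFLSTIVA"), size=length))
            out[pos - 1 : pos - 1] = list(ins)
            new_truth = _shift_truth(new_truth, pos - 1, length)
        else:
            del out[pos - 1 : pos - 1 + length]
            new_truth = _shift_truth(new_truth, pos - 1, -length)
    return "".join(out), new_truth


def make_family(
    type_: str,
    n: int,
    identity_target: float,
    rng: np.random.Generator,
    skeleton: tuple[ProteinRecord, dict] | None = None,
    profile: TypeProfile | None = None,
    allow_indels: bool = True,
    tolerance: float = 2.0,
    max_iter: int = 8,
) -> list[tuple[ProteinRecord, dict]]:
    """n family members derived from one skeleton, calibrated so the mean
    pairwise identity lies within ±tolerance points of 100*identity_target.
    Conserved cysteines are never touched; target 1.0 yields exact duplicates."""
    if n < 2:
        raise ConfigError("a family needs n >= 2 members")
    if not 0.66 <= identity_target <= 1.0:
        raise ConfigError("identity_target must be in [0.66, 1.0]")
    if skeleton is None:
        profile = profile or profile_by_type(default_profiles(), type_)
        skeleton = make_skeleton(type_, profile, rng)
    base_seq, base_truth = skeleton[0].sequence, skeleton[1]
    if identity_target == 1.0:
        return [
            (ProteinRecord(id=f"{type_}-m{i+1}", sequence=base_seq), dict(base_truth))
            for i in range(n)
        ]
    rate = (1.0 - identity_target) / 1.6
    target_pct = 100.0 * identity_target
    for _ in range(max_iter):
        members = []
        for i in range(n):
            seq, truth = _mutate_member(base_seq, base_truth, rate, rng, allow_indels)
            members.append(
                (ProteinRecord(id=f"{type_}-m{i+1}", sequence=seq), truth)
            )
        idents = [
            pairwise_identity(members[i][0], members[j][0])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        mean_id = float(np.mean(idents))
        if abs(mean_id - target_pct) <= tolerance:
            return members
        gap_now = max(100.0 - mean_id, 0.05)
        rate = min(0.45, max(1e-4, rate * (100.0 - target_pct) / gap_now))
    raise ConfigError(
        f"could not calibrate family identity to {identity_target} "
        f"(last mean {mean_id:.1f})"
    )


# ---------------------------------------------------------------------------
# epitope planting
# ---------------------------------------------------------------------------

_33MER_COUNTS = {"DQ2.5-glia-a1a": 1, "DQ2.5-glia-a1b": 2, "DQ2.5-glia-a2": 3}


def _scrub(seq: list[str], cores: list[str], keep: set[int]) -> None:
    """Destroy every core occurrence not inside ``keep`` (0-based positions)
    by replacing its middle residue with S (S occurs in no panel core)."""
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for core in cores:
            start = s.find(core)
            while start != -1:
                span = set(range(start, start + len(core)))
                if not span <= keep:
                    seq[start + len(core) // 2] = "S"
                    changed = True
                    break
                start = s.find(core, start + 1)
            if changed:
                break


def plant_epitopes(
    seq: str,
    rr_span: tuple[int, int],
    plan: tuple[tuple[str, int], ...],
    panel: EpitopePanel,
    rng: np.random.Generator,
) -> tuple[str, dict[str, int]]:
    """Return the sequence with exactly the planned epitope copy counts.

    All incidental panel-core occurrences are scrubbed first; planned blocks
    are written into a contiguous window of the repetitive region, separated
    by single S residues so no new core can straddle a junction.
    """
    cores = {e.name: e.core for e in panel.epitopes}
    expected: dict[str, int] = {e.name: 0 for e in panel.epitopes}
    blocks: list[str] = []
    for name, copies in plan:
        if name == "33mer":
            for _ in range(copies):
                blocks.append(THIRTY_THREE_MER)
            for ep, c in _33MER_COUNTS.items():
                expected[ep] += c * copies
        else:
            blocks.extend([cores[name]] * copies)
            expected[name] += copies
    out = list(seq)
    if blocks:
        window = "S" + "S".join(blocks) + "S"
        rr_s, rr_e = rr_span[0] - 1, rr_span[1]  # to 0-based [s, e)
        margin = 12  # keep the repeat-region boundaries detectable
        room = (rr_e - margin) - (rr_s + margin) - len(window)
        if room < 0:
            raise ConfigError("repetitive region too short for the epitope plan")
        off = rr_s + margin + int(rng.integers(0, room + 1))
        keep = set(range(off, off + len(window)))
        out[off : off + len(window)] = list(window)
    else:
        keep = set()
    _scrub(out, list(cores.values()), keep)
    final = "".join(out)
    for name, core in cores.items():
        n = 0
        start = final.find(core)
        while start != -1:
            n += 1
            start = final.find(core, start + 1)
        if n != expected[name]:
            raise ConfigError(
                f"epitope planting failed for {name}: {n} != {expected[name]}"
            )
    return final, expected


def embed_epitopes(
    protein: ProteinRecord,
    epitope: Epitope,
    copies: int,
    rng: np.random.Generator,
    rr_span: tuple[int, int],
) -> ProteinRecord:
    """Mutate a protein so that exactly ``copies`` non-overlapping occurrences
    of one epitope core exist (incidental occurrences are destroyed first)."""
    if copies < 0:
        raise ConfigError("copies must be >= 0")
    panel = EpitopePanel(epitopes=[epitope])
    plan = ((epitope.name, copies),) if copies else ()
    seq, _ = plant_epitopes(protein.sequence, rr_span, plan, panel, rng)
    return replace(protein, sequence=seq)


# ---------------------------------------------------------------------------
# reverse translation and pseudogenization
# ---------------------------------------------------------------------------


def reverse_translate(protein_seq: str, rng: np.random.Generator) -> str:
    """Flat-codon-table reverse translation with junction-safe codon choices
    (no internal ATG can form across codon boundaries)."""
    codons: list[str] = []
    for i, aa in enumerate(protein_seq):
        nxt = protein_seq[i + 1] if i + 1 < len(protein_seq) else ""
        if aa == "L" and nxt == "T":
            codons.append("TTA")  # TTA+ACx puts TAA in the +1 register
            continue
        if aa == "T" and nxt == "S":
            codons.append("ACT")  # ACT+AGC puts TAG in the -1 register
            continue
        if aa == "S" and codons and codons[-1].endswith("T"):
            codons.append("AGC")
            continue
        options = _CODONS[aa]
        if nxt == "C":
            options = tuple(c for c in options if not c.endswith("A")) or options
        codons.append(str(rng.choice(list(options))))
    return "".join(codons)


def transcript_from_protein(
    gene_id: str, protein_seq: str, rng: np.random.Generator, meta: dict | None = None
) -> TranscriptRecord:
    cds = reverse_translate(protein_seq, rng) + "TAA"
    return TranscriptRecord(
        id=gene_id, sequence=UTR5 + cds + UTR3, meta=dict(meta or {})
    )


def _longest_orf_mature_len(transcript: TranscriptRecord, sp_len: int = 20) -> int:
    orfs = find_orfs(transcript, 1)
    return (len(orfs[0].protein) - sp_len) if orfs else -1


def pseudogenize(
    transcript: TranscriptRecord,
    mode: str | None,
    rng: np.random.Generator,
    band_min_aa: int | None = None,
    max_tries: int = 200,
) -> TranscriptRecord:
    """Disrupt a coding sequence with a premature stop codon or a 1-nt
    frameshift placed in the first half of the CDS, retrying positions until
    the defect is manifest (the longest remaining ORF falls below the
    mature-length band and no spurious ATG was created)."""
    if mode is None:
        return transcript
    if mode not in ("premature_stop", "frameshift"):
        raise ConfigError(f"unknown pseudogenization mode {mode!r}")
    if band_min_aa is None:
        band_min_aa = generic_profile().mature_length_band[0]
    seq = transcript.sequence
    cds_start = seq.find("ATG")
    if cds_start < 0:
        raise ConfigError("transcript has no start codon")
    stop = cds_start
    while seq[stop : stop + 3] not in STOP_CODONS:
        stop += 3
    n_codons = (stop - cds_start) // 3
    n_atg = seq.count("ATG")
    for _ in range(max_tries):
        k = int(rng.integers(max(10, n_codons // 4), n_codons // 2))
        if mode == "premature_stop":
            pos = cds_start + 3 * k
            mutant = seq[:pos] + "TAA" + seq[pos + 3 :]
        else:
            pos = cds_start + 3 * k + int(rng.integers(0, 3))
            if rng.random() < 0.5:
                mutant = seq[:pos] + seq[pos + 1 :]  # 1-nt deletion
            else:
                nt = str(rng.choice(["C", "T"]))
                mutant = seq[:pos] + nt + seq[pos:]  # 1-nt insertion
        rec = TranscriptRecord(
            id=transcript.id, sequence=mutant, meta=dict(transcript.meta)
        )
        if rec.sequence.count("ATG") > n_atg:
            continue  # a junction ATG appeared; try elsewhere
        if 0 <= _longest_orf_mature_len(rec) < band_min_aa:
            return rec
    raise ConfigError(
        f"could not pseudogenize {transcript.id!r} with mode {mode!r}"
    )


# ---------------------------------------------------------------------------
# spot simulation, deletion-line matrix, expression counts
# ---------------------------------------------------------------------------


def simulate_spots(
    db: dict[str, ProteinRecord],
    enzymes: tuple[Enzyme, ...],
    params: DigestParams,
    detection_prob: float,
    contaminant_rate: float,
    rng: np.random.Generator,
    spots_per_protein: dict[str, int] | None = None,
) -> tuple[list[SpotObservation], dict[str, str]]:
    """Simulated 2-DE spot observations (one per enzyme per spot) plus the
    spot -> generating-protein truth map.

    Each spot samples the generating protein's theoretical peptides with
    Bernoulli(detection_prob), per enzyme, and adds Poisson(contaminant_rate)
    peptides drawn from the digests of other proteins.
    """
    ids = sorted(db)
    theoretical = {
        pid: {
            enz.name: sorted({p.sequence for p in digest(db[pid], enz, params)})
            for enz in enzymes
        }
        for pid in ids
    }
    observations: list[SpotObservation] = []
    truth: dict[str, str] = {}
    counter = 0
    for pid in ids:
        n_spots = (spots_per_protein or {}).get(pid, 1)
        for _ in range(n_spots):
            counter += 1
            spot_id = f"spot-{counter:03d}"
            truth[spot_id] = pid
            for enz in enzymes:
                peps = [
                    p
                    for p in theoretical[pid][enz.name]
                    if rng.random() < detection_prob
                ]
                n_contam = int(rng.poisson(contaminant_rate))
                for _ in range(n_contam):
                    others = [o for o in ids if o != pid]
                    if not others:
                        break
                    other = str(rng.choice(others))
                    pool = theoretical[other][enz.name]
                    if pool:
                        peps.append(str(rng.choice(pool)))
                observations.append(SpotObservation(spot_id, enz.name, sorted(set(peps))))
    return observations, truth


DELETION_LINES = {
    "DLGliA1": "Gli-A1",
    "DLGliB1": "Gli-B1",
    "DLGliD1": "Gli-D1",
    "DLGliA2": "Gli-A2",
    "DLGliB2": "Gli-B2",
    "DLGliD2": "Gli-D2",
}
WILD_TYPE_LINE = "XY81"


def build_matrix(
    gene_locus: dict[str, str],
    spot_truth: dict[str, str],
    rng: np.random.Generator,
    mixture_spots: dict[str, tuple[str, str]] | None = None,
) -> SpotPresenceMatrix:
    """Deletion-line presence/absence matrix: every spot is present in the
    wild type and absent only in the line lacking its generating gene's locus.
    Mixture spots (two generating genes from different loci) are absent in two
    lines and flagged."""
    lines = [WILD_TYPE_LINE] + list(DELETION_LINES)
    line_locus: dict[str, str | None] = {WILD_TYPE_LINE: None, **DELETION_LINES}
    rows = {}
    for spot_id in sorted(spot_truth):
        locus = gene_locus[spot_truth[spot_id]]
        rows[spot_id] = {
            line: (line_locus[line] is None or line_locus[line] != locus)
            for line in lines
        }
    mixture_spots = mixture_spots or {}
    for spot_id, (gene_a, gene_b) in sorted(mixture_spots.items()):
        loci = {gene_locus[gene_a], gene_locus[gene_b]}
        rows[spot_id] = {
            line: (line_locus[line] is None or line_locus[line] not in loci)
            for line in lines
        }
    present = pd.DataFrame.from_dict(rows, orient="index")[lines]
    return SpotPresenceMatrix(
        present=present,
        line_locus=line_locus,
        mixture_spots=set(mixture_spots),
    )


def simulate_expression(
    gene_ids: list[str],
    gene_types: dict[str, str],
    transcript_lengths: dict[str, int],
    timepoints: tuple[int, ...],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Developmental read-count table (gene, timepoint, count, length,
    library_total) with storage-protein-like upregulation across grain
    development; gamma genes transcribe highest, omega lowest."""
    base_by_type = {"alpha": 120.0, "gamma": 260.0, "delta": 60.0, "omega": 40.0}
    mult = {t: m for t, m in zip(timepoints, (0.05, 0.6, 2.5, 8.0))}
    rows = []
    for gid in gene_ids:
        base = base_by_type.get(gene_types[gid], 50.0) * float(rng.uniform(0.6, 1.5))
        for t in timepoints:
            library = int(1_000_000 * float(rng.uniform(0.9, 1.1)))
            count = int(round(base * mult[t] * float(rng.uniform(0.92, 1.08))))
            rows.append(
                {
                    "gene": gid,
                    "timepoint": t,
                    "count": count,
                    "length": transcript_lengths[gid],
                    "library_total": library,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCorpus:
    config: GeneratorConfig
    transcripts: list[TranscriptRecord]
    proteins: dict[str, ProteinRecord]  # active precursors by gene id
    domain_truth: dict[str, DomainMap]
    truth: pd.DataFrame
    panel: EpitopePanel
    spot_observations: list[SpotObservation]
    spot_truth: dict[str, str]
    matrix: SpotPresenceMatrix
    pcr: dict[str, PcrEvidence]
    expression: pd.DataFrame

    @property
    def active_gene_ids(self) -> list[str]:
        return list(self.truth.loc[self.truth.status == "active", "gene_id"])

    def gene_locus(self) -> dict[str, str]:
        return dict(zip(self.truth.gene_id, self.truth.locus))

    def write(self, outdir) -> None:
        from . import io as gio

        gio.write_corpus(self, outdir)


def _truth_to_domain_map(truth: dict, length: int) -> DomainMap:
    order = {"SP": 0, "NR": 1, "RR": 2, "PQR": 3, "PQR1": 3, "UR1": 4,
             "PQR2": 5, "UR2": 6, "UR": 4}
    segs = sorted(truth["spans"].items(), key=lambda kv: kv[1][0])
    return DomainMap(segments=[(lab, s, e) for lab, (s, e) in segs])


def make_corpus(config: GeneratorConfig | None = None) -> SyntheticCorpus:
    """Generate the full labeled corpus for one seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    profiles = default_profiles()
    panel = default_panel()
    members = config.composition

    # --- group active members into per-(type, locus) families -------------
    families: dict[tuple[str, str], list[MemberSpec]] = {}
    for spec in members:
        if spec.status == "active":
            families.setdefault((spec.type, spec.locus), []).append(spec)

    proteins: dict[str, ProteinRecord] = {}
    domain_truth: dict[str, DomainMap] = {}
    member_truth: dict[str, dict] = {}
    epitope_totals: dict[str, int] = {}

    # one ancestral skeleton per type, then per-locus families
    type_skeletons: dict[str, tuple[ProteinRecord, dict]] = {}
    for type_ in ("alpha", "gamma", "delta"):
        if any(k[0] == type_ for k in families):
            profile = profile_by_type(profiles, type_)
            type_skeletons[type_] = make_skeleton(type_, profile, rng)

    for (type_, locus) in sorted(families):
        specs = sorted(families[(type_, locus)], key=lambda s: s.gene_id)
        profile = profile_by_type(profiles, type_)
        if type_ == "omega":
            # omega subtypes differ in N-terminus and repeats: one skeleton each
            drafts = []
            for spec in specs:
                skel, truth = make_skeleton(type_, profile, rng, subtype=spec.subtype)
                drafts.append((skel, truth))
        else:
            ancestor_seq, ancestor_truth = type_skeletons[type_]
            anc_seq, anc_truth = _mutate_member(
                ancestor_seq.sequence, ancestor_truth, 0.035, rng, allow_indels=False
            )
            anc = (ProteinRecord(id=f"{type_}-{locus}", sequence=anc_seq), anc_truth)
            if len(specs) == 1:
                drafts = [anc]
            else:
                target = config.family_identity.get(type_, 0.9)
                drafts = make_family(
                    type_, len(specs), target, rng, skeleton=anc
                )
        for spec, (draft, truth) in zip(specs, drafts):
            if spec.duplicate_of and spec.duplicate_of in proteins:
                # a 100%-identical paralog pair (same coding product from two
                # genes); downstream matching must group them
                src = spec.duplicate_of
                proteins[spec.gene_id] = ProteinRecord(
                    id=spec.gene_id, sequence=proteins[src].sequence
                )
                domain_truth[spec.gene_id] = domain_truth[src]
                member_truth[spec.gene_id] = member_truth[src]
                epitope_totals[spec.gene_id] = epitope_totals[src]
                continue
            seq, truth = draft.sequence, dict(truth)
            # subtype tail signature (alpha only)
            if type_ == "alpha":
                s, e = truth["signature_span"]
                sig = CT_SIGNATURE if spec.subtype == "CT" else CSTT_SIGNATURE
                seq = seq[: s - 1] + sig + seq[e:]
            # epitope plan
            rr_span = truth["spans"]["RR"]
            seq, expected = plant_epitopes(seq, rr_span, spec.epitope_plan, panel, rng)
            # extra cysteines in the repetitive region, never inside a
            # planted epitope occurrence
            cores = [e.core for e in panel.epitopes]

            def _core_count(s: str) -> int:
                return sum(s.count(c) for c in cores)

            for _ in range(spec.extra_cys):
                rr_s, rr_e = truth["spans"]["RR"]
                before = _core_count(seq)
                while True:
                    pos = int(rng.integers(rr_s + 8, rr_e - 8))
                    window = seq[pos - 10 : pos + 10]
                    if "C" in window:
                        continue
                    cand = seq[: pos - 1] + "C" + seq[pos:]
                    if _core_count(cand) == before:
                        break
                seq = cand
            proteins[spec.gene_id] = ProteinRecord(
                id=spec.gene_id, sequence=seq, form="precursor"
            )
            domain_truth[spec.gene_id] = _truth_to_domain_map(truth, len(seq))
            member_truth[spec.gene_id] = truth
            epitope_totals[spec.gene_id] = sum(expected.values())

    # --- transcripts -------------------------------------------------------
    transcripts: list[TranscriptRecord] = []
    pseudo_modes: dict[str, str] = {}
    for spec in members:
        if spec.status == "active":
            tr = transcript_from_protein(
                spec.gene_id, proteins[spec.gene_id].sequence, rng
            )
        else:
            profile = profile_by_type(profiles, spec.type)
            skel, _ = make_skeleton(spec.type, profile, rng, subtype=spec.subtype)
            tr = transcript_from_protein(spec.gene_id, skel.sequence, rng)
            tr = pseudogenize(tr, spec.defect_mode, rng)
            pseudo_modes[spec.gene_id] = spec.defect_mode or "none"
        transcripts.append(tr)

    # --- spots, matrix, PCR ------------------------------------------------
    accumulated = {s.gene_id for s in members if s.accumulated}
    acc_db = {gid: proteins[gid] for gid in sorted(accumulated)}
    params = DigestParams()
    spots_per = {
        gid: int(
            rng.choice(
                list(config.spots_per_protein), p=list(config.spots_per_protein_weights)
            )
        )
        for gid in sorted(acc_db)
    }
    observations, spot_truth = simulate_spots(
        acc_db,
        DEFAULT_ENZYMES,
        params,
        config.detection_prob,
        config.contaminant_rate,
        rng,
        spots_per_protein=spots_per,
    )
    gene_locus = {s.gene_id: s.locus for s in members}
    mixtures: dict[str, tuple[str, str]] = {}
    if config.n_mixture_spots and len(acc_db) >= 2:
        acc_ids = sorted(acc_db)
        for i in range(config.n_mixture_spots):
            while True:
                a, b = rng.choice(acc_ids, size=2, replace=False)
                if gene_locus[str(a)] != gene_locus[str(b)]:
                    break
            mixtures[f"spot-mix{i+1}"] = (str(a), str(b))
    matrix = build_matrix(gene_locus, spot_truth, rng, mixture_spots=mixtures)

    pcr: dict[str, PcrEvidence] = {}
    for spec in members:
        if spec.pcr and spec.status == "active":
            present = {WILD_TYPE_LINE: True}
            for line, locus in DELETION_LINES.items():
                present[line] = locus != spec.locus
            pcr[spec.gene_id] = PcrEvidence(gene_id=spec.gene_id, present=present)

    # --- expression --------------------------------------------------------
    active_ids = [s.gene_id for s in members if s.status == "active"]
    tr_len = {t.id: len(t.sequence) for t in transcripts}
    expression = simulate_expression(
        active_ids,
        {s.gene_id: s.type for s in members},
        tr_len,
        config.timepoints_daf,
        rng,
    )

    # --- truth table --------------------------------------------------------
    rows = []
    spots_by_gene: dict[str, list[str]] = {}
    for spot, gid in spot_truth.items():
        spots_by_gene.setdefault(gid, []).append(spot)
    for spec in members:
        active = spec.status == "active"
        rows.append(
            {
                "gene_id": spec.gene_id,
                "type": spec.type,
                "subtype": spec.subtype if active else "none",
                "locus": spec.locus,
                "status": spec.status,
                "defect": "none" if active else pseudo_modes[spec.gene_id],
                "accumulated": spec.accumulated,
                "extra_cys": spec.extra_cys,
                "mature_length": (
                    len(proteins[spec.gene_id]) - 20 if active else 0
                ),
                "mature_mass_da": (
                    round(peptide_mass(proteins[spec.gene_id].sequence[20:]), 2)
                    if active
                    else 0.0
                ),
                "epitope_total": epitope_totals.get(spec.gene_id, 0),
                "spots": ",".join(sorted(spots_by_gene.get(spec.gene_id, []))),
            }
        )
    truth = pd.DataFrame(rows)

    return SyntheticCorpus(
        config=config,
        transcripts=transcripts,
        proteins=proteins,
        domain_truth=domain_truth,
        truth=truth,
        panel=panel,
        spot_observations=observations,
        spot_truth=spot_truth,
        matrix=matrix,
        pcr=pcr,
        expression=expression,
    )
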