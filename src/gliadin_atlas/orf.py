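"""ORF finding and active/pseudogene assessment of oriented transcripts.

Only forward-strand ORFs are considered: full-length non-chimeric transcript
reads are already oriented. An ORF is an ATG followed by an in-frame stop
within the transcript; the translated protein excludes the stop.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .errors import InputError
from .profiles import TypeProfile
from .records import CodingStatus, ProteinRecord, TranscriptRecord

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
CODON_TO_AA = dict(standard_dna_table.forward_table)


def translate_codons(seq: str, start: int) -> str:
    """Translate from 0-based ``start`` until a stop codon or sequence end.

    Codons containing N (or any non-AA codon other than a stop) become 'X'-free:
    they terminate the walk, which is the conservative choice for noisy reads.
    """
    out = []
    for i in range(start, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            break
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            break
        out.append(aa)
    return "".join(out)


@dataclass
class Orf:
    frame: int  # 0, 1 or 2
    span: tuple[int, int]  # 1-based inclusive, ATG..stop (stop included)
    protein: ProteinRecord


def find_orfs(transcript: TranscriptRecord, min_orf_aa: int) -> list[Orf]:
    """All forward-strand complete ORFs of length >= ``min_orf_aa`` amino
    acids, longest first (ties by start position).

    Every ATG opens a candidate, including ATGs nested inside a longer ORF.
    """
    if min_orf_aa < 1:
        raise InputError("min_orf_aa must be >= 1")
    seq = transcript.sequence
    # first in-frame stop at or after each position, per frame
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    orfs: list[Orf] = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        stop = next((s for s in stops_by_frame[i % 3] if s >= i + 3), None)
        if stop is None:
            continue
        aa_len = (stop - i) // 3
        if aa_len < min_orf_aa:
            continue
        protein = ProteinRecord(
            id=f"{transcript.id}|orf{i + 1}",
            sequence=translate_codons(seq, i),
            form="precursor",
        )
        if len(protein) != aa_len:  # N-containing codon interrupted translation
            continue
        orfs.append(Orf(frame=i % 3, span=(i + 1, stop + 3), protein=protein))
    orfs.sort(key=lambda o: (-len(o.protein.sequence), o.span[0]))
    return orfs


def _stop_free_runs(seq: str, frame: int) -> list[tuple[int, int]]:
    """Maximal stop-free codon runs in a frame, as 0-based [start, end) nt spans."""
    runs = []
    start = frame
    i = frame
    while i + 3 <= len(seq):
        if seq[i : i + 3] in STOP_CODONS:
            if i > start:
                runs.append((start, i))
            start = i + 3
        i += 3
    if i > start:
        runs.append((start, i))
    return runs


def _qp_fraction(seq: str, start: int, end: int) -> float:
    """Q+P fraction of the translation of seq[start:end) in its own frame."""
    aa = []
    for i in range(start, end - 2, 3):
        aa.append(CODON_TO_AA.get(seq[i : i + 3], "X"))
    if not aa:
        return 0.0
    return sum(1 for a in aa if a in "QP") / len(aa)


def assess_coding_status(
    transcript: TranscriptRecord,
    profile: TypeProfile,
    min_orf_aa: int = 50,
) -> CodingStatus:
    """Decide whether a transcript carries an intact gliadin coding sequence.

    active: the longest ORF is >= ``min_orf_aa`` and its mature length
    (ORF protein minus signal peptide) falls in the profile's band.

    Otherwise the transcript is a pseudogene. The defect class is decided from
    the earliest-ATG candidate ORF (the presumed original CDS start):

    * no qualifying stop-free continuation past the truncation -> premature_stop
      (or no_orf when no ORF exists at all);
    * among stop-free runs that cover the truncation point and would restore a
      band-length product, the one whose translation is most Q/P-rich
      (i.e. still reads like a gliadin) identifies the intact reading register:
      same frame as the candidate ORF -> premature_stop (a single in-frame stop
      interrupts an otherwise intact frame), shifted frame -> frameshift.
    """
    seq = transcript.sequence
    all_orfs = find_orfs(transcript, 1)
    if not all_orfs:
        return CodingStatus(status="pseudogene", defect="no_orf", orf_span=None)
    longest = all_orfs[0]
    span = longest.span if len(longest.protein) >= min_orf_aa else None
    lo, hi = profile.mature_length_band
    mature_len = len(longest.protein) - profile.signal_peptide_len
    if len(longest.protein) >= min_orf_aa and lo <= mature_len <= hi:
        return CodingStatus(status="active", defect="none", orf_span=longest.span)

    # candidate original CDS: earliest ATG (ties: longest)
    cand = min(all_orfs, key=lambda o: (o.span[0], -len(o.protein.sequence)))
    s0 = cand.span[0] - 1  # 0-based ATG
    trunc = cand.span[1]  # 0-based index just past the stop codon
    need_nt = 3 * (lo + profile.signal_peptide_len)

    best = None  # (qp_fraction, -run_end, frame)
    for frame in range(3):
        for rs, re in _stop_free_runs(seq, frame):
            if re <= trunc or rs > trunc:
                continue  # must reach the truncation point and extend past it
            if re - s0 < need_nt:
                continue  # could not restore a band-length product
            start = rs
            while start < s0:  # align to the run's frame, at or after the ATG
                start += 3
            qp = _qp_fraction(seq, start, re)
            key = (qp, -re)
            if best is None or key > (best[0], best[1]):
                best = (qp, -re, frame)
    if best is None:
        return CodingStatus(status="pseudogene", defect="premature_stop", orf_span=span)
    defect = "premature_stop" if best[2] == s0 % 3 else "frameshift"
    return CodingStatus(status="pseudogene", defect=defect, orf_span=span)
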