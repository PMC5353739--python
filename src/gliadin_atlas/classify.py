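"""Gliadin type classification, domain segmentation, cysteine accounting and
subtype calls.

The type score combines three lines of evidence, with the conserved-cysteine
count carrying the most weight (the type definitions themselves hinge on it):

    score = 0.50 * 1/(1+|cys_obs - cys_expected|)
          + 0.35 * repeat-motif coverage of the candidate repetitive region
          + 0.15 * mature N-terminus prefix match

A protein whose best score falls below ``score_min`` is returned as
type=unknown (HMW/LMW glutenin subunits and other non-gliadins pass through
this way).
"""
from __future__ import annotations

from .errors import ConfigError, SegmentationError, SubtypeError
from .profiles import TypeProfile
from .records import DomainMap, ProteinRecord

SCORE_MIN_DEFAULT = 0.5
_W_CYS, _W_MOTIF, _W_NTERM = 0.50, 0.35, 0.15


def motif_hits(
    seq: str, motifs: tuple[str, ...], max_mismatch: int = 0
) -> list[tuple[int, int]]:
    """0-based [start, end) spans of every (overlapping) motif occurrence,
    optionally tolerating up to ``max_mismatch`` substitutions per window
    (prolamin repeats are degenerate; a one-mismatch tolerance keeps the
    repeat region detectable in diverged homoeologs)."""
    spans = []
    if max_mismatch == 0:
        for motif in motifs:
            start = seq.find(motif)
            while start != -1:
                spans.append((start, start + len(motif)))
                start = seq.find(motif, start + 1)
    else:
        for motif in motifs:
            m = len(motif)
            for start in range(len(seq) - m + 1):
                mism = 0
                for a, b in zip(seq[start : start + m], motif):
                    if a != b:
                        mism += 1
                        if mism > max_mismatch:
                            break
                if mism <= max_mismatch:
                    spans.append((start, start + m))
    spans.sort()
    return spans


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def hit_cluster(
    spans: list[tuple[int, int]], max_gap: int = 60
) -> list[tuple[int, int]]:
    """Merged hit spans of the largest cluster (hits separated by <= max_gap),
    i.e. the candidate repetitive region; isolated stray hits elsewhere in the
    protein are ignored. The gap tolerance is wide enough to bridge epitope
    blocks embedded inside the repeats."""
    if not spans:
        return []
    merged = _merge_spans(spans)
    clusters: list[list[tuple[int, int]]] = [[merged[0]]]
    for s, e in merged[1:]:
        if s - clusters[-1][-1][1] <= max_gap:
            clusters[-1].append((s, e))
        else:
            clusters.append([(s, e)])
    return max(clusters, key=lambda c: c[-1][1] - c[0][0])


_DENSITY_SPAN_FLOOR = 30  # aa: a real repetitive region is at least this long


def motif_density(
    seq: str, motifs: tuple[str, ...], max_mismatch: int = 1
) -> float:
    """Motif coverage of the candidate repetitive region (largest hit
    cluster); the denominator is floored so isolated hits score low."""
    cluster = hit_cluster(motif_hits(seq, motifs, max_mismatch))
    if not cluster:
        return 0.0
    covered = sum(e - s for s, e in cluster)
    span = cluster[-1][1] - cluster[0][0]
    return covered / max(span, _DENSITY_SPAN_FLOOR)


def classify_type(
    protein: ProteinRecord,
    profiles: list[TypeProfile],
    score_min: float = SCORE_MIN_DEFAULT,
) -> tuple[str, float]:
    """Best-scoring gliadin type for a protein, or ("unknown", best_score)."""
    if not profiles:
        raise ConfigError("classify_type needs at least one profile")
    best_type, best_score, best_dens = "unknown", -1.0, 0.0
    for profile in profiles:
        mature = protein.mature_sequence(profile.signal_peptide_len)
        cys_term = 1.0 / (1.0 + abs(mature.count("C") - profile.expected_conserved_cys))
        dens = motif_density(mature, profile.repeat_motifs)
        nterm = 1.0 if mature.startswith(tuple(profile.nterm_prefixes)) else 0.0
        score = _W_CYS * cys_term + _W_MOTIF * dens + _W_NTERM * nterm
        if score > best_score:
            best_type, best_score, best_dens = profile.type, score, dens
    # a protein with no detectable repeat region is not a gliadin at all
    if best_score < score_min or best_dens == 0.0:
        return "unknown", best_score
    return best_type, best_score


def _q_runs(seq: str, q_run_min: float, q_window: int) -> list[tuple[int, int]]:
    """Maximal polyglutamine runs as 0-based [start, end) spans.

    Pure Q runs are found first; adjacent runs separated by a single non-Q
    residue are merged when the merged stretch keeps Q frequency >= q_run_min.
    Runs shorter than q_window are dropped.
    """
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "Q":
            j = i
            while j < len(seq) and seq[j] == "Q":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= 1:
            ms, me = merged[-1][0], e
            q_frac = sum(1 for c in seq[ms:me] if c == "Q") / (me - ms)
            if q_frac >= q_run_min:
                merged[-1] = (ms, me)
                continue
        merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= q_window]


def _split_unique_region(seq: str, start: int, end: int) -> int:
    """Split point (0-based, in [start, end]) between two unique regions:
    the midpoint of the largest gap between consecutive cysteines."""
    cys = [i for i in range(start, end) if seq[i] == "C"]
    if len(cys) < 2:
        raise SegmentationError("cannot split unique regions: fewer than 2 cysteines")
    best_gap, split = -1, None
    for a, b in zip(cys, cys[1:]):
        if b - a > best_gap:
            best_gap, split = b - a, (a + b + 1) // 2
    return split


def segment_domains(protein: ProteinRecord, profile: TypeProfile) -> DomainMap:
    """Full-coverage segmentation of a precursor according to the profile's
    domain grammar. 1-based inclusive coordinates on the precursor."""
    if protein.form != "precursor":
        raise SegmentationError("segmentation operates on precursor sequences")
    seq = protein.sequence
    sp = profile.signal_peptide_len
    if len(seq) <= sp + profile.q_window:
        raise SegmentationError("protein shorter than its signal peptide")
    mature = seq[sp:]
    hits = motif_hits(mature, profile.repeat_motifs, max_mismatch=1)
    if not hits:
        raise SegmentationError(
            f"no repeat motif of type {profile.type!r} found in {protein.id!r}"
        )
    rr_first = sp + hits[0][0]  # 0-based precursor coords
    rr_last = sp + max(e for _, e in hits)  # exclusive
    L = len(seq)
    grammar = profile.domain_grammar
    segs: list[tuple[str, int, int]] = [("SP", 1, sp)]

    def q_runs_after(pos0: int) -> list[tuple[int, int]]:
        # a run may begin inside the last repeat motif (repeats often end in
        # Q); clip it at pos0 rather than discarding it
        out = []
        for s, e in _q_runs(mature, profile.q_run_min, profile.q_window):
            s, e = sp + s, sp + e
            if e > pos0 and e - max(s, pos0) >= profile.q_window:
                out.append((max(s, pos0), e))
        return out

    if grammar == ("SP", "RR", "PQR1", "UR1", "PQR2", "UR2"):
        qruns = q_runs_after(rr_first)
        if len(qruns) < 2:
            raise SegmentationError(
                f"alpha grammar needs two polyglutamine runs after the repeats "
                f"({len(qruns)} found in {protein.id!r})"
            )
        (q1s, q1e), (q2s, q2e) = qruns[0], qruns[1]
        segs += [
            ("RR", sp + 1, q1s),
            ("PQR1", q1s + 1, q1e),
            ("UR1", q1e + 1, q2s),
            ("PQR2", q2s + 1, q2e),
            ("UR2", q2e + 1, L),
        ]
    elif grammar == ("SP", "NR", "RR", "PQR", "UR1", "UR2"):
        if rr_first <= sp:
            raise SegmentationError("gamma grammar needs a short N-terminal region")
        qruns = q_runs_after(rr_first)
        if not qruns:
            raise SegmentationError("gamma grammar needs a polyglutamine run")
        q1s, q1e = qruns[0]
        split = _split_unique_region(seq, q1e, L)
        segs += [
            ("NR", sp + 1, rr_first),
            ("RR", rr_first + 1, q1s),
            ("PQR", q1s + 1, q1e),
            ("UR1", q1e + 1, split),
            ("UR2", split + 1, L),
        ]
    elif grammar == ("SP", "NR", "RR", "UR"):
        if rr_first <= sp:
            raise SegmentationError("delta grammar needs a short N-terminal region")
        segs += [
            ("NR", sp + 1, rr_first),
            ("RR", rr_first + 1, rr_last),
            ("UR", rr_last + 1, L),
        ]
    elif grammar == ("SP", "NR", "RR"):
        if rr_first <= sp:
            raise SegmentationError("omega grammar needs a short N-terminal region")
        segs += [("NR", sp + 1, rr_first), ("RR", rr_first + 1, L)]
    else:
        raise ConfigError(f"unsupported domain grammar {grammar!r}")

    for label, s, e in segs:
        if e < s:
            raise SegmentationError(
                f"grammar collapsed: segment {label!r} is empty in {protein.id!r}"
            )
    return DomainMap(segments=segs)


def count_cysteines(
    protein: ProteinRecord, profile: TypeProfile, domains: DomainMap
) -> tuple[int, int, list[int]]:
    """(cys_total, cys_conserved, extra positions) on the mature chain.

    Cysteines inside the profile's conserved domains count as conserved, up to
    the expected number; all others are extras (1-based precursor positions).
    """
    seq = protein.sequence
    sp = profile.signal_peptide_len if protein.form == "precursor" else 0
    positions = [i + 1 for i in range(sp, len(seq)) if seq[i] == "C"]
    conserved = 0
    extras: list[int] = []
    for pos in positions:
        label = domains.label_at(pos) if protein.form == "precursor" else None
        in_conserved = label in profile.conserved_cys_domains
        if in_conserved and conserved < profile.expected_conserved_cys:
            conserved += 1
        else:
            extras.append(pos)
    return len(positions), conserved, extras


def subtype_alpha(
    protein: ProteinRecord, domains: DomainMap, profile: TypeProfile
) -> str:
    """CT or CSTT, from the sequence downstream of the last conserved cysteine."""
    rules = profile.subtype_rules
    if set(rules) != {"CT", "CSTT"}:
        raise ConfigError("alpha subtype_rules must define CT and CSTT patterns")
    seq = protein.sequence
    conserved = [
        i + 1
        for i in range(len(seq))
        if seq[i] == "C" and domains.label_at(i + 1) in profile.conserved_cys_domains
    ][: profile.expected_conserved_cys]
    if not conserved:
        raise SubtypeError(f"{protein.id!r}: no conserved cysteine; subtype undeterminable")
    tail = seq[conserved[-1]:]
    scores = {
        name: len(motif_hits(tail, (pattern,))) for name, pattern in rules.items()
    }
    if scores["CT"] == scores["CSTT"]:
        raise SubtypeError(
            f"{protein.id!r}: CT/CSTT discriminators tie ({scores['CT']} hits each)"
        )
    return max(scores, key=scores.get)  # type: ignore[arg-type]


OMEGA5_STARTS = ("SRL",)
OMEGA12_STARTS = ("ARE", "ARQ", "KEL")
_OMEGA5_MOTIFS = ("FPQQQ", "QQIPQQ")
_OMEGA12_MOTIF = "PQQPFP"


def subtype_omega(protein: ProteinRecord, signal_peptide_len: int = 20) -> tuple[str, str]:
    """(omega5 | omega12, 4-residue N-terminal label) for an omega-gliadin.

    omega5: N-terminus SRL... with FPQQQ or QQIPQQ repeats; omega12: N-terminus
    ARE/ARQ/KEL with PQQPFP repeats. When neither start rule fires, motif
    evidence dominates (e.g. a novel ARPL start with PQQPFP repeats is still an
    omega1,2-gliadin).
    """
    mature = protein.mature_sequence(signal_peptide_len)
    has5 = any(m in mature for m in _OMEGA5_MOTIFS)
    has12 = _OMEGA12_MOTIF in mature
    label = mature[:4]
    if mature.startswith(OMEGA5_STARTS) and has5:
        return "omega5", label
    if mature.startswith(OMEGA12_STARTS) and has12:
        return "omega12", label
    if has12 and not has5:
        return "omega12", label
    if has5 and not has12:
        return "omega5", label
    raise SubtypeError(f"{protein.id!r}: no omega subtype rule fires")
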