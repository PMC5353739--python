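"""End-to-end orchestration: transcripts -> annotations -> spot matches ->
locus assignments -> epitope summaries, plus the run manifest.

Each stage is a thin composition of the per-module operations so that scripts,
the CLI and the tests all run the same code path.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    classify_type,
    count_cysteines,
    segment_domains,
    subtype_alpha,
    subtype_omega,
)
from .digest import DEFAULT_ENZYMES, DigestParams, build_peptide_index
from .epitopes import EpitopePanel, EpitopeSummary, scan, summarize
from .errors import SegmentationError, SubtypeError
from .loci import (
    GeneAssignment,
    PcrEvidence,
    SpotAssignment,
    SpotPresenceMatrix,
    assign_all_spots,
    assign_gene,
)
from .masses import peptide_mass
from .match import MatchResult, SpotObservation, equivalence_groups, match_spot
from .orf import assess_coding_status, find_orfs
from .profiles import TypeProfile, default_profiles, generic_profile, profile_by_type
from .records import CodingStatus, ProteinRecord, TranscriptRecord

log = logging.getLogger("gliadin_atlas")


def assess_transcript(
    transcript: TranscriptRecord,
    profiles: list[TypeProfile] | None = None,
    min_orf_aa: int = 50,
) -> CodingStatus:
    """Coding status without knowing the gliadin type: a transcript is active
    if its longest ORF fits any type's mature-length band; defect classes are
    taken from the type-agnostic band spanning all types."""
    profiles = profiles or default_profiles()
    for profile in profiles:
        status = assess_coding_status(transcript, profile, min_orf_aa)
        if status.status == "active":
            return status
    return assess_coding_status(transcript, generic_profile(profiles), min_orf_aa)


def annotate_transcript(
    transcript: TranscriptRecord,
    profiles: list[TypeProfile] | None = None,
    min_orf_aa: int = 50,
) -> dict:
    """One annotation-table row: coding status plus, for active transcripts,
    type, subtype, domains, cysteine accounting, mature length and mass."""
    profiles = profiles or default_profiles()
    status = assess_transcript(transcript, profiles, min_orf_aa)
    row = {
        "id": transcript.id,
        "status": status.status,
        "defect": status.defect,
        "type": "unknown",
        "type_score": 0.0,
        "subtype": "none",
        "nterm_label": "",
        "cys_total": 0,
        "cys_conserved": 0,
        "cys_extra": "",
        "mature_length": 0,
        "mature_mass_da": 0.0,
        "domains": None,
    }
    if status.status != "active":
        return row
    protein = find_orfs(transcript, min_orf_aa)[0].protein
    protein = ProteinRecord(id=transcript.id, sequence=protein.sequence)
    type_, score = classify_type(protein, profiles)
    row["type"] = type_
    row["type_score"] = round(score, 3)
    if type_ == "unknown":
        return row
    profile = profile_by_type(profiles, type_)
    mature = protein.mature_sequence(profile.signal_peptide_len)
    row["nterm_label"] = mature[:4]
    row["mature_length"] = len(mature)
    row["mature_mass_da"] = round(peptide_mass(mature), 2)
    try:
        domains = segment_domains(protein, profile)
    except SegmentationError as exc:
        log.warning("segmentation failed for %s: %s", transcript.id, exc)
        return row
    row["domains"] = domains
    total, conserved, extras = count_cysteines(protein, profile, domains)
    row["cys_total"] = total
    row["cys_conserved"] = conserved
    row["cys_extra"] = ",".join(map(str, extras))
    try:
        if type_ == "alpha":
            row["subtype"] = subtype_alpha(protein, domains, profile)
        elif type_ == "omega":
            row["subtype"], row["nterm_label"] = subtype_omega(
                protein, profile.signal_peptide_len
            )
    except SubtypeError as exc:
        log.warning("subtype call failed for %s: %s", transcript.id, exc)
    return row


def classify_transcripts(
    transcripts: list[TranscriptRecord],
    profiles: list[TypeProfile] | None = None,
    min_orf_aa: int = 50,
) -> pd.DataFrame:
    rows = [annotate_transcript(t, profiles, min_orf_aa) for t in transcripts]
    df = pd.DataFrame(rows)
    log.info(
        "classified %d transcripts: %d active (%s)",
        len(df),
        int((df.status == "active").sum()),
        dict(df.loc[df.status == "active", "type"].value_counts()),
    )
    return df


def match_all_spots(
    observations: list[SpotObservation],
    db: list[ProteinRecord],
    min_unique: int = 1,
    min_coverage: float = 0.1,
    params: DigestParams | None = None,
) -> list[MatchResult]:
    params = params or DigestParams()
    index = build_peptide_index(db, DEFAULT_ENZYMES, params)
    groups = equivalence_groups(db, DEFAULT_ENZYMES, params)
    by_spot: dict[str, list[SpotObservation]] = {}
    for obs in observations:
        by_spot.setdefault(obs.spot_id, []).append(obs)
    results = [
        match_spot(
            by_spot[s], db, index, min_unique, min_coverage,
            DEFAULT_ENZYMES, params, groups,
        )
        for s in sorted(by_spot)
    ]
    log.info(
        "matched %d spots: %d with a match",
        len(results),
        sum(1 for r in results if r.matched_ids),
    )
    return results


def assign_all_genes(
    gene_ids: list[str],
    matches: list[MatchResult],
    matrix: SpotPresenceMatrix,
    pcr: dict[str, PcrEvidence] | None = None,
) -> tuple[dict[str, SpotAssignment], list[GeneAssignment]]:
    spot_assignments = assign_all_spots(matrix)
    pcr = pcr or {}
    assignments = [
        assign_gene(g, matches, spot_assignments, pcr.get(g), matrix.line_locus)
        for g in gene_ids
    ]
    log.info(
        "assigned %d of %d genes to a locus",
        sum(1 for a in assignments if a.locus),
        len(assignments),
    )
    return spot_assignments, assignments


def epitope_summaries(
    proteins: list[ProteinRecord], panel: EpitopePanel
) -> list[EpitopeSummary]:
    return [summarize(scan(p, panel), p, panel) for p in proteins]


def epitope_matrix(summaries: list[EpitopeSummary]) -> pd.DataFrame:
    """Proteins x epitopes copy-count matrix (the epitope-map figure as a table)."""
    return pd.DataFrame(
        {s.protein_id: s.per_epitope_copies for s in summaries}
    ).T.fillna(0).astype(int)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_manifest(
    outdir: Path, seed: int | None, inputs: list[Path], counts: dict[str, int]
) -> dict:
    manifest = {
        "tool": "gliadin-atlas",
        "version": __version__,
        "seed": seed,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
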