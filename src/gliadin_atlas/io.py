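"""File formats: FASTA via Biopython, tables as TSV.

Coordinates in domain tables are 1-based inclusive (documented in the column
header comment of each writer).
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .epitopes import Epitope, EpitopePanel
from .errors import InputError
from .loci import PcrEvidence, SpotPresenceMatrix
from .match import SpotObservation
from .records import DomainMap, ProteinRecord, TranscriptRecord


def read_transcripts(path: str | Path) -> list[TranscriptRecord]:
    return [
        TranscriptRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_proteins(path: str | Path, form: str = "precursor") -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), form=form)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records, path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_panel(path: str | Path) -> EpitopePanel:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"name", "restriction", "core"}
    if not required <= set(df.columns):
        raise InputError(f"panel TSV needs columns {sorted(required)}")
    epitopes = [
        Epitope(
            name=row["name"],
            core=row["core"],
            restriction=row["restriction"],
            native_core=row.get("native_core") or None,
        )
        for _, row in df.iterrows()
    ]
    return EpitopePanel(epitopes=epitopes)


def write_panel(panel: EpitopePanel, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": e.name,
                "restriction": e.restriction,
                "core": e.core,
                "native_core": e.native_core or "",
            }
            for e in panel.epitopes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_spots(path: str | Path) -> list[SpotObservation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    obs: dict[tuple[str, str], list[str]] = {}
    for _, row in df.iterrows():
        obs.setdefault((row["spot_id"], row["enzyme"]), []).append(row["peptide"])
    return [
        SpotObservation(spot_id=k[0], enzyme_name=k[1], peptides=v)
        for k, v in sorted(obs.items())
    ]


def write_spots(observations: list[SpotObservation], path: str | Path) -> None:
    rows = [
        {"spot_id": o.spot_id, "enzyme": o.enzyme_name, "peptide": p}
        for o in observations
        for p in o.peptides
    ]
    pd.DataFrame(rows, columns=["spot_id", "enzyme", "peptide"]).to_csv(
        path, sep="\t", index=False
    )


def read_matrix(
    path: str | Path, line_locus: dict[str, str | None]
) -> SpotPresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mixture: set[str] = set()
    if "mixture" in df.columns:
        mixture = set(df.index[df["mixture"].astype(int) == 1])
        df = df.drop(columns=["mixture"])
    present = df.astype(int).astype(bool)
    return SpotPresenceMatrix(
        present=present, line_locus=line_locus, mixture_spots=mixture
    )


def write_matrix(matrix: SpotPresenceMatrix, path: str | Path) -> None:
    out = matrix.present.astype(int).copy()
    out["mixture"] = [
        1 if s in matrix.mixture_spots else 0 for s in matrix.present.index
    ]
    out.index.name = "spot_id"
    out.to_csv(path, sep="\t")


def read_pcr(
    path: str | Path, line_locus: dict[str, str | None]
) -> dict[str, PcrEvidence]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    lines = [c for c in df.columns if c in line_locus]
    return {
        gene: PcrEvidence(
            gene_id=gene,
            present={line: bool(int(df.loc[gene, line])) for line in lines},
        )
        for gene in df.index
    }


def write_pcr(pcr: dict[str, PcrEvidence], path: str | Path) -> None:
    df = pd.DataFrame(
        {g: {k: int(v) for k, v in e.present.items()} for g, e in sorted(pcr.items())}
    ).T
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_domains(domains: dict[str, DomainMap], path: str | Path) -> None:
    """BED-like TSV, but 1-based inclusive coordinates."""
    rows = [
        {"id": pid, "start": s, "end": e, "label": lab}
        for pid, dm in sorted(domains.items())
        for lab, s, e in dm.segments
    ]
    pd.DataFrame(rows, columns=["id", "start", "end", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    cols = [
        "id", "status", "defect", "type", "type_score", "subtype", "nterm_label",
        "cys_total", "cys_conserved", "cys_extra", "mature_length", "mature_mass_da",
    ]
    df[[c for c in cols if c in df.columns]].to_csv(path, sep="\t", index=False)


def write_corpus(corpus, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(corpus.transcripts, outdir / "transcripts.fa")
    write_fasta(
        [corpus.proteins[g] for g in sorted(corpus.proteins)], outdir / "proteins.fa"
    )
    corpus.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_panel(corpus.panel, outdir / "panel.tsv")
    write_spots(corpus.spot_observations, outdir / "spots.tsv")
    write_matrix(corpus.matrix, outdir / "matrix.tsv")
    write_pcr(corpus.pcr, outdir / "pcr.tsv")
    corpus.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    write_domains(corpus.domain_truth, outdir / "domains.tsv")
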