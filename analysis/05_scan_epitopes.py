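#!/usr/bin/env python
"""Scan the accumulated gliadins for CD epitopes and bin the loads.

Expected on the default corpus: of 38 accumulated proteins, 10 carry no
epitope, 8 carry one or two, 20 carry three or more; CSTT alpha-gliadins are
epitope-poor while the Gli-D2 CT alphas carry the 33-mer epitope trio.
"""
import argparse
from pathlib import Path

import pandas as pd

from gliadin_atlas import io
from gliadin_atlas.pipeline import epitope_matrix, epitope_summaries

parser = argparse.ArgumentParser()
parser.add_argument("--corpus", type=Path, default=Path("results/corpus"))
parser.add_argument("--out", type=Path, default=Path("results/epitope_matrix.tsv"))
args = parser.parse_args()

proteins = io.read_proteins(args.corpus / "proteins.fa")
truth = pd.read_csv(args.corpus / "truth.tsv", sep="\t")
accumulated = set(truth.loc[truth.accumulated, "gene_id"])
db = [p for p in proteins if p.id in accumulated]
panel = io.read_panel(args.corpus / "panel.tsv")

summaries = epitope_summaries(db, panel)
epitope_matrix(summaries).rename_axis("protein_id").to_csv(args.out, sep="\t")
pd.DataFrame(
    [
        {"protein_id": s.protein_id, "total": s.total,
         "distinct": s.distinct, "category": s.category}
        for s in summaries
    ]
).to_csv(args.out.parent / "epitope_summary.tsv", sep="\t", index=False)

cats = pd.Series([s.category for s in summaries]).value_counts().to_dict()
print(f"epitope matrix written to {args.out}")
print(f"  {len(db)} accumulated proteins x {len(panel.epitopes)} epitopes")
print(f"  load bins: {cats}")
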