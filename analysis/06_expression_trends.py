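#!/usr/bin/env python
"""RPKM-normalize the developmental read counts and classify trends.

Storage-protein genes are transcriptionally upregulated through grain filling;
all active genes in the default corpus classify as upregulated.
"""
import argparse
from pathlib import Path

import pandas as pd

from gliadin_atlas.expression import rpkm, trend_class

parser = argparse.ArgumentParser()
parser.add_argument("--corpus", type=Path, default=Path("results/corpus"))
parser.add_argument("--out", type=Path, default=Path("results/expression_rpkm.tsv"))
args = parser.parse_args()

df = pd.read_csv(args.corpus / "expression.tsv", sep="\t")
df["rpkm"] = [
    rpkm(r["count"], r["length"], r["library_total"]) for _, r in df.iterrows()
]
trends = {
    gene: trend_class(sorted((r["timepoint"], r["rpkm"]) for _, r in sub.iterrows()))
    for gene, sub in df.groupby("gene")
}
df["trend"] = df["gene"].map(trends)
df.to_csv(args.out, sep="\t", index=False)
counts = pd.Series(list(trends.values())).value_counts().to_dict()
print(f"rpkm table written to {args.out}")
print(f"  trends: {counts}")
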