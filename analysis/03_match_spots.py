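#!/usr/bin/env python
"""Match simulated 2-DE spots to the protein database.

Uniqueness first, coverage as fallback; genes with indistinguishable digests
(e.g. the two identical gamma proteins) are matched as one equivalence group.
"""
import argparse
from pathlib import Path

import pandas as pd

from gliadin_atlas import io
from gliadin_atlas.pipeline import match_all_spots

parser = argparse.ArgumentParser()
parser.add_argument("--corpus", type=Path, default=Path("results/corpus"))
parser.add_argument("--out", type=Path, default=Path("results/spot_matches.tsv"))
parser.add_argument("--min-unique", type=int, default=1)
parser.add_argument("--min-coverage", type=float, default=0.1)
args = parser.parse_args()

proteins = io.read_proteins(args.corpus / "proteins.fa")
truth = pd.read_csv(args.corpus / "truth.tsv", sep="\t")
accumulated = set(truth.loc[truth.accumulated, "gene_id"])
db = [p for p in proteins if p.id in accumulated]
observations = io.read_spots(args.corpus / "spots.tsv")
results = match_all_spots(observations, db, args.min_unique, args.min_coverage)

pd.DataFrame(
    [
        {
            "spot_id": r.spot_id,
            "matched_ids": ",".join(r.matched_ids),
            "evidence": r.evidence,
            "equivalence_group": int(r.equivalence_group),
        }
        for r in results
    ]
).to_csv(args.out, sep="\t", index=False)
n_match = sum(1 for r in results if r.matched_ids)
n_group = sum(1 for r in results if r.equivalence_group)
print(f"matches written to {args.out}")
print(f"  {n_match} of {len(results)} spots matched ({n_group} to equivalence groups)")
by_ev = pd.Series([r.evidence for r in results]).value_counts().to_dict()
print(f"  evidence: {by_ev}")
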