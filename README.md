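# gliadin-atlas

Genome-wide characterization of wheat gliadins — the monomeric gluten
proteins that dominate the celiac-disease (CD) epitope load of bread wheat —
as a tested, reusable pipeline.

Bread wheat (*Triticum aestivum*, AABBDD) carries its gliadin genes in six
compound loci: *Gli-A1/B1/D1* (group-1 short arms; γ-, ω- and δ-gliadins) and
*Gli-A2/B2/D2* (group-6 short arms; α-gliadins). Characterizing which of
these highly similar homoeologs and paralogs are transcribed, which encode
intact proteins, which proteins actually accumulate in the grain, and which
carry CD epitopes requires stitching together full-length transcript
classification, comparative 2-DE proteomics against locus deletion lines, and
epitope bioinformatics. This package implements each of those analysis steps:

- **`gliadin_atlas.orf`** — forward-strand ORF finding on oriented
  full-length transcripts and active/pseudogene calling (premature stop vs
  frameshift vs no ORF), using per-type mature-length bands.
- **`gliadin_atlas.classify`** — classification of proteins into α/γ/δ/ω
  types from conserved-cysteine counts (α: 6, γ: 8, δ: 8, ω: 0), repeat-motif
  density and N-terminal signatures; domain segmentation per type grammar
  (signal peptide, repetitive region, polyglutamine runs, unique regions);
  cysteine accounting; α CT/CSTT and ω5/ω1,2 subtype calls.
- **`gliadin_atlas.epitopes`** — exact overlapping-substring scanning of
  9-residue CD epitope cores (copy counting as in the canonical 33-mer, which
  carries DQ2.5-glia-α1a/α1b/α2 with 1/2/3 copies) and per-protein,
  per-category, per-locus summaries.
- **`gliadin_atlas.digest` / `gliadin_atlas.match`** — in-silico chymotrypsin
  and thermolysin digestion (≤2 missed cleavages, 300–6000 Da window),
  peptide-uniqueness indexing, protein coverage, and the spot→gene decision
  rule (unique peptides first, maximal coverage as fallback, equivalence
  groups for indistinguishable proteins, NMF otherwise).
- **`gliadin_atlas.loci`** — spot→locus assignment from the deletion-line
  presence/absence matrix and gene→locus assignment combining spot evidence
  (SA) with PCR mapping (PM), with conflict detection.
- **`gliadin_atlas.expression`** — RPKM (`C / ((L/1000)·(N/1e6))`) and
  developmental trend classification.
- **`gliadin_atlas.synthetic`** — a fully labeled synthetic corpus generator
  that emulates the study design: 52 transcripts (42 active: 25 α
  [13 CT / 12 CSTT], 11 γ, 1 δ, 5 ω; 10 pseudogenes: 7 α / 2 γ / 1 ω),
  homoeolog families at controlled identity, planted epitope copy counts,
  simulated two-enzyme spot observations, the deletion-line matrix, PCR
  evidence and read counts — deterministic per seed.

The shipped CT/CSTT tail signatures and most epitope cores are synthetic
placeholders (`SYN-` prefixed) so the machinery is testable end to end; users
with real data should supply their own subtype signatures (via
`TypeProfile.subtype_rules`) and a curated epitope panel TSV.

## Worked example

```bash
gliadin-atlas run --seed 7 --outdir run/
```

prints (stage logs omitted):

```
active 42/52; matched 73/73 spots; assigned 42 genes
```

i.e. of the 52 corpus transcripts, 42 are called active (the 10 planted
pseudogenes are rejected for premature stops or frameshifts), every simulated
2-DE spot is matched back to its generating gene — the two 100%-identical γ
proteins are matched as one equivalence group — and all 42 genes land on
their true *Gli* locus. The same steps are available as numbered narrative
drivers:

```bash
python analysis/01_simulate_corpus.py      # 52 transcripts, 73 spots, matrix
python analysis/02_classify_transcripts.py # 42 active; 25 α / 11 γ / 1 δ / 5 ω; 13 CT / 12 CSTT
python analysis/03_match_spots.py          # 73/73 spots matched, 5 via an equivalence group
python analysis/04_assign_loci.py          # accumulated per locus: 4/6/7/6/9/6 (A:10 B:15 D:13)
python analysis/05_scan_epitopes.py        # epitope load bins: 10 zero / 8 one-two / 20 three+
python analysis/06_expression_trends.py    # all 42 active genes upregulated
```

Each writes its tables under `results/`. The library equivalents are
`classify_transcripts`, `match_all_spots`, `assign_all_genes`,
`epitope_summaries` in `gliadin_atlas.pipeline`.

A pure-library example — scanning the celiac-immunodominant 33-mer:

```python
>>> from gliadin_atlas.epitopes import *
>>> from gliadin_atlas.records import ProteinRecord
>>> p = ProteinRecord("33mer", THIRTY_THREE_MER, form="mature")
>>> panel = EpitopePanel([Epitope("a1a", DQ25_GLIA_A1A),
...                       Epitope("a1b", DQ25_GLIA_A1B),
...                       Epitope("a2", DQ25_GLIA_A2)])
>>> summarize(scan(p, panel), p, panel).per_epitope_copies
{'a1a': 1, 'a1b': 2, 'a2': 3}
```

## Module docs

See `docs/methods.md` for the models, scoring functions, parameter defaults
and the limits of what the synthetic corpus can establish about real data.
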