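# Methods

This note records the models and procedures implemented in `gliadin_atlas`,
the parameters that matter, the design choices made where the problem was
genuinely open, and what the synthetic corpus does and does not establish.

## Gliadin type model

Each gliadin type is described by a `TypeProfile`: an ordered domain grammar,
repeat motifs, an expected conserved-cysteine count, the domains hosting
those cysteines, a mature-length band, and N-terminal prefixes.

| type | grammar | conserved cys | mature band (aa) |
|------|---------|---------------|------------------|
| α | SP–RR–PQR1–UR1–PQR2–UR2 | 6 (UR1+UR2) | 275–332 |
| γ | SP–NR–RR–PQR–UR1–UR2 | 8 (UR1+UR2) | 278–364 |
| δ | SP–NR–RR–UR | 8 (UR) | 300–348 |
| ω | SP–NR–RR | 0 | 352–446 |

SP = signal peptide (fixed 20 aa by default, configurable), NR = short
N-terminal region, RR = repetitive region, PQR = polyglutamine region, UR =
unique region. The bands are the published per-type protein-length ranges
with a ±7 aa margin for indel variation. Coordinates are 1-based inclusive on
the precursor throughout.

### Type score

```
score = 0.50 · 1/(1+|cys_obs − cys_expected|)
      + 0.35 · motif density over the candidate repetitive region
      + 0.15 · [mature N-terminus matches a type prefix]
```

The cysteine term dominates deliberately: the field's type definitions hinge
on the conserved cysteine count, and it alone separates α (6) from γ (8) and
ω (0) even when repeats are ambiguous. Motif density breaks the remaining
ties (γ vs δ share 8 cysteines but different repeat units; a protein with one
extra cysteine, e.g. a 7-cys α, scores 0.5 on both the α and γ cysteine terms
and is resolved by its α-type repeats). Proteins scoring < 0.5, or with no
detectable repeat region at all, are returned as `unknown` — this is the
pass-through route for HMW/LMW glutenin subunits.

Motif matching tolerates one substitution per motif window: prolamin repeats
are degenerate, and exact matching loses the repeat region in homoeologs a
few percent diverged. Density is motif coverage of the largest hit cluster
(hits ≤ 60 aa apart, so an epitope block embedded in the repeats does not
split the region), with the denominator floored at 30 aa so a single stray
hit cannot score as a repeat region.

### Segmentation

Segmentation anchors on (i) the first/last fuzzy motif hit and (ii)
polyglutamine runs: maximal pure-Q runs, merged across single-residue
interruptions when the merged Q-frequency stays ≥ 0.8 (`q_run_min`), kept at
length ≥ 8 (`q_window` — real PQRs are ≥ 10 aa; shorter accidental Q-runs
arise from indels in repeats). α needs two Q-runs after the repeat start
(PQR1, PQR2); γ needs one plus a two-cysteine-group unique region that is
split at the midpoint of the largest inter-cysteine gap. Boundary precision
against generator truth is ± ~4 aa on diverged family members (the tests
allow 6); the dominant error source is a polyglutamine run swallowing the
trailing Q of the last repeat unit.

### Subtypes

α proteins split into CT vs CSTT on the sequence downstream of the last
conserved cysteine, matched against two configurable signature strings; the
shipped signatures are synthetic (the real discriminating residues are in
supplementary material we do not redistribute). ω subtyping is rule-based:
SRL start + FPQQQ/QQIPQQ repeats → ω5; ARE/ARQ/KEL start + PQQPFP → ω1,2;
when no start rule fires, motif evidence dominates (so a novel ARPL start
with PQQPFP repeats is still ω1,2).

## Coding-status assessment

A transcript is **active** when its longest forward-strand ORF (every ATG is
a candidate; ORFs must terminate at a stop) is ≥ `min_orf_aa` (default 50)
and the ORF's mature length falls in the profile's band. Type-agnostic
assessment tries every profile and falls back to the band spanning all types.

Otherwise the transcript is a pseudogene, and the defect class is decided
from the earliest-ATG candidate ORF: among stop-free codon runs (any frame)
that cover the truncation point and would restore a band-length product, the
run whose translation is most Q/P-rich identifies the intact reading
register — same register as the candidate ORF means a single interrupting
stop (`premature_stop`); a shifted register means the downstream sequence is
intact one frame away (`frameshift`). The composition tie-break matters
because Q/P-rich codon streams are frequently stop-free even out of register,
so "a shifted frame reads through" is necessary but not sufficient evidence
of a frameshift; "reads through *as a gliadin*" is. `no_orf` is returned when
no ATG→stop ORF exists.

## Percent identity

Needleman–Wunsch, match +1, mismatch 0, linear gap −0.9 per column, computed
on a ×10 integer scale (exact DP). With these scores every co-optimal
alignment provably has the same number of identities and gaps (an identity
difference would need to be 0.9× an integer), so percent identity is
well-defined independent of traceback order; traceback is canonical
(diagonal > up > left) and the pair is sorted before alignment, making the
statistic exactly symmetric. Identity = identical columns ÷ aligned columns
after trimming terminal-gap columns. The implementation is row-vectorized in
numpy; tests cross-check the optimal score against `Bio.Align` and the full
statistic against an independent plain-Python DP.

## Digestion and spot matching

Chymotrypsin cuts C-terminal to F/Y/W/L unless the next residue is proline;
thermolysin cuts N-terminal to A/F/I/L/M/V with no proline block. Both are
plain data (`Enzyme`) and fully configurable. Digestion enumerates every
fragment between cleavage boundaries with ≤ `max_missed` (default 2) internal
sites, then filters to the 300–6000 Da average-mass window. I and L are
distinct residues; peptide placement on proteins is exact substring matching
(upstream search-engine concerns such as PSM scoring and FDR are out of
scope — the pipeline consumes peptide lists).

Spot→gene matching pools both enzymes' observations per spot, collapses the
database into equivalence groups (identical theoretical peptide sets under
both enzymes — the situation of two genes encoding 100%-identical proteins),
and decides: (1) a group owning ≥ `min_unique` (default 1) observed
group-unique peptides wins, ties broken by coverage; (2) otherwise the
candidate group of maximal coverage wins if coverage ≥ `min_coverage`
(default 0.1); (3) otherwise no match found (NMF). Coverage is the
residue-union of all exact placements divided by mature length.

## Locus assignment

A spot absent in exactly one deletion line takes that line's locus; absent in
none → unassigned, in several → conflict. Spots flagged as mixtures are
excluded from evidence. A gene's SA locus is the unanimous locus of its
matched spots; its PM locus is the locus of the single line lacking its PCR
amplicon; SA+PM requires agreement, and disagreement raises a conflict error
rather than prioritizing either side (no precedent exists for resolving one).

## RPKM and trends

RPKM = C ÷ ((L/1000)·(N/10⁶)) with L the full transcript length by default.
A series is `upregulated` when last/first ≥ `fold_min` (default 2) and no
value dips more than `tol` (default 20%) below the running maximum; `flat`
when max/min < `fold_min`; otherwise `other`. The fold and tolerance defaults
encode a qualitative "generally increasing" criterion and are configurable.

## Synthetic corpus

The default `GeneratorConfig` reproduces the study design: 52 transcripts —
42 active (25 α: 13 CT + 12 CSTT distributed 8/10/7 over *Gli-A2/B2/D2*;
11 γ over *Gli-A1/B1/D1*; 1 δ; 5 ω including one ω5 and one novel-ARPL ω1,2)
and 10 pseudogenes (7 α, 2 γ, 1 ω; premature stops and frameshifts in equal
measure). Four α genes are not accumulated (no spots; PCR evidence instead),
leaving 38 accumulated proteins at 4/6/7/6/9/6 per locus. One γ pair is
emitted 100% identical at the protein level with synonymous-only coding
differences. Extra cysteines are planted in one α, two γ and two ω members.
Epitope loads are planted to the published bin structure (10 zero / 8
one-or-two / 20 three-plus), with the *Gli-D2* CT α-gliadins carrying the
33-mer epitope trio and the CSTT group epitope-free.

Construction details that matter:

- Families derive from one skeleton per type and one ancestor per locus;
  substitutions (never at conserved cysteines, signatures or region edges)
  and small RR-confined indels are applied at a rate calibrated against
  measured mean pairwise identity (default targets: α 0.92, γ 0.86, ω 0.82;
  ±2 points).
- Epitope planting first scrubs every incidental panel-core occurrence, then
  writes the planned blocks into the repeat-region interior separated by
  single serines (no panel core contains S, so junction hits are impossible),
  keeping 12 aa clear of the region edges; the result is verified by re-scan.
- Repeat tracts carry LT/TS dipeptide interruptions every ~30–45 residues
  (real prolamin repeats are similarly degenerate). Reverse translation uses
  a flat codon table with deterministic exceptions (Y→TAC, N→AAC, D→GAC; no
  A-ending codon immediately before a cysteine; TTA/ACT/AGC at the
  interruptions). Jointly these guarantee that no spurious ATG forms across
  codon junctions — so the longest ORF of every transcript is its true CDS —
  and that both shifted reading registers contain stop codons, so frameshifts
  truncate translation as they do in real pseudogenes.
- `pseudogenize` draws mutation positions in the first half of the CDS and
  retries until the defect is manifest (longest remaining ORF below the
  length band and no new ATG), mirroring the operational definition of a
  defective coding region.
- Spot simulation: 1–3 spots per accumulated protein; each spot samples the
  protein's theoretical peptides per enzyme with Bernoulli(detection_prob =
  0.8 by default) and adds Poisson(contaminant_rate = 0.02) peptides from
  other proteins. Two mixture spots (two genes from different loci) exercise
  the exclusion path.
- Everything derives from one `numpy` Generator; a fixed seed gives
  byte-identical FASTA/TSV output.

**What passing tests show — and do not.** Round-trip recovery on this corpus
shows the pipeline's logic is correct under the stated noise model: the
classifier recovers exactly the planted composition because the corpus is
generated from the same type grammars the classifier tests. It does not show
that the shipped motif weights or synthetic subtype signatures discriminate
real wheat sequences, that real MS detection behaves like independent
Bernoulli draws, or that real deletion lines remove exactly one locus
(linked *Glu-3* loci are handled only by a mixture/type-tag exclusion
mechanism). Real-data use requires a curated epitope panel and
alignment-derived subtype signatures.

## Problem sizes and determinism

The default test suite and acceptance script run the full 52-transcript
corpus (one shared instance per session), 500-instance oracle-equivalence
sweeps per operation (transcripts ≤ 450 nt, proteins ≤ 90 aa for the
quadratic oracles), and a 200-spot noise simulation; the complete suite runs
in well under a minute on one CPU. All randomness flows from explicit seeds;
hypothesis-based property tests are bounded and deadline-free.
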