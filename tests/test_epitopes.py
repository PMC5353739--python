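"""CD-epitope scanning, copy counting and summaries."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliadin_atlas.epitopes import (
    DQ25_GLIA_A1A,
    DQ25_GLIA_A1B,
    DQ25_GLIA_A2,
    THIRTY_THREE_MER,
    Epitope,
    EpitopePanel,
    categorize,
    locus_summary,
    scan,
    summarize,
)
from gliadin_atlas.records import ProteinRecord
from gliadin_atlas.synthetic import embed_epitopes, make_skeleton

from oracles import epitope_scan


def _panel(**cores):
    return EpitopePanel(
        epitopes=[Epitope(name, core, "DQ2.5") for name, core in cores.items()]
    )


def test_33mer_carries_three_epitopes_with_overlapping_copies():
    """The canonical 33-mer: copy counts 1 / 2 / 3 for the three DQ2.5
    alpha-epitopes, all overlaps counted."""
    protein = ProteinRecord("m33", THIRTY_THREE_MER, form="mature")
    panel = _panel(a1a=DQ25_GLIA_A1A, a1b=DQ25_GLIA_A1B, a2=DQ25_GLIA_A2)
    s = summarize(scan(protein, panel), protein, panel)
    assert s.per_epitope_copies == {"a1a": 1, "a1b": 2, "a2": 3}
    assert s.total == 6
    assert s.distinct == 3
    assert s.category == "three_plus"


def test_empty_panel_scans_to_nothing():
    protein = ProteinRecord("p", "PQPQLPYPQPQLPY")
    assert scan(protein, EpitopePanel(epitopes=[])) == []


def test_scan_matches_naive_oracle():
    rng = np.random.default_rng(9)
    aa = list("QPFLYSTIVA")
    panel = _panel(
        e1="PFPQPQLPY", e2="QPQLPYPQP", e3="QQQQPPPFF", e4="LYSTIVAQP"
    )
    cores = {e.name: e.core for e in panel.epitopes}
    for _ in range(150):
        seq = "".join(rng.choice(aa, size=int(rng.integers(30, 300))))
        protein = ProteinRecord("p", seq)
        got = {(h.epitope_name, h.position) for h in scan(protein, panel)}
        assert got == epitope_scan(seq, cores)


def test_hits_ordered_by_position_then_name():
    protein = ProteinRecord("p", "PQPQLPYPQPQLPYPQ")
    panel = _panel(b="PQPQLPYPQ", a="QPQLPYPQP")
    hits = scan(protein, panel)
    assert [(h.position, h.epitope_name) for h in hits] == sorted(
        (h.position, h.epitope_name) for h in hits
    )


@given(total=st.integers(min_value=0, max_value=40))
@settings(deadline=None)
def test_category_bins_are_monotone(total):
    cat = categorize(total)
    if total == 0:
        assert cat == "zero"
    elif total <= 2:
        assert cat == "one_to_two"
    else:
        assert cat == "three_plus"


def test_summary_totals_invariant_under_panel_reordering():
    protein = ProteinRecord("p", THIRTY_THREE_MER, form="mature")
    p1 = _panel(a1a=DQ25_GLIA_A1A, a2=DQ25_GLIA_A2)
    p2 = _panel(a2=DQ25_GLIA_A2, a1a=DQ25_GLIA_A1A)
    s1 = summarize(scan(protein, p1), protein, p1)
    s2 = summarize(scan(protein, p2), protein, p2)
    assert s1.total == s2.total
    assert s1.per_epitope_copies == s2.per_epitope_copies


def test_no_hits_is_category_zero():
    protein = ProteinRecord("p", "AAAAAAAAAAAA")
    panel = _panel(e="PFPQPQLPY")
    s = summarize([], protein, panel)
    assert (s.total, s.category) == (0, "zero")


def test_single_hit_is_one_to_two():
    protein = ProteinRecord("p", "AAA" + "PFPQPQLPY" + "AAA")
    panel = _panel(e="PFPQPQLPY")
    s = summarize(scan(protein, panel), protein, panel)
    assert (s.total, s.category) == (1, "one_to_two")


@pytest.mark.parametrize("copies", [0, 1, 3, 4])
def test_embed_epitopes_roundtrip(alpha_profile, copies):
    """Planting k non-overlapping copies yields exactly k on rescan."""
    rng = np.random.default_rng(33)
    skel, truth = make_skeleton("alpha", alpha_profile, rng)
    epitope = Epitope("e", "PFPQPQLPY", "DQ2.5")
    planted = embed_epitopes(skel, epitope, copies, rng, truth["spans"]["RR"])
    panel = EpitopePanel(epitopes=[epitope])
    assert len(scan(planted, panel)) == copies


def test_embed_epitopes_is_deterministic(alpha_profile):
    skel, truth = make_skeleton("alpha", alpha_profile, np.random.default_rng(5))
    epitope = Epitope("e", "PFPQPQLPY", "DQ2.5")
    a = embed_epitopes(skel, epitope, 4, np.random.default_rng(8), truth["spans"]["RR"])
    b = embed_epitopes(skel, epitope, 4, np.random.default_rng(8), truth["spans"]["RR"])
    assert a.sequence == b.sequence


def test_locus_summary_aggregates_corpus_truth(corpus, corpus_truth, panel):
    from gliadin_atlas.pipeline import epitope_summaries

    acc = [g for g in sorted(corpus.proteins) if corpus_truth.accumulated[g]]
    summaries = epitope_summaries([corpus.proteins[g] for g in acc], panel)
    table = locus_summary(summaries, corpus.gene_locus())
    assert int(table.n_proteins.sum()) == len(acc)
    expected = corpus_truth.loc[acc].groupby("locus").epitope_total.sum()
    for locus, total in expected.items():
        assert int(table.loc[locus, "total_epitopes"]) == int(total)
    # published load bins: 10 epitope-free, 8 with 1-2, 20 with >=3
    cats = [s.category for s in summaries]
    assert (cats.count("zero"), cats.count("one_to_two"), cats.count("three_plus")) == (
        10,
        8,
        20,
    )
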