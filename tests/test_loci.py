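"""Deletion-line locus assignment for spots and genes."""
from __future__ import annotations

import importlib.resources

import pandas as pd
import pytest

from gliadin_atlas.errors import ConflictError, InputError
from gliadin_atlas.io import read_matrix
from gliadin_atlas.loci import (
    GLI_LOCI,
    PcrEvidence,
    SpotPresenceMatrix,
    assign_all_spots,
    assign_gene,
    assign_spot,
    summarize_loci,
)
from gliadin_atlas.match import MatchResult
from gliadin_atlas.synthetic import DELETION_LINES, WILD_TYPE_LINE

LINE_LOCUS = {WILD_TYPE_LINE: None, **DELETION_LINES}
LINES = [WILD_TYPE_LINE] + list(DELETION_LINES)


def _matrix(rows: dict[str, list[int]], mixture=()) -> SpotPresenceMatrix:
    present = pd.DataFrame.from_dict(rows, orient="index", columns=LINES).astype(bool)
    return SpotPresenceMatrix(
        present=present, line_locus=LINE_LOCUS, mixture_spots=set(mixture)
    )


def test_spot_absent_in_one_line_assigns_that_locus():
    m = _matrix({"s": [1, 1, 1, 0, 1, 1, 1]})  # absent only in DLGliD1
    assert assign_spot("s", m).locus == "Gli-D1"


def test_spot_present_everywhere_is_unassigned():
    m = _matrix({"s": [1] * 7})
    a = assign_spot("s", m)
    assert a.locus is None
    assert a.reason == "no_evidence"


def test_spot_absent_in_two_lines_is_conflict():
    m = _matrix({"s": [1, 0, 0, 1, 1, 1, 1]})
    assert assign_spot("s", m).reason == "conflict"


def test_mixture_spot_excluded():
    m = _matrix({"s": [1, 0, 1, 1, 1, 1, 1]}, mixture=["s"])
    assert assign_spot("s", m).reason == "mixture"


def test_spot_absent_in_wild_type_rejected():
    with pytest.raises(InputError):
        _matrix({"s": [0, 1, 1, 1, 1, 1, 1]})


@pytest.fixture(scope="module")
def reference_panel():
    """The published 82-spot deletion-line presence panel."""
    path = importlib.resources.files("gliadin_atlas") / "data" / "xiaoyan81_spot_panel.tsv"
    return read_matrix(path, LINE_LOCUS)


def test_reference_panel_spot_bookkeeping(reference_panel):
    """Per-line missing-spot counts 10/17/20/15/13/7 sum to the 82
    well-resolved gliadin spots; every spot gets exactly one locus."""
    assignments = assign_all_spots(reference_panel)
    per_locus = {
        locus: sum(1 for a in assignments.values() if a.locus == locus)
        for locus in GLI_LOCI
    }
    assert per_locus == {
        "Gli-A1": 10, "Gli-B1": 17, "Gli-D1": 20,
        "Gli-A2": 15, "Gli-B2": 13, "Gli-D2": 7,
    }
    assert sum(per_locus.values()) == 82 == len(assignments)
    assert all(a.locus is not None for a in assignments.values())


def _spot_assignments(mapping):
    m = _matrix(
        {
            s: [0 if LINE_LOCUS[l] == locus else 1 for l in LINES]
            for s, locus in mapping.items()
        }
    )
    return assign_all_spots(m)


def test_gene_assignment_sa_pm_and_both():
    spots = _spot_assignments({"43": "Gli-D1", "44": "Gli-D1", "66": "Gli-B2"})
    matches = [
        MatchResult("43", ["gW4"], "unique_peptide"),
        MatchResult("44", ["gW4"], "unique_peptide"),
        MatchResult("66", ["gA18"], "unique_peptide"),
    ]
    sa = assign_gene("gW4", matches, spots)
    assert (sa.locus, sa.evidence) == ("Gli-D1", "SA")

    pcr = PcrEvidence("gNMF", {l: (LINE_LOCUS[l] != "Gli-B2") for l in LINES})
    pm = assign_gene("gNMF", [], spots, pcr, LINE_LOCUS)
    assert (pm.locus, pm.evidence) == ("Gli-B2", "PM")

    pcr2 = PcrEvidence("gA18", {l: (LINE_LOCUS[l] != "Gli-B2") for l in LINES})
    both = assign_gene("gA18", matches, spots, pcr2, LINE_LOCUS)
    assert (both.locus, both.evidence) == ("Gli-B2", "SA+PM")


def test_sa_pm_disagreement_raises_conflict():
    spots = _spot_assignments({"1": "Gli-A1"})
    matches = [MatchResult("1", ["g"], "unique_peptide")]
    pcr = PcrEvidence("g", {l: (LINE_LOCUS[l] != "Gli-B1") for l in LINES})
    with pytest.raises(ConflictError):
        assign_gene("g", matches, spots, pcr, LINE_LOCUS)


def test_gene_with_no_evidence_is_unassigned():
    a = assign_gene("g", [], {})
    assert a.locus is None and a.evidence is None


def test_assignment_order_independent():
    spots = _spot_assignments({"a": "Gli-A2", "b": "Gli-A2"})
    m1 = [MatchResult("a", ["g"], "unique_peptide"), MatchResult("b", ["g"], "unique_peptide")]
    r1 = assign_gene("g", m1, spots)
    r2 = assign_gene("g", list(reversed(m1)), spots)
    assert (r1.locus, r1.evidence, r1.matched_spots) == (r2.locus, r2.evidence, r2.matched_spots)


def test_corpus_locus_recovery_and_summary(corpus, corpus_truth):
    """All planted loci recovered; accumulated per-locus counts 4/6/7/6/9/6
    and subgenome totals conserve the grand total."""
    from gliadin_atlas.pipeline import assign_all_genes, match_all_spots

    acc = [g for g in sorted(corpus.proteins) if corpus_truth.accumulated[g]]
    results = match_all_spots(corpus.spot_observations, [corpus.proteins[g] for g in acc])
    _, assignments = assign_all_genes(
        sorted(corpus.proteins), results, corpus.matrix, corpus.pcr
    )
    truth_locus = corpus.gene_locus()
    for a in assignments:
        assert a.locus == truth_locus[a.gene_id]
    accumulated = [a for a in assignments if a.evidence and "SA" in a.evidence]
    summary = summarize_loci(accumulated, dict(zip(corpus.truth.gene_id, corpus.truth.type)))
    assert summary["by_locus"].to_dict() == {
        "Gli-A1": 4, "Gli-B1": 6, "Gli-D1": 7, "Gli-A2": 6, "Gli-B2": 9, "Gli-D2": 6,
    }
    assert summary["by_subgenome"].sum() == summary["by_locus"].sum() == 38
    assert summary["by_type"].sum() == 38
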