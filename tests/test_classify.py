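"""Type classification, domain segmentation, cysteine accounting, subtypes."""
from __future__ import annotations

import numpy as np
import pytest

from gliadin_atlas.classify import (
    classify_type,
    count_cysteines,
    segment_domains,
    subtype_alpha,
    subtype_omega,
)
from gliadin_atlas.errors import SegmentationError, SubtypeError
from gliadin_atlas.pipeline import classify_transcripts
from gliadin_atlas.records import ProteinRecord
from gliadin_atlas.synthetic import make_skeleton

BOUNDARY_TOL_AA = 6  # segmentation precision on diverged family members


@pytest.fixture(scope="module")
def skeletons(profiles):
    rng = np.random.default_rng(21)
    out = {}
    for p in profiles:
        subtype = "omega5" if p.type == "omega" else "none"
        out[p.type] = make_skeleton(p.type, p, rng, subtype=subtype)
    return out


@pytest.mark.parametrize("type_", ["alpha", "gamma", "delta", "omega"])
def test_skeletons_classify_as_their_type(skeletons, profiles, type_):
    protein, _ = skeletons[type_]
    got, score = classify_type(protein, profiles)
    assert got == type_
    assert score >= 0.5


def test_unrelated_protein_is_unknown(profiles):
    protein = ProteinRecord("x", "MKV" + "GAGEKHDERD" * 30)
    got, _ = classify_type(protein, profiles)
    assert got == "unknown"


def test_gamma_grammar_has_six_segments(skeletons, gamma_profile):
    protein, _ = skeletons["gamma"]
    domains = segment_domains(protein, gamma_profile)
    assert [s[0] for s in domains.segments] == ["SP", "NR", "RR", "PQR", "UR1", "UR2"]
    assert domains.length == len(protein.sequence)


def test_all_q_protein_fails_segmentation(alpha_profile):
    with pytest.raises(SegmentationError):
        segment_domains(ProteinRecord("q", "Q" * 300), alpha_profile)


def test_alpha_skeleton_cysteines(skeletons, alpha_profile):
    protein, _ = skeletons["alpha"]
    domains = segment_domains(protein, alpha_profile)
    assert count_cysteines(protein, alpha_profile, domains) == (6, 6, [])


def test_omega_skeleton_is_cysteine_free(skeletons, omega_profile):
    protein, _ = skeletons["omega"]
    domains = segment_domains(protein, omega_profile)
    assert count_cysteines(protein, omega_profile, domains) == (0, 0, [])


def test_extra_cysteine_reported_with_position(skeletons, alpha_profile):
    protein, truth = skeletons["alpha"]
    rr_s, rr_e = truth["spans"]["RR"]
    pos = (rr_s + rr_e) // 2
    seq = protein.sequence
    mutant = ProteinRecord("x", seq[: pos - 1] + "C" + seq[pos:])
    domains = segment_domains(mutant, alpha_profile)
    total, conserved, extras = count_cysteines(mutant, alpha_profile, domains)
    assert (total, conserved) == (7, 6)
    assert extras == [pos]


def test_cys_total_equals_naive_count(corpus, profiles):
    from gliadin_atlas.profiles import profile_by_type

    truth = corpus.truth.set_index("gene_id")
    for gid, protein in sorted(corpus.proteins.items()):
        profile = profile_by_type(profiles, truth.loc[gid, "type"])
        domains = segment_domains(protein, profile)
        total, _, _ = count_cysteines(protein, profile, domains)
        assert total == protein.sequence[20:].count("C")


def test_omega_subtype_rules():
    srl = ProteinRecord("o5", "SRLL" + "FPQQQ" * 40, form="mature")
    assert subtype_omega(srl) == ("omega5", "SRLL")
    arq = ProteinRecord("o12", "ARQL" + "PQQPFP" * 40, form="mature")
    assert subtype_omega(arq) == ("omega12", "ARQL")
    # novel ARPL N-terminus: repeat-motif evidence dominates
    arp = ProteinRecord("onew", "ARPL" + "PQQPFP" * 40, form="mature")
    assert subtype_omega(arp) == ("omega12", "ARPL")
    with pytest.raises(SubtypeError):
        subtype_omega(ProteinRecord("bad", "MMMM" + "AAAA" * 40, form="mature"))


def test_alpha_subtype_no_cysteine_error(skeletons, alpha_profile):
    protein, _ = skeletons["alpha"]
    seq = protein.sequence.replace("C", "S")
    domains = segment_domains(ProteinRecord("nocys", seq), alpha_profile)
    with pytest.raises(SubtypeError):
        subtype_alpha(ProteinRecord("nocys", seq), domains, alpha_profile)


@pytest.fixture(scope="module")
def corpus_annotations(corpus):
    return classify_transcripts(corpus.transcripts).set_index("id")


def test_corpus_type_split_recovered(corpus_annotations, corpus_truth):
    """25 alpha / 11 gamma / 1 delta / 5 omega among the 42 actives,
    classified from sequence content alone."""
    act = corpus_annotations[corpus_annotations.status == "active"]
    counts = act.type.value_counts().to_dict()
    assert counts == {"alpha": 25, "gamma": 11, "omega": 5, "delta": 1}
    merged = act.join(corpus_truth, rsuffix="_t")
    assert (merged.type == merged.type_t).all()


def test_corpus_subtypes_recovered(corpus_annotations, corpus_truth):
    """13 CT / 12 CSTT alpha split and all omega subtypes recovered."""
    act = corpus_annotations[corpus_annotations.status == "active"]
    merged = act.join(corpus_truth, rsuffix="_t")
    assert (merged.subtype == merged.subtype_t).all()
    alpha = merged[merged.type == "alpha"]
    assert (alpha.subtype == "CT").sum() == 13
    assert (alpha.subtype == "CSTT").sum() == 12


def test_corpus_domain_boundaries_close_to_truth(corpus, corpus_annotations):
    act = corpus_annotations[corpus_annotations.status == "active"]
    checked = 0
    for gid, row in act.iterrows():
        detected = row["domains"]
        assert detected is not None
        truth = {lab: (s, e) for lab, s, e in corpus.domain_truth[gid].segments}
        for lab, s, e in detected.segments:
            assert abs(s - truth[lab][0]) <= BOUNDARY_TOL_AA
            assert abs(e - truth[lab][1]) <= BOUNDARY_TOL_AA
            checked += 1
    assert checked > 150
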