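"""The synthetic-corpus generator: determinism, families, planted facts."""
from __future__ import annotations

import numpy as np
import pytest

from gliadin_atlas.align import pairwise_identity
from gliadin_atlas.loci import assign_all_spots
from gliadin_atlas.synthetic import (
    GeneratorConfig,
    make_corpus,
    make_family,
    make_skeleton,
    published_composition,
)


def test_composition_matches_study_design():
    members = published_composition()
    assert len(members) == 52
    active = [m for m in members if m.status == "active"]
    assert len(active) == 42
    by_type = {}
    for m in active:
        by_type[m.type] = by_type.get(m.type, 0) + 1
    assert by_type == {"alpha": 25, "gamma": 11, "delta": 1, "omega": 5}
    alphas = [m for m in active if m.type == "alpha"]
    assert sum(1 for m in alphas if m.subtype == "CT") == 13
    assert sum(1 for m in alphas if m.subtype == "CSTT") == 12
    pseudo = [m for m in members if m.status == "pseudogene"]
    p_types = sorted(m.type for m in pseudo)
    assert p_types == ["alpha"] * 7 + ["gamma"] * 2 + ["omega"]
    assert sum(1 for m in members if m.accumulated) == 38


def test_corpus_is_deterministic_per_seed(tmp_path):
    a = make_corpus(GeneratorConfig(seed=123))
    b = make_corpus(GeneratorConfig(seed=123))
    assert [t.sequence for t in a.transcripts] == [t.sequence for t in b.transcripts]
    assert {g: p.sequence for g, p in a.proteins.items()} == {
        g: p.sequence for g, p in b.proteins.items()
    }
    a.write(tmp_path / "x")
    b.write(tmp_path / "y")
    for f in sorted((tmp_path / "x").iterdir()):
        assert f.read_bytes() == (tmp_path / "y" / f.name).read_bytes()


def test_different_seeds_differ():
    a = make_corpus(GeneratorConfig(seed=1))
    b = make_corpus(GeneratorConfig(seed=2))
    assert [t.sequence for t in a.transcripts] != [t.sequence for t in b.transcripts]


def test_skeleton_lengths_respect_band(profiles):
    rng = np.random.default_rng(2)
    for profile in profiles:
        for _ in range(5):
            subtype = "omega5" if profile.type == "omega" else "none"
            protein, truth = make_skeleton(profile.type, profile, rng, subtype=subtype)
            mature = len(protein.sequence) - profile.signal_peptide_len
            lo, hi = profile.mature_length_band
            assert lo <= mature <= hi
            spans = truth["spans"]
            assert spans["SP"] == (1, 20)
            assert spans[list(spans)[-1]][1] == len(protein.sequence)


def test_family_identity_calibration(alpha_profile):
    rng = np.random.default_rng(6)
    members = make_family("alpha", 4, 0.90, rng, profile=alpha_profile)
    idents = [
        pairwise_identity(members[i][0], members[j][0])
        for i in range(4)
        for j in range(i + 1, 4)
    ]
    assert 88.0 <= float(np.mean(idents)) <= 92.0


def test_family_target_one_gives_duplicates(gamma_profile):
    rng = np.random.default_rng(8)
    members = make_family("gamma", 2, 1.0, rng, profile=gamma_profile)
    assert pairwise_identity(members[0][0], members[1][0]) == 100.0


def test_family_preserves_conserved_cysteines(gamma_profile):
    rng = np.random.default_rng(13)
    members = make_family("gamma", 5, 0.85, rng, profile=gamma_profile)
    counts = {m[0].sequence.count("C") for m in members}
    assert counts == {8}


def test_matrix_conservation_and_planted_loci(corpus):
    matrix = corpus.matrix
    wt = matrix.present[matrix.wild_type]
    assert wt.all()  # every spot present in wild type
    assignments = assign_all_spots(matrix)
    truth_locus = corpus.gene_locus()
    per_locus: dict[str, int] = {}
    for spot, gene in corpus.spot_truth.items():
        a = assignments[spot]
        assert a.locus == truth_locus[gene]
        per_locus[a.locus] = per_locus.get(a.locus, 0) + 1
    mixtures = [s for s, a in assignments.items() if a.reason == "mixture"]
    assert len(mixtures) == corpus.config.n_mixture_spots
    assert sum(per_locus.values()) + len(mixtures) == len(matrix.spots)


def test_truth_table_is_complete(corpus):
    truth = corpus.truth
    assert len(truth) == 52
    assert set(truth.loc[truth.status == "active", "gene_id"]) == set(corpus.proteins)
    assert (truth.loc[truth.status == "pseudogene", "defect"] != "none").all()


def test_identical_paralog_pair(corpus):
    """The corpus contains a 100%-identical gamma protein pair whose coding
    regions differ only by synonymous substitutions."""
    g2, g3 = corpus.proteins["Gli-g2"], corpus.proteins["Gli-g3"]
    assert pairwise_identity(g2, g3) == 100.0
    t = {tr.id: tr.sequence for tr in corpus.transcripts}
    assert t["Gli-g2"] != t["Gli-g3"]
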