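"""Spot -> gene matching decision rule."""
from __future__ import annotations

import numpy as np
import pytest

from gliadin_atlas.digest import DigestParams, build_peptide_index
from gliadin_atlas.match import (
    EVIDENCE_COVERAGE,
    EVIDENCE_NMF,
    EVIDENCE_UNIQUE,
    SpotObservation,
    equivalence_groups,
    match_spot,
)
from gliadin_atlas.records import ProteinRecord
from gliadin_atlas.synthetic import simulate_spots
from gliadin_atlas.digest import DEFAULT_ENZYMES

NO_FILTER = DigestParams(max_missed=2, mass_min_da=0.0, mass_max_da=1e9, min_len_aa=1)


@pytest.fixture(scope="module")
def toy_db():
    return [
        ProteinRecord("g1", "AGFAGYAGLKKFMNPQRSTV"),
        ProteinRecord("g2", "AGFAGYAGLKRFMNPQRSTV"),  # 1 aa from g1
        ProteinRecord("g3", "CCCDDDEEEFFFGGGHHHII"),
    ]


@pytest.fixture(scope="module")
def toy_index(toy_db):
    return build_peptide_index(toy_db, params=NO_FILTER)


def test_unique_peptide_wins(toy_db, toy_index):
    obs = [SpotObservation("s1", "chymotrypsin", ["AGLKKF", "AGF"])]
    result = match_spot(obs, toy_db, toy_index, params=NO_FILTER)
    assert result.matched_ids == ["g1"]
    assert result.evidence == EVIDENCE_UNIQUE


def test_identical_proteins_form_one_equivalence_group():
    db = [
        ProteinRecord("g2", "AGFAGYAGLKKF"),
        ProteinRecord("g3", "AGFAGYAGLKKF"),
        ProteinRecord("g4", "CCCDDDEEEFFF"),
    ]
    groups = equivalence_groups(db, params=NO_FILTER)
    assert ("g2", "g3") in groups
    index = build_peptide_index(db, params=NO_FILTER)
    obs = [SpotObservation("s", "chymotrypsin", ["AGFAGY"])]
    result = match_spot(obs, db, index, params=NO_FILTER)
    assert result.matched_ids == ["g2", "g3"]
    assert result.equivalence_group


def test_foreign_peptides_yield_nmf(toy_db, toy_index):
    obs = [SpotObservation("s", "chymotrypsin", ["WWWWWW"])]
    result = match_spot(obs, toy_db, toy_index, params=NO_FILTER)
    assert result.evidence == EVIDENCE_NMF
    assert result.matched_ids == []


def test_empty_observation_warns_and_returns_nmf(toy_db, toy_index):
    with pytest.warns(UserWarning):
        result = match_spot(
            [SpotObservation("s", "chymotrypsin", [])], toy_db, toy_index,
            params=NO_FILTER,
        )
    assert result.evidence == EVIDENCE_NMF


def test_coverage_fallback_when_no_unique_peptide():
    db = [ProteinRecord("g1", "AGFAGYAGLKKF"), ProteinRecord("g2", "AGFAGYAGLKKF")]
    db.append(ProteinRecord("g3", "MNPVTSTVMNPV"))
    index = build_peptide_index(db, params=NO_FILTER)
    obs = [SpotObservation("s", "chymotrypsin", ["AGFAGY", "AGL"])]
    result = match_spot(obs, db, index, min_unique=3, params=NO_FILTER)
    assert result.evidence == EVIDENCE_COVERAGE
    assert result.matched_ids == ["g1", "g2"]


def test_noisy_simulation_recovers_generating_gene(corpus, corpus_truth):
    """At detection 0.6 / contamination 0.05 the generating gene (or its
    equivalence group) is recovered for >= 95% of simulated spots."""
    from gliadin_atlas.pipeline import match_all_spots

    rng = np.random.default_rng(99)
    acc = {
        g: corpus.proteins[g]
        for g in sorted(corpus.proteins)
        if corpus_truth.accumulated[g]
    }
    obs, truth = simulate_spots(
        acc, DEFAULT_ENZYMES, DigestParams(), 0.6, 0.05, rng,
        {g: 2 for g in acc},
    )
    results = match_all_spots(obs, list(acc.values()))
    ok = sum(1 for r in results if truth[r.spot_id] in r.matched_ids)
    assert ok / len(results) >= 0.95
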