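"""In-silico digestion, peptide indexing and coverage."""
from __future__ import annotations

import numpy as np
import pytest

from gliadin_atlas.digest import (
    CHYMOTRYPSIN,
    THERMOLYSIN,
    DigestParams,
    build_peptide_index,
    coverage,
    digest,
)
from gliadin_atlas.errors import InputError
from gliadin_atlas.masses import peptide_mass
from gliadin_atlas.records import ProteinRecord

from oracles import chymotrypsin_sites, digest_fragments, thermolysin_sites

NO_FILTER = DigestParams(max_missed=2, mass_min_da=0.0, mass_max_da=1e9, min_len_aa=1)


def test_chymotryptic_peptides_of_agfagy():
    peps = digest(ProteinRecord("p", "AGFAGY"), CHYMOTRYPSIN, NO_FILTER)
    assert {p.sequence for p in peps} == {"AGF", "AGY", "AGFAGY"}


def test_proline_blocks_chymotrypsin():
    peps = digest(ProteinRecord("p", "AGFPGY"), CHYMOTRYPSIN, NO_FILTER)
    assert {p.sequence for p in peps} == {"AGFPGY"}


@pytest.mark.parametrize(
    "enzyme,site_fn",
    [(CHYMOTRYPSIN, chymotrypsin_sites), (THERMOLYSIN, thermolysin_sites)],
)
def test_digest_matches_bruteforce_enumeration(enzyme, site_fn):
    rng = np.random.default_rng(17)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(100):
        seq = "".join(rng.choice(aa, size=int(rng.integers(20, 120))))
        params = DigestParams(
            max_missed=int(rng.integers(0, 3)),
            mass_min_da=300.0,
            mass_max_da=6000.0,
            min_len_aa=1,
        )
        got = {p.sequence for p in digest(ProteinRecord("p", seq), enzyme, params)}
        want = digest_fragments(
            seq, site_fn(seq), params.max_missed, peptide_mass,
            params.mass_min_da, params.mass_max_da, params.min_len_aa,
        )
        assert got == want


def test_zero_missed_peptides_reconstruct_protein():
    rng = np.random.default_rng(23)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    params = DigestParams(max_missed=0, mass_min_da=0.0, mass_max_da=1e9, min_len_aa=1)
    for _ in range(25):
        seq = "".join(rng.choice(aa, size=int(rng.integers(30, 150))))
        protein = ProteinRecord("p", seq)
        for enzyme in (CHYMOTRYPSIN, THERMOLYSIN):
            peps = digest(protein, enzyme, params)
            placed = sorted(
                (span, p.sequence) for p in peps for span in p.spans["p"]
            )
            assert "".join(frag for _, frag in placed) == seq


def test_index_on_identical_proteins_has_no_unique_peptide():
    db = [ProteinRecord("a", "AGFAGYAGL"), ProteinRecord("b", "AGFAGYAGL")]
    index = build_peptide_index(db, params=NO_FILTER)
    assert index
    assert all(parents == {"a", "b"} for parents in index.values())


def test_single_protein_db_is_all_unique():
    index = build_peptide_index([ProteinRecord("a", "AGFAGYAGL")], params=NO_FILTER)
    assert all(parents == {"a"} for parents in index.values())


def test_point_difference_localizes_unique_peptides():
    a = "AGFAGYAGLKKF"
    b = "AGFAGYAGLKRF"  # differs at position 11
    db = [ProteinRecord("a", a), ProteinRecord("b", b)]
    index = build_peptide_index(db, params=NO_FILTER)
    for pep, parents in index.items():
        in_a, in_b = pep in a, pep in b
        if in_a and in_b:
            assert parents == {"a", "b"}
        else:
            assert len(parents) == 1


def test_duplicate_ids_rejected():
    with pytest.raises(InputError):
        build_peptide_index([ProteinRecord("a", "AGF"), ProteinRecord("a", "AGY")])


def test_coverage_bounds_and_examples():
    protein = ProteinRecord("p", "A" * 30)
    assert coverage(protein, [protein.sequence]) == 1.0
    assert coverage(protein, []) == 0.0
    # overlapping peptides covering residues 1-10 and 6-15 of a 30-mer
    seq = "ACDEFGHIKLMNPQRSTVWY" + "YWVTSRQPNM"
    two = ProteinRecord("p", seq)
    assert coverage(two, [seq[0:10], seq[5:15]]) == pytest.approx(15 / 30)


def test_coverage_monotone_in_observed_peptides():
    rng = np.random.default_rng(31)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    seq = "".join(rng.choice(aa, size=120))
    protein = ProteinRecord("p", seq)
    peps = [seq[i : i + 8] for i in range(0, 100, 7)]
    prev = 0.0
    for k in range(len(peps) + 1):
        cov = coverage(protein, peps[:k])
        assert cov >= prev
        assert 0.0 <= cov <= 1.0
        prev = cov
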