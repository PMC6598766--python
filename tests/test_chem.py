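"""Structure handling: standardisation, fingerprints, similarity, scaffolds."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from zfscreen.chem import (
    Fingerprint,
    StructureParseError,
    bemis_murcko_scaffold,
    compute_fingerprint,
    find_duplicates,
    make_compound,
    scaffold_summary,
    similarity_matrix,
    standardize_structure,
    tanimoto,
)

from conftest import compound


class TestStandardize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("CCO", "CCO"),
            ("CCO.Cl", "CCO"),          # largest organic fragment survives
            ("OCC", "CCO"),             # atom-order variants collapse
            ("[Na+].CC(=O)[O-]", "CC(=O)O"),  # salt stripped, charge neutralised
        ],
    )
    def test_examples(self, raw, expected):
        assert standardize_structure(raw) == expected

    def test_idempotent_on_varied_structures(self, drug_compounds):
        for c in drug_compounds:
            once = standardize_structure(c.smiles)
            assert standardize_structure(once) == once

    def test_unparseable_raises_with_offender(self):
        with pytest.raises(StructureParseError) as err:
            standardize_structure("not-a-molecule((")
        assert "not-a-molecule" in str(err.value)


class TestFingerprint:
    def test_same_molecule_same_bits(self):
        assert compute_fingerprint("CCO") == compute_fingerprint("OCC")

    def test_aromatic_vs_aliphatic_ring_differ(self):
        assert compute_fingerprint("c1ccccc1") != compute_fingerprint("C1CCCCC1")

    def test_nonempty_and_in_range(self, drug_compounds):
        for c in drug_compounds:
            fp = compute_fingerprint(c.smiles)
            assert fp.bits
            assert all(0 <= b < fp.n_bits for b in fp.bits)


class TestTanimoto:
    def test_hand_computed_overlap(self):
        a = Fingerprint(frozenset({1, 2, 3}))
        b = Fingerprint(frozenset({2, 3, 4}))
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_disjoint_is_zero_identical_is_one(self):
        a = Fingerprint(frozenset({1, 2}))
        b = Fingerprint(frozenset({3, 4}))
        assert tanimoto(a, b) == 0.0
        assert tanimoto(a, a) == 1.0

    def test_both_empty_defined_as_zero(self):
        e = Fingerprint(frozenset())
        assert tanimoto(e, e) == 0.0

    @given(
        st.sets(st.integers(0, 255), max_size=40),
        st.sets(st.integers(0, 255), max_size=40),
    )
    def test_symmetry_and_bounds(self, sa, sb):
        a, b = Fingerprint(frozenset(sa), 256), Fingerprint(frozenset(sb), 256)
        t = tanimoto(a, b)
        assert 0.0 <= t <= 1.0
        assert t == tanimoto(b, a)
        if sa:
            assert tanimoto(a, a) == 1.0


class TestSimilarityMatrix:
    def test_matches_rdkit_bulk_oracle(self, small_library):
        compounds = small_library[0][:50]
        m = similarity_matrix(compounds)
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        fps = [gen.GetFingerprint(Chem.MolFromSmiles(c.smiles)) for c in compounds]
        for i in range(len(fps)):
            for j in range(len(fps)):
                expected = (
                    DataStructs.TanimotoSimilarity(fps[i], fps[j]) if i != j else 1.0
                )
                assert m.values[i, j] == pytest.approx(expected)
        assert np.allclose(m.values, m.values.T)

    def test_single_and_duplicate(self):
        one = [compound("a", "CCO")]
        assert similarity_matrix(one).values.tolist() == [[1.0]]
        two = [compound("a", "CCO"), compound("b", "OCC")]
        assert similarity_matrix(two).values[0, 1] == 1.0

    def test_unparseable_compound_named_in_error(self):
        bad = [compound("ok", "CCO"), compound("broken", "xx((")]
        with pytest.raises(StructureParseError) as err:
            similarity_matrix(bad)
        assert "broken" in str(err.value)


class TestScaffolds:
    @pytest.mark.parametrize(
        "smiles,scaffold",
        [
            ("Cc1ccccc1", "c1ccccc1"),                  # side chain pruned
            ("CCO", ""),                                # acyclic
            ("c1ccccc1CCc1ccccc1", "c1ccc(CCc2ccccc2)cc1"),  # linker retained
        ],
    )
    def test_hand_pruned_examples(self, smiles, scaffold):
        assert bemis_murcko_scaffold(smiles) == scaffold

    def test_summary_counts(self):
        shared = [
            compound("tol", "Cc1ccccc1"),
            compound("etb", "CCc1ccccc1"),
            compound("phe", "Oc1ccccc1"),
        ]
        s = scaffold_summary(shared)
        assert (s.n_scaffolds, s.n_singleton_scaffolds) == (1, 0)
        mixed = [compound("tol", "Cc1ccccc1"), compound("chx", "OC1CCCCC1")]
        s2 = scaffold_summary(mixed)
        assert (s2.n_scaffolds, s2.n_singleton_scaffolds) == (2, 2)
        empty = scaffold_summary([])
        assert (empty.n_compounds, empty.n_scaffolds, empty.n_acyclic) == (0, 0, 0)

    def test_membership_conservation(self, small_library):
        compounds = small_library[0]
        s = scaffold_summary(compounds)
        n_members = sum(len(v) for v in s.scaffold_to_members.values())
        assert n_members + s.n_acyclic == s.n_compounds
        assert s.n_singleton_scaffolds <= s.n_scaffolds


class TestDuplicates:
    def test_spelling_variants_match_enantiomers_do_not(self):
        lib_a = [
            compound("a1", "N[C@@H](C)C(=O)O"),  # L-alanine
            compound("a2", "CCO"),
        ]
        lib_b = [
            compound("b1", "N[C@H](C)C(=O)O"),   # D-alanine: stereo layer differs
            compound("b2", "OCC"),               # ethanol spelled differently
        ]
        assert find_duplicates(lib_a, lib_b) == [("a2", "b2")]

    def test_disjoint_libraries(self):
        assert find_duplicates([compound("a", "CCO")], [compound("b", "CCN")]) == []

    def test_matches_bruteforce_all_pairs(self, small_library):
        compounds, _ = small_library
        lib_a = [c for c in compounds if c.library_id == "T"]
        lib_b = [c for c in compounds if c.library_id == "S"]
        expected = sorted(
            (a.compound_id, b.compound_id)
            for a in lib_a
            for b in lib_b
            if a.identity_key is not None and a.identity_key == b.identity_key
        )
        assert sorted(find_duplicates(lib_a, lib_b)) == expected
        assert len(expected) >= 2  # the generator planted cross-library copies

    def test_null_identity_key_skipped(self):
        broken = make_compound("x", "T", "T01", "B02", "x", "((bad")
        assert broken.identity_key is None
        assert find_duplicates([broken], [compound("b", "CCO")]) == []
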