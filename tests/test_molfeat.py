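"""Featurization: ring perception, group counting, conjugation, assembly."""

import numpy as np
import pytest
from rdkit import Chem

from ccspec import molfeat
from ccspec.molfeat import (
    DESCRIPTOR_LENGTH,
    assemble_descriptor_vector,
    conjugation_descriptors,
    count_groups,
    classify_ring_systems,
    electronic_descriptors,
    featurize,
    parse_molecule,
)
from conftest import GOLDEN_A, GOLDEN_B, GOLDEN_COUNTS, GOLDEN_SMILES


class TestParseMolecule:
    @pytest.mark.parametrize(
        "smiles, n_aromatic, n_systems",
        [("c1ccccc1", 6, 1), ("C", 0, 0), ("c1ccc2ccccc2c1", 10, 1)],
    )
    def test_ring_perception(self, smiles, n_aromatic, n_systems):
        g = parse_molecule(smiles)
        assert g.n_aromatic_atoms == n_aromatic
        assert len(g.ring_systems) == n_systems

    def test_naphthalene_is_one_two_fused_system_of_10_atoms(self):
        g = parse_molecule("c1ccc2ccccc2c1")
        (sys,) = g.ring_systems
        assert sys.kind == "two_fused"
        assert len(sys.atoms) == 10

    def test_unparsable_smiles_names_offender(self):
        with pytest.raises(ValueError, match="not-a-smiles"):
            parse_molecule("not-a-smiles")

    def test_every_aromatic_atom_in_exactly_one_system(self, smiles_corpus):
        for smi in smiles_corpus:
            g = parse_molecule(smi)
            counts = {}
            for s in g.ring_systems:
                for a in s.atoms:
                    counts[a] = counts.get(a, 0) + 1
            for atom in g.mol.GetAtoms():
                if atom.GetIsAromatic():
                    assert counts.get(atom.GetIdx()) == 1, smi


class TestRingSystemClassification:
    def test_hydroquinone_para(self):
        g = parse_molecule("Oc1ccc(O)cc1")
        (sys,) = classify_ring_systems(g)
        assert sys.kind == "isolated"
        assert sys.substituent_positions == ("para",)

    def test_26_disubstituted_naphthalene_both_beta(self):
        g = parse_molecule("Cc1ccc2cc(C)ccc2c1")
        (sys,) = classify_ring_systems(g)
        assert sys.kind == "two_fused"
        assert sys.substituent_positions == ("beta", "beta")

    def test_benzene_no_substituents(self):
        g = parse_molecule("c1ccccc1")
        (sys,) = classify_ring_systems(g)
        assert sys.kind == "isolated"
        assert sys.substituent_positions == ()

    def test_anthracene_linear_three_fused(self):
        g = parse_molecule("c1ccc2cc3ccccc3cc2c1")
        (sys,) = classify_ring_systems(g)
        assert sys.kind == "three_fused"

    def test_9_substituted_anthracene_gamma(self):
        g = parse_molecule("Cc1c2ccccc2cc2ccccc12")
        (sys,) = classify_ring_systems(g)
        assert sys.kind == "three_fused"
        assert sys.substituent_positions == ("gamma",)

    def test_nonlinear_fusion_unsupported_goes_to_other(self):
        g = parse_molecule("c1ccc2ccc3ccccc3c2c1")  # phenanthrene
        (sys,) = classify_ring_systems(g)
        assert sys.kind == "unsupported"
        gv = count_groups(g)
        assert gv["Other groups"] == 14


class TestCountGroups:
    def test_worked_example_counts(self):
        g = parse_molecule(GOLDEN_SMILES)
        gv = count_groups(g)
        for key, expected in GOLDEN_COUNTS.items():
            assert gv[key] == expected, key
        # nothing else is set
        assert gv.nonzero() == {k: v for k, v in GOLDEN_COUNTS.items() if v}

    def test_hydroquinone(self):
        gv = count_groups(parse_molecule("Oc1ccc(O)cc1"))
        assert gv["-OH(ph)"] == 2
        assert gv["N1(para-)"] == 1
        assert gv[">C=(Ring)"] == 2
        assert gv["-CH=(Ring)"] == 4

    def test_methane_overflows(self):
        gv = count_groups(parse_molecule("C"))
        assert gv["Other groups"] == 1
        assert gv.counts.sum() == 1

    def test_counts_non_negative_and_conservation(self, smiles_corpus):
        for smi in smiles_corpus:
            g = parse_molecule(smi)
            gv = count_groups(g)
            assert (gv.counts >= 0).all(), smi
            # every heavy atom attributed exactly once
            assert sorted(gv.attribution) == list(range(g.n_atoms)), smi

    def test_ph_and_plain_variant_disjoint_per_instance(self, smiles_corpus):
        pairs = [("-OH", "-OH(ph)"), ("-NH2", "-NH2(ph)"), ("-Cl", "-Cl(ph)")]
        for smi in smiles_corpus:
            gv = count_groups(parse_molecule(smi))
            for plain, ph in pairs:
                n_anchor = sum(
                    1 for v in gv.attribution.values() if v in (plain, ph)
                )
                # each instance was attributed to exactly one of the variants
                assert n_anchor >= gv[plain] + gv[ph]

    def test_biphenyl_ar_ar(self):
        gv = count_groups(parse_molecule("c1ccc(-c2ccccc2)cc1"))
        assert gv["Ar-Ar"] == 1

    def test_stilbene_bridge(self):
        gv = count_groups(parse_molecule("C(=C/c1ccccc1)\\c1ccccc1"))
        assert gv[">C=C<(1)"] == 1
        assert gv[">C=C<(2)"] == 0

    def test_styrene_bridge(self):
        gv = count_groups(parse_molecule("C=Cc1ccccc1"))
        assert gv[">C=C<(2)"] == 1


class TestConjugation:
    @pytest.mark.parametrize(
        "smiles, a, b",
        [
            ("c1ccccc1", 3, 3),
            ("C=CC=C", 2, 2),
            ("CC", 0, 0),
            ("C=C", 0, 0),  # an isolated double bond is not conjugated
            ("c1ccc(-c2ccccc2)cc1", 6, 6),
        ],
    )
    def test_examples(self, smiles, a, b):
        cd = conjugation_descriptors(parse_molecule(smiles))
        assert (cd.A, cd.B) == (a, b)

    def test_b_le_a_over_corpus(self, smiles_corpus):
        for smi in smiles_corpus:
            cd = conjugation_descriptors(parse_molecule(smi))
            assert 0 <= cd.B <= cd.A, smi


class TestElectronicBlock:
    def test_spelling_invariance(self):
        a = electronic_descriptors(parse_molecule("c1ccccc1O"))
        b = electronic_descriptors(parse_molecule("Oc1ccccc1"))
        np.testing.assert_array_equal(a, b)

    def test_non_degenerate(self):
        a = electronic_descriptors(parse_molecule("C"))
        b = electronic_descriptors(parse_molecule("CC"))
        assert not np.array_equal(a, b)

    def test_benzene_has_no_heteroatom_estate(self):
        g = parse_molecule("c1ccccc1")
        vals = electronic_descriptors(g)
        # TPSA and H-bond donor/acceptor counts vanish for a pure hydrocarbon
        names = list(molfeat.ELECTRONIC_DESCRIPTORS)
        assert vals[names.index("TPSA")] == 0.0
        assert vals[names.index("NumHDonors")] == 0.0
        assert vals[names.index("NumHAcceptors")] == 0.0


class TestAssembly:
    def test_length_and_blocks(self):
        d = featurize("c1ccccc1", solvent_polarity=0.5)
        assert d.values.shape == (DESCRIPTOR_LENGTH,)
        assert d.values[-1] == 0.5
        np.testing.assert_array_equal(
            d.block("group"), count_groups(parse_molecule("c1ccccc1")).as_array()
        )

    def test_electronic_length_mismatch_raises(self):
        g = parse_molecule("C")
        with pytest.raises(ValueError, match="electronic block"):
            assemble_descriptor_vector(
                count_groups(g), conjugation_descriptors(g), np.zeros(5), 0.0
            )

    def test_featurization_is_spelling_invariant(self, smiles_corpus):
        for smi in smiles_corpus[:20]:
            alt = Chem.MolToSmiles(
                Chem.MolFromSmiles(smi), canonical=False, doRandom=False
            )
            np.testing.assert_array_equal(
                featurize(smi, 0.3).values, featurize(alt, 0.3).values
            )

    def test_worked_example_vector_matches_printed_counts(self):
        d = featurize(GOLDEN_SMILES, solvent_polarity=1.0)
        names = molfeat.descriptor_names()
        for key, expected in GOLDEN_COUNTS.items():
            assert d.values[names.index(key)] == expected
        assert d.values[names.index("A(conj_total)")] == GOLDEN_A
        assert d.values[names.index("B(conj_largest)")] == GOLDEN_B


class TestSolventLookup:
    def test_required_solvents_present(self):
        table = molfeat.solvent_polarity_table()
        names = set(table.iloc[:, 0])
        assert {"Water", "DMF", "Acetone", "Ethanol", "Toluene"} <= names

    def test_lookup_and_passthrough(self):
        assert molfeat.lookup_solvent_polarity("water") == 1.0
        assert molfeat.lookup_solvent_polarity(0.42) == 0.42
        with pytest.raises(KeyError):
            molfeat.lookup_solvent_polarity("unobtainium")
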