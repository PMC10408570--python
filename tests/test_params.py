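"""SMIRKS library I/O, chemical-perception assignment, validation."""

import numpy as np
import pytest

from deff.params import (
    AssignmentError,
    LibraryParseError,
    MolecularGraph,
    ParameterLibrary,
    SmirksRecord,
    assign_parameters,
    load_library,
    save_library,
    validate_library,
    _unsafe_library,
    _unsafe_record,
)
from deff.potentials import GlobalShape, PairParams


def minimal_library():
    return ParameterLibrary(
        records=[
            SmirksRecord("[#1:1]", PairParams(0.015, 2.9), "H-gen"),
            SmirksRecord("[#1:1]-[#8]", PairParams(0.0, 1.0), "H-polar"),
            SmirksRecord("[#6X4:1]", PairParams(0.1, 3.8), "C"),
            SmirksRecord("[#8:1]", PairParams(0.2, 3.4), "O"),
        ],
        shape=GlobalShape(16.766, 4.427),
    )


class TestLibraryIO:
    def test_round_trip_identity(self, tmp_path, library):
        path = tmp_path / "ff.xml"
        save_library(library, path)
        lib2 = load_library(path)
        assert len(lib2.records) == len(library.records)
        for a, b in zip(library.records, lib2.records):
            assert a.smirks == b.smirks and a.label == b.label
            assert a.params.epsilon == b.params.epsilon
            assert a.params.r_m == b.params.r_m
        assert lib2.shape == library.shape
        assert lib2.scale14_vdw == library.scale14_vdw
        assert lib2.scale14_elec == library.scale14_elec
        assert lib2.vsites == library.vsites

    def test_order_preserved(self, tmp_path, library):
        path = tmp_path / "ff.xml"
        save_library(library, path)
        labels = [r.label for r in load_library(path).records]
        assert labels == [r.label for r in library.records]

    def test_missing_global_shape_rejected(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<DEForceField><DoubleExponential/></DEForceField>")
        with pytest.raises(LibraryParseError, match="GlobalShape"):
            load_library(path)

    def test_malformed_xml_rejected(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<DEForceField><unclosed>")
        with pytest.raises(LibraryParseError):
            load_library(path)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(LibraryParseError, match="duplicate"):
            ParameterLibrary(
                records=[
                    SmirksRecord("[#1:1]", PairParams(0.1, 2.0), "X"),
                    SmirksRecord("[#6:1]", PairParams(0.1, 3.0), "X"),
                ],
                shape=GlobalShape(10.0, 4.0),
            )


class TestSmirksRecord:
    def test_needs_exactly_one_tagged_atom(self):
        with pytest.raises(LibraryParseError, match="exactly one"):
            SmirksRecord("[#1]", PairParams(0.1, 2.0), "untagged")
        with pytest.raises(LibraryParseError, match="exactly one"):
            SmirksRecord("[#1:1]-[#6:1]", PairParams(0.1, 2.0), "double")

    def test_unparseable_pattern(self):
        with pytest.raises(LibraryParseError):
            SmirksRecord("[#1:1](((", PairParams(0.1, 2.0), "bad")


class TestAssignment:
    def test_ethanol_last_match_wins(self, ethanol):
        params, labels = assign_parameters(ethanol, minimal_library())
        by_element = {}
        for el, lab in zip(ethanol.elements, labels):
            by_element.setdefault(el, set()).add(lab)
        assert by_element["C"] == {"C"}
        assert by_element["O"] == {"O"}
        # hydroxyl H refined to the polar record, the 5 C-H stay generic
        assert by_element["H"] == {"H-gen", "H-polar"}
        assert labels.count("H-polar") == 1
        assert labels.count("H-gen") == 5

    def test_polar_hydrogen_has_no_vdw(self, ethanol):
        params, labels = assign_parameters(ethanol, minimal_library())
        i = labels.index("H-polar")
        assert params[i].epsilon == 0.0

    def test_bromine_record_matches(self, library):
        mol = MolecularGraph.from_smiles("Brc1ccccc1")
        params, labels = assign_parameters(mol, library)
        br = mol.elements.index("Br")
        assert labels[br] == "Br"

    def test_unparameterised_element_rejected(self):
        mol = MolecularGraph.from_smiles("CP")  # P has no record
        with pytest.raises(AssignmentError, match="P"):
            assign_parameters(mol, minimal_library())

    def test_permutation_invariance(self, ethanol):
        params, labels = assign_parameters(ethanol, minimal_library())
        n = ethanol.n_atoms
        rng = np.random.default_rng(7)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        remap = {int(old): int(new) for new, old in enumerate(perm)}
        permuted = MolecularGraph(
            elements=[ethanol.elements[i] for i in perm],
            formal_charges=[ethanol.formal_charges[i] for i in perm],
            partial_charges=ethanol.partial_charges[perm],
            bonds=[(remap[i], remap[j], o) for i, j, o in ethanol.bonds],
        )
        p2, l2 = assign_parameters(permuted, minimal_library())
        assert [l2[remap[i]] for i in range(n)] == labels


class TestValidation:
    def test_valid_library_clean(self, library):
        assert validate_library(library) == []

    def test_invalid_shape_flagged(self):
        lib = _unsafe_library([], 4.0, 16.0)
        codes = {i["code"] for i in validate_library(lib)}
        assert "invalid_shape" in codes

    def test_negative_epsilon_flagged(self):
        lib = _unsafe_library([_unsafe_record("[#1:1]", -0.1, 2.0, "bad")], 16.0, 4.0)
        codes = {i["code"] for i in validate_library(lib)}
        assert "negative_epsilon" in codes

    def test_nonpositive_rm_flagged(self):
        lib = _unsafe_library([_unsafe_record("[#1:1]", 0.1, 0.0, "bad")], 16.0, 4.0)
        codes = {i["code"] for i in validate_library(lib)}
        assert "nonpositive_r_m" in codes


class TestMolecularGraph:
    def test_charge_sum_invariant(self):
        with pytest.raises(ValueError, match="sum"):
            MolecularGraph(["O", "H"], [0, 0], np.array([0.5, 0.1]), [(0, 1, 1.0)])

    def test_sdf_round_trip_charges(self, tmp_path):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles("CO"))
        AllChem.EmbedMolecule(mol, randomSeed=3)
        charges = np.linspace(-0.3, 0.3, mol.GetNumAtoms())
        charges -= charges.mean()
        mol.SetProp("PartialCharges", " ".join(f"{q:.6f}" for q in charges))
        path = tmp_path / "mol.sdf"
        with Chem.SDWriter(str(path)) as w:
            w.write(mol)
        graph = MolecularGraph.from_sdf(path)
        assert graph.n_atoms == mol.GetNumAtoms()
        np.testing.assert_allclose(graph.partial_charges, charges, atol=1e-6)
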