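"""Geometry module: XYZ I/O, bond perception, donor classification, pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chelastab.atomdata import covalent_radius
from chelastab.errors import (
    EmptySelectionError,
    MultipleMetalAtomsError,
    NoMetalAtomError,
    StructureMismatchError,
    XYZFormatError,
)
from chelastab.geometry import (
    ComplexStructure,
    bond_graph,
    classify_donors,
    distance_stats,
    pair_contacts,
    read_xyz,
    write_xyz,
)


class TestReadXYZ:
    def test_minimal_valid_file(self, xyz_file):
        s = read_xyz(xyz_file)
        assert s.n_atoms == 3
        assert s.metal_index == 0 and s.metal_symbol == "La"
        np.testing.assert_allclose(s.coords[1], [2.5, 0, 0])

    def test_no_metal_is_distinct_error(self, tmp_path):
        p = tmp_path / "x.xyz"
        p.write_text("1\nno metal\nO 0 0 0\n")
        with pytest.raises(NoMetalAtomError):
            read_xyz(p)

    def test_multiple_metals_is_distinct_error(self, tmp_path):
        p = tmp_path / "x.xyz"
        p.write_text("2\ntwo\nLa 0 0 0\nAc 5 0 0\n")
        with pytest.raises(MultipleMetalAtomsError):
            read_xyz(p)

    @pytest.mark.parametrize(
        "body",
        [
            "nonsense\ncomment\nLa 0 0 0\n",             # malformed count
            "2\nshort\nLa 0 0 0\n",                        # missing atom line
            "1\nbad coord\nLa 0 zero 0\n",                 # non-numeric
        ],
    )
    def test_malformed_files(self, tmp_path, body):
        p = tmp_path / "bad.xyz"
        p.write_text(body)
        with pytest.raises(XYZFormatError):
            read_xyz(p)

    @settings(derandomize=True, max_examples=25)
    @given(
        coords=st.lists(
            st.tuples(*[st.floats(-50, 50, allow_nan=False) for _ in range(3)]),
            min_size=1,
            max_size=8,
        )
    )
    def test_roundtrip_preserves_coordinates(self, tmp_path_factory, coords):
        """write(read(f)) reproduces coordinates to 6 decimals, order kept."""
        tmp = tmp_path_factory.mktemp("rt")
        syms = ["La"] + ["O"] * (len(coords) - 1)
        s = ComplexStructure("rt", tuple(syms), np.array(coords), 0)
        p1, p2 = tmp / "a.xyz", tmp / "b.xyz"
        write_xyz(s, p1)
        s2 = read_xyz(p1)
        write_xyz(s2, p2)
        s3 = read_xyz(p2)
        np.testing.assert_allclose(s3.coords, s.coords, atol=5e-7)
        assert s3.symbols == s.symbols


class TestBondGraph:
    def test_oh_bond_and_distant_pair(self):
        s = ComplexStructure(
            "t", ("La", "O", "H", "O"),
            np.array([[9, 9, 9], [0, 0, 0], [0.96, 0, 0], [5, 0, 0]]), 0,
        )
        g = bond_graph(s)
        assert g.has_edge(1, 2)
        assert not g.has_edge(1, 3)
        assert 0 not in g  # metal excluded

    def test_agrees_with_exhaustive_pairwise_check(self):
        """Brute-force oracle: re-derive adjacency for random atom clouds."""
        rng = np.random.default_rng(42)
        elements = ["C", "N", "O", "H", "S"]
        for _ in range(10):
            n = 20
            syms = ("La",) + tuple(rng.choice(elements, n - 1))
            coords = rng.uniform(0, 6.0, size=(n, 3))
            s = ComplexStructure("cloud", syms, coords, 0)
            g = bond_graph(s, scale=1.3)
            for i in range(1, n):
                for j in range(i + 1, n):
                    d = np.linalg.norm(coords[i] - coords[j])
                    expect = d <= 1.3 * (covalent_radius(syms[i]) + covalent_radius(syms[j]))
                    assert g.has_edge(i, j) == expect


class TestClassifyDonors:
    def test_recovers_all_hand_built_classes(self, mixed_donor_complex):
        s, expected = mixed_donor_complex
        got = {c.atom_index: c.donor_class for c in classify_donors(s)}
        assert got == expected

    def test_invariant_under_rigid_motion(self, mixed_donor_complex):
        s, expected = mixed_donor_complex
        rng = np.random.default_rng(3)
        # random rotation (QR of a Gaussian matrix) plus translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = ComplexStructure(
            s.label, s.symbols, s.coords @ q.T + np.array([5.0, -3.0, 1.5]), 0
        )
        got = {c.atom_index: c.donor_class for c in classify_donors(moved)}
        assert got == expected

    def test_contacts_sorted_and_within_cutoff(self, mixed_donor_complex):
        s, _ = mixed_donor_complex
        cons = classify_donors(s, cutoff=3.1)
        idx = [c.atom_index for c in cons]
        assert idx == sorted(idx)
        assert all(0 < c.distance <= 3.1 for c in cons)


class TestPairContacts:
    def test_identity_pairing_gives_zero_deltas(self, mixed_donor_complex):
        s, _ = mixed_donor_complex
        pairs = pair_contacts(s, s)
        assert pairs and all(p.delta == 0.0 for p in pairs)

    def test_uniform_offset_recovered(self, mixed_donor_complex):
        """Radially displacing every donor by +0.06 A shifts every delta."""
        s, expected = mixed_donor_complex
        coords = s.coords.copy()
        for i in expected:  # donor atoms only; substituents follow rigidly
            u = coords[i] / np.linalg.norm(coords[i])
            grp = [j for j in range(s.n_atoms)
                   if j != 0 and np.linalg.norm(coords[j] - coords[i]) < 2.0] + [i]
            for j in set(grp):
                coords[j] = s.coords[j] + 0.06 * u
        cmp_ = ComplexStructure("mixed", ("Ac",) + s.symbols[1:], coords, 0)
        pairs = pair_contacts(s, cmp_)
        assert len(pairs) == len(expected)
        np.testing.assert_allclose([p.delta for p in pairs], 0.06, atol=1e-9)

    def test_element_mismatch_is_hard_failure(self, mixed_donor_complex):
        s, _ = mixed_donor_complex
        syms = list(s.symbols)
        syms[1] = "N"  # carboxylate O swapped for N
        bad = ComplexStructure("mixed", tuple(syms), s.coords, 0)
        with pytest.raises(StructureMismatchError):
            pair_contacts(s, bad, mode="by_index")

    def test_by_class_matches_by_rank_with_warning(self, mixed_donor_complex):
        s, expected = mixed_donor_complex
        with pytest.warns(UserWarning):
            pairs = pair_contacts(s, s, mode="by_class")
        assert len(pairs) == len(expected)
        assert all(p.delta == 0.0 for p in pairs)


class TestDistanceStats:
    def test_identical_records_give_zero(self):
        recs = [("A", "O_carboxylate", 2.5), ("A", "N_amine", 2.7)]
        out = distance_stats(recs, recs)
        assert out["overall"]["mean_abs_dev"] == 0.0
        assert out["overall"]["rmsd"] == 0.0

    def test_symmetric_deviations(self):
        calc = [("A", "O_water", 2.5), ("A", "O_water", 2.5)]
        expt = [("A", "O_water", 2.6), ("A", "O_water", 2.4)]
        out = distance_stats(calc, expt)
        assert out["overall"]["mean_abs_dev"] == pytest.approx(0.1)
        assert out["overall"]["rmsd"] == pytest.approx(0.1)

    def test_rmsd_at_least_mad(self):
        rng = np.random.default_rng(0)
        calc = [("A", "O_water", 2.5 + rng.normal(0, 0.05)) for _ in range(40)]
        expt = [("A", "O_water", 2.5) for _ in range(40)]
        out = distance_stats(calc, expt)
        assert out["overall"]["rmsd"] >= out["overall"]["mean_abs_dev"] >= 0

    def test_per_element_split(self):
        calc = [("A", "O_water", 2.52), ("A", "N_amine", 2.80)]
        expt = [("A", "O_water", 2.50), ("A", "N_amine", 2.70)]
        out = distance_stats(calc, expt)
        assert out["O"]["rmsd"] == pytest.approx(0.02)
        assert out["N"]["rmsd"] == pytest.approx(0.10)

    def test_empty_join_fails(self):
        with pytest.raises(EmptySelectionError):
            distance_stats([], [])
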