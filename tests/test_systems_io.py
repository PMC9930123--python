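"""Geometry I/O, water recognition and the closest-N partition."""

import numpy as np
import pytest

from qmmeda.systems_io import (Atom, GenerationError, MolecularSystem,
                               ParseError, ValidationError,
                               WATER_GEOMETRY, TIP3P_CHARGES,
                               SOLUTE_TEMPLATES, generate_synthetic_snapshot,
                               partition_closest_n, raw_from_system,
                               read_structure, read_xyz, write_xyz, read_pdb,
                               RawSolvatedSystem)


WATER_XYZ = """3
one water
O   0.0000000 0.0000000 0.0000000
H   0.9572000 0.0000000 0.0000000
H  -0.2399000 0.9266000 0.0000000
"""


class TestXYZ:
    def test_parse_water(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text(WATER_XYZ)
        sys_ = read_xyz(p)
        assert sys_.n_atoms == 3
        assert sys_.elements == ["O", "H", "H"]
        assert int(sys_.nuclear_charges.sum()) == 10
        assert np.allclose(sys_.atoms[1].position, [0.9572, 0, 0])

    def test_round_trip(self, tmp_path):
        p1, p2 = tmp_path / "a.xyz", tmp_path / "b.xyz"
        p1.write_text(WATER_XYZ)
        s1 = read_xyz(p1)
        write_xyz(s1, p2, comment="one water")
        s2 = read_xyz(p2)
        assert s2.elements == s1.elements
        assert np.abs(s2.positions - s1.positions).max() < 1e-6
        # writing the re-read system reproduces the file byte for byte
        p3 = tmp_path / "c.xyz"
        write_xyz(s2, p3, comment="one water")
        assert p3.read_text() == p2.read_text()

    @pytest.mark.parametrize("content, match", [
        ("5\nwrong count\nO 0 0 0\nH 1 0 0\nH 0 1 0\n", "declared 5"),
        ("2\ntoo many\nO 0 0 0\nH 1 0 0\nH 0 1 0\n", "more coordinate"),
        ("not_a_number\nx\nO 0 0 0\n", "atom count"),
        ("1\nbad coords\nO zero 0 0\n", "non-numeric"),
        ("1\nshort line\nO 0 0\n", "El x y z"),
    ])
    def test_malformed(self, tmp_path, content, match):
        p = tmp_path / "bad.xyz"
        p.write_text(content)
        with pytest.raises(ParseError, match=match):
            read_xyz(p)

    def test_unknown_element(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\nmystery\nXx 0 0 0\n")
        with pytest.raises(ValidationError, match="Xx"):
            read_xyz(p)

    def test_format_dispatch(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text(WATER_XYZ)
        assert read_structure(p).n_atoms == 3
        with pytest.raises(ValueError, match="unsupported"):
            read_structure(tmp_path / "w.cif")


class TestPDB:
    def test_parse(self, tmp_path):
        pdb = (
            "HEADER    test\n"
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\n"
            "ATOM      2  H1  HOH A   1       0.957   0.000   0.000"
            "  1.00  0.00           H\n"
            "HETATM    3  H2  HOH A   1      -0.240   0.927   0.000"
            "  1.00  0.00           H\n"
            "END\n")
        p = tmp_path / "w.pdb"
        p.write_text(pdb)
        sys_ = read_pdb(p)
        assert sys_.elements == ["O", "H", "H"]
        assert np.allclose(sys_.atoms[1].position, [0.957, 0, 0])

    def test_no_records(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER nothing\nEND\n")
        with pytest.raises(ParseError, match="no ATOM"):
            read_pdb(p)


def _raw_with_waters(dists, solute_el="Na"):
    """One-atom solute at the origin, one water per requested O distance."""
    waters = np.array([WATER_GEOMETRY + np.array([d, 0.0, 0.0])
                       for d in dists])
    return RawSolvatedSystem(
        solute_elements=[solute_el], solute_positions=np.zeros((1, 3)),
        solute_charge=1 if solute_el == "Na" else 0,
        water_positions=waters,
        water_charges=np.tile(TIP3P_CHARGES, (len(dists), 1)),
        water_dipoles=None)


class TestPartition:
    def test_ordering(self):
        raw = _raw_with_waters([5.0, 3.0, 7.0])
        snap = partition_closest_n(raw, 2)
        assert snap.n_qm_waters == 2
        qm_pos = snap.qm_system.positions[1:]
        # closest (3 Å) and next (5 Å) oxygens present, 7 Å water in MM
        assert any(np.allclose(p, [3.0, 0, 0]) for p in qm_pos)
        assert any(np.allclose(p, [5.0, 0, 0]) for p in qm_pos)
        assert snap.mm_region.n_charges == 3
        assert np.allclose(snap.mm_region.positions[0], [7.0, 0, 0])

    def test_boundary_all_qm(self):
        raw = _raw_with_waters([3.0, 4.0])
        snap = partition_closest_n(raw, 2)
        assert snap.mm_region.n_charges == 0
        assert snap.qm_system.n_atoms == 1 + 6

    def test_out_of_range(self):
        raw = _raw_with_waters([3.0])
        with pytest.raises(ValueError, match="n_qm_waters"):
            partition_closest_n(raw, 2)

    def test_broken_triplet_rejected(self):
        raw = _raw_with_waters([3.0])
        raw.water_positions[0, 1] += 5.0  # stretch one O-H far beyond 1.3 Å
        with pytest.raises(ValidationError, match="broken water"):
            partition_closest_n(raw, 1)

    def test_completeness_invariant(self):
        raw = generate_synthetic_snapshot("formate", 12, seed=5).raw
        for n in (0, 4, 12):
            snap = partition_closest_n(raw, n)
            n_qm_w_atoms = len(snap.partition.fragment_b_indices)
            assert n_qm_w_atoms + snap.mm_region.n_charges == 3 * 12

    def test_brute_force_reranking(self):
        """Max QM-water metric <= min MM-water metric (brute-force check)."""
        raw = generate_synthetic_snapshot("ammonium", 200, seed=1).raw
        com = raw.solute_center_of_mass()
        metric = np.linalg.norm(
            raw.water_positions - com[None, None, :], axis=2).min(axis=1)
        snap = partition_closest_n(raw, 50)
        qm_o = snap.qm_system.positions[5::3]  # oxygens of QM waters
        qm_idx = [int(np.argmin(np.linalg.norm(
            raw.water_positions[:, 0, :] - o, axis=1))) for o in qm_o]
        mm_idx = [i for i in range(200) if i not in qm_idx]
        assert len(qm_idx) == 50
        assert metric[qm_idx].max() <= metric[mm_idx].min() + 1e-12

    def test_radius_monotone_in_n(self):
        raw = generate_synthetic_snapshot("ammonium", 20, seed=9).raw
        com = raw.solute_center_of_mass()
        radii = []
        for n in (2, 5, 10, 20):
            snap = partition_closest_n(raw, n)
            qm_w = snap.qm_system.positions[5:]
            radii.append(np.linalg.norm(qm_w - com, axis=1).max())
        assert all(a <= b + 1e-12 for a, b in zip(radii, radii[1:]))

    def test_translation_invariance(self):
        raw = generate_synthetic_snapshot("formate", 8, seed=2).raw
        shift = np.array([11.0, -4.0, 2.5])
        moved = RawSolvatedSystem(
            solute_elements=raw.solute_elements,
            solute_positions=raw.solute_positions + shift,
            solute_charge=raw.solute_charge,
            water_positions=raw.water_positions + shift,
            water_charges=raw.water_charges, water_dipoles=None)
        s1 = partition_closest_n(raw, 3)
        s2 = partition_closest_n(moved, 3)
        assert np.allclose(s2.qm_system.positions - shift,
                           s1.qm_system.positions, atol=1e-9)


class TestSyntheticSnapshots:
    def test_single_water_construction(self):
        snap = generate_synthetic_snapshot("ammonium", 1, seed=7)
        assert snap.n_qm_waters == 1
        assert snap.mm_region.n_charges == 0
        w = snap.qm_system.positions[5:8]
        assert abs(np.linalg.norm(w[1] - w[0]) - 0.9572) < 1e-6
        assert abs(np.linalg.norm(w[2] - w[0]) - 0.9572) < 1e-6

    def test_determinism(self):
        a = generate_synthetic_snapshot("glycine_zwitterion", 7, seed=42)
        b = generate_synthetic_snapshot("glycine_zwitterion", 7, seed=42)
        assert np.array_equal(a.qm_system.positions, b.qm_system.positions)
        c = generate_synthetic_snapshot("glycine_zwitterion", 7, seed=43)
        assert not np.array_equal(a.qm_system.positions,
                                  c.qm_system.positions)

    def test_min_distance_respected(self):
        snap = generate_synthetic_snapshot("formate", 30, seed=4,
                                           min_distance=2.25)
        pos = snap.qm_system.positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        # exclude intramolecular contacts (solute block, water triplets)
        blocks = [list(range(4))] + [
            [4 + 3 * w + k for k in range(3)] for w in range(30)]
        for blk in blocks:
            d[np.ix_(blk, blk)] = np.inf
        assert d.min() > 2.25 - 1e-9

    def test_packing_failure(self):
        with pytest.raises(GenerationError, match="increase"):
            generate_synthetic_snapshot("ammonium", 500, seed=0,
                                        min_distance=8.0,
                                        max_rejections=200)

    def test_polarizable_dipole_field_oracle(self):
        """mu_i = alpha_i E(R_i) with E recomputed by a double loop."""
        snap = generate_synthetic_snapshot("formate", 100, seed=1,
                                           polarizable=True)
        raw = snap.raw
        tpl = SOLUTE_TEMPLATES["formate"]
        for w in (0, 13, 57, 99):
            r_o = raw.water_positions[w, 0]
            efield = np.zeros(3)
            for q, p in zip(tpl["template_charges"], tpl["positions"]):
                dvec = r_o - p
                efield += q * dvec / np.linalg.norm(dvec) ** 3
            for v in range(raw.n_waters):
                if v == w:
                    continue  # a water is not polarized by its own charges
                for k in range(3):
                    dvec = r_o - raw.water_positions[v, k]
                    efield += raw.water_charges[v, k] * dvec \
                        / np.linalg.norm(dvec) ** 3
            assert np.allclose(raw.water_dipoles[w, 0], 0.53 * efield,
                               atol=1e-12)
            # hydrogens carry no polarizability
            assert np.all(raw.water_dipoles[w, 1:] == 0.0)

    def test_water_charges_are_tip3p(self):
        snap = generate_synthetic_snapshot("ammonium", 3, seed=1)
        assert np.allclose(snap.raw.water_charges,
                           np.tile([-0.834, 0.417, 0.417], (3, 1)))

    def test_unknown_template(self):
        with pytest.raises(ValueError, match="unknown solute template"):
            generate_synthetic_snapshot("benzene", 3, seed=1)

    @pytest.mark.parametrize("name", ["ammonium", "glycine_zwitterion",
                                      "formate"])
    def test_template_charges_sum_to_formal_charge(self, name):
        tpl = SOLUTE_TEMPLATES[name]
        assert abs(tpl["template_charges"].sum() - tpl["charge"]) < 1e-12


def test_raw_from_system_roundtrip(tmp_path):
    """A flat parsed system splits back into solute + validated waters."""
    snap = generate_synthetic_snapshot("ammonium", 4, seed=6)
    p = tmp_path / "full.xyz"
    write_xyz(snap.qm_system, p)
    parsed = read_xyz(p)
    raw = raw_from_system(parsed, 5, solute_charge=1)
    assert raw.n_waters == 4
    re_snap = partition_closest_n(raw, 2)
    assert re_snap.n_qm_waters == 2
    assert re_snap.mm_region.n_charges == 6
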