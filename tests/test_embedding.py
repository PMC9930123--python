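"""MM embedding: charge-pair dipole expansion, potentials, file formats."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qmmeda.embedding import (ChargePairExpansion, EmbeddingError,
                              InducedDipole, MMRegion, PointCharge,
                              evaluate_mm_potential, expand_dipole,
                              merged_fragment_potential, nuclei_mm_energy,
                              read_dipoles, read_point_charges,
                              write_dipoles, write_point_charges)
from qmmeda.systems_io import FragmentPartition
from qmmeda.units import COULOMB_KCAL


def _dipole_potential(mu_vec, site, point):
    """Analytic point-dipole potential mu·r_hat / r^2 (e/Å)."""
    r = np.asarray(point) - np.asarray(site)
    d = np.linalg.norm(r)
    return float(np.dot(mu_vec, r)) / d ** 3


class TestExpandDipole:
    def test_arithmetic(self):
        pair = expand_dipole(InducedDipole([0, 0, 0], [0, 0, 0.1]),
                             separation=0.001)
        assert pair.plus.charge == pytest.approx(100.0)
        assert pair.minus.charge == pytest.approx(-100.0)
        assert np.allclose(pair.plus.position, [0, 0, 0.0005])
        assert np.allclose(pair.minus.position, [0, 0, -0.0005])

    def test_zero_dipole(self):
        pair = expand_dipole(InducedDipole([1, 2, 3], [0, 0, 0]), 1e-3)
        assert pair.plus.charge == 0.0 and pair.minus.charge == 0.0

    def test_bad_separation(self):
        with pytest.raises(EmbeddingError, match="positive"):
            expand_dipole(InducedDipole([0, 0, 0], [0, 0, 1]), -1e-3)

    @given(st.lists(st.floats(-0.5, 0.5), min_size=3, max_size=3))
    def test_moment_reconstruction(self, mu):
        mu = np.array(mu)
        pair = expand_dipole(InducedDipole([0.3, -1.0, 2.0], mu), 1e-3)
        assert np.abs(pair.reconstructed_moment - mu).max() < 1e-12

    def test_matches_analytic_point_dipole(self):
        mu = np.array([0, 0, 0.1])
        dip = InducedDipole([0, 0, 0], mu)
        region = MMRegion(dipole_positions=[[0, 0, 0]], dipole_moments=[mu],
                          expansion_separation=1e-3)
        for point in ([0, 0, 2.0], [2.0, 0, 0], [1.2, -0.7, 1.1]):
            got = evaluate_mm_potential(region, [point])[0]
            ref = _dipole_potential(mu, [0, 0, 0], point)
            if ref != 0.0:
                assert abs(got - ref) / abs(ref) < 1e-5
            else:
                assert abs(got) < 1e-10

    def test_error_scales_as_d_squared(self):
        mu = np.array([0.02, -0.05, 0.1])
        point = [0, 0, 2.0]
        ref = _dipole_potential(mu, [0, 0, 0], point)
        errors = []
        for d in (1e-2, 1e-3, 1e-4):
            region = MMRegion(dipole_positions=[[0, 0, 0]],
                              dipole_moments=[mu], expansion_separation=d)
            errors.append(abs(evaluate_mm_potential(region, [point])[0]
                              - ref))
        # halving d cuts the error ~4x; a decade cuts it ~100x
        for e_big, e_small in zip(errors, errors[1:]):
            assert 30.0 < e_big / e_small < 300.0


class TestMMPotential:
    def test_single_charge(self):
        region = MMRegion(positions=[[0, 0, 0]], charges=[1.0])
        assert evaluate_mm_potential(region, [[2, 0, 0]])[0] == \
            pytest.approx(0.5)

    def test_empty_region(self):
        assert np.all(evaluate_mm_potential(MMRegion.empty(),
                                            [[1, 1, 1], [2, 2, 2]]) == 0.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n, m = rng.integers(1, 50), rng.integers(1, 20)
            pos = rng.normal(scale=5.0, size=(n, 3))
            qs = rng.normal(size=n)
            pts = rng.normal(scale=5.0, size=(m, 3)) + 20.0
            region = MMRegion(positions=pos, charges=qs)
            got = evaluate_mm_potential(region, pts)
            ref = np.array([sum(q / np.linalg.norm(p - r)
                                for q, r in zip(qs, pos)) for p in pts])
            assert np.abs((got - ref) / ref).max() < 1e-12

    def test_linearity_in_charges(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(10, 3))
        q1, q2 = rng.normal(size=10), rng.normal(size=10)
        pts = rng.normal(size=(5, 3)) + 10.0
        v1 = evaluate_mm_potential(MMRegion(positions=pos, charges=q1), pts)
        v2 = evaluate_mm_potential(MMRegion(positions=pos, charges=q2), pts)
        v12 = evaluate_mm_potential(
            MMRegion(positions=pos, charges=q1 + q2), pts)
        assert np.abs(v12 - (v1 + v2)).max() < 1e-10

    def test_coincident_point_rejected(self):
        region = MMRegion(positions=[[1, 1, 1]], charges=[1.0])
        with pytest.raises(EmbeddingError, match="coincides"):
            evaluate_mm_potential(region, [[1, 1, 1]])


class TestNucleiMMEnergy:
    def test_proton_anion_pair(self):
        region = MMRegion(positions=[[1, 0, 0]], charges=[-1.0])
        e = nuclei_mm_energy([(1, [0, 0, 0])], region)
        assert e == pytest.approx(-COULOMB_KCAL)
        assert e == pytest.approx(-332.06, abs=0.01)

    def test_empty(self):
        assert nuclei_mm_energy([(8, [0, 0, 0])], MMRegion.empty()) == 0.0
        assert nuclei_mm_energy([], MMRegion(positions=[[1, 0, 0]],
                                             charges=[1.0])) == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        nuclei = [(int(z), rng.normal(size=3))
                  for z in rng.integers(1, 9, size=5)]
        pos = rng.normal(size=(30, 3)) + 8.0
        qs = rng.normal(size=30)
        region = MMRegion(positions=pos, charges=qs)
        got = nuclei_mm_energy(nuclei, region)
        ref = sum(COULOMB_KCAL * z * q / np.linalg.norm(np.array(rn) - rq)
                  for z, rn in nuclei for q, rq in zip(qs, pos))
        assert abs((got - ref) / ref) < 1e-10

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        nuclei_pos = rng.normal(size=(4, 3))
        Z = [1, 6, 7, 8]
        mm_pos = rng.normal(size=(12, 3)) + 6.0
        qs = rng.normal(size=12)
        mus = rng.normal(scale=0.05, size=(12, 3))
        # a random proper rotation
        q_, r_ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q_) < 0:
            q_[:, 0] = -q_[:, 0]
        e1 = nuclei_mm_energy(
            list(zip(Z, nuclei_pos)),
            MMRegion(positions=mm_pos, charges=qs,
                     dipole_positions=mm_pos, dipole_moments=mus))
        e2 = nuclei_mm_energy(
            list(zip(Z, nuclei_pos @ q_.T)),
            MMRegion(positions=mm_pos @ q_.T, charges=qs,
                     dipole_positions=mm_pos @ q_.T,
                     dipole_moments=mus @ q_.T))
        assert abs((e1 - e2) / e1) < 1e-10

    def test_dipoles_enter_via_pairs(self):
        mu = np.array([0, 0, 0.1])
        region = MMRegion(dipole_positions=[[0, 0, 4.0]],
                          dipole_moments=[mu])
        e = nuclei_mm_energy([(1, [0, 0, 0])], region)
        ref = COULOMB_KCAL * _dipole_potential(mu, [0, 0, 4.0], [0, 0, 0])
        assert abs(e - ref) / abs(ref) < 1e-5


class TestMergedPotentialSpec:
    def test_separation_validated(self):
        partition = FragmentPartition([0], [1], 0, 0)
        region = MMRegion(positions=[[0, 0, 5.0]], charges=[-0.8],
                          dipole_positions=[[0, 0, 5.0]],
                          dipole_moments=[[0, 0, 0.05]],
                          expansion_separation=1.0)
        with pytest.raises(EmbeddingError, match="not much shorter"):
            merged_fragment_potential(partition, region,
                                      qm_positions=[[0, 0, 0], [1, 0, 0]])

    def test_expansion_included(self):
        partition = FragmentPartition([0], [1], 0, 0)
        region = MMRegion(positions=[[0, 0, 5.0]], charges=[-0.8],
                          dipole_positions=[[0, 0, 5.0]],
                          dipole_moments=[[0, 0, 0.05]])
        spec = merged_fragment_potential(partition, region,
                                         qm_positions=[[0, 0, 0]])
        assert spec.mode == "charges+dipoles"
        assert spec.charges.size == 3  # fixed charge + the two pair charges
        assert spec.charges.sum() == pytest.approx(-0.8)

    def test_charges_only_mode(self):
        partition = FragmentPartition([0], [1], 0, 0)
        region = MMRegion(positions=[[0, 0, 5.0]], charges=[-0.8],
                          dipole_positions=[[0, 0, 5.0]],
                          dipole_moments=[[0, 0, 0.05]])
        spec = merged_fragment_potential(partition, region,
                                         qm_positions=[[0, 0, 0]],
                                         include_dipoles=False)
        assert spec.mode == "charges" and spec.charges.size == 1


class TestFiles:
    def test_pc_roundtrip(self, tmp_path):
        region = MMRegion(positions=np.arange(9.0).reshape(3, 3),
                          charges=[-0.834, 0.417, 0.417])
        p = tmp_path / "mm.pc"
        write_point_charges(region, p)
        pos, qs = read_point_charges(p)
        assert np.abs(pos - region.positions).max() < 1e-9
        assert np.abs(qs - region.charges).max() < 1e-9

    def test_dip_roundtrip(self, tmp_path):
        region = MMRegion(dipole_positions=[[1, 2, 3]],
                          dipole_moments=[[0.01, -0.02, 0.03]])
        p = tmp_path / "mm.dip"
        write_dipoles(region, p)
        pos, mom = read_dipoles(p)
        assert np.abs(pos - [[1, 2, 3]]).max() < 1e-9
        assert np.abs(mom - [[0.01, -0.02, 0.03]]).max() < 1e-9

    def test_comments_and_errors(self, tmp_path):
        p = tmp_path / "mm.pc"
        p.write_text("# comment\n\n0 0 0 1.0\n")
        pos, qs = read_point_charges(p)
        assert qs.tolist() == [1.0]
        p.write_text("0 0 1.0\n")
        with pytest.raises(EmbeddingError, match="x y z q"):
            read_point_charges(p)
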