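"""Shared fixtures: small solvated systems and their decompositions.

SCF-heavy objects are session-scoped so each expensive decomposition
runs once per test session.
"""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from qmmeda.eda_core import EDAConfig, assemble_eda
from qmmeda.embedding import MMRegion
from qmmeda.systems_io import (Atom, FragmentPartition, MolecularSystem,
                               SolvatedSnapshot, generate_synthetic_snapshot,
                               partition_closest_n)

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: a hydrogen-bonded water dimer (donor O-H...O), Å
WATER_DIMER_XYZ = np.array([
    [-1.551007, -0.114520, 0.000000],
    [-1.934259, 0.762503, 0.000000],
    [-0.599677, 0.040712, 0.000000],
    [1.350625, 0.111469, 0.000000],
    [1.680398, -0.373741, -0.758561],
    [1.680398, -0.373741, 0.758561],
])
WATER_DIMER_ELEMENTS = ["O", "H", "H", "O", "H", "H"]


def water_dimer_system(offset=0.0):
    pos = WATER_DIMER_XYZ.copy()
    pos[3:, 0] += offset
    return MolecularSystem(
        [Atom(e, p) for e, p in zip(WATER_DIMER_ELEMENTS, pos)])


@pytest.fixture(scope="session")
def water_dimer_snapshot():
    return SolvatedSnapshot(
        qm_system=water_dimer_system(),
        partition=FragmentPartition([0, 1, 2], [3, 4, 5], 0, 0),
        mm_region=MMRegion.empty(),
        provenance="water dimer fixture")


@pytest.fixture(scope="session")
def water_dimer_result(water_dimer_snapshot):
    return assemble_eda(water_dimer_snapshot,
                        EDAConfig(embedding_mode="none"))


@pytest.fixture(scope="session")
def ammonium_raw():
    """Synthetic ammonium cation in 10 waters (seed-fixed)."""
    return generate_synthetic_snapshot("ammonium", 10, seed=3).raw


@pytest.fixture(scope="session")
def ammonium_small_raw():
    """Synthetic ammonium cation in 4 waters (for all-QM comparisons)."""
    return generate_synthetic_snapshot("ammonium", 4, seed=8).raw


@pytest.fixture(scope="session")
def ammonium_snapshot(ammonium_raw):
    """2 QM waters, remaining 8 as TIP3P MM charges."""
    return partition_closest_n(ammonium_raw, 2)


@pytest.fixture(scope="session")
def ammonium_result(ammonium_snapshot):
    return assemble_eda(ammonium_snapshot, EDAConfig(embedding_mode="charges"))


@pytest.fixture(scope="session")
def naf_result():
    """Na+ / F- ion pair at 20 Å, pure QM."""
    sys_ = MolecularSystem([Atom("Na", [0, 0, 0]), Atom("F", [0, 0, 20.0])])
    snap = SolvatedSnapshot(
        qm_system=sys_, partition=FragmentPartition([0], [1], +1, -1),
        mm_region=MMRegion.empty(), provenance="NaF 20A")
    return assemble_eda(snap, EDAConfig(embedding_mode="none"))


@pytest.fixture(scope="session")
def hehe_far_result():
    """Two He atoms at 100 Å: every component must vanish."""
    sys_ = MolecularSystem([Atom("He", [0, 0, 0]), Atom("He", [0, 0, 100.0])])
    snap = SolvatedSnapshot(
        qm_system=sys_, partition=FragmentPartition([0], [1], 0, 0),
        mm_region=MMRegion.empty(), provenance="HeHe 100A")
    return assemble_eda(snap, EDAConfig(embedding_mode="none"))
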