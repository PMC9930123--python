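"""MM embedding: fixed point charges and induced dipoles.

The MM region enters the QM Hamiltonian as a one-electron potential
built from fixed atomic charges; induced atomic dipoles are represented
as finite pairs of opposite charges placed on the atom and aligned with
the dipole vector.  The intra-pair self-energy of an expansion is never
evaluated — only MM→QM potentials and nuclei–MM cross terms exist.

File formats: `.pc` holds `x y z q` per line (Å, e); `.dip` holds
`x y z mux muy muz` (Å, e·Å).  Lines starting with `#` are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import COULOMB_KCAL

__all__ = [
    "PointCharge", "InducedDipole", "ChargePairExpansion", "MMRegion",
    "EmbeddingError", "expand_dipole", "evaluate_mm_potential",
    "nuclei_mm_energy", "merged_fragment_potential", "EmbeddingSpec",
    "read_point_charges", "write_point_charges", "read_dipoles",
    "write_dipoles",
]

DEFAULT_EXPANSION_SEPARATION = 1e-3  # Å


class EmbeddingError(ValueError):
    pass


@dataclass(frozen=True)
class PointCharge:
    position: np.ndarray  # Å
    charge: float         # e

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not (np.all(np.isfinite(pos)) and np.isfinite(self.charge)):
            raise EmbeddingError("non-finite point charge")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "charge", float(self.charge))


@dataclass(frozen=True)
class InducedDipole:
    position: np.ndarray  # Å
    moment: np.ndarray    # e·Å

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        mom = np.asarray(self.moment, dtype=float).reshape(3)
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(mom))):
            raise EmbeddingError("non-finite induced dipole")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "moment", mom)


@dataclass(frozen=True)
class ChargePairExpansion:
    """A dipole replaced by two opposite charges ±|mu|/d at R ± (d/2)·mu_hat."""

    plus: PointCharge
    minus: PointCharge
    separation: float  # Å

    @property
    def reconstructed_moment(self):
        return self.plus.charge * (self.plus.position - self.minus.position)


def expand_dipole(dipole: InducedDipole,
                  separation: float = DEFAULT_EXPANSION_SEPARATION
                  ) -> ChargePairExpansion:
    """Replace a point dipole by a finite pair of opposite charges."""
    if separation <= 0:
        raise EmbeddingError(f"separation must be positive, got {separation}")
    mu = np.linalg.norm(dipole.moment)
    if mu == 0.0:
        zero = PointCharge(dipole.position, 0.0)
        return ChargePairExpansion(zero, zero, separation)
    unit = dipole.moment / mu
    q = mu / separation
    half = 0.5 * separation * unit
    return ChargePairExpansion(
        plus=PointCharge(dipole.position + half, q),
        minus=PointCharge(dipole.position - half, -q),
        separation=separation)


@dataclass
class MMRegion:
    """Fixed point charges plus optional induced dipoles.

    Arrays are the canonical storage (positions in Å, charges in e,
    moments in e·Å); the list-of-objects view is available through
    :meth:`point_charges` / :meth:`induced_dipoles`.
    """

    positions: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3)))
    charges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dipole_positions: np.ndarray | None = None
    dipole_moments: np.ndarray | None = None
    expansion_separation: float = DEFAULT_EXPANSION_SEPARATION

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        if self.positions.shape[0] != self.charges.shape[0]:
            raise EmbeddingError("positions/charges length mismatch")
        if (self.dipole_moments is None) != (self.dipole_positions is None):
            raise EmbeddingError("dipole positions and moments must be "
                                 "given together")
        if self.dipole_moments is not None:
            self.dipole_positions = np.asarray(
                self.dipole_positions, dtype=float).reshape(-1, 3)
            self.dipole_moments = np.asarray(
                self.dipole_moments, dtype=float).reshape(-1, 3)
            if self.dipole_positions.shape != self.dipole_moments.shape:
                raise EmbeddingError("dipole array shape mismatch")
        if self.expansion_separation <= 0:
            raise EmbeddingError("expansion_separation must be positive")

    @classmethod
    def empty(cls):
        return cls()

    @classmethod
    def from_lists(cls, point_charges, induced_dipoles=(),
                   expansion_separation=DEFAULT_EXPANSION_SEPARATION):
        pcs = list(point_charges)
        dips = list(induced_dipoles)
        return cls(
            positions=np.array([c.position for c in pcs]).reshape(-1, 3),
            charges=np.array([c.charge for c in pcs]),
            dipole_positions=np.array(
                [d.position for d in dips]).reshape(-1, 3) if dips else None,
            dipole_moments=np.array(
                [d.moment for d in dips]).reshape(-1, 3) if dips else None,
            expansion_separation=expansion_separation)

    @property
    def n_charges(self):
        return self.charges.shape[0]

    @property
    def n_dipoles(self):
        return 0 if self.dipole_moments is None else \
            self.dipole_moments.shape[0]

    @property
    def is_empty(self):
        return self.n_charges == 0 and self.n_dipoles == 0

    def point_charges(self):
        return [PointCharge(p, q) for p, q in
                zip(self.positions, self.charges)]

    def induced_dipoles(self):
        if self.dipole_moments is None:
            return []
        return [InducedDipole(p, m) for p, m in
                zip(self.dipole_positions, self.dipole_moments)]

    def expanded_charges(self, include_dipoles=True):
        """All effective point charges: fixed + dipole charge pairs.

        Returns (positions (K,3) Å, charges (K,) e).
        """
        pos = [self.positions]
        qs = [self.charges]
        if include_dipoles and self.n_dipoles:
            for dip in self.induced_dipoles():
                pair = expand_dipole(dip, self.expansion_separation)
                if pair.plus.charge != 0.0:
                    pos.append(pair.plus.position[None, :])
                    pos.append(pair.minus.position[None, :])
                    qs.append(np.array([pair.plus.charge]))
                    qs.append(np.array([pair.minus.charge]))
        return np.vstack(pos), np.concatenate(qs)


# ---------------------------------------------------------------------------
# potentials and energies (classical)

def evaluate_mm_potential(region: MMRegion, points,
                          include_dipoles=True) -> np.ndarray:
    """Electrostatic potential of the MM region at given points (e/Å).

    phi(r) = sum_i q_i / |r - R_i|, dipoles entering through their
    charge-pair expansions.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    pos, qs = region.expanded_charges(include_dipoles)
    if qs.size == 0:
        return np.zeros(pts.shape[0])
    diff = pts[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    bad = np.argwhere(dist < 1e-8)
    if bad.size:
        i, j = bad[0]
        raise EmbeddingError(
            f"evaluation point {i} coincides with MM charge {j} "
            f"(distance {dist[i, j]:.2e} Å)")
    return (qs[None, :] / dist).sum(axis=1)


def nuclei_mm_energy(fragment_nuclei, region: MMRegion,
                     include_dipoles=True) -> float:
    """Classical nuclei–MM Coulomb energy in kcal/mol.

    ``fragment_nuclei`` is a sequence of (Z, position-Å) pairs; dipoles
    enter via their charge-pair expansions.
    """
    nuclei = list(fragment_nuclei)
    if not nuclei:
        return 0.0
    Z = np.array([float(z) for z, _ in nuclei])
    pos_n = np.array([np.asarray(p, dtype=float) for _, p in nuclei])
    phi = evaluate_mm_potential(region, pos_n, include_dipoles)
    return COULOMB_KCAL * float(Z @ phi)


@dataclass
class EmbeddingSpec:
    """The merged fragment+MM potential handed to the SCF backend.

    Carries the fully expanded MM charge set (fixed charges plus dipole
    charge pairs) in Å/e.  The backend folds it into the one-electron
    Hamiltonian of the fragment whose nuclear potential is being merged
    (the solvent fragment B) and into every nuclei–MM cross term.
    """

    positions: np.ndarray  # (K, 3) Å
    charges: np.ndarray    # (K,) e
    mode: str = "charges"

    @property
    def is_empty(self):
        return self.charges.size == 0


def merged_fragment_potential(partition, region: MMRegion,
                              qm_positions=None,
                              include_dipoles=True) -> EmbeddingSpec:
    """Build the embedded-potential specification for fragment B.

    The MM region attaches to the solvent fragment only; when induced
    dipoles are present their charge-pair separation is validated
    against the shortest QM–MM distance (d must be < 0.1 × that
    distance, because the pair must mimic a point dipole everywhere in
    the QM region).
    """
    if region.n_dipoles and include_dipoles and qm_positions is not None \
            and len(qm_positions):
        qm = np.asarray(qm_positions, dtype=float).reshape(-1, 3)
        d = np.linalg.norm(
            qm[:, None, :] - region.dipole_positions[None, :, :], axis=2)
        dist_c = np.linalg.norm(
            qm[:, None, :] - region.positions[None, :, :], axis=2) \
            if region.n_charges else d
        shortest = min(d.min(), dist_c.min())
        if region.expansion_separation >= 0.1 * shortest:
            raise EmbeddingError(
                f"expansion separation {region.expansion_separation} Å is "
                f"not much shorter than the closest QM-MM distance "
                f"{shortest:.3f} Å (limit {0.1 * shortest:.3f} Å)")
    pos, qs = region.expanded_charges(include_dipoles)
    mode = "charges+dipoles" if (include_dipoles and region.n_dipoles) \
        else "charges"
    return EmbeddingSpec(positions=pos, charges=qs, mode=mode)


# ---------------------------------------------------------------------------
# file formats

def write_point_charges(region: MMRegion, path):
    with open(path, "w") as fh:
        fh.write("# x y z q (Angstrom, e)\n")
        for p, q in zip(region.positions, region.charges):
            fh.write(f"{p[0]:18.10f} {p[1]:18.10f} {p[2]:18.10f} "
                     f"{q:14.8f}\n")


def read_point_charges(path):
    pos, qs = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 4:
                raise EmbeddingError(
                    f"expected 'x y z q' at {path}:{lineno}")
            vals = [float(v) for v in parts]
            pos.append(vals[:3])
            qs.append(vals[3])
    return np.array(pos).reshape(-1, 3), np.array(qs)


def write_dipoles(region: MMRegion, path):
    with open(path, "w") as fh:
        fh.write("# x y z mux muy muz (Angstrom, e*Angstrom)\n")
        if region.dipole_moments is None:
            return
        for p, m in zip(region.dipole_positions, region.dipole_moments):
            fh.write(f"{p[0]:18.10f} {p[1]:18.10f} {p[2]:18.10f} "
                     f"{m[0]:14.10f} {m[1]:14.10f} {m[2]:14.10f}\n")


def read_dipoles(path):
    pos, moms = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 6:
                raise EmbeddingError(
                    f"expected 'x y z mux muy muz' at {path}:{lineno}")
            vals = [float(v) for v in parts]
            pos.append(vals[:3])
            moms.append(vals[3:])
    return np.array(pos).reshape(-1, 3), np.array(moms).reshape(-1, 3)
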