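"""Geometry and region handling.

Reads and writes structures (XYZ, minimal PDB), recognizes water
molecules, assigns the N closest waters to the QM region and builds
synthetic solvated snapshots that emulate MD output: a small ionic or
zwitterionic solute surrounded by rigid three-site waters carrying
force-field charges and, optionally, induced atomic dipoles.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .embedding import MMRegion, write_point_charges, write_dipoles, \
    read_point_charges, read_dipoles

__all__ = [
    "Atom", "MolecularSystem", "FragmentPartition", "SolvatedSnapshot",
    "ParseError", "ValidationError",
    "read_structure", "read_xyz", "write_xyz", "read_pdb",
    "partition_closest_n", "generate_synthetic_snapshot",
    "write_snapshot_bundle", "read_snapshot_bundle",
    "SOLUTE_TEMPLATES", "WATER_GEOMETRY", "TIP3P_CHARGES",
]

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
}
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
}

#: rigid 3-site water geometry (Å, local frame): O, H, H
WATER_GEOMETRY = np.array([
    [0.0, 0.0, 0.0],
    [0.9572, 0.0, 0.0],
    [-0.23998721, 0.92662721, 0.0],
])
#: TIP3P fixed charges (e) for O, H, H
TIP3P_CHARGES = np.array([-0.834, 0.417, 0.417])
#: isotropic atomic polarizability (Å^3) for O, H, H used by the
#: polarizable option (POL3-like oxygen-centered response)
WATER_POLARIZABILITIES = np.array([0.53, 0.0, 0.0])

_MAX_OH_BOND = 1.3  # Å, water-triplet validation threshold


class ParseError(ValueError):
    """Malformed structure file; carries the offending line number."""

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message} ({loc})" if loc else message)
        self.path = path
        self.line = line


class ValidationError(ValueError):
    """Chemically inconsistent input (bad element, broken water, ...)."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, nuclear charge Z and position in Å."""

    element: str
    position: np.ndarray
    atomic_number: int = 0

    def __post_init__(self):
        el = self.element.capitalize()
        if el not in ATOMIC_NUMBERS:
            raise ValidationError(f"unknown element symbol {self.element!r}")
        object.__setattr__(self, "element", el)
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValidationError(f"non-finite coordinates for {el}: {pos}")
        object.__setattr__(self, "position", pos)
        z = ATOMIC_NUMBERS[el]
        if self.atomic_number not in (0, z):
            raise ValidationError(
                f"atomic_number {self.atomic_number} does not match {el}")
        object.__setattr__(self, "atomic_number", z)


class MolecularSystem:
    """An ordered collection of atoms with total charge and multiplicity."""

    def __init__(self, atoms, total_charge=0, multiplicity=1,
                 check_closed_shell=True):
        atoms = list(atoms)
        if not atoms:
            raise ValidationError("a molecular system needs at least one atom")
        self.atoms = atoms
        self.total_charge = int(total_charge)
        self.multiplicity = int(multiplicity)
        if self.multiplicity < 1:
            raise ValidationError("multiplicity must be a positive integer")
        # parsed files may not know the charge yet; the EDA re-validates
        # once the fragment charges are attached
        if check_closed_shell and self.multiplicity == 1 \
                and self.n_electrons % 2 != 0:
            raise ValidationError(
                f"odd electron count ({self.n_electrons}) is incompatible "
                "with a closed-shell (singlet) system")

    @property
    def n_atoms(self):
        return len(self.atoms)

    @property
    def elements(self):
        return [a.element for a in self.atoms]

    @property
    def positions(self):
        return np.array([a.position for a in self.atoms])

    @property
    def nuclear_charges(self):
        return np.array([float(a.atomic_number) for a in self.atoms])

    @property
    def n_electrons(self):
        return int(self.nuclear_charges.sum()) - self.total_charge

    @property
    def masses(self):
        return np.array([ATOMIC_MASSES[a.element] for a in self.atoms])

    def center_of_mass(self, indices=None):
        idx = np.arange(self.n_atoms) if indices is None else \
            np.asarray(indices, dtype=int)
        m = self.masses[idx]
        return (m[:, None] * self.positions[idx]).sum(axis=0) / m.sum()

    def __repr__(self):
        return (f"MolecularSystem({self.n_atoms} atoms, "
                f"charge={self.total_charge}, mult={self.multiplicity})")


@dataclass
class FragmentPartition:
    """Solute (fragment A) / QM-solvent (fragment B) atom assignment."""

    fragment_a_indices: list
    fragment_b_indices: list
    charge_a: int
    charge_b: int

    def __post_init__(self):
        self.fragment_a_indices = [int(i) for i in self.fragment_a_indices]
        self.fragment_b_indices = [int(i) for i in self.fragment_b_indices]
        if set(self.fragment_a_indices) & set(self.fragment_b_indices):
            raise ValidationError("fragment index sets overlap")

    def validate(self, system: MolecularSystem):
        union = sorted(self.fragment_a_indices + self.fragment_b_indices)
        if union != list(range(system.n_atoms)):
            raise ValidationError(
                "fragments do not partition the QM system exactly")
        if self.charge_a + self.charge_b != system.total_charge:
            raise ValidationError(
                f"fragment charges {self.charge_a}+{self.charge_b} do not "
                f"sum to the total charge {system.total_charge}")


@dataclass
class SolvatedSnapshot:
    """A partitioned snapshot: QM system, A/B fragments, MM region.

    ``raw`` keeps the unpartitioned picture (solute + every water with
    its per-atom force-field charges and optional induced dipoles) so
    the same snapshot can be re-partitioned at a different QM size.
    """

    qm_system: MolecularSystem
    partition: FragmentPartition
    mm_region: MMRegion
    provenance: str = ""
    raw: "RawSolvatedSystem | None" = None

    @property
    def n_qm_waters(self):
        return len(self.partition.fragment_b_indices) // 3


@dataclass
class RawSolvatedSystem:
    """Solute plus all waters, before any QM/MM split."""

    solute_elements: list
    solute_positions: np.ndarray      # (n_solute, 3) Å
    solute_charge: int
    water_positions: np.ndarray       # (n_waters, 3, 3) Å; O, H, H
    water_charges: np.ndarray         # (n_waters, 3) e
    water_dipoles: np.ndarray | None  # (n_waters, 3, 3) e·Å or None
    provenance: str = ""

    @property
    def n_waters(self):
        return self.water_positions.shape[0]

    def solute_system(self):
        atoms = [Atom(el, p) for el, p in
                 zip(self.solute_elements, self.solute_positions)]
        return MolecularSystem(atoms, total_charge=self.solute_charge)

    def solute_center_of_mass(self):
        m = np.array([ATOMIC_MASSES[e] for e in self.solute_elements])
        return (m[:, None] * self.solute_positions).sum(axis=0) / m.sum()


# ---------------------------------------------------------------------------
# structure files

def read_xyz(path) -> MolecularSystem:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty XYZ file", path, 1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("first line must be the atom count", path, 1)
    if len(lines) < n + 2:
        raise ParseError(
            f"declared {n} atoms but file has only {max(len(lines) - 2, 0)} "
            "coordinate lines", path, len(lines))
    atoms = []
    for i in range(n):
        lineno = i + 3
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise ParseError("expected 'El x y z'", path, lineno)
        el = parts[0]
        if el.capitalize() not in ATOMIC_NUMBERS:
            raise ValidationError(
                f"unknown element symbol {el!r} at line {lineno} of {path}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError("non-numeric coordinate", path, lineno)
        atoms.append(Atom(el, xyz))
    # trailing non-blank lines mean the declared count is wrong
    for j, extra in enumerate(lines[n + 2:], start=n + 3):
        if extra.strip():
            raise ParseError(
                f"declared {n} atoms but found more coordinate lines",
                path, j)
    return MolecularSystem(atoms, total_charge=0, check_closed_shell=False)


def write_xyz(system: MolecularSystem, path, comment=""):
    with open(path, "w") as fh:
        fh.write(f"{system.n_atoms}\n{comment}\n")
        for a in system.atoms:
            x, y, z = a.position
            fh.write(f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def read_pdb(path) -> MolecularSystem:
    """Minimal PDB reader: ATOM/HETATM coordinate records only."""
    atoms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                xyz = [float(line[30:38]), float(line[38:46]),
                       float(line[46:54])]
            except ValueError:
                raise ParseError("malformed coordinate columns", path, lineno)
            el = line[76:78].strip()
            if not el:  # fall back to the atom-name column
                name = line[12:16].strip()
                el = name[:2].capitalize() if name[:2].capitalize() in \
                    ATOMIC_NUMBERS else name[:1]
            if el.capitalize() not in ATOMIC_NUMBERS:
                raise ValidationError(
                    f"unknown element {el!r} at line {lineno} of {path}")
            atoms.append(Atom(el, xyz))
    if not atoms:
        raise ParseError("no ATOM/HETATM records found", path, 1)
    return MolecularSystem(atoms, total_charge=0, check_closed_shell=False)


def read_structure(path, fmt=None) -> MolecularSystem:
    """Read a structure file; format inferred from the extension."""
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "pdb":
        return read_pdb(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


# ---------------------------------------------------------------------------
# water recognition and the closest-N partition

def waters_from_system(system: MolecularSystem, n_solute_atoms: int):
    """Split a parsed system into solute block + O,H,H water triplets."""
    n_solvent = system.n_atoms - n_solute_atoms
    if n_solvent % 3 != 0:
        raise ValidationError(
            f"{n_solvent} solvent atoms do not form O,H,H triplets")
    pos = system.positions
    els = system.elements
    waters = []
    for w in range(n_solvent // 3):
        i = n_solute_atoms + 3 * w
        if els[i] != "O" or els[i + 1] != "H" or els[i + 2] != "H":
            raise ValidationError(
                f"solvent atoms {i}..{i + 2} are not an O,H,H triplet "
                f"({els[i]},{els[i + 1]},{els[i + 2]})")
        for hh in (1, 2):
            d = np.linalg.norm(pos[i + hh] - pos[i])
            if d > _MAX_OH_BOND:
                raise ValidationError(
                    f"broken water triplet at atoms {i}..{i + 2}: "
                    f"O-H distance {d:.2f} Å > {_MAX_OH_BOND} Å")
        waters.append(pos[i:i + 3])
    return np.array(waters).reshape(-1, 3, 3)


def raw_from_system(system: MolecularSystem, n_solute_atoms: int,
                    solute_charge: int = 0,
                    water_charges=None, water_dipoles=None,
                    provenance="") -> RawSolvatedSystem:
    """Build the unpartitioned solute+waters picture from a flat system."""
    waters = waters_from_system(system, n_solute_atoms)
    nw = waters.shape[0]
    if water_charges is None:
        wq = np.tile(TIP3P_CHARGES, (nw, 1))
    else:
        wq = np.asarray(water_charges, dtype=float).reshape(nw, 3)
    return RawSolvatedSystem(
        solute_elements=system.elements[:n_solute_atoms],
        solute_positions=system.positions[:n_solute_atoms],
        solute_charge=solute_charge,
        water_positions=waters,
        water_charges=wq,
        water_dipoles=None if water_dipoles is None else
        np.asarray(water_dipoles, dtype=float).reshape(nw, 3, 3),
        provenance=provenance)


def _water_com_distances(raw: RawSolvatedSystem):
    """Min over each water's three atoms of the distance to the solute COM."""
    com = raw.solute_center_of_mass()
    d = np.linalg.norm(raw.water_positions - com[None, None, :], axis=2)
    return d.min(axis=1)


def partition_closest_n(snapshot, n_qm_waters: int,
                        expansion_separation: float = 1e-3
                        ) -> SolvatedSnapshot:
    """Assign the n closest waters (min atom-to-solute-COM distance) to
    the QM region; all remaining water atoms populate the MM region.

    ``snapshot`` may be a :class:`SolvatedSnapshot` carrying its raw
    system or a :class:`RawSolvatedSystem` directly.  Ties are broken by
    input order (stable sort).
    """
    raw = snapshot.raw if isinstance(snapshot, SolvatedSnapshot) else snapshot
    if raw is None:
        raise ValidationError(
            "snapshot does not carry its raw solute+waters description")
    n_qm_waters = int(n_qm_waters)
    if n_qm_waters < 0 or n_qm_waters > raw.n_waters:
        raise ValueError(
            f"n_qm_waters={n_qm_waters} outside 0..{raw.n_waters}")
    # triplet integrity check (O-H bond length)
    for w in range(raw.n_waters):
        for hh in (1, 2):
            d = np.linalg.norm(raw.water_positions[w, hh]
                               - raw.water_positions[w, 0])
            if d > _MAX_OH_BOND:
                raise ValidationError(
                    f"broken water triplet #{w}: O-H distance {d:.2f} Å")
    order = np.argsort(_water_com_distances(raw), kind="stable")
    qm_w = np.sort(order[:n_qm_waters])
    mm_w = np.sort(order[n_qm_waters:])

    atoms = [Atom(el, p) for el, p in
             zip(raw.solute_elements, raw.solute_positions)]
    for w in qm_w:
        for k, el in enumerate(("O", "H", "H")):
            atoms.append(Atom(el, raw.water_positions[w, k]))
    qm_system = MolecularSystem(atoms, total_charge=raw.solute_charge)
    n_solute = len(raw.solute_elements)
    partition = FragmentPartition(
        fragment_a_indices=list(range(n_solute)),
        fragment_b_indices=list(range(n_solute, qm_system.n_atoms)),
        charge_a=raw.solute_charge, charge_b=0)
    partition.validate(qm_system)

    if len(mm_w):
        mm_pos = raw.water_positions[mm_w].reshape(-1, 3)
        mm_q = raw.water_charges[mm_w].reshape(-1)
        mm_dip = None if raw.water_dipoles is None else \
            raw.water_dipoles[mm_w].reshape(-1, 3)
    else:
        mm_pos = np.zeros((0, 3))
        mm_q = np.zeros(0)
        mm_dip = None if raw.water_dipoles is None else np.zeros((0, 3))
    mm_region = MMRegion(
        positions=mm_pos, charges=mm_q,
        dipole_positions=None if mm_dip is None else mm_pos,
        dipole_moments=mm_dip,
        expansion_separation=expansion_separation)
    return SolvatedSnapshot(
        qm_system=qm_system, partition=partition, mm_region=mm_region,
        provenance=raw.provenance, raw=raw)


# ---------------------------------------------------------------------------
# synthetic snapshots

def _template(elements, positions, charge, template_charges):
    return {
        "elements": list(elements),
        "positions": np.asarray(positions, dtype=float),
        "charge": charge,
        "template_charges": np.asarray(template_charges, dtype=float),
    }


_T = 1.013 / math.sqrt(3.0)  # ammonium N-H projection
SOLUTE_TEMPLATES = {
    "ammonium": _template(
        ["N", "H", "H", "H", "H"],
        [[0.0, 0.0, 0.0], [_T, _T, _T], [-_T, -_T, _T],
         [-_T, _T, -_T], [_T, -_T, -_T]],
        +1, [-0.54, 0.385, 0.385, 0.385, 0.385]),
    "glycine_zwitterion": _template(
        ["N", "C", "C", "O", "O", "H", "H", "H", "H", "H"],
        [[1.49, 0.0, 0.0],          # N (ammonium end)
         [0.0, 0.0, 0.0],           # C-alpha
         [-0.55, 1.42, 0.0],        # carboxylate C
         [-1.79, 1.50, 0.0],        # O
         [0.14, 2.49, 0.0],         # O
         [1.86, 0.95, 0.17],        # H on N
         [1.86, -0.51, 0.80],       # H on N
         [1.86, -0.51, -0.80],      # H on N
         [-0.36, -0.55, 0.89],      # H on C-alpha
         [-0.36, -0.55, -0.89]],    # H on C-alpha
        0, [-0.30, 0.00, 0.70, -0.80, -0.80, 0.36, 0.36, 0.36, 0.06, 0.06]),
    "formate": _template(
        ["C", "H", "O", "O"],
        [[0.0, 0.0, 0.0], [0.0, 0.0, 1.10],
         [1.13, 0.0, -0.53], [-1.13, 0.0, -0.53]],
        -1, [0.44, 0.06, -0.75, -0.75]),
}
SOLUTE_TEMPLATES["glycine"] = SOLUTE_TEMPLATES["glycine_zwitterion"]


def _random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class GenerationError(RuntimeError):
    """Packing failure while placing waters."""


def generate_synthetic_snapshot(solute_template: str, n_waters: int,
                                seed: int, shell_spacing: float = 1.0,
                                first_shell_radius: float = 3.0,
                                min_distance: float = 2.25,
                                polarizable: bool = False,
                                max_rejections: int = 20000
                                ) -> SolvatedSnapshot:
    """Build a deterministic solvated snapshot around a template solute.

    Rigid TIP3P-charge waters are placed on concentric shells with random
    orientations; a placement is rejected when any of its atoms comes
    closer than ``min_distance`` (Å) to an already placed atom.  With
    ``polarizable`` each water atom also carries an induced dipole
    mu_i = alpha_i * E(R_i), E being the Coulomb field of the solute's
    template charges and the other waters' fixed charges.
    """
    if solute_template not in SOLUTE_TEMPLATES:
        raise ValueError(f"unknown solute template {solute_template!r}; "
                         f"choose from {sorted(SOLUTE_TEMPLATES)}")
    if n_waters < 1:
        raise ValueError("n_waters must be >= 1")
    tpl = SOLUTE_TEMPLATES[solute_template]
    rng = np.random.default_rng(seed)

    placed = [tpl["positions"].copy()]
    waters = []
    shell = 0
    rejections = 0
    # capacity of a shell grows with its surface; sample positions uniformly
    while len(waters) < n_waters:
        radius = first_shell_radius + shell * shell_spacing
        capacity = max(1, int(4.0 * math.pi * radius ** 2 / 9.0))
        placed_on_shell = 0
        attempts = 0
        while placed_on_shell < capacity and len(waters) < n_waters:
            u, v = rng.random(2)
            theta = math.acos(1.0 - 2.0 * u)
            phi = 2.0 * math.pi * v
            center = radius * np.array([
                math.sin(theta) * math.cos(phi),
                math.sin(theta) * math.sin(phi),
                math.cos(theta)])
            rot = _random_rotation(rng)
            wpos = center + (WATER_GEOMETRY - WATER_GEOMETRY.mean(axis=0)) @ rot.T
            all_placed = np.vstack(placed)
            if np.min(np.linalg.norm(
                    all_placed[:, None, :] - wpos[None, :, :], axis=2)) \
                    < min_distance:
                rejections += 1
                attempts += 1
                if rejections > max_rejections:
                    raise GenerationError(
                        f"failed to place water {len(waters) + 1} after "
                        f"{max_rejections} rejections; increase "
                        "shell_spacing or first_shell_radius")
                if attempts > 30 * capacity:
                    break  # shell effectively full, move outward
                continue
            placed.append(wpos)
            waters.append(wpos)
            placed_on_shell += 1
        shell += 1

    water_positions = np.array(waters)
    nw = len(waters)
    water_charges = np.tile(TIP3P_CHARGES, (nw, 1))

    dipoles = None
    if polarizable:
        dipoles = np.zeros((nw, 3, 3))
        flat_w = water_positions.reshape(-1, 3)
        flat_q = water_charges.reshape(-1)
        src_pos = np.vstack([tpl["positions"], flat_w])
        src_q = np.concatenate([tpl["template_charges"], flat_q])
        for w in range(nw):
            own = set(range(tpl["positions"].shape[0] + 3 * w,
                            tpl["positions"].shape[0] + 3 * w + 3))
            mask = np.array([i not in own for i in range(len(src_q))])
            for k in range(3):
                alpha = WATER_POLARIZABILITIES[k]
                if alpha == 0.0:
                    continue
                r = water_positions[w, k] - src_pos[mask]
                d = np.linalg.norm(r, axis=1)
                efield = (src_q[mask, None] * r / d[:, None] ** 3).sum(axis=0)
                dipoles[w, k] = alpha * efield  # e·Å

    raw = RawSolvatedSystem(
        solute_elements=tpl["elements"],
        solute_positions=tpl["positions"],
        solute_charge=tpl["charge"],
        water_positions=water_positions,
        water_charges=water_charges,
        water_dipoles=dipoles,
        provenance=f"synthetic:{solute_template},n={n_waters},seed={seed}")
    return partition_closest_n(raw, nw)


# ---------------------------------------------------------------------------
# snapshot bundles (directory of plain-text files)

def write_snapshot_bundle(snapshot: SolvatedSnapshot, directory):
    os.makedirs(directory, exist_ok=True)
    write_xyz(snapshot.qm_system, os.path.join(directory, "qm.xyz"),
              comment=snapshot.provenance)
    p = snapshot.partition
    with open(os.path.join(directory, "fragments.json"), "w") as fh:
        json.dump({"fragment_a": p.fragment_a_indices,
                   "fragment_b": p.fragment_b_indices,
                   "charge_a": p.charge_a, "charge_b": p.charge_b}, fh,
                  indent=1)
    write_point_charges(snapshot.mm_region,
                        os.path.join(directory, "mm_charges.pc"))
    if snapshot.mm_region.dipole_moments is not None:
        write_dipoles(snapshot.mm_region,
                      os.path.join(directory, "mm_dipoles.dip"))


def read_snapshot_bundle(directory) -> SolvatedSnapshot:
    qm = read_xyz(os.path.join(directory, "qm.xyz"))
    with open(os.path.join(directory, "fragments.json")) as fh:
        frag = json.load(fh)
    partition = FragmentPartition(frag["fragment_a"], frag["fragment_b"],
                                  frag["charge_a"], frag["charge_b"])
    qm = MolecularSystem(qm.atoms,
                         total_charge=frag["charge_a"] + frag["charge_b"])
    partition.validate(qm)
    pc_path = os.path.join(directory, "mm_charges.pc")
    dip_path = os.path.join(directory, "mm_dipoles.dip")
    positions, charges = read_point_charges(pc_path) if \
        os.path.exists(pc_path) else (np.zeros((0, 3)), np.zeros(0))
    dpos, dmom = read_dipoles(dip_path) if os.path.exists(dip_path) \
        else (None, None)
    mm = MMRegion(positions=positions, charges=charges,
                  dipole_positions=dpos, dipole_moments=dmom)
    return SolvatedSnapshot(qm_system=qm, partition=partition, mm_region=mm,
                            provenance=f"bundle:{directory}")
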