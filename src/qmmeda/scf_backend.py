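"""Electronic-structure backend: restricted Hartree–Fock on a shared AO frame.

All states of one energy decomposition (complex, counterpoise-padded
fragments, frozen determinant, constrained relaxations) live in the same
AO space — the full complex basis — so a single :class:`SCFFrame` owns
the integrals and every state is a density matrix plus bookkeeping.

Ghost atoms contribute basis functions but no nucleus and no electrons;
an MM embedding contributes a one-electron potential plus classical
nuclei–MM terms.  The decomposition algebra downstream is method-
agnostic at the single-determinant level; this backend implements RHF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from ._basis_data import BASIS_SETS
from .integrals import build_ao_basis
from .units import ANGSTROM_TO_BOHR

__all__ = [
    "BasisSpec", "GhostSpec", "SCFConfig", "SCFState", "FragmentPotential",
    "SCFFrame", "run_scf", "build_frozen_state",
    "relax_fragment_in_partner_field", "ConvergenceError",
    "UnsupportedError", "FrameError", "DegeneracyError",
]


class ConvergenceError(RuntimeError):
    pass


class UnsupportedError(ValueError):
    pass


class FrameError(ValueError):
    """States passed together do not share an AO frame/embedding."""


class DegeneracyError(RuntimeError):
    """Combined occupied spaces are (near-)linearly dependent."""


@dataclass(frozen=True)
class BasisSpec:
    """Basis-set label plus optional per-element override map."""

    name: str = "sto-3g"
    overrides: tuple = ()

    def shells(self, elements):
        key = self.name.lower()
        if key not in BASIS_SETS:
            raise UnsupportedError(
                f"basis {self.name!r} not available; shipped: "
                f"{sorted(BASIS_SETS)}")
        table = dict(BASIS_SETS[key])
        for el, name in dict(self.overrides).items():
            alt = name.lower()
            if alt not in BASIS_SETS or el not in BASIS_SETS[alt]:
                raise UnsupportedError(
                    f"override {el}->{name} not resolvable")
            table[el] = BASIS_SETS[alt][el]
        missing = sorted({e for e in elements if e not in table})
        if missing:
            raise UnsupportedError(
                f"basis {self.name!r} lacks elements {missing}")
        return table


@dataclass(frozen=True)
class GhostSpec:
    """Atom indices whose basis is present but nucleus/electrons absent."""

    ghost_atom_indices: tuple = ()

    def __init__(self, ghost_atom_indices=()):
        object.__setattr__(self, "ghost_atom_indices",
                           tuple(int(i) for i in ghost_atom_indices))


@dataclass(frozen=True)
class SCFConfig:
    tol_energy: float = 1e-10   # hartree
    tol_density: float = 1e-8   # RMS
    max_iter: int = 200
    diis_size: int = 8

    @classmethod
    def default(cls):
        return cls(tol_energy=1e-8, tol_density=1e-6)

    @classmethod
    def tight(cls):
        return cls(tol_energy=1e-10, tol_density=1e-8)


@dataclass
class SCFState:
    """A converged or constructed closed-shell electronic state."""

    total_energy: float              # hartree, incl. nuclear + MM constants
    density_matrix: np.ndarray       # AO basis, Tr(D S) = n_electrons
    occupied_orbitals: np.ndarray    # AO x n_occ coefficients
    n_electrons: int
    converged: bool
    basis: BasisSpec
    embedding: object = None         # EmbeddingSpec or None
    frame: "SCFFrame" = None
    real_indices: tuple = ()
    mo_energies: np.ndarray | None = None
    n_iterations: int = 0
    label: str = ""

    def trace_ds(self):
        return float(np.sum(self.density_matrix * self.frame.S))


@dataclass
class FragmentPotential:
    """Frozen electrostatic potential of a fragment (plus merged MM).

    ``matrix`` is the AO operator experienced by an *electron*:
    -sum_I Z_I/|r-R_I| + Hartree potential of the frozen density
    (- MM charge potential when the embedding is merged in).
    ``nuclear_sources``/``electron_density`` allow the classical
    potential to be evaluated at nuclei for energy constants.
    """

    matrix: np.ndarray
    frame: "SCFFrame"
    nuclear_sources: tuple            # ((Z, position-bohr), ...)
    electron_density: np.ndarray | None
    embedding: object = None
    label: str = ""

    def classical_potential_at(self, points_bohr):
        """phi(r) of the frozen fragment distribution, a.u. (e/bohr)."""
        pts = np.asarray(points_bohr, dtype=float).reshape(-1, 3)
        phi = np.zeros(pts.shape[0])
        for Z, R in self.nuclear_sources:
            phi += Z / np.linalg.norm(pts - R, axis=1)
        if self.electron_density is not None:
            for i, p in enumerate(pts):
                Vp = self.frame.basis.potential(p[None, :], np.ones(1))
                phi[i] -= float(np.sum(self.electron_density * Vp))
        if self.embedding is not None and not self.embedding.is_empty:
            mm_pos = self.embedding.positions * ANGSTROM_TO_BOHR
            for i, p in enumerate(pts):
                phi[i] += float(np.sum(
                    self.embedding.charges
                    / np.linalg.norm(mm_pos - p, axis=1)))
        return phi


class SCFFrame:
    """Shared AO space + integrals for one molecular geometry."""

    def __init__(self, system, basis: BasisSpec = BasisSpec()):
        self.system = system
        self.basis_spec = basis
        self.elements = system.elements
        self.positions_bohr = system.positions * ANGSTROM_TO_BOHR
        self.nuclear_charges = system.nuclear_charges
        self.basis = build_ao_basis(
            self.elements, self.positions_bohr, basis.shells(self.elements))
        self.nao = self.basis.nao
        self.S, self.T = self.basis.overlap_kinetic()
        self._eri = None
        self._v_atom = None
        self._dipole = None

    # ---- lazy integral blocks -------------------------------------------
    @property
    def eri(self):
        if self._eri is None:
            self._eri = self.basis.eri()
        return self._eri

    @property
    def v_atom(self):
        """v_atom[I] = AO matrix of 1/|r - R_I| for every atom center."""
        if self._v_atom is None:
            n = len(self.elements)
            self._v_atom = np.array([
                self.basis.potential(self.positions_bohr[i][None, :],
                                     np.ones(1))
                for i in range(n)])
        return self._v_atom

    @property
    def dipole_ints(self):
        if self._dipole is None:
            self._dipole = self.basis.dipole()
        return self._dipole

    # ---- one-electron pieces --------------------------------------------
    def nuclear_attraction(self, real_indices):
        """-sum_{I in real} Z_I <mu|1/|r-R_I||nu>."""
        V = np.zeros((self.nao, self.nao))
        for i in real_indices:
            V -= self.nuclear_charges[i] * self.v_atom[i]
        return V

    def mm_matrix(self, embedding):
        """Electron / MM-charge interaction matrix (negative of potential)."""
        if embedding is None or embedding.is_empty:
            return np.zeros((self.nao, self.nao))
        pts = embedding.positions * ANGSTROM_TO_BOHR
        return -self.basis.potential(pts, embedding.charges)

    def nuclear_repulsion(self, real_indices):
        e = 0.0
        idx = list(real_indices)
        for a in range(len(idx)):
            for b in range(a):
                i, j = idx[a], idx[b]
                e += (self.nuclear_charges[i] * self.nuclear_charges[j]
                      / np.linalg.norm(self.positions_bohr[i]
                                       - self.positions_bohr[j]))
        return e

    def nuclei_embedding_energy(self, real_indices, embedding):
        """Classical nuclei–MM Coulomb energy, hartree."""
        if embedding is None or embedding.is_empty:
            return 0.0
        pts = embedding.positions * ANGSTROM_TO_BOHR
        e = 0.0
        for i in real_indices:
            d = np.linalg.norm(pts - self.positions_bohr[i], axis=1)
            e += self.nuclear_charges[i] * float(
                np.sum(embedding.charges / d))
        return e

    def coulomb(self, D):
        return np.einsum("pqrs,rs->pq", self.eri, D, optimize=True)

    def exchange(self, D):
        return np.einsum("prqs,rs->pq", self.eri, D, optimize=True)

    def core_hamiltonian(self, real_indices, embedding=None, extra_oei=None,
                         uniform_field=None):
        h = self.T + self.nuclear_attraction(real_indices)
        h = h + self.mm_matrix(embedding)
        if extra_oei is not None:
            h = h + extra_oei
        if uniform_field is not None:
            f = np.asarray(uniform_field, dtype=float)
            for k in range(3):
                if f[k] != 0.0:
                    h = h + f[k] * self.dipole_ints[k]
        return h

    def constant_energy(self, real_indices, embedding=None,
                        uniform_field=None, extra_const=0.0):
        const = self.nuclear_repulsion(real_indices)
        const += self.nuclei_embedding_energy(real_indices, embedding)
        if uniform_field is not None:
            f = np.asarray(uniform_field, dtype=float)
            for i in real_indices:
                const -= self.nuclear_charges[i] * float(
                    f @ self.positions_bohr[i])
        return const + extra_const

    # ---- energies of given densities ------------------------------------
    def electronic_energy(self, D, h):
        J = self.coulomb(D)
        K = self.exchange(D)
        return float(np.sum(D * h) + 0.5 * np.sum(D * J)
                     - 0.25 * np.sum(D * K))

    def energy_of_density(self, D, real_indices, embedding=None,
                          extra_oei=None, uniform_field=None,
                          extra_const=0.0):
        """Total RHF energy of a supplied (idempotent) density matrix."""
        h = self.core_hamiltonian(real_indices, embedding, extra_oei,
                                  uniform_field)
        return self.electronic_energy(D, h) + self.constant_energy(
            real_indices, embedding, uniform_field, extra_const)

    # ---- the SCF driver ---------------------------------------------------
    def ao_indices_of_atoms(self, atom_indices):
        """AO indices centered on the given atoms."""
        atoms = set(int(i) for i in atom_indices)
        return np.array([k for k in range(self.nao)
                         if int(self.basis.ao_atom[k]) in atoms])

    def scf(self, real_indices, charge=0, embedding=None, extra_oei=None,
            uniform_field=None, extra_const=0.0, config=SCFConfig.tight(),
            initial_density=None, ao_restrict=None, label="") -> SCFState:
        """Converge an RHF state.

        ``ao_restrict`` limits the variational space to a subset of AO
        indices (used for constrained fragment relaxations, where the
        response must stay within the fragment's own basis).
        """
        real_indices = tuple(int(i) for i in real_indices)
        nelec = int(sum(self.nuclear_charges[i] for i in real_indices)
                    - charge)
        if nelec < 0:
            raise UnsupportedError(f"negative electron count {nelec}")
        if nelec % 2 != 0:
            raise UnsupportedError(
                f"open-shell fragment (n_electrons={nelec}) is not "
                "supported by the closed-shell decomposition")
        const = self.constant_energy(real_indices, embedding, uniform_field,
                                     extra_const)
        if nelec == 0:
            D = np.zeros((self.nao, self.nao))
            return SCFState(
                total_energy=const, density_matrix=D,
                occupied_orbitals=np.zeros((self.nao, 0)), n_electrons=0,
                converged=True, basis=self.basis_spec, embedding=embedding,
                frame=self, real_indices=real_indices, label=label)
        h = self.core_hamiltonian(real_indices, embedding, extra_oei,
                                  uniform_field)
        if ao_restrict is None:
            sub = np.arange(self.nao)
            h_s, S_s, eri_s = h, self.S, self.eri
            D0 = initial_density
        else:
            sub = np.asarray(sorted(int(i) for i in ao_restrict))
            ix = np.ix_(sub, sub)
            h_s = h[ix]
            S_s = self.S[ix]
            eri_s = self.eri[np.ix_(sub, sub, sub, sub)]
            D0 = None if initial_density is None else initial_density[ix]
        try:
            e_elec, D_s, C_s, mo_e, iters = _rhf_loop(
                h_s, S_s, eri_s, nelec, config, D0, label)
        except ConvergenceError:
            # oscillation between near-degenerate occupations: damp with
            # a level shift (does not change the converged solution)
            e_elec, D_s, C_s, mo_e, iters = _rhf_loop(
                h_s, S_s, eri_s, nelec,
                SCFConfig(tol_energy=config.tol_energy,
                          tol_density=config.tol_density,
                          max_iter=2 * config.max_iter,
                          diis_size=config.diis_size),
                D0, label, level_shift=0.25)
        if ao_restrict is None:
            D, C = D_s, C_s
        else:
            D = np.zeros((self.nao, self.nao))
            D[np.ix_(sub, sub)] = D_s
            C = np.zeros((self.nao, C_s.shape[1]))
            C[sub] = C_s
        return SCFState(
            total_energy=e_elec + const, density_matrix=D,
            occupied_orbitals=C, n_electrons=nelec,
            converged=True, basis=self.basis_spec, embedding=embedding,
            frame=self, real_indices=real_indices,
            mo_energies=mo_e, n_iterations=iters, label=label)

    # ---- fragment potentials ---------------------------------------------
    def fragment_potential(self, state: SCFState, include_embedding=False,
                           label="") -> FragmentPotential:
        """Frozen electrostatic (Coulomb-only) potential of a fragment."""
        mat = self.nuclear_attraction(state.real_indices) \
            + self.coulomb(state.density_matrix)
        emb = state.embedding if include_embedding else None
        if emb is not None:
            mat = mat + self.mm_matrix(emb)
        nuc = tuple((float(self.nuclear_charges[i]),
                     self.positions_bohr[i].copy())
                    for i in state.real_indices)
        return FragmentPotential(
            matrix=mat, frame=self, nuclear_sources=nuc,
            electron_density=state.density_matrix.copy(), embedding=emb,
            label=label)

    def point_charge_potential(self, positions_angstrom, charges,
                               label="point charges") -> FragmentPotential:
        """Classical external potential from bare point charges."""
        pos_b = np.asarray(positions_angstrom, dtype=float).reshape(-1, 3) \
            * ANGSTROM_TO_BOHR
        qs = np.asarray(charges, dtype=float).reshape(-1)
        mat = -self.basis.potential(pos_b, qs)
        nuc = tuple((float(q), p.copy()) for q, p in zip(qs, pos_b))
        return FragmentPotential(matrix=mat, frame=self,
                                 nuclear_sources=nuc, electron_density=None,
                                 label=label)


def _rhf_loop(h, S, eri, nelec, config: SCFConfig, initial_density=None,
              label="", level_shift=0.0):
    """Closed-shell SCF iterations with DIIS on a fixed integral set.

    ``level_shift`` (hartree) raises the virtual manifold to damp
    oscillations between near-degenerate occupations; it alters the
    iteration path only, not the converged energy.  Returns
    (electronic energy, density, occupied coefficients, MO energies,
    iteration count).
    """
    nocc = nelec // 2
    s_eval, s_evec = np.linalg.eigh(S)
    keep = s_eval > 1e-10
    X = s_evec[:, keep] / np.sqrt(s_eval[keep])

    def diag(F, D_prev):
        Fp = X.T @ F @ X
        if level_shift != 0.0:
            P = 0.5 * X.T @ S @ D_prev @ S @ X
            Fp = Fp + level_shift * (np.eye(Fp.shape[0]) - P)
        e, Cp = np.linalg.eigh(Fp)
        return e, X @ Cp

    def gmat(D):
        J = np.einsum("pqrs,rs->pq", eri, D, optimize=True)
        K = np.einsum("prqs,rs->pq", eri, D, optimize=True)
        return J - 0.5 * K

    if initial_density is not None:
        D = initial_density
    else:
        _, C = diag(h, np.zeros_like(h))
        D = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    e_old = None
    e_new = float("nan")
    drms = float("nan")
    fock_list, err_list = [], []
    for it in range(1, config.max_iter + 1):
        F = h + gmat(D)
        err = F @ D @ S - S @ D @ F
        fock_list.append(F)
        err_list.append(err)
        if len(fock_list) > config.diis_size:
            fock_list.pop(0)
            err_list.pop(0)
        if len(fock_list) > 1:
            m = len(fock_list)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for a in range(m):
                for b in range(m):
                    B[a, b] = np.sum(err_list[a] * err_list[b])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                coef = np.linalg.solve(B, rhs)[:m]
                F = sum(c * f for c, f in zip(coef, fock_list))
            except np.linalg.LinAlgError:
                pass
        mo_e, C = diag(F, D)
        D_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        e_new = float(np.sum(D_new * h) + 0.5 * np.sum(D_new * gmat(D_new)))
        drms = float(np.sqrt(np.mean((D_new - D) ** 2)))
        D = D_new
        if e_old is not None and abs(e_new - e_old) < config.tol_energy \
                and drms < config.tol_density:
            return e_new, D, C[:, :nocc], mo_e, it
        e_old = e_new
    raise ConvergenceError(
        f"SCF did not converge in {config.max_iter} iterations "
        f"(last dE={abs(e_new - (e_old if e_old is not None else e_new)):.2e},"
        f" dRMS={drms:.2e}, label={label!r})")


# ---------------------------------------------------------------------------
# module-level operations

def run_scf(system, basis=BasisSpec(), ghosts=GhostSpec(), embedding=None,
            method="rhf", config=SCFConfig.tight(), uniform_field=None,
            frame=None, charge=None, label="") -> SCFState:
    """SCF of a system with optional ghost atoms and MM embedding.

    Ghost atoms keep their basis functions in the variational space but
    contribute no nucleus and no electrons (counterpoise scheme).
    """
    if method.lower() not in ("rhf", "hf", "scf"):
        raise UnsupportedError(
            f"method {method!r} not available in the built-in backend; "
            "use 'rhf'")
    if frame is None:
        frame = SCFFrame(system, basis)
    ghost = set(ghosts.ghost_atom_indices)
    bad = [i for i in ghost if i < 0 or i >= system.n_atoms]
    if bad:
        raise ValueError(f"ghost indices out of range: {bad}")
    real = [i for i in range(system.n_atoms) if i not in ghost]
    chg = system.total_charge if charge is None else charge
    return frame.scf(real, charge=chg, embedding=embedding,
                     uniform_field=uniform_field, config=config, label=label)


def build_frozen_state(state_a: SCFState, state_b: SCFState,
                       embedding=None, cond_threshold=1e10) -> SCFState:
    """Antisymmetrized frozen state from two fragment states.

    Occupied orbitals of A and B (already expressed in the shared
    complex AO space via their ghost-padded SCFs) are concatenated and
    symmetrically (Löwdin) orthogonalized; the energy is the full-system
    expectation value over the resulting determinant, embedding included.
    """
    if state_a.frame is not state_b.frame:
        raise FrameError("fragment states do not share an AO frame")
    frame = state_a.frame
    C = np.hstack([state_a.occupied_orbitals, state_b.occupied_orbitals])
    nocc = C.shape[1]
    if nocc == 0:
        D = np.zeros((frame.nao, frame.nao))
    else:
        M = C.T @ frame.S @ C
        evals = np.linalg.eigvalsh(M)
        if evals[0] <= 0 or evals[-1] / evals[0] > cond_threshold:
            raise DegeneracyError(
                "combined occupied spaces are near-linearly dependent "
                f"(condition number {evals[-1] / max(evals[0], 1e-300):.2e})")
        M_inv_half = sla.fractional_matrix_power(M, -0.5).real
        C = C @ M_inv_half
        D = 2.0 * C @ C.T
    real = tuple(sorted(set(state_a.real_indices)
                        | set(state_b.real_indices)))
    energy = frame.energy_of_density(D, real, embedding=embedding)
    return SCFState(
        total_energy=energy, density_matrix=D, occupied_orbitals=C,
        n_electrons=state_a.n_electrons + state_b.n_electrons,
        converged=True, basis=frame.basis_spec, embedding=embedding,
        frame=frame, real_indices=real, label="frozen")


def relax_fragment_in_partner_field(own_state: SCFState,
                                    partner_potential: FragmentPotential,
                                    config=SCFConfig.tight(),
                                    restrict_to_own_aos=True) -> SCFState:
    """SCF of one fragment in the frozen electrostatic field of its partner.

    The fragment keeps its own Hamiltonian (nuclei + electrons + its own
    merged MM embedding, if any); the partner enters only through the
    frozen one-electron potential.  The variational space is restricted
    to the fragment's own AO functions: the first-order density is an
    intrafragment response, and an unconstrained relaxation would let
    the electrons collapse onto the partner's bare nuclear wells (no
    Pauli exclusion from the frozen partner electrons in a purely
    electrostatic potential).  The relaxed minus unperturbed density is
    that fragment's polarization density.
    """
    frame = own_state.frame
    if partner_potential.frame is not frame:
        raise FrameError("partner potential built on a different frame")
    # classical interaction of own nuclei with the frozen partner field
    own_nuc_pos = np.array([frame.positions_bohr[i]
                            for i in own_state.real_indices])
    own_Z = np.array([frame.nuclear_charges[i]
                      for i in own_state.real_indices])
    if len(own_state.real_indices):
        phi = partner_potential.classical_potential_at(own_nuc_pos)
        const = float(own_Z @ phi)
    else:
        const = 0.0
    ao_restrict = frame.ao_indices_of_atoms(own_state.real_indices) \
        if restrict_to_own_aos else None
    charge = int(round(sum(own_Z) - own_state.n_electrons))
    return frame.scf(
        own_state.real_indices, charge=charge, embedding=own_state.embedding,
        extra_oei=partner_potential.matrix, extra_const=const, config=config,
        initial_density=own_state.density_matrix, ao_restrict=ao_restrict,
        label=f"relax({own_state.label})")
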