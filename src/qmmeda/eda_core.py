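"""The energy decomposition itself.

The counterpoise-corrected solute–solvent interaction energy

    dE = E_AB - E_A - E_B          (fragments in the full complex basis)

is split into

    dE = E_elec + E_Pau + E_pol,
    E_pol = E_ind + E_disp,

with E_elec the classical Coulomb interaction between the frozen
fragment charge distributions, E_Pau the energy difference between the
antisymmetrized frozen determinant and (fragments + E_elec), E_pol the
variational relaxation from the frozen determinant to the complex SCF,
and the induction/dispersion split evaluated at second-order
perturbation level from constrained fragment relaxations.

Under QM/MM embedding the MM charge potential is merged into the
solvent fragment's nuclear potential and the solute-nuclei–MM Coulomb
term is added to the electrostatic component, so the decomposition sums
to the full QM/MM interaction energy (solute against QM + MM solvent).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .embedding import MMRegion, merged_fragment_potential
from .scf_backend import (SCFFrame, SCFConfig, BasisSpec, SCFState,
                          build_frozen_state, relax_fragment_in_partner_field,
                          FrameError, UnsupportedError)
from .units import HARTREE_TO_KCAL
from . import induction_pt

__all__ = ["EDAConfig", "DeformationDensities", "EDAResult",
           "electrostatic_energy", "pauli_energy", "polarization_energy",
           "assemble_eda", "EMBEDDING_MODES"]

EMBEDDING_MODES = ("none", "charges", "charges+dipoles")


@dataclass(frozen=True)
class EDAConfig:
    method: str = "rhf"
    basis: str = "sto-3g"
    embedding_mode: str = "charges"
    scf: SCFConfig = field(default_factory=SCFConfig.tight)

    def __post_init__(self):
        if self.embedding_mode not in EMBEDDING_MODES:
            raise ValueError(
                f"embedding_mode must be one of {EMBEDDING_MODES}")

    def key(self):
        return json.dumps({
            "method": self.method, "basis": self.basis,
            "embedding": self.embedding_mode,
            "tol_e": self.scf.tol_energy, "tol_d": self.scf.tol_density},
            sort_keys=True)


@dataclass
class DeformationDensities:
    """Pauli and polarization electron deformation densities (AO)."""

    pauli: np.ndarray          # D_frozen - D_A - D_B
    polarization: np.ndarray   # D_complex - D_frozen

    def traces(self, overlap):
        """Electron-conservation residuals Tr(dD·S); both must vanish."""
        return (float(np.sum(self.pauli * overlap)),
                float(np.sum(self.polarization * overlap)))


@dataclass
class EDAResult:
    """Interaction-energy components in kcal/mol plus diagnostics."""

    e_elec: float
    e_pauli: float
    e_pol: float
    e_ind: float
    e_disp: float
    e_total: float
    cp_total: float
    closure_residual: float
    induction_diagnostics: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def components(self):
        return {"ELE": self.e_elec, "PAU": self.e_pauli, "POL": self.e_pol,
                "TOT": self.e_total, "DISP": self.e_disp, "IND": self.e_ind}

    def to_dict(self):
        d = asdict(self)
        return d

    def to_json(self, path=None, indent=1):
        payload = json.dumps(self.to_dict(), indent=indent, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _require_shared_frame(*states):
    frames = {id(s.frame) for s in states if s is not None}
    if len(frames) > 1:
        raise FrameError("states do not share an AO frame")


def electrostatic_energy(state_a: SCFState, state_b: SCFState, partition,
                         embedding=None) -> float:
    """Classical Coulomb interaction of the frozen fragment distributions.

    Nuclear–nuclear cross term + nuclear–electron both directions +
    electron–electron Hartree cross term; with an MM embedding attached
    to fragment B the MM potential acts on A's frozen density and the
    solute-nuclei–MM term is added.  Returns kcal/mol.
    """
    _require_shared_frame(state_a, state_b)
    frame = state_a.frame
    ia, ib = state_a.real_indices, state_b.real_indices
    Z = frame.nuclear_charges
    pos = frame.positions_bohr
    e = 0.0
    for i in ia:
        for j in ib:
            e += Z[i] * Z[j] / np.linalg.norm(pos[i] - pos[j])
    Da, Db = state_a.density_matrix, state_b.density_matrix
    # electrons of A in B's nuclear potential and vice versa
    e += float(np.sum(Da * frame.nuclear_attraction(ib)))
    e += float(np.sum(Db * frame.nuclear_attraction(ia)))
    # Hartree cross term
    e += float(np.sum(Da * frame.coulomb(Db)))
    # MM region merged into fragment B: acts on A's frozen distribution
    if embedding is not None and not embedding.is_empty:
        e += float(np.sum(Da * frame.mm_matrix(embedding)))
        e += frame.nuclei_embedding_energy(ia, embedding)
    return e * HARTREE_TO_KCAL


def pauli_energy(frozen: SCFState, state_a: SCFState, state_b: SCFState,
                 e_elec: float) -> float:
    """Exchange + repulsion evaluated jointly as an energy difference:
    E_Pau = E_frozen - E_A - E_B - E_elec (kcal/mol)."""
    _require_shared_frame(frozen, state_a, state_b)
    return (frozen.total_energy - state_a.total_energy
            - state_b.total_energy) * HARTREE_TO_KCAL - e_elec


def polarization_energy(complex_state: SCFState, frozen: SCFState) -> float:
    """Variational relaxation from the frozen determinant (kcal/mol, <= 0)."""
    _require_shared_frame(complex_state, frozen)
    return (complex_state.total_energy - frozen.total_energy) \
        * HARTREE_TO_KCAL


def assemble_eda(snapshot, config: EDAConfig = EDAConfig()) -> EDAResult:
    """Full decomposition of one solvated snapshot.

    Runs the three SCF calculations (complex with embedding, fragment A
    with B's ghost basis and no MM, fragment B with A's ghost basis and
    the merged MM embedding), builds the frozen antisymmetrized state,
    evaluates the components and the induction/dispersion split, and
    cross-checks against the counterpoise-corrected supermolecular
    interaction energy.
    """
    system = snapshot.qm_system
    partition = snapshot.partition
    partition.validate(system)
    mm_region = snapshot.mm_region if snapshot.mm_region is not None \
        else MMRegion.empty()

    if config.embedding_mode == "none":
        emb = None
    else:
        emb = merged_fragment_potential(
            partition, mm_region, qm_positions=system.positions,
            include_dipoles=(config.embedding_mode == "charges+dipoles"))
        if emb.is_empty:
            emb = None

    if config.method.lower() not in ("rhf", "hf", "scf"):
        raise UnsupportedError(
            f"method {config.method!r} not available; use 'rhf'")

    frame = SCFFrame(system, BasisSpec(config.basis))
    ia = partition.fragment_a_indices
    ib = partition.fragment_b_indices

    state_a = frame.scf(ia, charge=partition.charge_a, embedding=None,
                        config=config.scf, label="fragment A")
    state_b = frame.scf(ib, charge=partition.charge_b, embedding=emb,
                        config=config.scf, label="fragment B")
    complex_state = frame.scf(
        list(range(system.n_atoms)), charge=system.total_charge,
        embedding=emb, config=config.scf, label="complex",
        initial_density=state_a.density_matrix + state_b.density_matrix)

    frozen = build_frozen_state(state_a, state_b, embedding=emb)

    e_elec = electrostatic_energy(state_a, state_b, partition, emb)
    e_pau = pauli_energy(frozen, state_a, state_b, e_elec)
    e_pol = polarization_energy(complex_state, frozen)
    e_total = e_elec + e_pau + e_pol
    cp_total = (complex_state.total_energy - state_a.total_energy
                - state_b.total_energy) * HARTREE_TO_KCAL
    closure = e_total - cp_total

    deform = DeformationDensities(
        pauli=frozen.density_matrix - state_a.density_matrix
        - state_b.density_matrix,
        polarization=complex_state.density_matrix - frozen.density_matrix)
    tr_pau, tr_pol = deform.traces(frame.S)

    ind = induction_pt.induction_dispersion(
        frame, state_a, state_b, e_pol, embedding=emb, config=config.scf)

    meta = {
        "method": config.method, "basis": config.basis,
        "embedding_mode": "none" if emb is None else emb.mode,
        "n_mm_charges": 0 if emb is None else int(emb.charges.size),
        "n_qm_waters": len(ib) // 3,
        "snapshot": snapshot.provenance,
        "scf_tolerances": [config.scf.tol_energy, config.scf.tol_density],
        "trace_pauli_density": tr_pau,
        "trace_polarization_density": tr_pol,
        "second_order_caveat": (
            "the induction/dispersion split of polarization is exact only "
            "at second-order perturbation level; treat it as indicative "
            "for strongly interacting ions"),
        "config_hash": hashlib.sha1(config.key().encode()).hexdigest()[:12],
    }
    if ind.warning:
        meta["induction_warning"] = ind.warning

    return EDAResult(
        e_elec=e_elec, e_pauli=e_pau, e_pol=e_pol,
        e_ind=ind.e_ind, e_disp=ind.e_disp,
        e_total=e_total, cp_total=cp_total, closure_residual=closure,
        induction_diagnostics=ind.diagnostics(), metadata=meta)
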