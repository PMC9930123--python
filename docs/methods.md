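# Methods

This note documents the model implemented in `qmmeda`, its assumptions,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## The decomposition

The interaction energy of two closed-shell fragments A (solute) and B
(solvent) at the complex geometry is the counterpoise-corrected
supermolecular difference ΔE = E_AB − E_A − E_B, with both fragment
energies computed in the full complex basis (ghost functions on the
absent fragment's atoms).  Three SCF solutions and one constructed
determinant define the components:

1. **Fragment states.**  A is converged with B's atoms as ghosts and no
   MM potential; B is converged with A's atoms as ghosts and, when
   embedding is active, with the MM charge potential merged into its
   one-electron Hamiltonian (the MM region belongs to the solvent).
2. **E_elec** is assembled from integrals over the two frozen densities:
   nuclear–nuclear cross terms, nuclear–electron attraction in both
   directions, the Hartree cross term, plus — under embedding — the MM
   potential acting on A's frozen density and the classical
   solute-nuclei–MM sum.  No exchange enters: this is the classical
   electrostatic interaction of unperturbed charge distributions.
3. **E_Pau.**  The occupied orbitals of both fragment states are
   concatenated and symmetrically (Löwdin) orthogonalized; the resulting
   idempotent determinant is the frozen antisymmetrized state.
   E_Pau = E_frozen − E_A − E_B − E_elec evaluates exchange and
   repulsion jointly as an energy difference.  Löwdin was chosen over
   sequential schemes because it treats the fragments symmetrically and
   is invariant to basis ordering; a Gram–Schmidt construction spans the
   same occupied space and must give the same energy (tested to
   1e-8 hartree).
4. **E_pol** = E_complex − E_frozen ≤ 0 by the variational principle
   (the frozen determinant is an admissible trial state of the complex
   Fock problem).

Because the three components telescope, their sum equals ΔE
identically; the reported `closure_residual` measures only arithmetic
consistency and sits at machine precision.  Electron conservation,
Tr(Δρ_Pau·S) = Tr(Δρ_pol·S) = 0, is checked on every run.

## Induction and dispersion

The polarization component is split at second-order perturbation level.
Each fragment is relaxed self-consistently in the frozen electrostatic
(Coulomb-only) potential of its partner — v̂_B carries the merged MM
potential, v̂_A does not.  Two deliberate constraints:

- **Intrafragment response.**  The relaxation is restricted to the
  fragment's own AO functions.  The perturbative first-order density is
  a sum of intrafragment excitations; an unconstrained relaxation in the
  full complex basis would let electrons collapse onto the partner's
  bare nuclei (a purely electrostatic potential carries no Pauli
  exclusion from the frozen partner electrons).  Consequently the
  polarization densities Δρ_pol^F are measured against the fragment's
  SCF in that same restricted (monomer) space, free of counterpoise
  components.
- **No mutual iteration.**  A responds to frozen B and B to frozen A;
  the two responses are never coupled self-consistently, matching the
  uncoupled second-order picture (and the frozen induced dipoles of the
  polarizable embedding).

From the charge-induction energy E_ch-ind = ∫Δρ_pol^A v̂_B +
∫Δρ_pol^B v̂_A and the intrafragment deformation costs
E_intra^F = E_F[relaxed] − E_F[unperturbed] ≥ 0 (each fragment's own
Hamiltonian, embedding included for B), induction is the total
relaxation energy E_ind = E_ch-ind + E_intra^A + E_intra^B.  In the
linear-response regime this equals E_ch-ind/2 ("half of the gain is
wasted polarizing"); both routes are computed and their discrepancy is
serialized in `induction_diagnostics`.  Beyond the tolerance
(1% relative or 0.05 kcal/mol, whichever is larger) a warning is
recorded in the metadata — never raised — because strong ion–water
coupling genuinely leaves the second-order regime.  Dispersion is
defined as the exact remainder E_disp = E_pol − E_ind; at the
single-determinant level this remainder contains interfragment
relaxation and coupling rather than true London dispersion, which is
why it is reported with the second-order caveat in the result metadata.
Positive induction values are reported as-is and flagged, not clipped.

## MM embedding

Fixed charges enter the solvent fragment's Hamiltonian as
−Σ_i q_i ∫χ_μ |r−R_i|⁻¹ χ_ν and the nuclei–MM cross terms as classical
Coulomb sums (k = 332.0637 kcal·Å/(mol·e²)).  Induced dipoles are
represented as charge pairs ±|μ|/d at R ± (d/2)μ̂ with d = 1e-3 Å by
default; the pair potential converges to the point-dipole form as
O(d²).  d is validated against 0.1× the shortest QM–MM distance at
embedding time.  The unphysical intra-pair self-energy is never
evaluated: only MM→QM potentials and nuclei–MM cross terms exist in the
code.  MM self-energy in general (charge–charge within the MM region)
is likewise excluded — it cancels in every difference the decomposition
reports.  Mutual QM↔MM polarization is out of scope: dipoles are frozen
input.

## SCF backend

A restricted Hartree–Fock engine over contracted cartesian s/p
Gaussians (McMurchie–Davidson integrals, numba-compiled; Boys function
by series + downward recursion, switching to the asymptotic branch at
x > 35).  STO-3G is shipped for H, He, C, N, O, F and Na — every
element the templates and fixtures produce.  The decomposition algebra
is method-agnostic for single determinants, so conclusions about the
*machinery* (closure, embedding equivalence, classical limits) transfer
to any backend; absolute component values at STO-3G are qualitative.
DIIS with a canonical-orthogonalization threshold of 1e-10 on overlap
eigenvalues; on oscillation between near-degenerate occupations
(e.g. ionic dissociation limits) the driver retries with a 0.25 hartree
virtual level shift, which alters the iteration path only.  Tolerances:
ΔE < 1e-10 hartree and RMS(ΔD) < 1e-8 (the `tight` preset, default for
every decomposition, so component sums close far below 0.01 kcal/mol);
a `default` preset (1e-8/1e-6) exists for scans where speed matters.
The complex SCF is seeded with D_A + D_B, which both accelerates
convergence and selects the physically relevant (e.g. ionic) basin.

## Synthetic snapshots

The generator emulates one MD frame: a rigid template solute (ammonium,
glycine zwitterion, or formate) surrounded by rigid three-site waters
(O–H 0.9572 Å, 104.52°) carrying TIP3P charges (O −0.834 e,
H +0.417 e), placed on concentric shells (first shell 3.0 Å, spacing
1.0 Å) with uniformly random orientations and a 2.25 Å minimum
interatomic distance — first-shell O···N/O contacts of ~2.6–3.0 Å,
realistic for water around small ions.  With the polarizable option
each water oxygen carries an induced dipole μ = αE with α = 0.53 Å³
(the classic polarizable-water oxygen value; hydrogens 0), E being the
Coulomb field of the solute template charges and all other waters'
fixed charges — a water is not polarized by its own sites, and the
dipoles are *not* iterated to self-consistency, mirroring how a
polarizable force field's converged dipoles arrive as frozen input.
Everything is deterministic in the seed.

What the generator does **not** emulate: thermal disorder from a real
trajectory (orientations are random, not Boltzmann-weighted), hydrogen-
bond network structure, solute flexibility, counterions, or bulk
density beyond a few shells.  A green test on synthetic snapshots
therefore establishes that the machinery is correct — closure,
embedding equivalence, conservation laws, classical limits — not that
any particular converged QM-region size transfers to real MD frames;
published reference decompositions require the original trajectory
snapshot, which is not distributable.

## Scans and statistics

`run_scan` re-partitions one snapshot at increasing QM sizes (waters
ranked by the minimum distance from any of their three atoms to the
solute's center of mass; ties broken by input order) and reports each
component's deviation from the largest-region reference.
`converged_size` returns the smallest size whose deviations — and those
of every larger sampled size — stay within ±1 kcal/mol; entering the
band once is not enough, and `None` is a valid outcome (anions
typically fail to converge).  Ensemble statistics use the sample
(n−1) standard deviation — the convention matters at n = 20 and is
recorded in the output — and RSTD = 100·σ/|mean|, reported as missing
when the mean vanishes.  `sample_mean_convergence` subsamples a
time-ordered ensemble at equispaced indices (0, n//k, 2·n//k, ...);
it is order-dependent by design and documented as such.

## Known limitations

- RHF only: no DFT functionals, open shells, or post-SCF correlation;
  STO-3G only (minimal-basis polarizabilities are small, so induction
  magnitudes are lower bounds).
- The exchange/repulsion separation inside the Pauli term is not
  implemented (energy-difference evaluation only).
- Dispersion is a second-order remainder, not a correlated dispersion
  energy.
- Water recognition requires contiguous O,H,H triplets after the solute
  block (O–H < 1.3 Å), matching MD topology ordering; arbitrary solvent
  topologies are not perceived.
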