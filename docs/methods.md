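# Methods

This note documents the models, conventions and numerical choices behind
`qeqnn`, in the order a prediction flows through the code.

## Energy model

The total energy of a configuration with positions R and total charge Q is

    E_total(R, Q) = E_elec(R, Q) + E_short(R, Q)

**Electrostatics.** Atomic charges are Gaussian distributions of per-element
width sigma_i. The electrostatic energy combines pairwise screened Coulomb
interactions and self terms,

    E_elec = sum_{i<j} ke Q_i Q_j erf(r_ij / (sqrt2 gamma_ij)) / r_ij
           + sum_i ke Q_i^2 / (2 sigma_i sqrt(pi)),
    gamma_ij = sqrt(sigma_i^2 + sigma_j^2),

with ke = 14.399645 eV A/e^2. The charges themselves minimize the
charge-equilibration (Qeq) functional

    E_Qeq = E_elec + sum_i (chi_i Q_i + J_i Q_i^2 / 2)

subject to sum_i Q_i = Q_tot. Stationarity gives a linear system
`A Q + chi + lambda 1 = 0`, which we solve together with the constraint as
one augmented (N+1)-dimensional LU-factored solve; the Lagrange multiplier
lambda is reported with the solution. J_i is an element hardness; chi_i is
predicted per atom by a neural network (below).

**Periodic systems.** A is built by Ewald summation: a reciprocal-space sum
over k != 0 with Gaussian splitting width eta, a real-space correction
`[erf(r/(sqrt2 gamma)) - erf(r/(sqrt2 eta))]/r` over all image pairs within
`r_cut_real`, a diagonal `ke sqrt(2/pi) (1/gamma_ii - 1/eta)`, and a uniform
background term `-2 pi ke eta^2 / V` that makes energies of non-neutral
cells independent of eta. Written this way every term carries ke and has
units of eV/e^2; the splitting-parameter-independence property (energies and
forces agree to < 1e-6 between eta = 0.5 and 1.0 A) is tested and is the
operative check on the diagonal convention. eta, r_cut_real and the k-space
cutoff are chosen from an accuracy target (default truncation scale 1e-8):
`r_cut_real = sqrt2 * max(eta, gamma_max) * erfcinv(tol)` and
`k_cut = sqrt(2 ln(1/tol)) / eta`. The implied boundary condition is
tin-foil (conducting); a periodic cell therefore differs from the same
cluster in vacuum by the dipole surface term, which vanishes for dipole-free
charge distributions.

**Forces.** Forces are total derivatives of E_total(R, Q(R)). The implicit
charge response dQ/dR is obtained by one adjoint solve of the factored
augmented system per configuration: with g = dE/dQ (Coulomb plus the
short-range network's charge-input sensitivity), solving M [u; mu] = [g; 0]
turns every response term into contractions of u with dA/dR and dchi/dR.
dA/dR is stored as a per-pair vector table (the kernel depends only on pair
geometry), so force kernels cost O(N^2), not O(N^3). Analytic forces match
central finite differences to < 1e-5 eV/A on random water boxes; this is an
acceptance property.

## Descriptors

Local environments are encoded by atom-centered symmetry functions: radial
G2 terms `exp(-eta (r - r_s)^2) fc(r)` and angular G4 terms
`2^(1-zeta) (1 + lambda cos theta)^zeta exp(-eta (r_ij^2 + r_ik^2 + r_jk^2))
fc(r_ij) fc(r_ik) fc(r_jk)` with the cosine cutoff
`fc = (cos(pi r / r_cut) + 1)/2`. Two built-in O/H sets:

* `default`: 8 radial widths (0.001-1.5 1/A^2) per element pair at
  r_cut = 6.35 A (12 bohr) and 8 angular functions per element triple
  (eta in {1e-4, 0.03}, zeta in {1, 4}, lambda = +-1), mirroring common
  published water sets;
* `compact`: 4 radial widths at 6.0 A and a 3.8 A angular cutoff — the set
  used in the package's own desk-scale benchmarks, chosen to keep the
  triple loops cheap in cells of ~25 atoms.

Both are serializable to an n2p2-style settings file and fully
user-overridable. Descriptors are min/max scaled to [-1, 1] on the training
set; functions constant over the training set are flagged degenerate and map
to zero. Neighbor lists replicate the cell by as many images as the cutoff
requires, so cutoffs larger than the box are handled exactly. Gradients are
accumulated analytically per neighbor (numba kernels) and verified against
finite differences at 1e-6.

## Networks and training

Each element has two feed-forward networks with two hidden layers of 15
tanh nodes and a linear output: an electronegativity network
chi_i = NN_chi(G_i), and a short-range atomic-energy network
E_i = NN_E(G_i ++ Q_i) whose extra input is the equilibrated atomic charge
(min/max scaled like the descriptors). E_short = sum_i E_i plus a
per-element composition baseline fit by linear least squares.

Training is two-stage:

1. **Electrostatic stage.** NN_chi parameters are fit to minimize the
   per-atom MSE of equilibrated charges against the reference charges. The
   gradient flows through the constrained linear solve via one adjoint solve
   per configuration and iteration; the factored augmented system and all
   descriptors are precomputed once per configuration and shared across
   members and iterations.
2. **Short-range stage.** The electrostatic energy evaluated with the
   stage-1 charges is subtracted from the reference energy, and (by default)
   the full analytic electrostatic force — including the dQ/dR response — is
   likewise subtracted from the force targets (`subtract_elec_forces=False`
   switches this off, leaving raw force targets). The loss is the per-atom
   energy MSE plus `force_weight` (default 10) times the force-component
   MSE. The mixed second derivatives this requires (d/dtheta of dE/dG) are
   hand-derived and vectorized; no autodiff framework is used.

During training the charge input of the short-range network is the
*reference* charge (teacher forcing); at inference it is the predicted
equilibrated charge, and the network's sensitivity to it enters the force
through the adjoint. The force model used inside the stage-2 loss keeps the
charge inputs fixed (their geometric response is not differentiated during
training); full consistency holds at inference, where the finite-difference
force check applies.

The optimizer is full-batch L-BFGS. The committee workflow's protocol is
quoted in epochs (15 for quick retrains inside active-learning rounds,
50/100 for final electrostatic/short-range trainings); because quasi-Newton
full-batch iterations are not comparable one-to-one with per-pattern
filter updates, one epoch is mapped to 10 L-BFGS iterations. Convergence
tolerances are effectively disabled (ftol 1e-14) so the iteration budget is
the binding control.

A committee is n such models (default 4) sharing one symmetry-function set
and differing only in their initialization seeds. Its per-atom force
disagreement is

    sigma_F(alpha) = sqrt( (1/n) sum_i |F_i,alpha - Fbar_alpha|^2 ),

zero for n = 1. A **2G mode** trains charge-free short-range committees on
raw energies/forces and attaches a user-supplied fixed per-element charge
table used only for dipole analysis — the comparison baseline for what
charge equilibration buys.

## Active learning

The first batch is chosen by greedy farthest-point (max-min) selection on
per-element-averaged scaled descriptor vectors, deterministic with ties
broken by pool index. Every later round scores the entire remaining pool by
sigma_F aggregated per configuration — maximum over atoms by default, so a
single poorly modeled environment is enough to select a structure (mean
aggregation is available) — labels the top 20, and quick-retrains all
members warm-started from their current weights. Selected indices are never
rescored. The sampling bias is a one-sided harmonic in the aggregated
disagreement, `E_bias = k (sigma_max - sigma0)^2` above sigma0, C^1 at the
threshold, with finite-difference forces restricted to atoms near the
worst-disagreement atom; below threshold the dynamics are untouched. A
staged generation protocol accumulates training data across stages
(pools may be sampled with the current committee and increasing bead
counts) and re-trains from scratch with the long protocol per generation.

## Dynamics

Ring-polymer dynamics in normal modes: P beads per nucleus, springs at
omega_P = P/(beta hbar), sampled at bead temperature P T. The integrator is
an O-B-A-B-O splitting with exact free-ring-polymer propagation (A) and
exact per-mode Ornstein-Uhlenbeck kicks (O). PILE-L frictions: internal
modes gamma_k = 2 omega_k, centroid 1/tau (pimd_nvt). TRPMD leaves the
centroid unthermostatted and damps internal modes with
gamma_k = lambda 2 omega_k, lambda = 0.5 default. PA-CMD scales internal
mode masses so every internal frequency equals Gamma (default 16) times a
reference frequency `cmd_omega_ref` (a proxy for the stiffest physical
mode — set it near the system's stretch frequency), with strong internal
thermostatting; the centroid then moves on the adiabatically averaged
surface, and the default timestep is 0.25 fs (1.0/0.5 fs for
classical/PIMD). P = 1 reduces every scheme to classical dynamics
bit-compatibly given the same noise stream. Classical NVT offers Langevin
or stochastic-velocity-rescaling thermostats.

Estimators logged per step: bead kinetic energy and temperature, primitive
and centroid-virial quantum kinetic-energy estimators (the primitive
estimator's spring coefficient is m omega_P^2/P), spring energy, and the
conserved quantity. The virial estimator is validated against the analytic
finite-P harmonic-oscillator value

    KE_P = 3/(2 beta) + (omega^2/(2 beta)) sum_{k>=1} 1/(omega_k^2+omega^2)

per Cartesian degree of freedom (3 SE agreement is an acceptance property).
Random streams are counter-based (Philox keyed by the seed with the step
index as counter), so fanned-out NVE windows are reproducible and
independent. Masses are held internally in eV fs^2/A^2.

## Spectra

Dipoles use the classical point-charge expression per molecule: molecules
are made whole with minimum-image connectivity, each molecule's center of
mass is shifted to the origin, and mu_m = sum Q_i (R_i - R_COM); the total
cell dipole is the molecular sum. For neutral molecules the COM shift is a
no-op; molecular net charges from intermolecular charge transfer are small
and a warning triggers only at ion scale (> 0.25 e). Mdot is a central
finite difference of the stored per-frame dipoles — this uses exactly the
charges written during the dynamics run rather than requiring dQ/dt from
the model. The IR lineshape is the one-sided cosine transform of the
Mdot autocorrelation (FFT-based, verified against the direct double loop)
under a Hann window cos^2(pi t/(2 tau)), tau = 0.3 ps default, on a 1 cm^-1
grid to 4500 cm^-1 or Nyquist. Spectra from independent NVE windows are
averaged pointwise. No quantum correction factor is applied. Negative
excursions of the windowed transform are expected and not clipped.

For multi-bead trajectories the stored frame carries the centroid positions
and bead-averaged charges (TRPMD/PIMD) or centroid charges (PA-CMD,
classical).

Layer-resolved slab spectra assign molecules per frame by COM distance from
the slab center of mass along z: Layer 1 within +-4 A (bulk-like, ~8 A
thick), Layer 2 the next 4 A on each side (interfacial). Per-layer spectra
transform per-layer dipole sums; the total spectrum is computed from the
full cell dipole, so interlayer cross-correlations belong to the total only.
RDFs are normalized by ideal-gas shell counts with the (N-1) correction for
like-species pairs; density profiles histogram molecular COMs, recentered
per frame.

## Synthetic reference oracle

The oracle stands in for an electronic-structure reference so the full
workflow is testable at desk scale. It is a flexible water model: harmonic
O-H bonds (r0 = 0.9572 A, k = 20 eV/A^2), harmonic H-O-H angle
(theta0 = 104.52 deg, k = 4 eV/rad^2), a switched Lennard-Jones O-O term
(epsilon = 0.0067 eV, sigma = 3.166 A, switched off between 5 and 6 A over
periodic images), and its own ground-truth Qeq with coordination-dependent
electronegativity chi_i = chi0(element) + c CN_i, where CN is a smooth
cosine-switched neighbor count within 3.2 A and c = 0.3 eV/e per neighbor.
chi0_O = +17.8 eV/e and chi0_H = 0 were chosen once so the isolated molecule
carries water-like charges (q_O ~ -0.66 e, dipole ~ 1.87 D); the harmonic
bond constant places the O-H stretch band near 2400 cm^-1. Labels (energy,
analytic forces including the charge response, charges) are deterministic,
and the coordination coupling makes charges genuinely environment-dependent
(gas-to-bulk per-atom shifts of tens of me) — the feature the 4G
architecture must capture and a fixed-charge model cannot.

What the oracle does *not* emulate: electronic polarizability beyond Qeq,
anharmonic bond chemistry (no dissociation), dispersion beyond O-O LJ,
realistic hydrogen-bond network spectroscopy, or the noise structure of
density-functional labels. Passing the closed-loop tests therefore
demonstrates that the machinery (descriptors, Qeq, training, selection,
dynamics, spectra) is correct and self-consistent — not that any particular
accuracy would be reached against ab initio water.

Bulk boxes are packed on a jittered lattice with random molecular
orientations at 0.997 g/cm^3 (64 molecules -> a 12.43 A cube); slabs fill a
central layer with >= 12.5 A vacuum on each side. Candidate pools come from
per-configuration Gaussian displacements with amplitudes drawn uniformly
from a range (0.02-0.08 A for thermal-scale training data; 0.02-0.2 A for
heterogeneous active-learning pools) or from oracle Langevin dynamics with
a decorrelating stride.

## Benchmark problem sizes

The package's validation experiments (in `qeqnn.experiments`, reused by the
acceptance script) run on 8-molecule bulk boxes with the `compact`
descriptor set and 4-member committees: 300 training + 60 held-out
configurations for closed-loop recovery; 300-candidate pools, a 100-label
budget and 3 seed replicates for the query-by-committee comparison (both
arms follow the identical incremental warm-started training schedule, only
the selection rule differs); a 16-bead harmonic oscillator at
beta hbar omega = 2 for the quantum-statistics check; and a 2 ps classical
NVT run of 8 waters for the end-to-end IR smoke test. These sizes were
chosen as the smallest that exercise every code path with meaningful
statistics.

## Known limitations

* Plain Ewald only (no mesh methods); fixed cells, no stress tensor or
  barostats, no rigid-body constraints.
* Triclinic cells are supported for static energies; dynamics assumes
  orthorhombic cells in practice (trajectory tooling, RDF normalization).
* The Qeq matrix build is dense O(N^2) in storage and the augmented solve
  O(N^3) in time — appropriate for a few hundred atoms, not thousands.
* Charge-input response is neglected inside the stage-2 training loss
  (teacher forcing); inference forces are exactly consistent.
* The disagreement bias potential uses finite-difference forces restricted
  to a neighborhood, so it is for sampling robustness, not for conserved
  dynamics.
* No third-generation (direct charge prediction) variant; no GPU path.
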