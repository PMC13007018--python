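# qeqnn

Fourth-generation neural-network potentials with global charge
equilibration, committee-based active learning, path-integral dynamics, and
infrared spectra computed directly from model-predicted atomic charges.

## The problem

Short-range machine-learned potentials describe each atom from its local
environment, so they cannot respond to nonlocal charge transfer and
polarization — effects that matter in condensed phases and at interfaces
(the air–water interface being the canonical example). Fourth-generation
high-dimensional neural-network potentials (4G-HDNNPs) fix this by
splitting the energy

    E_total(R, Q) = E_elec(R, Q) + E_short(R, Q)

where the atomic charges Q_i come from a *global* charge equilibration
(Qeq): per-atom electronegativities chi_i are predicted by one set of
per-element networks from local symmetry-function descriptors, and the
charges minimize

    E_Qeq = E_elec + sum_i (chi_i Q_i + 1/2 J_i Q_i^2),   sum_i Q_i = Q_tot,

a single constrained linear solve (Ewald-summed for periodic cells).
E_short is a second set of per-element networks that take the descriptors
*and* the equilibrated charge as input. Forces are analytic, including the
implicit charge response dQ/dR.

Because the model predicts physically meaningful charges, the infrared
spectrum comes for free: with M(t) = sum_i Q_i R_i (molecule-wise,
minimum-image reconstructed and COM-shifted), the absorption lineshape is
the Hann-windowed Fourier transform of the dipole-derivative
autocorrelation <Mdot(0)·Mdot(t)> — no dipole training needed. Committees
of n models (different random seeds) provide both the production potential
(ensemble mean) and a query-by-committee (QbC) active-learning signal: the
per-atom force disagreement

    sigma_F(alpha) = [ 1/n sum_i (F_i,alpha - Fbar_alpha)^2 ]^(1/2).

The package implements this entire workflow — descriptors, Qeq + Ewald
electrostatics, two-stage training, QbC selection with a disagreement bias
potential, classical MD and path-integral dynamics (PIMD / TRPMD / PA-CMD
with the PILE thermostat), and the spectroscopy/structure analyses (IR,
RDF, slab density profiles, layer-resolved interface spectra) — plus a
**synthetic reference oracle**: a flexible water model with ground-truth
coordination-dependent Qeq charges that stands in for electronic-structure
labels, so the full pipeline runs and is testable on a desk in minutes.
See `docs/methods.md` for the model conventions and numerical choices.

## Worked example

The console script drives everything from one YAML file:

```yaml
# quickstart.yaml
seed: 7
outdir: quickstart
system:   {kind: bulk, n_molecules: 8, temperature: 298.0}
generate: {n_configs: 120, amplitude_min: 0.02, amplitude_max: 0.08}
train:    {committee_size: 4, epochs_elec: 50, epochs_short: 100, test_fraction: 0.1}
md:       {scheme: classical_nvt, n_steps: 1000, dt: 1.0, stride: 2}
spectrum: {tau: 200.0}
```

```
$ qeqnn --config quickstart.yaml generate
labeled 120 configurations -> quickstart/data
$ qeqnn --config quickstart.yaml train        # ~3 min, 1 CPU
trained committee of 4; member-4 test force RMSE 0.0284 eV/A
$ qeqnn --config quickstart.yaml md
md: 501 frames -> quickstart/md
$ qeqnn --config quickstart.yaml spectrum
spectra -> quickstart/spectra
$ qeqnn --config quickstart.yaml validate
{
 "n_configs": 120,
 "charge_rmse_me": 0.1089053074265086,
 "energy_rmse_mev_per_atom": 0.7143767312553327,
 "force_rmse_mev_per_a": 31.366737844121765,
 "dipole_mae_debye": 0.00168658497078959
}
```

Reading the numbers: the committee reproduces the oracle's atomic charges
to 0.11 me RMSE and its energies to 0.71 meV/atom; force errors are
31 meV/A against oracle forces of order 1 eV/A; and total-cell dipoles —
which the model never saw during training — agree to 0.0017 D because the
equilibrated charges are physical. `quickstart/spectra/ir_total.dat` is a
two-column wavenumber/intensity table from the MD run; the oracle water's
intramolecular bands appear near 1700 cm^-1 (bend) and 2400 cm^-1 (O–H
stretch, set by the oracle's harmonic bond constant), below the broad
libration band. `qeqnn select` runs query-by-committee rounds instead of
fixed-dataset training, and `qeqnn pimd` runs TRPMD/PA-CMD with the same
committee.

The same machinery is available as a library (`qeqnn.model`,
`qeqnn.active_learning`, `qeqnn.dynamics`, `qeqnn.spectra`,
`qeqnn.oracle`); `qeqnn.experiments` packages the benchmark experiments
used below.

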