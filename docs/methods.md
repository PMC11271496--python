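# Methods

`mlal` implements an active-learning (AL) workflow for training reactive
machine-learning potentials (MLPs) in explicit solvent, together with the
reaction-dynamics analyses that such potentials are built for: umbrella
sampling with WHAM reconstruction, downhill/uphill trajectory ensembles with
bond-formation time gaps, radial distribution functions and hydrogen-bond
statistics. Everything runs against built-in analytic reference potentials
that stand in for an electronic-structure backend, so the full workflow is
testable on a single desk-scale machine.

## The active-learning loop

The loop alternates four steps: train the MLP on the current labeled set;
propagate a short MLP-MD episode; hand the episode's **last frame** to a
selector; on acceptance, label the frame with the reference backend, append
it, retrain, and reset the episode index. The episode duration follows the
schedule **(n³ + 2) fs**, where n is the MD-run index starting at 0 and reset
to 0 after every accepted structure, with a 0.5 fs timestep. The run is
converged when the next episode would exceed the maximum simulation time
(5 ps by default), i.e. no structure was selected within the full schedule
2, 3, 10, 29, …, 4915 fs.

Episodes start from a designated structure of the initial training set with
fresh Maxwell–Boltzmann velocities. Restarting from the most recently
accepted structure is available (`ALConfig.restart="latest"`) but not the
default: with a poor early model it lets each accepted, slightly distorted
frame become the next starting point, and the training set drifts into
physically meaningless regions.

MD instability (a non-finite force or any component above 10³ eV Å⁻¹)
aborts an episode; the partial trajectory's final frame is still a
legitimate candidate — an unstable model's frames are exactly what needs
selecting. A frame the reference backend refuses to label (the analogue of
an SCF that fails to converge on an unphysical structure) is dropped and
the episode index advances; the toy references refuse structures outside
their validity domain (e.g. an O–H bond stretched beyond 1.8 Å).

### Selectors

* **energy** — add when E_T < |E_ref − E_MLP| ≤ 10·E_T; discard above
  10·E_T (too distorted to be informative); skip below E_T. Requires one
  reference call per evaluated frame.
* **similarity** — add when the maximum kernel similarity max(**K**) of the
  candidate to all training descriptors falls below k_T, with
  K_i = |**p**₀·**p**ᵢ|^ζ over unit-normalized global SOAP vectors.
* **distance** — add when the candidate's local outlier factor (LOF) in
  descriptor space exceeds the 80th percentile (lower nearest-rank) of the
  training set's own leave-self-out LOF values; the threshold is recomputed
  whenever the set changes. LOF uses the standard k-nearest-neighbour
  reachability construction (k = 10 by default; the neighbour count is a
  free parameter). Exact duplicate descriptors are collapsed before LOF to
  avoid zero reachability densities; k-NN ties break by dataset index.

The similarity threshold must be matched to the sharpness of the
descriptor, which varies with system size: atom-averaged SOAP vectors of
thermally distinct 27-water frames score 0.997–0.9999 against a covering
set, while 8-water frames spread far lower. The 27-water study uses
k_T = 0.9995 (at ζ = 4); where several system sizes are compared, the
threshold is calibrated a priori from the data itself
(`studies.calibrated_similarity_kt`): k_T is a low percentile of the
pairwise kernel similarities within the initial set — "add what is more
novel than the spread already present". Very low thresholds admit
unphysical structures; k_T = 1 degenerately accepts every non-identical
frame.

## Descriptors

SOAP power spectra are computed natively: the Gaussian-smeared neighbour
density (width σ_atom) is expanded in Gaussian radial functions and
spherical harmonics, p_{ss'nn'l} = Σ_m c^s_{nlm} c^{s'*}_{n'lm}. Radial
integrals are pre-tabulated with exponentially scaled modified spherical
Bessel functions and stored as cubic splines of the neighbour distance, so
per-pair evaluation is a spline lookup; spherical harmonics and their
θ-derivatives come from stable recursions of the fully normalized
associated Legendre functions (the pole-singular m·Y/sinθ factor follows
its own recursion and never divides by sinθ; a fixed internal generic
rotation keeps constructed axis-aligned geometries away from the poles). A
C² switching function over the outer 1 Å takes the neighbour weight to zero
at r_cut, keeping MLP-MD energy conservation clean.

The global descriptor of a configuration is the per-atom power spectra
averaged and unit-normalized (for selectors), or summed without
normalization (as extensive features for the energy model). Gradients are
analytic and provided in adjoint form: given ∂E/∂p the calculator returns
∂E/∂positions in one pass; a full feature Jacobian (for force training) and
a per-atom adjoint (for local models) use the same pair machinery. All
three paths are validated against finite differences to ~1e-9.

Default hyperparameters (r_cut = 5 Å, n_max = 6, l_max = 4, σ_atom = 0.5 Å,
ζ = 4) follow common SOAP practice; every value is configuration-exposed.
The radial basis optionally concentrates resolution at bonding distances
(`radial_power` > 1 compresses the centre grid toward r = 0).

## The internal MLP

The trainable potential is ridge regression over SOAP power-spectrum
features, in three flavours:

* **linear** (default): total energy = w·Φ + per-species baselines, with Φ
  the *summed* (extensive) power spectrum — the same inductive bias as
  linear atomic cluster expansion models. Trained on energies **and
  forces**: one configuration contributes one energy equation but 3N force
  equations, and with tens of configurations the force information is what
  brings the model to chemical accuracy (energies alone plateau an order of
  magnitude higher; measured directly during development). Fitting uses
  incrementally accumulated normal equations, so AL retraining after each
  acceptance costs one solve, not a re-assembly.
* **local**: sparse kernel regression on per-atom environments
  (Gaussian-approximation-potential construction) with farthest-point
  sampled representative environments.
* **kernel**: dual kernel ridge |p·q|^ζ over normalized global descriptors,
  energies only — the similarity kernel reused as a small interpolator.

The linear model accepts several descriptor channels at once (e.g. a
sharp short-range channel plus a smooth long-range one). The water studies
use a single channel whose cutoff matches the reference potential's 6 Å
interaction range — interactions the descriptor cannot see cannot be
learned, and with a 5 Å descriptor on a 6 Å-ranged potential the energy
error plateaus several-fold higher — with σ = 0.25 Å, n_max = 9 and a
power-spaced radial grid concentrating resolution at bonding distances.
The regularization λ is relative to the design-matrix scale (default
1e-11; the water studies use 1e-12); the single energy row per
configuration is up-weighted by `energy_weight` (default 10) against its
3N force rows.

Forces are the analytic negative gradient through the descriptor adjoint;
central finite differences (`force_method="fd"`, O(6N) descriptor
evaluations per call) are retained as the independent cross-check used in
tests, not as the production path — at acceptance scale the quadratic cost
would make the MD episodes two orders of magnitude slower.

## Reference potentials

* **ToyWaterPotential** — flexible point-charge water: harmonic O–H
  stretches (k = 45 eV Å⁻², r₀ = 0.96 Å) and H–O–H bends (k = 3.5 eV rad⁻²,
  θ₀ = 104.5°), TIP3P-like O–O Lennard-Jones and ±0.834/0.417 point
  charges, everything beyond bonding multiplied by a C² switch that
  vanishes at 6 Å. The parameters put the liquid O–O RDF first peak near
  2.8 Å (checked against the potential's own MD, not experiment). Hydrogens
  bind to their nearest oxygen at every call, which keeps the potential
  total (defined and finite) even for distorted structures; *labeling*
  additionally enforces the 1.8 Å validity limit described above.
* **TwoBondReactivePotential** — a four-atom model cycloaddition: two
  fragments with harmonic internal bonds; the two forming bonds r₁, r₂ each
  move on the asymmetric double well V(r) = h(x²−1)² + t·x, x = (r−r_m)/b
  (defaults h = 0.6 eV, t = 0.15 eV, r_m = 2.325 Å, b = 0.875 Å: reactant
  well near 3.2 Å, deeper product well near 1.45 Å), plus a coupling
  g(r₁−r₂)² that controls how synchronously the bonds form. Because the
  solute has no other internal interactions, the relaxed PES at fixed
  (r₁, r₂) is analytically V(r₁) + V(r₂) + g(r₁−r₂)² — the scan oracle.
  Atoms beyond the first four are toy-water solvent with a switched
  Lennard-Jones solute–solvent coupling.
* **HarmonicDimerPotential / DoubleWellDimerPotential** — two-atom systems
  with closed-form behaviour (oscillation period; free-energy profile
  F(r) = U(r) − 2k_BT ln r along a distance coordinate) used as oracles.

## Molecular dynamics

Velocity Verlet (NVE) and the BAOAB splitting of Langevin dynamics (NVT;
friction default 0.02 fs⁻¹ — the thermostat choice is free, Langevin was
picked for its unbiased configurational sampling and simplicity). Units:
eV, Å, fs, amu; 1 eV = 23.0605 kcal mol⁻¹ at reporting boundaries. Initial
velocities are Maxwell–Boltzmann with net momentum removed. Harmonic biases
act on scalar coordinates (interatomic distances or the reaction coordinate
ξ); frozen atoms are excluded from integration. Restrained minimization
uses L-BFGS with a 1e-3 eV Å⁻¹ force tolerance.

Energy-conservation bookkeeping: with the 0.5 fs production timestep the
27-water cluster's instantaneous total energy oscillates with an amplitude
of a few 1e-4 eV/atom (the usual bounded Verlet oscillation of stiff
modes); the secular drift — measured as the difference between the
time-averaged total energy of the first and last picosecond — is an order
of magnitude smaller. Halving dt reduces the error fourfold, as expected
for a second-order integrator.

## Reaction analysis

The reaction coordinate is ξ = (r₁ + r₂)/2; Δr = |r₂ − r₁| measures
asynchronicity. A configuration is **product** when both forming bonds are
below 1.6 Å and **reactant** when both exceed 3.0 Å. A bond's formation
time is its first downward crossing of 1.6 Å (no recrossing debounce —
only the product criterion is externally fixed; at the observed crossing
speeds a debounce changes nothing). The time gap Δt = |t(r₂) − t(r₁)|
separates concerted (< 60 fs) from stepwise trajectories; timeouts are
excluded from Δt statistics.

Umbrella sampling uses harmonic windows along ξ; the production layout is
15 windows over [1.55, 4.0] Å at 10 eV Å⁻² plus 15 over [1.7, 2.5] Å at
20 eV Å⁻² (per-window overrides accept other spring constants, e.g. 13/30
eV Å⁻² where overlap demands it). Window seeding is steered MD from the
start structure with window-to-window warm starts (a nudged-elastic-band
seeding would serve the same purpose; steered MD keeps the dependency
surface small). The first 10% of each window is discarded as burn-in, and
adjacent windows must share histogram support. Free energies come from
WHAM iterated to 1e-7 eV on the window offsets; profiles are min-shifted,
reported in kcal mol⁻¹, and the barrier is the highest maximum between the
reactant (large-ξ) basin and the product basin. WHAM was chosen as the
estimator; umbrella integration is a noted alternative.

Downhill ensembles launch unbiased thermal trajectories from a
solvent-perturbed TS pool (solvent equilibrated with the solute frozen,
then the solute re-optimized with the solvent frozen under harmonic
restraints holding the forming bonds at their TS values). Uphill ensembles
launch from restrained reactant states (forming bonds held within
[3.0, 5.0] Å) and are driven over the barrier by a weak 0.4 eV Å⁻² harmonic
per forming bond, centred at the product distance — the same per-bond form
as the reactant restraints. The pair of springs lowers the effective
barrier to a few k_BT so trajectories cross thermally within the 3 ps
budget (a single spring of that stiffness on ξ leaves the barrier a dozen
k_BT high and nothing crosses). Initial velocities are plain
Maxwell–Boltzmann in both cases — no mode-specific excitation.

RDFs use minimum-image distances and ideal-gas normalization (orthorhombic
cells only; r_max ≤ L/2). Hydrogen bonds follow the standard geometric
criterion — donor–acceptor O···O below 3.5 Å and donor–H–acceptor angle
above 140° (the criterion is configuration-exposed); the per-solvent
hydrogen-bond count is binned by the solvent oxygen's distance from the
solute centre of mass, with the far-field bin as the bulk estimate.

## Synthetic study systems and what they do (not) show

The generators build: jittered-lattice water clusters (27 molecules is the
selector-comparison system) equilibrated by the reference potential;
periodic water boxes at liquid density (64 molecules — the smallest cube
whose half-box exceeds the 6 Å interaction cutoff); and the four-atom
reactive dimer, optionally solvated. Initial AL data comes from random
displacement of a seed structure (gas phase; amplitude default 0.1 Å,
uniform per Cartesian component — the simplest bounded choice) or from
reference-MD snapshots of the equilibrated cluster (condensed phase, where
cluster configurations rather than displaced geometries are the natural
initial data).

One property of the 27-water cluster matters for interpreting accuracy
numbers: it is glassy. Different equilibration seeds settle into different
hydrogen-bond-network basins whose descriptors barely overlap, and a model
trained in one basin extrapolates poorly to another. The validation studies
therefore anchor everything — initial data, AL episodes, and held-out
evaluation frames — to one common equilibrated cluster, which is also the
physically meaningful reading of "train a potential for this system".
Passing tests show the workflow learns the thermally accessible
neighbourhood of a given structure to the stated accuracy; they do not show
transferability across independently generated clusters, nor anything
about real electronic-structure reference data. Within a 1 ps evaluation
trajectory the hydrogen-bond network keeps rearranging, and the linear
model's energy error grows from ≈1.5 kcal mol⁻¹ over the first half
picosecond to ≈3–4 kcal mol⁻¹ over the full picosecond (total energy, 81
atoms — about 2 meV/atom) while force errors stay near 1.3 kcal mol⁻¹ Å⁻¹;
higher-body-order nonlinear models are the known route below that energy
plateau and are beyond this package's linear form (the per-atom kernel
mode narrows but does not close the gap at desk-scale sparse-set sizes).

## Problem sizes in the validation suite

The acceptance studies run at deliberately chosen desk scales: the
similarity-selector accuracy study uses the 27-molecule cluster with a
500 fs AL episode cap (the full 5 ps cap semantics are exercised exactly on
a two-atom system, where the complete 23.4 ps episode schedule is cheap),
40 initial reference-MD snapshots spanning 2 ps (condensed-phase initial
data is cluster configurations, not displaced geometries),
200 held-out frames spanning 1 ps of reference MD, and the single-channel
MLP described above; the selector data-efficiency comparison uses 8-molecule
clusters over three seeds; free-energy recovery uses the double-well dimer
with 12 windows of 8 ps; the RDF comparison uses the 64-molecule periodic
box, an MLP fitted to 14 bulk reference snapshots, and 0.6 ps of MLP-MD
against 0.6 ps of reference MD. These sizes are the package's standing
choices for a single-workstation validation run.

## Known limitations

* Periodic support is orthorhombic-only; no Ewald electrostatics (the toy
  references use switched short-range Coulomb by construction).
* The MLP's linear form caps accuracy for broad configuration spaces;
  the local (per-atom kernel) mode helps for strongly multi-basin data but
  normalized-environment kernels discard coordination-scale information.
* LOF and similarity selectors act on global (whole-configuration)
  descriptors; per-atom selector variants are not implemented.
* External quantum-chemistry backends are an interface stub only
  (`ExternalBackendStub`): the package never manages electronic-structure
  processes.
* Only the 1D free-energy profile along ξ is implemented; no 2D FES,
  committor analysis, or cavity-volume statistics.
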