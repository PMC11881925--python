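# Methods

## Model and scope

`magmd` integrates classical point particles whose only field coupling is the
Lorentz force of a static, homogeneous magnetic field directed along +z.
Electric fields, induced (time-varying) fields, and magnetic interactions
between particles are outside the model. Conservative interactions are
pairwise Lennard-Jones plus point-charge electrostatics; molecules may carry
rigid distance constraints. Boxes are orthorhombic and periodic, or open
(non-periodic) for single-particle and cluster work.

Internal units are GROMACS-like — nm, ps, u, e, kJ/mol — chosen so that
1 u·nm²/ps² = 1 kJ/mol exactly and the only magnetic constant needed is the
Larmor conversion K_Ω = 9.6485332e-5 rad·ps⁻¹ per (e·T/u), i.e. Ω = K_Ω·qB/m.
B is accepted in tesla on every interface; the Lorentz force never appears
in force units.

## The field-coupled integrator

Velocity Verlet is retained, with the magnetic acceleration Ω·S·v
(S·v = (v_y, −v_x, 0)) entering both half-steps:

* position update — explicit, with the magnetic acceleration evaluated from
  the start-of-step velocity;
* velocity update — trapezoidal in the magnetic acceleration, hence implicit
  in the unknown end-of-step velocity. With h = ΩΔt/2 the xy block of
  (I − hS) is [[1, −h], [h, 1]], inverted in closed form
  (I − hS)⁻¹ = [[1, h], [−h, 1]]/(1+h²); det = 1 + h² > 0, so the solve is
  unconditionally well posed. The z component is the ordinary half-kick.

Properties relied upon by the tests: the force-free velocity map is the
Cayley rotation (I − hS)⁻¹(I + hS), orthogonal for every h (|v_xy| conserved
to machine precision, v_z untouched — magnetic forces do no work); at B = 0
every magnetic term is exactly zero, so the integrator is algebraically the
textbook one; against the analytic gyro-helix the global position error
converges as O(Δt²); negating q (or B) mirrors trajectories bitwise because
every magnetic term is odd in h.

Sign convention: positive Ω (positive q, B along +z) gyrates clockwise when
viewed from +z, following F = q v × B with the axes right-handed. Reported
chirality (+1 counter-clockwise / −1 clockwise) is defined in this
convention; only relative statements (cation vs anion) are
convention-independent, and only those are asserted about physical systems.

Sub-step order of one step (fixed contract): NVT half-kick → position update
→ SHAKE on positions (with the Δr/Δt velocity correction) → force recompute
→ implicit magnetic velocity solve → RATTLE on velocities → NVT half-kick.
Constraints run last so emitted states always satisfy them; the thermostat
scales all components isotropically, preserving the field-free limit. A
non-finite guard runs every step and aborts with step/particle context.

## Interactions

Lennard-Jones with Lorentz–Berthelot mixing, shifted so U(r_c) = 0 (forces
from the unshifted form), and reaction-field Coulomb
U = f q_i q_j (1/r + k_rf r² − c_rf) with ε_rf = 78.5, both sharing a
cutoff (default 0.9 nm for water boxes; an infinite cutoff degrades
gracefully to plain LJ + Coulomb for open systems). Reaction field was
chosen over mesh Ewald deliberately: it is deterministic, desk-scale, exact
to test against a brute-force double loop, and adequate for diffusion
trends; absolute dielectric or interfacial properties are out of scope.

Pairs come from a Verlet list (cutoff + 0.1 nm skin) rebuilt when any
particle has moved more than half the skin. The list is built by a
vectorized all-pairs distance scan rather than a cell grid — at the ≤ few
thousand particles this engine targets, the O(N²) scan is faster in
practice and trivially verifiable; the brute-force-equality property test
would catch any pair bookkeeping error. The hot pair loop and the scan are
numba-jitted when numba is importable; an exactly equivalent vectorized
numpy path is the fallback, and the two are cross-checked in the tests.

## Constraints, thermostat, start-up

Rigid molecules (SPC/E water: two O–H of 0.1 nm and one H–H of 0.16330 nm
closing the 109.47° angle) are enforced by SHAKE/RATTLE: sequential
Gauss–Seidel sweeps over constraints, position stage against the pre-step
bond directions, velocity stage removing bond-parallel relative velocity;
pairwise corrections conserve momentum exactly. Default distance tolerance
1e-8 nm, velocity tolerance 1e-10 nm/ps, at most 500 sweeps before a
constraint-failure error naming the worst molecule.

Temperature control is a single-chain Nosé–Hoover thermostat with mass
Q = N_df·k_B·T·τ² applied in half-kicks outermost in the step; N_df counts
3N minus constraints minus 3 when centre-of-mass motion is removed. COM
removal defaults to on for periodic boxes and off for open/single-ion runs,
where the axial drift is itself an observable.

Freshly built lattices are relaxed by a constrained steepest-descent
minimizer (displacement-capped moves along the force, SHAKE re-projection
after each move) before dynamics; this is a start-up utility, not a general
optimizer.

## Builders and synthetic fixtures

`build_water_box(n)` places molecules at the centres of a cubic sub-lattice
(minimum O–O distance = lattice spacing, ≥ 0.24 nm enforced) with
independent random orientations, then draws Maxwell–Boltzmann velocities,
removes net momentum, projects out constraint-violating components and
rescales to the requested temperature. The box edge follows from the target
density (997 kg/m³ default; 887 molecules give a 2.986 nm cube, 216 — the
default desk-scale size — a 1.865 nm cube, which just accommodates the
0.9 nm cutoff).

The analysis oracles are generated, not simulated: `make_helix_fixture`
emits exact analytic gyro-helices with consistent velocities, and
`make_brownian_fixture` emits ideal Gaussian random walks of known D
(per-axis increment variance 2DΔt). What they deliberately do not emulate:
helices carry no noise, and Brownian walks have no ballistic/caged regime,
no hydrodynamic correlations and no finite box — so tests passing on them
certify the estimators (circle fit, phase fit, Einstein fit), not the
realism of any simulated liquid.

## Observables

* Cyclotron characterization: algebraic (Kåsa) circle fit in xy for centre
  and radius; angular rate from a linear fit to the unwrapped phase of
  (v_x, v_y), falling back to the position phase about the fitted centre;
  period 2π/|rate|, chirality its sign; v_z from the mean axial velocity.
  Phase fitting was preferred over peak finding because it works for
  partial rotations and any sampling stride. At least 10 frames and ~0.5 rad
  of angular progress are required.
* MSD over all sliding origins (direct loop, adequate at desk scale), on
  unwrapped coordinates only; lag grid up to half the run by default.
* Self-diffusion by least squares on a user-chosen MSD window, D = slope/6,
  reported in m²/s (1 nm²/ps = 1.0e-6 m²/s exactly); the slope's standard
  error is propagated, and a curvature diagnostic warns when the window
  looks non-linear (ballistic or caged).
* RMSD with optimal superposition (Kabsch, SVD with determinant
  correction); radius of gyration mass-weighted, emitted in two per-axis
  conventions — about-axis (RMS distance from the COM-parallel axis;
  headline, satisfying Rg² = ½ΣRg_axis²) and single-coordinate spread —
  because "per-axis Rg" is ambiguous in common usage. Both are labelled in
  the output.

All observables are pure functions of the trajectory; re-running an
analysis reproduces its tables byte for byte.

## Validation experiments and chosen problem sizes

The engine is validated by the experiments in `tests/test_acceptance.py`:

* free Na⁺/Cl⁻ gyration at 80–1500 kT — period and radius against the
  closed forms (T·B and r·B constant to < 1%), period at 80 kT ≈ 18.7 ps,
  exact chirality mirror, exactly constant v_z over 200,000 steps at
  Δt = 0.1 fs (20 ps);
* exact field-free reduction to an independently written plain velocity
  Verlet (LJ dimer and 27-molecule water cluster, 1000 steps, ≤1e-12 per
  coordinate);
* O(Δt²) convergence to the analytic helix and Cayley norm conservation up
  to h = 100;
* the water pipeline at the package's desk scale: 216 SPC/E molecules,
  steepest-descent start-up, 10 ps NVT equilibration (Δt 1 fs, τ 0.2 ps),
  120 ps NVT production (Δt 2 fs, τ 1 ps, 300 K), MSD fit window 10–40 ps.
  This yields D ≈ 2.0e-9 m²/s, asserted only against the broad physically
  sane band 1.5–3.5e-9 m²/s: at 216 molecules and ~100 ps, finite-size
  suppression (~10–15% for this box), the reaction-field scheme and
  sampling noise each move D by more than any field-induced trend, so
  field-dependence of D is explicitly not asserted;
* estimator oracles: helix round-trip to 1e-6, Brownian D recovery to 5%
  (500 particles × 2000 frames), rigid-transform RMSD < 1e-10, Rg identity
  to 1e-12, plus RMSD/Rg tracking of controlled perturbations at
  protein-observable scale (jittered tumbling cloud staying under the
  0.15 nm stability threshold).

`scripts/acceptance.py` re-runs the sodium-period experiment from scratch
and reports the measured period (18.71 ps; the closed form rounds to the
same value).

## Numerical choices and degenerate inputs

Δt = 0.1 fs for free-ion runs (resolves even Ω ≈ 6.3 rad/ps at 1500 kT to
h ≈ 3e-4); 0.5–1 fs for constrained-water equilibration, 2 fs for rigid
SPC/E production. NVE energy conservation for the constrained cluster shows
clean Δt² scaling of the bounded energy oscillation (1.8e-5 relative over
10 ps at 0.5 fs). Overlapping particles (r < 1e-6 nm) raise a singularity
error naming the pair; zero-step runs return the initial state as a single
frame; neutral particles have Ω = 0 and feel no magnetic term; a zero box
line in a GRO file denotes an open system. Determinism is a contract:
identical inputs and seed give bit-identical trajectories and tables.

## Known limitations

No Ewald/PME electrostatics, no bonded force fields beyond rigid
constraints, no pressure coupling (NVE/NVT only), orthorhombic boxes only,
no protein force field — conformational observables (RMSD, Rg) are provided
and validated on synthetic structures, but simulating a solvated protein is
out of scope. Extreme fields combined with long steps (h ≫ 1) remain
numerically stable (the solve is exact), but the physics of such regimes —
e.g. field-driven instabilities reported for megatesla-scale simulations
elsewhere — is not modelled beyond the integrator's own guarantees.
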