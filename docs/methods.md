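# Methods

This note documents the models, estimators and numerical choices behind
`abfe`, in the order data flows through the package: time-series
preparation, MBAR estimation, restraints and cycle assembly, the toy
host–guest system used for validation, and the affinity benchmark layer.

## Scope and units

All public energies are in kcal/mol (kT = 0.0019872041·T; 0.59248 kcal/mol
at the default 298.15 K). Reduced potentials u = U/kT appear only inside
the estimators and in energy tables. Distances are in Å, angles in
degrees at API boundaries and radians internally. The standard state is
1 mol/L, i.e. one molecule per V° = 1660.539 Å³; this value is fixed in
`ThermoState` and enters only through the analytic restraint term and the
exact oracle, so changing it shifts both consistently.

## Equilibration and decorrelation

Each sampled window contributes a scalar time series (its own-state
reduced potential). `prepare_samples` removes the first
⌊fraction·n⌋ frames (default fraction 0.1, mirroring the common practice
of discarding the first tenth of a production run), then estimates the
statistical inefficiency g = 1 + 2τ on the remainder and thins with
stride ⌈g⌉ starting at the first retained frame. The autocovariance sum
uses the triangular (1 − t/T) factor and truncates at the first
non-positive normalized autocorrelation; a constant series returns g = 1
by convention. Integer striding (rather than fractional-index thinning)
keeps index sets deterministic and reproducible. The stride ⌈g⌉ errs on
the side of discarding samples: for barely-correlated data (g ≈ 1.05) it
still halves the sample; the bootstrap uncertainty accounts for the
retained sample size, so this costs precision, not correctness.

## MBAR estimation

`mbar_solve` solves the multistate Bennett acceptance ratio equations for
K states given every sample's reduced potential at every state. Free
energies are dimensionless with f₁ ≡ 0. The solver iterates the
self-consistent update with log-sum-exp stabilization, which is globally
convergent but linear; once the residual max|Δf| drops below 2, it
switches to an undamped Newton step on the convex MBAR objective (with
the analytic K×K Hessian), which converges quadratically. A Newton step
is rejected in favour of the self-consistent update if it is non-finite
or more than doubles the previous step size. Convergence is declared at
max|Δf| < 1e-10 (configurable); exceeding the iteration budget raises an
error carrying the residual. On the solution the per-sample weights are
non-negative, each sample's mixture weights sum to 1, and each state's
weights sum to 1; for K = 2 the solution satisfies Bennett's implicit
equation to solver precision (both are asserted in the tests). An
overlap matrix is computed on request and a warning flag is raised when
any adjacent-state overlap falls below 1e-6; the flag propagates to the
estimate rather than aborting, because a disconnected ladder is a
scientific problem, not a numerical one.

## Bootstrap uncertainties

`bootstrap_free_energy` reports the mean and sample standard deviation of
n_boot replicate estimates, where replicate 0 is the unresampled data and
the remaining replicates resample the decorrelated samples within each
state independently with replacement, preserving per-state counts. The
resampling unit is the decorrelated sample: thinning happens first, so
the bootstrap sees approximately independent draws. Conversion to
kcal/mol uses kT at the data temperature. Each public operation takes
one integer seed; per-state resampling streams are derived from it with a
fixed offset, so estimates are bit-reproducible. Replicates solve MBAR
warm-started from the full-data solution (typically 3–6 Newton
iterations each).

`combine_repeats` pools the bootstrap samples of repeated calculations
(e.g. three repeats of 200 replicates → 600) and reports the pooled mean
and standard deviation, so the final uncertainty reflects both estimator
noise and repeat-to-repeat scatter. Pooling is authoritative: the MBAR
asymptotic covariance is deliberately not used for reported errors.
Single-run bootstrap structurally under-reports the run-to-run scatter —
it resamples states independently and so cannot see the cross-state
correlation of the shared replica pool, nor correlation surviving the
thinning; on the toy system the seed-to-seed scatter of one-repeat
estimates is ≈1.5× their bootstrap sd. Pooled repeats recover an honest
uncertainty, which is why the end-to-end pipeline runs repeats by
default.

## Boresch restraint and its analytic free energy

The restraint fixes the guest relative to three host anchors (c, b, a)
and three guest anchors (A, B, C) with six harmonic terms: r = |a−A|,
θA = ∠(b,a,A), θB = ∠(a,A,B), and dihedrals φA = (c,b,a,A),
φB = (b,a,A,B), φC = (a,A,B,C). Dihedral deviations are wrapped to
(−180°, 180°] before squaring. Angular force constants are canonically
kcal/mol/rad²; configurations may declare `deg^-2` and are converted with
(180/π)² ≈ 3283, since both readings of "10 kcal mol⁻¹ Å⁻² [deg⁻²]"
occur in the literature and they differ enormously in stiffness.

The free energy of restraining a non-interacting ligand at standard
concentration is the stiff-spring closed form

    ΔG_restr = kT ln[ 8π² V° √(K_r K_θA K_θB K_φA K_φB K_φC)
                      / (r0² sinθA0 sinθB0 (2πkT)³) ],

+6.831 kcal/mol for the canonical all-10 restraint at r0 = 5 Å,
θ0 = 90°. `boresch_quadrature_dG` evaluates the same quantity without
the stiff-spring approximation, integrating the six separable factors of
the restrained configurational integral with the exact Jacobian
r² sinθA sinθB. The two differ by the first-order correction
kT²(1/K_θA + 1/K_θB)/2 − kT²/(K_r r0²), ≈ +0.034 kcal/mol at
K_θ = 10 kcal/mol/rad²; the tests assert this residual analytically and
the sub-0.01 agreement reached for stiffer (or per-deg²) constants. The
formula is singular as θ0 → 0 or π; reference angles within 1e-6 rad of
a pole raise an error.

## Lambda schedules

A window is a triple (λ_restraint, λ_coulomb, λ_vdW), 1 = fully coupled.
Schedules run from the physical, fully coupled endpoint toward the
decoupled one, in the order: restraint on at full coupling (complex
only), then charges annihilated, then van der Waals decoupled through the
soft core. Annihilating charges first avoids bare charges on sites
without repulsive cores. Consecutive legs share one boundary state,
stored once. The default spacings Δλ_coul = 0.1 and Δλ_vdW = 0.05 with
the 12-value restraint list (0, 0.01, 0.025, 0.05, 0.075, 0.1, 0.15,
0.2, 0.3, 0.5, 0.75, 1.0) give 42 complex and 31 solvent windows; the
dense small-λ end of the restraint list handles the entropy bottleneck of
first confining a free ligand.

## Cycle assembly

The standard binding free energy closes the double-decoupling cycle:

    ΔG°_bind = ΔG_solv^elec+vdw + ΔG_solv^restr
             + ΔG_prot^elec+vdw + ΔG_prot^restr + Σ corrections,

with legs in the directions: decouple in solvent, restrain the
non-interacting ligand (analytic), recouple in the complex, release the
restraint in the complex. The uncertainty is the root sum square of the
leg uncertainties; corrections enter as exact additive terms. Charge
corrections (residual integrated potentials from an external
Poisson–Boltzmann calculation) are summarized by their per-frame mean; a
warning is flagged when the frame-to-frame standard deviation reaches
0.05 kcal/mol. A long-range dispersion correction slot works the same
way. Computing either correction is out of scope; only their application
is implemented.

Multiple binding modes combine as ΔG_comb = −kT ln Σᵢ exp(−ΔGᵢ/kT)
(log-sum-exp evaluated stably): the combined value never exceeds the
strongest mode and approaches it as the gaps grow. Mode uncertainties
propagate by paired resampling: one bootstrap value is drawn per mode,
combined, and the standard deviation taken over 10,000 seeded resamples.

## Toy host–guest system

The synthetic-data generator is a rigid triatomic guest binding a
three-site host in a 20 Å cubic box: soft-core Lennard-Jones plus
linearly scaled Coulomb interactions (Lorentz–Berthelot mixing, Coulomb
constant 332.06 kcal·Å/mol/e²), a Boresch restraint defined at the
energy-minimized bound pose, and rigid-body Monte Carlo sampling. It
emulates exactly the statistical structure the analysis assumes — a
ladder of λ-coupled Boltzmann distributions with controllable overlap and
autocorrelation and a known exact binding free energy — and nothing
else: there is no solvent, no internal flexibility, no periodic
electrostatics, and no force field realism. Passing tests therefore
validate the estimators and cycle bookkeeping, not molecular-mechanics
fidelity. Because the rigid guest has no interaction partners in the
"solvent" environment, the solvent decoupling leg is identically zero
there; the exact oracle shares this property, so the comparison remains a
full end-to-end check of the complex legs, the analytic restraint term
and the standard-state bookkeeping.

The default model binds at −3.17 kcal/mol at the minimum (≈5.3 kT), a
moderate binder whose exact standard binding free energy is
−1.084 kcal/mol; restraint reference coordinates are r0 = 3.66 Å,
θA0 = 75°, θB0 = 67°, far from the angular poles. The well depth is a
kinetic design choice: with ≈5 kT the bound↔unbound exchange of the
fully coupled, unrestrained state (equilibrium bound fraction ≈0.12)
relaxes within the first few percent of a sampling run — verified by its
bound-fraction trace — so the 10% equilibration discard genuinely covers
the initial transient from the all-bound start. An earlier, deeper
variant (6.6 kT) relaxed on the same scale as a whole desk run and left
a visible initialization bias.

The soft core is Beutler-type with α = 0.5 and λ-power 1:
E = λ·4ε[σ¹²/(ασ⁶(1−λ)+r⁶)² − σ⁶/(ασ⁶(1−λ)+r⁶)], finite at r = 0 for
λ < 1 (24ε at λ = 0.5, α = 0.5). Coulomb scales linearly in λ_coul and
is only ever non-zero while λ_vdW = 1 on its side of the path, so charges
are never exposed without repulsive cores.

Sampling is Metropolis Monte Carlo over rigid-body translations
(Gaussian, 0.5 Å) and rotations (uniform axis, ≤20° angle), tuned once to
≈30% acceptance on the default model. One move in ten proposes instead a
uniform reposition and reorientation in the whole box — a symmetric
proposal that teleports replicas at weakly coupled states. These jump
moves were added after a validation study against the exact oracle showed
slow box diffusion at the decoupled states: positional correlation times
far exceeded the energy-series autocorrelation used for thinning, which
inflated both the bias and the unreported variance of single runs. With
jumps, positional mixing no longer limits the estimates.
The translation bound is the box for the guest's
primary site; there are no periodic images (the box only bounds
translation), matching the oracle's integration domain exactly.

Replica exchange runs one replica per window. Every `swap_interval`
sweeps (default 10) an exchange round performs swap-attempt passes over
random disjoint replica pairs — K² attempts per round by default,
approximating Gibbs sampling of the replica↔state permutation — with
Metropolis acceptance on the reduced-potential difference, using the
(K×K) cross-evaluation matrix computed once per round. One sample per
state is retained every second round (configurable), with its reduced
potential at every state;
retained configurations are stored so every energy row can be re-derived
from its configuration (audited in the tests through an independent
slower code path). Neighbour swap acceptance, per-pair acceptance, the
any-state jump probability and replica-state visit counts are reported as
diagnostics; they are observed, not targeted.

`quadrature_binding_dG` is the independent oracle:
ΔG°_bind = −kT ln[Z_bound/(8π²V°)] with Z_bound the configurational
integral of the fully coupled, unrestrained guest over box and
orientations. It uses stratified Monte Carlo — two-thirds of the samples
uniform in a sphere covering the host (where the well lives), one-third
uniform in the remainder of the box — with 1.5 million samples by
default, a reported standard error (kT × relative error of Z, typically
<0.001 kcal/mol for the default model), and a hard failure above 1%
relative error rather than a silently imprecise oracle. In the
zero-coupling limit it reduces to −kT ln(V_box/V°) = −0.932 kcal/mol for
the 20 Å box, which the end-to-end pipeline must and does reproduce.

`run_full_toy_pipeline` chains everything: both environments sampled on
desk-scale schedules (Δλ_coul = 0.25, Δλ_vdW = 0.125 with the full
12-value restraint list → 24 complex and 13 solvent windows, about ten
per leg), 20,000 sweeps per window, 10% equilibration discard,
decorrelation, bootstrapped MBAR per leg (200 replicates), two
independent repeats of the whole calculation pooled per leg, the
analytic restraint term, cycle assembly. Repeats follow the analysis
protocol for production calculations (repeat, pool the bootstrap
samples); two of them is the desk-scale compromise between honest
uncertainties and runtime. These sizes are the package's validation
conditions: small enough to run a 20-seed coverage study on a laptop
CPU, large enough that the pipeline's 3-sd interval is a meaningful
±0.3 kcal/mol. One pipeline seed derives all sampler and bootstrap
streams by fixed offsets, so a run is exactly reproducible.

## Benchmark statistics

The packaged fixture stores the printed per-ligand values of the BRD4(1)
benchmark — eleven inhibitors with calculated (crystal-pose and
docked-pose), experimental, and docking-score free energies — verbatim at
one decimal. Summary statistics recompute from the ΔG columns, never
from printed difference columns (which carry rounding). MAE, RMSE,
Pearson r (plug-in) and Spearman ρ (midranks, ties averaged) come with
paired-bootstrap means and standard deviations over ligands (10,000
replicates, seeded); replicates on which a correlation is undefined are
skipped. The plug-in correlations on the rounded printed values
(r ≈ 0.875, ρ ≈ 0.861 for the crystal table) are reported alongside the
bootstrap summaries and are what the tests assert; bootstrap means of
correlations are biased low for n = 11 and are reported, not asserted.
A missing experimental uncertainty (single measurement) is stored as
missing, never as zero.

## Known limitations

- The toy system validates estimator statistics, not molecular-mechanics
  fidelity; its solvent legs are exactly zero by construction.
- The MBAR asymptotic covariance is a diagnostic only; all reported
  uncertainties are bootstrap/pooled.
- The stiff-spring analytic restraint term carries its known
  O(kT²/K) bias (≈0.034 kcal/mol at K_θ = 10 rad⁻²); users who need
  better at soft constants should use the quadrature value.
- Charge and dispersion corrections are applied, never computed.
- Energy tables must fit in memory; no streaming reader.
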