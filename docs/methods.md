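# Methods

## Model and sampling

The engine simulates single-site particles in a cubic periodic box under
truncated Lennard-Jones interactions (Lorentz-Berthelot combining, shared
cutoff `r_c`, minimum image) plus Coulomb electrostatics damped by a
Barker-Watts reaction field (dielectric `eps_rf`, default 78.4; the
reaction-field potential vanishes smoothly at the cutoff).  Units are
fixed package-wide: nm, kJ/mol, elementary charge, kelvin; conversions to
other unit systems belong to a reporting layer.

Sampling is single-particle-displacement Metropolis Monte Carlo in the
NVT ensemble.  Every quantity the method needs is an equilibrium ensemble
average, so Monte Carlo is sufficient and sidesteps thermostat and
integrator machinery; constant-pressure volume moves are deliberately not
part of the default surface.  The chain is driven entirely by
pre-generated random arrays from a single integer seed, so a run is
bit-reproducible; the inner loop is compiled with numba when available,
with an equivalent pure-numpy fallback.  Acceptance ratios around 0.3-0.5
at the default maximum displacement of 0.15 nm indicate healthy mixing
for the packaged systems.

During decoupled and partially coupled sampling the solute is tethered to
the box centre by a weak harmonic spring (10 kJ/mol/nm^2).  The tether is
identical in both end states, so it cancels exactly in the energy gap dU
and leaves all fitted quantities unchanged; it only prevents the ghost
solute from wandering.

## Alchemical coupling and its two paths

The reference state U0 has all solute-solvent interactions off; the
target state U1 is fully interacting.  Two paths connect them:

- **linear**: U(alpha) = (1-alpha) U0 + alpha U1.  On this path the TI
  integrand equals the instantaneous gap dU for every configuration —
  the identity the gradient-matching method rests on — so all *fitting*
  is done on the linear path.
- **soft-core** (Beutler-form vdW, alpha_sc = 0.5, linearly scaled
  charges): used for *thermodynamic integration* of the van der Waals
  stage.  The linear path's insertion integrand has a divergent mean at
  the decoupled endpoint (the r^-12 core is integrable only with the
  Boltzmann weight of a finite repulsion), so a full-range [0, 1] TI grid
  is only meaningful on the soft-core path, where the analytic
  d(energy)/d(alpha) is implemented and cached per snapshot.

Staged decoupling: an electrostatic stage (charges scaled, full vdW
present in both end states) followed by a vdW stage (cavity grown with
charges off).  A schedule validator rejects any interaction scaled in two
stages.

## Estimators

- `<dU>_alpha`: sample mean of the cached TI integrand with a
  block-averaged standard error (10 contiguous blocks by default, at
  least 5; block SEs were verified against across-seed scatter).
- TI: trapezoidal rule on any sorted grid, or Gauss-Legendre when the
  grid matches the nodes; SEs propagate as the quadrature-weighted
  root-sum-square.
- Hydration free energies repeat the whole calculation three times with
  distinct seeds.  The reported SE is the *maximum* of the across-repeat
  standard error and the quadrature-propagated SE of the repeat mean:
  with three repeats the empirical SE is chi-distributed with two degrees
  of freedom and occasionally collapses to near zero by chance, which
  would make 3-sigma consistency checks fail spuriously.
- Parameter derivative of `<dU>_alpha` (the quantity the fit needs): the
  fluctuation identity

      d<dU>_a/dl = <d(dU)/dl>_a - beta ( cov(dU, dE_a/dl) ),

  with the per-snapshot derivatives of dU and of the sampled potential
  E_a taken by central finite differences (relative step 1e-4, absolute
  floor 1e-6 in native units; steps recorded in the output).  The SE is
  the block standard error of the full combined estimator, not of its
  terms.  When the perturbed parameters touch only solute species, the
  solvent-solvent energy cancels exactly in the finite difference and is
  skipped — an exact optimisation, not an approximation.  The independent
  check is a brute-force oracle that re-simulates at K +/- delta with
  common random numbers and central-differences the two means; the two
  routes agree within combined statistical error for sigma, epsilon and
  charge parameters (see the acceptance suite).

## Objective and optimiser

Physical parameters map to dimensionless coordinates through
K_i = K_i(0) + t_i k_i.  The prior width t_i sets both the scale of the
coordinate and the strength of the Gaussian prior w_reg ||k||^2
(w_reg = 0.01): one prior width of movement costs 0.01.  Kind-level
default widths (sigma 0.05 nm, epsilon 0.2 kJ/mol, charge 0.1 e — about
10-30% of typical CG bead values) apply when a configuration does not
specify its own.  Mapped values that violate a physical bound (epsilon
>= 0, sigma > 0) are clipped with a warning rather than rejected, so a
trust-region trial step can never produce an unevaluable force field.

Each target term is L_m = sum_a w_a [(<dU>_a^model - <dU>_a^ref)/d]^2
with uniform weights w_a = 1/n_alpha and normalisation
d = max(1 kJ/mol, RMS of the reference means), making residuals
dimensionless and order one.  Whether per-point SE weighting would be
preferable is an open choice; uniform weights are the declared default.
The derivatives chain through the mapping (residual Jacobian
J = t * g / d) to an analytic gradient and a Gauss-Newton Hessian, which
is positive semidefinite by construction.  The reported *noise floor*
sum_a w_a (SE_a/d)^2 (reference plus current-model contributions) is the
expected value of the purely statistical part of the objective — the
level below which further "improvement" is meaningless.

The optimiser is trust-radius Newton-Raphson: dogleg solution of the
trust-region subproblem, Levenberg-Marquardt damping whenever the Hessian
is not positive definite, radius adapted by the classical 0.25/0.75 ratio
rule (shrink 0.5, expand 1.5, initial radius 0.3 in k-norm).  Because the
objective of a simulation-backed fit is stochastic, a step whose |actual
reduction| is below the noise floor is accepted but flagged; three
consecutive flagged steps terminate the run as noise-dominated.  The
returned solution is always the best-by-objective evaluated point.  An
L-BFGS wrapper behind the same callback contract exists for
deterministic cross-checks but is not the default.  Any iterate more than
3 prior widths from the start adds an over-fitting warning to the trace
without rejecting the step.

## Charged-solute corrections

Standard HFE assembly: dG_hyd_std = (dG_chg_raw + dG_cav) + dG_ABD +
dG_C1 + dG_std.  The standard-state term RT ln(v_gas/v_sol) evaluates to
7.93 kJ/mol at 298.15 K and 1 atm (7.96 at 1 bar).  The A+B+D corrections
properly come from continuum electrostatics; the package defines a
provider interface and ships an analytic Born-ion + Wigner lattice-sum
stand-in (synthetic, clearly labelled) — real numerical Poisson results
or published values enter as user-supplied numbers, and the published
side-chain budget table is packaged as CSV.  The C1 (P- to M-summation)
correction is likewise user-supplied, with a non-authoritative analytic
helper.  Correction gradients for fitting are central differences of the
correction evaluated at alpha-scaled parameters (alpha in [0.4, 1.0]; at
alpha = 0.9 the parameters sit at 90% of their value), and the corrected
reference data are raw_ref + cor_ref - cor_model per alpha point.
Correction gradients enter the Gauss-Newton Hessian through the same
chain rule as any other gradient contribution.

## Synthetic reference data and the canonical recovery experiment

The fixtures module emulates the role of a higher-resolution reference
model by running the same toy engine at ground-truth parameters K* and
packaging the noisy <dU>_alpha estimates as targets.  Reference and fit
phases use disjoint seed streams.  Because truth is known, recovery
quality is measured in absolute terms: success requires every free
parameter within max(5%, 2 propagated SE) of truth and the refit
hydration free energy within 3 combined SE of the reference value.
Parameter uncertainties come from linearising the stationarity condition
(cov(k) = H^-1 (4 J'W S W J) H^-1 with S the per-point residual variance
from both SE sources).  A parameter whose gradient never rises above
twice its own statistical error at any alpha point is flagged
non-identifiable, and a flagged fit is never declared a success.

The canonical scenario is a 1-bead apolar solute (sigma 0.47 nm, epsilon
2.0 kJ/mol, q 0) tethered in 100 LJ solvent particles (sigma 0.42 nm,
epsilon 0.8 kJ/mol) in a 2.5 nm box with a 0.9 nm cutoff at 298.15 K;
epsilon is started +20% high and must be recovered.  Fitting grids: 5
uniform electrostatic points (identically zero for this neutral solute,
but the staged machinery is exercised end to end) and 11 vdW points on
[0.4, 1.0] clustered geometrically towards full coupling — the window
where the linear-path integrand is both finite and informative, and the
same window used for correction gradients.  Each alpha point runs 480k
Metropolis moves after 12k of equilibration, saving every 1600th
configuration (300 snapshots).  The epsilon prior width is 2.0 kJ/mol —
the parameter's own magnitude.  This is an intentionally weak prior: the
premise of refitting is that the starting parameters may be far from
truth, so the prior should guard against runaway rather than inform the
answer; a much narrower width makes the data term comparable to the
penalty and biases the solution visibly towards the (deliberately wrong)
start.  Problem sizes throughout (box size, chain lengths, grid sizes)
are the package's own choices for a desk-scale verification surface.

What passing recovery does and does not show: the synthetic reference is
the *same* resolution and functional form as the fit model, so recovery
demonstrates the correctness and conditioning of the machinery
(estimators, derivatives, optimiser, bookkeeping) — not that a CG model
can reproduce a genuinely finer-grained reference, where representability
gaps appear.  A finer-grained reference mode (multi-site reference solute
mapped to one bead) is a natural extension and deliberately out of the
packaged acceptance surface.

## Numerical choices and degenerate inputs

- Pair distances below 1e-6 nm are an error in batch evaluation and an
  automatic rejection (energy sentinel 1e30) inside the sampler.
- Block averaging needs >= 10 samples; estimators reject shorter series.
- Gauss-Legendre integration validates the grid against the nodes to
  1e-9 before applying the weights.
- The dogleg solver damps the Hessian by escalating Levenberg-Marquardt
  shifts until Cholesky succeeds (40 doublings maximum); if the curvature
  along the gradient is non-positive the step falls back to the scaled
  steepest-descent boundary point.
- Tie-break on the best iterate: strict improvement is required, so the
  earliest of equal-valued iterates wins.
- Zero perturbation in a recovery scenario is allowed (the
  start-at-truth control); an empty perturbation map is rejected.

## Known limitations

- Single-site solvent and solute only; no bonded terms beyond the test
  hooks, no Ewald/PME, no NPT by default.
- The reaction-field treatment and the Born+Wigner correction stand-in
  are internally consistent but not quantitatively transferable to real
  water; the correction machinery is exercised with published budget
  numbers, not recomputed continuum electrostatics.
- Finite-difference parameter derivatives assume the potential is smooth
  in the parameters over the step; the LJ and Coulomb forms used here
  are.
- The across-repeat SE with three repeats is noisy; the conservative max
  rule above mitigates but does not eliminate this.
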