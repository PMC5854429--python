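# Methods

This note documents the models, estimators and numerical choices behind
`unspool`, and what the shipped validation runs do and do not demonstrate.

## Units and constants

Energies in kcal/mol, lengths in Å, time in ps, temperature in K;
k_B = 0.0019872 kcal/mol/K, so k_BT ≈ 0.596 kcal/mol at the default
300 K.  Masses are unit beads (1 kcal/mol·ps²/Å²) — the toy systems make
no claim of realistic time scales, only of correct equilibrium
distributions.  Harmonic terms are written k·x² throughout (no ½
factor), so a restraint of force constant k has Boltzmann variance
k_BT/(2k).

## Langevin dynamics

All sampling uses the BAOAB splitting of Langevin dynamics, chosen for
its accurate configurational averages at moderate time steps.  With
friction γ = 0 the step reduces to velocity Verlet.  Walkers and umbrella
windows advance in lockstep as one batched state array, drawing their
noise from a single seeded generator; because the batch layout is fixed
by (seed, walker count), runs are bitwise reproducible.  Friction is a
pure sampling-efficiency parameter here: the shipped benchmark protocols
use γ = 0.5 ps⁻¹ to speed diffusion along the reaction coordinate, while
the mimic's default remains 2.0 ps⁻¹; equilibrium results are unaffected
by this choice, only their convergence rate.

## Adaptive biasing (flooding)

The shared bias U(d) lives on a uniform grid (resolution Δd, default
1 Å).  Each deposit is a Gaussian kernel of width σ = Δd truncated at
4σ and renormalized over the in-grid nodes so that its integrated weight
(sum over nodes × Δd) is exactly k_BT·dt/τ per walker.  This makes the
conservation identity — integrated bias = k_BT/τ × summed in-range
walker residence time — hold to floating-point accuracy, and the total
deposition rate proportional to (walker count)/τ.  Between nodes the
bias is evaluated with a Catmull–Rom piecewise cubic whose analytic
derivative supplies the force; outside the range the bias is zero and
one-sided harmonic walls (k_w(d−d_wall)², no ½) hold the walkers.

The free-energy estimate is −U averaged over the final third of the
bias-snapshot history: the late-time bias fluctuates around −F + c by
the granularity of the deposition process, and time-averaging suppresses
that fluctuation without biasing the profile.  Convergence is diagnosed
from the per-interval deposited energy ("dropped energy"): when the
residual landscape V + U is flat, walkers visit all bins uniformly and
the last interval's per-node deposits are spatially uniform.  The
uniformity metric is max-over-nodes |deviation from the spatial mean| /
mean, evaluated on nodes at least 1 Å inside the walls.

Protocol scale of the shipped flooding benchmark: 8 walkers, τ = 100 ps,
3 000 ps, Δd = 0.25 Å on a 3 kcal/mol double well.  τ and the duration
were chosen so the total deposited energy is roughly an order of
magnitude larger than the fill volume of the landscape — enough to
flatten and then accumulate uniformly — while keeping the late-stage
deposition gentle; flooding much faster (τ of a few ps over long runs)
overfills the range and pushes walkers over the walls.

## Umbrella sampling and WHAM

Windows sit on an inclusive grid lo + spacing·i with a commensurability
check (no silent truncation).  Seeds are chosen per window as the stored
walker frame whose d is closest to the center, ties toward the lower
walker id.  The combined bias k(d−c)² + U_abmd(d) uses the frozen final
flooding bias, shared by reference across all windows of a stage.
Samples outside the configured keep-range are discarded (closed
interval, so samples exactly on the boundary are retained — window
centers may sit exactly on the range limits).

The WHAM equations are iterated on a binned grid (default bin width
1 Å, configurable) in log space (log-sum-exp), with the first window's
shift anchored to zero during iteration and the final profile
min-shifted.  The tolerance, 10⁻⁸ kcal/mol on max|ΔF_j|, applies to the
iterated window shifts.  Empty bins are reported as missing values,
never imputed; a window sharing no occupied bin with the others triggers
a warning naming it.  Per-sample unbiased weights evaluate the window
biases at the sample's bin center, which makes the weighted histogram
reproduce the WHAM P bin-for-bin exactly — the internal-consistency
check the tests assert.  No statistical-inefficiency correction is
applied to correlated samples; profiles are exact in the limit of
independent samples and otherwise carry the raw-data correlation, a
documented limitation.  A duration-convergence diagnostic
(`wham.convergence_series`) recomputes the profile from growing sample
prefixes and reports RMSDs between consecutive profiles.

The tests cross-check the fixed-point solver against an independent
second path: direct minimization of the convex WHAM log-likelihood with
analytic gradients (scipy L-BFGS), written from the estimating equations
rather than the iteration.

## Reweighting

Projections onto alternative coordinates accumulate weighted tallies
with ordered in-place adds, so every result is bit-identical to an
explicit loop over samples — asserted against brute-force oracles.
Integer coordinates (unwrapped-unit counts) are binned at unit width;
empty bins are missing, not zero.  2-D landscapes anchor the global
minimum at zero; marginalizing reproduces the 1-D profiles.

## The bead-on-spool mimic

Each of two identical arms is a chain of n beads (default 10), bead 0
outermost.  Bead j carries a scalar radial displacement x_j from its
wrapped reference position, confined to [0, 8] Å by soft walls
(50 kcal/mol/Å²).  M sites per arm (default 4, on beads 0, 3, 6, 9)
bind their bead with a well of depth ε (default 1 kcal/mol) extending to
the capture radius 4 Å with a 0.5 Å cosine shoulder for force
continuity.  A bead counts as unwrapped when x > 4 Å.  Sequential
unwrapping is enforced by a gating bond: bead j+1 pays
50·max(0, x_{j+1} − r₀)² scaled by (1 − u(x_j)), where the release
switch u ramps from 0 to 1 over x_j ∈ [4, 4.3] Å.  The rest length
r₀ = 3.8 Å sits two thermal penetration lengths below the threshold so
that a blocked bead's accessible volume matches a free wrapped bead's;
with that choice the exact free energy along the per-arm count is a
clean staircase — ≈ ε per site release, ≈ 0 between sites (residual
gating/shoulder corrections of a few per cent, visible in the oracle).
The end-to-end distance analog is d = 20 Å + Σx_j, a deterministic
function of the coordinates; a 3-D embedding (anchors on a 30 Å circle,
displacement along the outward radial unit) supplies frames for the
structural metrics, with the radial displacement equal to x_j exactly.

Two exact oracles accompany the mimic.  The transfer-integral
enumeration computes the joint distribution of (bead positions, count)
per arm by dynamic programming over a quadrature grid with a count
register — exact for this nearest-neighbour Hamiltonian — and convolves
the two independent arms.  The site-occupancy reduced model treats
unwrapping as strictly sequential two-state release with one-bead
partition functions; it is the hard-gate limit of the former and agrees
with it to the gating corrections.  Along the total count the two-end
split degeneracy mixes the site steps (several splits contribute to each
total), so per-site energies are read off the per-end profile, where the
arms' independence makes the steps equal ε exactly in the oracle.

What the mimic does and does not emulate: it reproduces stepwise
site energetics, two independently unwrapping ends, mirror symmetry,
thermal noise at fixed temperature, and a monotone coordinate–count
relationship.  It has no bending or twist elasticity, no sequence
dependence, no electrostatics, and its coordinate–count map is far
simpler than a real polymer's; passing the recovery tests demonstrates
the correctness of the estimation machinery, not fidelity to any real
nucleosome's energetics.

## Validation protocols and problem sizes

* **WHAM recovery**: 21 windows (2.5–7.5 Å, k = 1) × 20 000 samples
  drawn by exact rejection sampling from the biased densities, bin width
  0.05 Å; RMSD vs the analytic double well over the well-to-well range
  after mean alignment.  Typical result ≈ 0.016 kcal/mol.
* **Flooding convergence**: the protocol above; RMSD of the
  time-averaged −U vs the potential ≈ 0.05 kcal/mol, late-interval
  uniformity ≈ 0.06–0.14, conservation error ≈ 10⁻¹².
* **Mimic parameter recovery**: flooding (24 walkers, τ = 2 ps, 400 ps)
  seeds 71 windows (36–176 Å, spacing 2 Å, k = 0.2) sampled for 12 000 ps
  each (burn-in 600 ps); WHAM with 1 Å bins; per-site steps are
  plateau-mean differences of the per-end profile pooled over both ends
  (mirror symmetry), compared against the same estimator applied to the
  enumeration oracle; the total rise along the total count is compared
  to the oracle's.  Typical worst per-site deviation ≈ 0.05–0.11
  kcal/mol on ε = 1; total within a few per cent.  The slowest mode is
  exchange between the two arms' unwrapping splits at fixed d, which
  sets the umbrella duration.
* **Kernel checks**: contact probabilities equal an explicit all-pairs
  scan exactly (the accumulation is frame-ordered so no vectorization
  changes the result); the unwrapping threshold is strict (> 4 Å,
  outward), the contact cutoff inclusive (≤ 4 Å).

## Degenerate inputs and tie-breaks

Empty windows (all samples discarded) participate in WHAM with zero
count and are excluded from the overlap warning; seeding ties go to the
lower walker id; σ² estimates are clipped at zero before the square
root; grids that do not divide their range raise instead of truncating;
a profile with empty support raises.  All CSV outputs round-trip floats
at full precision.

## Known limitations

Biasing is 1-D only (no 2-D collective variables, no well-tempered
scaling, no replica exchange); WHAM is binned, with MBAR-style binless
estimation intentionally out of scope except as a conceptual cross-check;
no bootstrap error bars on profiles; the integrator is not meant for
stiff all-atom force fields.
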