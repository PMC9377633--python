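# Methods

## Model and conventions

All dynamics follow `tau dx/dt = -x + W f(x)` with `tau = 200 ms`.
`f` is the identity in linear mode and, in nonlinear mode, the
saturating map `r_min tanh(x/r_min)` for `x < 0`, `r_max tanh(x/r_max)`
otherwise, with `r_min = 1 Hz` and `r_max = 4 Hz`: slope one at the
origin, an asymmetric floor/ceiling on the rate deviation from baseline.
Norms are Euclidean throughout; initial conditions have unit norm, so a
response norm above 1 marks transient amplification and above 1.5 (50%
gain) marks an *amplified* condition. Stability always means
`max Re(lambda(W)) < 1`.

## Upper-triangular construction

`W~ = Lambda + T` in real Schur layout: real eigenvalues on the
diagonal, each conjugate pair `alpha ± i beta` as the block
`[[alpha, -beta], [beta, alpha]]`, blocks in randomised order, and `T`
strictly upper triangular with zeros at the super-diagonal cells covered
by the blocks (those cells belong to `Lambda`). The Frobenius norms of
the two parts are orthogonal components of `||W~||_F`, and
`||Lambda||_F² = Σ|lambda_k|²`.

Spectra keep 3% of eigenvalues purely real (6 of 200; the complement is
forced even for conjugacy). Imaginary parts are uniform on
`(-d_im/2, d_im/2)` in ± pairs (or clustered at ±c with a given radius);
real parts come in four flavours: uniform with supremum 0.5, a single
value, uniform on (-0.5, 0.5) with one purely real balancing eigenvalue
enforcing a zero sum (the no-autapse condition), and a zero-trace
construction with `M = |gamma_out|/0.5` eigenvalues pinned at 0.5
compensating a negative outlier. Real/imaginary pairings are random
apart from conjugacy.

Two choices here were genuinely open:

- **The balancing eigenvalue must be admissible.** Summing ~200 uniform
  real parts gives a balancer with a standard deviation of ~4, so about
  half of the raw draws would violate the stability supremum the same
  construction imposes. We redraw until the balancer is below 0.5. This
  conditions the real distribution slightly but is the only way the
  construction yields the stable networks the analysis requires.
- **Spectrum-norm targeting rescales imaginary parts only.** A target
  such as `||Lambda|| = 700` at N = 200 cannot be met by scaling the
  whole spectrum — real parts are capped near 0.5 by stability — so the
  sampled imaginary parts are scaled by a common factor to meet the
  target exactly, leaving the real distribution untouched. The 0% point
  of the norm-split sweep sets `Lambda = 0` (nilpotent); 100% sets
  `T = 0` (normal).

Feedforward structures are uniform entries on (-0.5, 0.5) at every
allowed position (optionally sparse, or restricted to the first
super-diagonal as 2-chains), linearly rescaled to the requested
Frobenius norm, or taken from the strictly-upper part of the real Schur
form of a stability-optimised circuit (in-block cells of the source
removed, then rescaled). Schur blocks keep LAPACK's deterministic
ordering; we found no need to reorder them, and scipy exposes only a
two-way partition of the real Schur form.

Rotation into a dense recurrent matrix uses a Haar-random orthogonal
`U`: `W_rec = U W~ Uᵀ` preserves the spectrum, the eigenvector-geometry
statistics and every amplification measure, which the tests verify.

## Integration and response measures

Explicit classical Runge–Kutta (RK4) with `dt = tau/100 = 2 ms` by
default; halving `dt` changes the maximal response norm by less than
1e-3 relative, and the nonlinear integrator was cross-checked against an
adaptive RK45 at rtol 1e-8 (max norms agree to four digits). The fastest
oscillations used here (`|Im lambda| ≲ 90`) stay well inside the RK4
stability region at this step. Linear trajectories use the closed-form
eigendecomposition (coefficients from `V⁻¹x0`, modal factors
`exp(t(lambda-1)/tau)`); when `cond(V) > 1e12` — near-defective,
nilpotent-dominated matrices — a matrix-exponential propagator replaces
it. An overflow guard aborts runs whose state norm exceeds 1e12 (the
interesting linear transients peak around 1e5).

The per-condition maximal linear norm is found on a log-spaced grid over
`(0, 50 tau]` (plus t = 0) refined by golden-section search around the
grid peak. The nonlinear transient duration Δt is the time from t = 0 to
the final down-crossing of `||r(t)|| = 1` (sub-threshold dips are
bridged; a total-time-above variant is exposed as an option and differs
by under 2% in practice), with linear interpolation of the crossing and
a censored flag when the horizon ends above threshold. Regimes: weak
(Δt ≤ 500 ms), short transient (< 2000 ms), long transient (≥ 2000 ms).

## Evoked energy and optimal bases

`E(a) = 2 tau ∫ ||x||² dt = aᵀQa` with `Q` solving
`AᵀQ + QA = -2 tau I`, `A = (W - I)/tau`, tau in seconds (so `Q = tau² I`
for the pure leak, E = 0.04 s²). The ordered basis is built by iterative
deflation — leading eigenvector of `Q` restricted to the shrinking
orthogonal complement — which for a symmetric `Q` coincides with its
sorted eigendecomposition; both facts are tested.

## Dalean networks and stabilisation

Half the neurons are excitatory (first N/2 columns, non-negative), half
inhibitory (non-positive); connections are Bernoulli(p = 0.1) with no
autapses, excitatory entries `w0/sqrt(N)` and inhibitory
`-(I/E) w0/sqrt(N)`, with
`w0 = R_outer / sqrt(p(1-p)[1+(I/E)²]/2)` and `R_outer = 10` by default
(this reproduces the printed per-connection weights 1.05 at I/E = 3 and
0.08 at I/E = 40). Closed forms: outlier
`gamma ≈ (p w0 sqrt(N)/2)(1 - I/E)`, inner radius
`R_outer sqrt(1/(2[1+(I/E)²]))`.

The stabiliser drives `max Re(lambda)` below `alpha_max = 0.5` by
gradient descent on the spectral abscissa smoothed through its
Lyapunov representation: at a shift `s` slightly above the current
abscissa, the factors `P` and `Q` solve
`(A-sI)P + P(A-sI)ᵀ = -I` and its transpose, and the descent direction
is `QP/tr(QP)` (verified against finite differences). The shift gap
closes proportionally to the distance from the target so the gradient
stays informative near convergence. Only inhibitory columns move (zero
entries included); after every step the matrix is projected back onto
the constraint set — inhibitory signs, empty diagonal, inhibitory
density ≤ 0.4 (pruning weakest-by-magnitude entries once, then freezing
the support), and the exact I/E ratio via a linear rescale of all
nonzero inhibitory weights. Two refinements matter in practice: the
gradient is differentiated *through* the ratio-restoring rescale
(removing the component a global rescale undoes), and when the true
abscissa is locally nonsmooth (eigenvalue-branch crossings) the line
search falls back to descent on the smooth fixed-shift trace surrogate.
The input is projected once before optimisation so the line search
compares feasible points (this matters when an E-to-I block has been
rescaled first). Acceptance is on outcome constraints only — abscissa,
Dale signs, density, ratio — not on the optimiser's path; at N = 200 the
optimiser converges in some 50–200 iterations (a few seconds), slower
when E-to-I connections are weakened (inhibition then has less leverage
over the unstable modes).

## Spectral density estimates

The empirical outer/inner imaginary radii use a Gaussian KDE (Silverman
bandwidth) of the imaginary parts, symmetrised and normalised to unit
integral, with the single most negative real eigenvalue (the outlier)
removed: the outer radius is the largest |Im| where the density still
reaches 0.005, the inner where it first falls below half its maximum.
On raw Dalean matrices at I/E = 3 the outer diameter averages ~21.5
(construction target 20). The half-max inner radius is
estimator-dependent: the radial eigenvalue density is a smooth gradient
rather than two sharp discs, and the Im-marginal carries a spike at zero
from purely real eigenvalues, so the KDE half-max radius (~5–6) sits
well above the asymptotic closed form (~2.24 at I/E = 3). Tests
therefore validate the estimator on a synthetic uniform disc and the
ordering inner < outer, not the closed-form value.

## Dimensionality measures

`erank(M) = exp(-Σ p_k log p_k)` with `p` the singular values normalised
by their 1-norm (natural log; scale-invariant). The matrix `P` collects,
for each amplified condition of the ordered basis, the leading principal
component of its (linear or nonlinear) rate trajectory — PCA over time
samples with the temporal mean subtracted, on the integrator grid — or
as many components as needed to reach 85% explained variance in the
`var85` variant. An empty `P` (nothing amplified) has no effective rank
and is reported as such.

## Synthetic data and what the tests show

Everything here is synthetic by design — the study objects *are*
generated matrices, not recordings. The generators emulate the stated
construction exactly (sizes, sparsity, weight formulas, spectrum
families); what they do not emulate is any feature of biological data
beyond Dale's law and sparsity (no cell-type structure beyond E/I, no
distance dependence, no noise, no external drive). Passing tests
therefore certify the mathematics of the constructions and measures, not
fits to physiological recordings.

Desk-scale defaults: sweeps average 20 realisations (overridable) and
trend tests use 2–3 seeds at N = 200 with 2–3 grid points, sizes chosen
so the full suite runs on a laptop-class machine; the monotone trends
they check are stable at these sizes.

## Known limitations

- The weak-regime landmark of the norm map — (feedforward, spectrum)
  norms (100, 700) giving Δt ≤ 500 ms — comes out at a median of
  ~550–950 ms here: the top-energy condition peaks near 2 and the slow
  modes (real parts up to 0.5) stretch the decay past the bound. The
  neighbouring landmarks (700, 100) ≥ 2 s and the ≥ 10 s narrow-spectrum
  transient reproduce with wide margins.
- With circuit-derived feedforward structure at norm 75 and broad
  spectra (d_im = d_re = 10), ~3% of conditions are amplified here
  against the reported ~1%; the stabiliser is a reimplementation from
  outcome constraints, so its Schur feedforward differs in fine
  structure.
- The stabiliser can legitimately fail on very small networks (N ≲ 20),
  where the density cap and ratio constraint leave few degrees of
  freedom; it raises with the best abscissa reached.
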