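# Methods

## Model and assumptions

All measures are defined for zero-mean, wide-sense-stationary Gaussian
vector processes admitting a stable, stably invertible (minimum-phase)
monic VAR representation G(L) u_t = ε_t with positive-definite innovation
covariance Ω. Estimation is per-equation ordinary least squares on
per-channel demeaned data, with no intercept, trend, or regularization
(an optional ridge parameter exists but defaults to zero). The innovation
covariance is the residual covariance with denominator T − p, consistent
with the Gaussian likelihood used by order selection. AIC/BIC use
−2·loglik + penalty with k = p·n² + n(n+1)/2 parameters, all candidate
orders scored on the common sample that excludes the first p_max rows.

The companion-form innovations realization (A, C, K, V) carries all
sub-process algebra. Its whitening filter
G(L) = I − C L (I − (A − KC)L)⁻¹ K reproduces the VAR filter exactly, so
"apply the whitening filter to data" and "take the regression residuals"
agree to round-off — a property the test suite checks rather than assumes.

A standing assumption, inherited from the framework itself: the diagonal
blocks of every whitening filter encountered (the full model's and those
of extracted sub-process models) must be stably invertible, because each
ME residual is such an inverse driven by an innovations block. Models
violating this raise `MinimumPhaseError`; no attempt is made to compute
the measures for them. Generic random stable VARs occasionally violate
the assumption, so the property tests draw candidates by rejection
(`tests/conftest.draw_assumable_model`) — the ordering and zero-detection
guarantees being tested hold under the assumption, and the rejection probe only gates
feasibility, never the asserted values.

## Sub-process models and entropy rates

The innovations model of a channel subset is obtained by solving the
filtering discrete algebraic Riccati equation for the original state
recursion observed through the kept rows, with correlated state and
observation noise. The stabilizing solution guarantees a stable,
minimum-phase sub-model whose spectrum equals the corresponding sub-block
of the full spectrum — enforced in tests at 1e−8. scipy's QZ-based DARE
solution is refined by a dozen fixed-point Riccati iterations (linear
convergence at the squared closed-loop radius), which brings the
zero-coupling measures down to the 1e−10 level the zero-detection
property requires. Wilson's iterative factorization on the frequency grid
is implemented independently and serves as the cross-check oracle
(convergence: successive-iterate relative step < 1e−9, cap 500
iterations); the two routes agree on innovation covariances to ~1e−12
relative on well-conditioned models, tested at 1e−5.

Entropy rates (nats per step) use h = ½ ln det Σ + n/2 (1 + ln 2π) for
innovations-driven processes and trapezoidal quadrature of ½ ln det S(θ)
over [0, π] otherwise. Because the integrands are smooth and periodic,
the uniform-grid trapezoid rule converges geometrically: at the default
1024-point grid the Kolmogorov–Szegő identity holds to ~1e−12 for radii
up to ~0.9. The PSD convention carries no 1/2π prefactor; every measure
is a difference of log-determinants, so the convention cancels.

## The three conditional constructions

* **Std**: x‖z from the (x, z) sub-model, x‖yz from the full model; the
  time value is the log-det ratio of the two driving covariances.
* **JEnt**: the joint residual (x; y)‖z is the inverse of the [xy, xy]
  whitening block of the full model — purely analytic, no factorization.
  Its x-marginal is not an innovations process, so the JEnt time-domain
  value is defined (and computed) as the full-band mean of its frequency
  curve; with the spectrally accurate quadrature this is exact to ~1e−12,
  which is why the variant ordering can be tested at 1e−9.
* **SEnt**: x‖z and y‖z are realized as one augmented state-space system
  driven by the full innovations (cascade of full model → sub-model
  whitening → inverse diagonal block, states stacked, identity
  feedthrough), and that system is factorized by a DARE with correlated
  state/observation noise. No model reduction is applied: state
  dimensions add along the cascade, trading parsimony for exactness. A
  grid route (evaluate the augmented output spectrum, factorize by
  Wilson, re-realize the causal factor as a truncated moving average) is
  exposed via `method="wilson"` purely as a cross-check; the two agree to
  ~1e−12 on test models.

The ME filters are strictly causal (no lag-0 term), so residuals retain
instantaneous correlation with their predictors; this is why the Ent
frequency curves can dip below zero at high frequencies while the
classical Geweke curves cannot.

The conditional Geweke decomposition (`cgcm_geweke_freq`) follows the
standard single-full-model construction: whiten the reduced (x, z)
process, re-express through the full transfer function, and subtract the
causal contribution of the source's partialized innovations. Its
full-band mean equals the standard conditional measure only under a
minimum-phase condition that is generic rather than guaranteed; on random
stable models the relative deviation is typically ~1e−3 (occasionally a
few percent), while the unconditional version is exact to machine
precision. The package therefore reports the curve as computed and the
tests assert approximate (5%) mean agreement plus the exact degenerate
reductions. The DTF is the row-normalized squared transfer magnitude;
the raw |H_ij|² is available behind a flag.

## The simulation benchmark

The generator reproduces a three-topology, 9-node VAR(1) study design:
a fixed demo network, a directed ring, and a star (hub drives all
boundary nodes), every node with a self-loop; the common coupling
coefficient is calibrated so the transition matrix has spectral radius
exactly 0.85 (closed form, since the radius is homogeneous in the
coefficient); innovations have the compound-symmetry covariance (2 on
the diagonal, 1 off it); series lengths are 120 samples (60 for the
star), deliberately short of asymptopia; burn-in is 10·n/(1 − radius)
steps. The demo network's exact edge set is this package's own synthetic
construction (a sparse mix of chains and fan-outs) and carries no
external authority; quantitative benchmark claims are anchored to the
ring and star, whose definitions are unambiguous.

What the generator does *not* emulate: hemodynamic convolution,
observation noise, downsampling, non-Gaussian innovations, or
nonstationarity. Passing benchmarks therefore demonstrate correctness of
the estimators under their stated model class, not robustness to fMRI
acquisition physics.

Significance testing permutes the time index of one source channel at a
time (destroying its autocorrelation — a known property of this test,
accepted deliberately), refits the model, and recomputes all measures
with that source. p-values use the add-one convention
(1 + #{null ≥ obs})/(1 + n_perm) ∈ (0, 1]. Pair-level accounting follows
the unordered-pair convention n_perm · n(n−1)/2 per trial (1,000
permutations × 9 channels → 36,000). ROC curves pool p-values across
trials and ordered pairs; pooling over the two benchmark topologies is
used for the headline variant-ranking comparison, which reduces the
Monte-Carlo error of the TPR estimates at a fixed FPR.

## The vectorized benchmark engine

`megc.benchmark` reimplements the VAR(1), scalar-channel,
conditional-on-rest case of the measures with every step batched across
datasets: OLS refits as batched normal equations, sub-model Riccati
solutions by a structured doubling algorithm (quadratic convergence;
~10 doublings suffice at radius 0.85) plus fixed-point polish, whitening
transfers from truncated AR expansions evaluated by FFT, and the SEnt
joint-residual factorization by a batched closed-arithmetic 2×2 Wilson
iteration. Engine resolution defaults (benchmark use): 17-point half
grid on [0, π] (32-point factorization circle), 32 AR lags, single
precision in the spectral phase. These trade a fraction of a percent of
spectral resolution — identical across observed and permuted datasets,
hence neutral to rank-based p-values — for roughly three orders of
magnitude of throughput. With full-resolution settings the engine matches
the object-path measures to ~1e−7 (time) and ~1e−5 (band), which the test
suite verifies; datasets whose refit is (near-)nonstationary or whose
factorization fails to converge are dropped from the null with the
denominator adjusted, mirroring the reference implementation's policy.

## Problem sizes used by the acceptance tests

Identity/ordering/oracle checks use 50–100 random stable models with
2–5 channels and orders 1–3, radii 0.4–0.9. The network-detection
replication runs the circular and star topologies at 120 trials and 100
permutations per channel (a size chosen so the full suite completes on a
single CPU in well under half an hour; the ranking margins observed are
many Monte-Carlo standard errors wide at this size), asserting that the
band-limited ([0, π/2]) SEnt statistic attains the highest pooled TPR at
FPR = 0.1 among the three variants and beats its own time-domain
statistic, with a 0.02 Monte-Carlo allowance (≈2 standard errors of the
pooled estimates). Null calibration uses 200 trials × 200 permutations
of a zero-transition network and requires the pooled p-value KS statistic
against U(0,1) to stay below 0.1.

At these series lengths the mean entropy-based curves over true edges dip
below zero beyond π/2 for the pairwise measure and the SEnt/JEnt variants
on both topologies; the Std-variant entropy curve does so on the ring but
stays positive on the star, so the negativity assertion is per-measure
(Std-Ent required negative on at least one topology).

## Known limitations

Linear, Gaussian, stationary models only; no solutions when diagonal
whitening blocks are not stably invertible (such models are rejected, not
approximated); permutation nulls do not preserve autocorrelation; the
conditional Geweke integral identity is approximate by nature; the
augmented SEnt realization grows additively in state dimension and is not
minimal; the engine's fast path is specialized to VAR(1) with scalar
source/target blocks (the object path handles the general case).
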