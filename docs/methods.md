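# Methods

## The observation model

MR magnitude data are the modulus of a complex-valued signal whose real and
imaginary parts are independent Gaussians with common variance φ.  For a
single (or complex-weighted multi-coil) acquisition the magnitude y follows
the Rician distribution

    p(y | μ, φ) = (y/φ) exp(−(y² + μ²)/(2φ)) I₀(yμ/φ),   y > 0,

where μ is the modulus of the complex mean and I₀ the modified Bessel
function of order zero.  When L coil signals are merged by
root-sum-of-squares, y follows the non-central χ (NC-χ) distribution with 2L
degrees of freedom,

    p(y | μ, φ, L) = y^L / (φ μ^{L−1}) exp(−(y² + μ²)/(2φ)) I_{L−1}(yμ/φ),

which reduces to the Rician at L = 1.  L may be any real ≥ 1; it is treated
as known here (estimating it is out of scope).  A Gaussian model
y ~ N(μ, φ) with the same parametrization serves as the comparison baseline:
it is the standard approximation, accurate when SNR = μ/√φ is large
(noticeably inaccurate below SNR ≈ 3).

### Regression structure

Both distribution parameters are linked to covariates:

    ln μᵢ = β₀ + xᵢᵀβ,    ln φᵢ = α₀ + zᵢᵀα,

with observations conditionally independent given the covariates.  The model
is outside the exponential family (the Bessel factor), so no conjugate
analysis exists; inference is by MCMC.  Lagged responses may appear as
ordinary columns of X or Z, which induces temporal dependence without any
special handling.

### Numerics

All densities are evaluated in log space.  `log I_ν(x)` is computed from the
exponentially scaled Bessel function (`ive`, or the faster `i0e`/`i1e`
kernels at L = 1), so arguments up to yμ/φ ≈ 10⁶ neither overflow nor
underflow; where `ive` itself underflows (tiny x at larger ν) the leading
term of the ascending series is used.  Derivatives w.r.t. (μ, φ) use the
Bessel ratio A(t) = I_L(t)/I_{L−1}(t) with the recurrence
A′ = 1 − A² − (2L−1)A/t; for t < 10⁻⁶ both are replaced by their exact
t → 0 limits (A ≈ t/2L, A′ ≈ 1/2L), which keeps the score finite as μ → 0
(the Rayleigh/central-χ limit).  The mean of the magnitude law (needed for
SNR calibration) is the confluent-hypergeometric expression
E[y] = √(2φ)·Γ(L+½)/Γ(L)·₁F₁(−½; L; −μ²/2φ), switched to the asymptote
√(μ² + (2L−1)φ) above μ²/2φ = 200 where the direct evaluation loses all
precision; the variance uses E[y²] = μ² + 2Lφ exactly, with the analogous
φ-limit guard.

## Priors

Two families are implemented.

**Generic regression prior.**  Design columns are standardized (mean 0,
sd 1); the standardization statistics are stored so results can be mapped
back.  The user states a log-normal prior mean m* and sd s* for μ at the
covariate mean; the implied intercept prior is β₀ ~ N(m, s²) with
s² = log[(s*/m*)² + 1], m = log m* − s²/2.  Coefficients get the
Fisher-information g-prior β ~ N(0, cΣ), Σ = (XᵀD̂X)⁻¹, where D̂ is the
per-observation Fisher information of the linear predictor at the prior
mode (all coefficients zero).  For the Rician/NC-χ families this expectation
has no closed form and is computed by one-off adaptive quadrature over y.
c = n gives a unit-information prior.  The variance-side prior mirrors the
same construction with the Fisher information for φ; the φ value at which
D̂ is evaluated defaults to the prior-mode value and is an argument.

**Variable selection.**  Binary indicators with independent Bernoulli(π)
priors, π = 0.5 by default, so all 2^p models are equally probable a priori.
Conditioning the coefficient prior on the excluded coefficients being zero
gives the Schur-complement covariance c(Σ_II − Σ_IIᶜ Σ_IᶜIᶜ⁻¹ Σ_IᶜI) on the
selected block; excluded coefficients are exactly zero.  Intercepts are
always included.

**DTI stability prior.**  For tensor fitting the g-prior is replaced by a
numerically more stable construction: the b = 0 measurements give the prior
means m_β = log(mean y|b=0) and m_α = log(var y|b=0); the intercepts get
variance d = 0.01 and the tensor parameters ω and variance coefficients α
get wide isotropic N(0, cI) priors with c = 100.  The b = 0 rows are then
removed from estimation.  Fewer than two b = 0 rows, or all-equal b = 0
values, are errors rather than silent fallbacks.

## The sampler

The joint posterior is simulated by a two-block Metropolis-within-Gibbs
scheme: (β₀, β, I_β) | · and (α₀, α, I_α) | ·, each updated by a joint
Metropolis–Hastings move.

**Tailored proposal.**  The coefficient proposal is multivariate t with 10
degrees of freedom (a normal proposal is a config switch), centered at the
terminal point of a fixed number (default 2) of damped Newton steps on the
conditional log posterior started from the current draw, with scale matrix
the negative inverse Hessian there.  Because the chain is already near the
mode, one or two steps suffice.  The Newton map is deterministic in its
starting point, so the reverse-proposal density in the MH ratio is obtained
by re-running the same map from the proposed point.  Where the conditional
is locally non-concave, the negative-curvature eigendirections of −H are
reflected to |λ| (saddle-free modification) with a small eigenvalue floor;
steps that decrease the conditional posterior are halved up to ten times
and abandoned if still downhill.  Numerical failures in proposal
construction count as rejections.

**Indicator moves.**  A random subset of min(4, p) indicators is proposed
per update, each selected indicator flipped with probability ½ — a
symmetric move whose density cancels from the ratio.  Newly included
coefficients start their Newton climb at zero.  Proposal densities are over
the selected coordinates only; the ratio uses the conditional selection
prior on each side.  Every stored draw satisfies β_j = 0 ⟺ I_j = 0.

**DTI parametrization.**  The single-tensor signal S = S₀ exp(−b gᵀDg) is
the same regression with design row x = −(b gx², b gy², b gz², 2b gx gy,
2b gy gz, 2b gx gz) and β the six tensor components.  Positive definiteness
is enforced by sampling the Log-Cholesky vector ω (D = ΩᵀΩ, upper-triangular
Ω with exponentiated diagonal) instead of β: the likelihood gradient routes
through the Jacobian ∂β/∂ω and the Hessian adds the curvature of the map
(six sparse second-derivative matrices).  Every draw maps to an SPD tensor,
hence FA ∈ [0, 1] and MD > 0 for every posterior sample.  Variable
selection is not applied to ω (zeros in ω are not interpretable tensor
zeros); on the variance side the six (standardized) diffusion columns form
Z by default and selection may be enabled there.  The chain starts at the
log-linear least-squares tensor projected onto the SPD cone.  Eigenvalues
are ordered descending and the principal eigenvector's sign is fixed by a
positive first nonzero component.  Gradient vectors are used exactly as
given (FSL image-coordinate bvecs); no reorientation is applied.  b-values
are s/mm², tensors mm²/s.

**Random-walk baselines.**  Two single-block random-walk Metropolis
samplers serve as efficiency baselines, proposing all parameters at once
from a normal centered at the current point: covariance s²I, or s²·(−H⁻¹)
with H the (block-diagonal) Hessian at the posterior mode.  log s follows a
Robbins–Monro recursion toward acceptance 0.234 during burn-in and is
frozen afterwards so the kept chain is Markovian.  A proposal identical to
the current point is counted as a rejection.

**Diagnostics.**  The inefficiency factor IF = 1 + 2Σ_k ρ_k is estimated by
FFT autocovariance with Geyer's initial-positive-sequence truncation
(consecutive autocorrelation pairs summed until a pair sum turns
non-positive); length/IF is the effective number of independent draws.
Chains shorter than 100 or constant chains are rejected.

## Synthetic data

The generator is the package's account of the study conditions.

* **Regression sets**: X and Z columns are independent standard normals,
  standardized exactly; y is drawn from the chosen magnitude law at the
  linked (μᵢ, φᵢ).  SNR is defined as mean(μ)/mean(sd(y)) with the exact
  magnitude sd; requesting an SNR solves for β₀ by root finding and errors
  (reporting the attainable range) if the target is out of reach.  The
  Gaussian family occasionally draws non-positive values; these are redrawn
  because magnitude data are intrinsically positive.
* **DTI voxels**: measurements follow S₀ exp(−b gᵀDg) with Rician/NC-χ/
  Gaussian noise, optionally heteroscedastic through a log-linear variance
  model over the standardized diffusion columns.  Multi-shell schemes place
  Fibonacci-lattice directions per shell (defaults: shells 1000/3000/5000/
  10000 s/mm², plus unweighted rows); these are approximately uniform and
  balanced but not electrostatically optimized.
* What is *not* emulated: spatial correlation between voxels, motion and
  eddy-current artifacts, coil-sensitivity profiles, realistic fMRI
  hemodynamics.  Passing tests therefore demonstrate correctness of the
  inference machinery under the stated generative model, not robustness to
  acquisition artifacts.

## Problem sizes and experiment design

Desk-scale experiment sizes were chosen so the full suite runs comfortably
on a laptop-class single core: regression recovery uses n = 500, p = q = 3
with 100 replications and 750-iteration chains (500 kept); voxel fits use
54–70 measurements and 800–2500 iterations; the model-comparison experiment
uses 5–6 replicate voxels per design.  The MCMC-vs-quadrature check uses a
deliberately small n = 40 two-parameter model where a 200×200 grid is
essentially exact.  Acceptance-rate and efficiency figures are reported for
a single representative synthetic voxel.

## Design choices on genuinely open points

* The per-update indicator subset size (min(4, p), each flipped w.p. ½) and
  the burn-in/chain lengths are not dictated by the model; all are exposed
  in `MCMCConfig`.
* The variance-side g-prior mirrors the mean-side Fisher construction.
* For DTI the variance design defaults to all six diffusion columns
  (selection can prune them); a subset can be configured.
* The RWM adaptation target (0.234) is the standard multivariate heuristic.
* Per-voxel seeds are derived by hashing (global seed, row-major voxel
  index), making serial and parallel volume fits bit-identical.

## Known limitations

* L is fixed, not estimated; complex-valued (phase-retaining) likelihoods
  are not implemented.
* The g-prior quadrature for D̂ assumes the prior-mode φ; strongly
  heteroscedastic priors would need a row-wise D̂.
* The Gaussian-model simulation redraws non-positive values, so at extreme
  noise its generative law is truncated; at the SNRs used in the
  experiments the truncation probability is negligible.
* FA is clipped to [0, 1] against floating-point overshoot in the
  eigenvalue arithmetic; MD is untouched.
* In single-voxel simulations the Gaussian model's FA deficit does not
  grow monotonically with the maximum b-value: shells that are fully
  below the noise floor shrink the Gaussian-fit tensor nearly
  isotropically, which dilutes (or can even reverse) the FA difference
  between the models even while the MD difference keeps growing.
  Map-level FA trends on real data additionally reflect spatially
  varying SNR, tensor shape and shell weighting, which the
  single-voxel generator does not emulate.
* Volume fitting is embarrassingly parallel per voxel but shares no
  information across voxels (no spatial priors).
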