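# ricianreg

Bayesian heteroscedastic Rician and non-central χ (NC-χ) regression with
variable selection, and a single-diffusion-tensor front-end for diffusion
MRI.

## The problem

MR magnitude data — diffusion-weighted imaging in particular — are the
modulus of a complex Gaussian signal and therefore follow a Rician
distribution (or, for root-sum-of-squares multi-coil data, a non-central χ
with 2L degrees of freedom).  The common Gaussian treatment is only accurate
at high SNR; at the low SNRs of high-b diffusion acquisitions it biases the
inferred signal and everything downstream of it.  `ricianreg` fits the
magnitude models exactly:

    yᵢ ~ NC-χ(μᵢ, φᵢ, L),    ln μᵢ = β₀ + xᵢᵀβ,    ln φᵢ = α₀ + zᵢᵀα,

with the Rician model as the L = 1 case and a Gaussian counterpart (same
links) for comparison.  Both the mean μ and the complex-noise variance φ are
regression functions, and Bernoulli indicators sampled jointly with the
coefficients perform Bayesian variable selection on either side.

Posterior simulation uses a two-block Metropolis-within-Gibbs sampler with
*tailored* proposals: each block proposes from a multivariate t₁₀ centered
at the end point of one or two damped Newton steps on the conditional
posterior, with the negative inverse Hessian as scale.  This yields
near-independent draws (inefficiency factors close to 1), one to two orders
of magnitude better than random-walk Metropolis — which matters when a
separate chain runs in every voxel.  Scaled-identity and Hessian-based RWM
baselines and the inefficiency-factor diagnostic IF = 1 + 2Σρₖ are included.

For DTI, the single-tensor model S = S₀·exp(−b gᵀDg) is fit per voxel in the
Log-Cholesky parametrization D = ΩᵀΩ, so every posterior draw is a symmetric
positive definite tensor and FA/MD come with full posterior uncertainty.
NIfTI volumes with FSL-style bvals/bvecs are fit voxel-wise into posterior
mean/sd maps.

## Worked example

Fitting one synthetic anisotropic voxel at SNR ≈ 20
(`python examples/02_dti_voxel.py`):

```
FA: posterior mean 0.782 +- 0.014   (truth 0.799)
MD: posterior mean 8.005e-04 +- 2.8e-05 mm^2/s   (truth 7.667e-04)
acceptance: mean-block 0.80, variance-block 0.70
```

The posterior mean FA/MD sit within about 1.5 posterior sds of the
generating tensor's values, and the tailored proposals are accepted
70–80% of the time.  `examples/01_rician_regression.py` shows coefficient
recovery and variable selection on generic regression data,
`examples/03_gaussian_vs_rician.py` reproduces the Gaussian model's
underestimation of MD at low SNR, and `examples/04_sampler_efficiency.py`
compares inefficiency factors against the RWM baselines.

A thin CLI wraps the same library calls:

```sh
ricianreg simulate --out voxel.csv --seed 1
ricianreg fit-voxel voxel.csv --out draws.csv --model rician --iters 2000
ricianreg diagnose draws.csv
ricianreg fit-volume dwi.nii.gz --bvals bvals --bvecs bvecs --out maps/
```

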