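"""Single-diffusion-tensor front-end.

The single-tensor signal model S_i = S0 exp(-b_i g_i' D g_i) is a magnitude
regression with log link: the design row for (b, g) is

    x' = -(b gx^2, b gy^2, b gz^2, 2 b gx gy, 2 b gy gz, 2 b gx gz)

and beta = (d_xx, d_yy, d_zz, d_xy, d_yz, d_xz), beta0 = ln S0.  Because D
must be positive definite, the sampler works in the unrestricted
Log-Cholesky parameter omega, with D = Omega' Omega and

    Omega = [[e^w1, w4,  w6 ],
             [0,    e^w2, w5],
             [0,    0,  e^w3]],

so every posterior draw maps to an SPD tensor by construction.  Scalar
summaries (mean diffusivity, fractional anisotropy) are functions of the
tensor eigenvalues and are computed per posterior draw.

Gradient-vector convention: vectors are used exactly as given (FSL
image-coordinate bvecs); no reorientation is applied.
b-values are in s/mm^2 and tensors in mm^2/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .noise_models import NoiseModel, logpdf
from .priors import PriorSpec, dti_prior
from .regression import CoefState, MagnitudeDataset
from .sampler import (
    CondTarget,
    MCMCConfig,
    PosteriorDraws,
    _block_update,
    _PriorCache,
    tailored_exchange,
)

__all__ = [
    "AcquisitionScheme",
    "TensorSummary",
    "dti_design",
    "omega_to_beta",
    "beta_jacobian",
    "beta_hessians",
    "omega_from_tensor",
    "tensor_from_beta",
    "tensor_summaries",
    "fit_voxel",
    "run_rwm_voxel",
]


@dataclass
class AcquisitionScheme:
    """Diffusion acquisition: b-values (s/mm^2) and unit gradient vectors."""

    b: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.g = np.atleast_2d(np.asarray(self.g, dtype=float))
        if self.g.shape != (len(self.b), 3):
            raise ValueError("gradients must be n x 3 matching the b vector")
        if np.any(self.b < 0):
            raise ValueError("b-values must be non-negative")

    @property
    def n(self) -> int:
        return len(self.b)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b == 0.0

    def weighted(self) -> "AcquisitionScheme":
        """The diffusion-weighted (b > 0) subset."""
        keep = ~self.b0_mask
        return AcquisitionScheme(self.b[keep], self.g[keep])


@dataclass
class TensorSummary:
    """Rotation-invariant tensor scalars plus the principal direction."""

    MD: float
    FA: float
    eigenvalues: np.ndarray
    principal_direction: np.ndarray


def dti_design(scheme: AcquisitionScheme, on_bad_gradient: str = "renormalize") -> np.ndarray:
    """n x 6 design matrix for the single-tensor model.

    Expects b = 0 rows to be removed beforehand (they calibrate the intercept
    priors instead).  Non-unit gradients on weighted rows are renormalized
    with a warning, or rejected with ``on_bad_gradient='error'``.
    """
    b, g = scheme.b.copy(), scheme.g.copy()
    weighted = b > 0
    norms = np.linalg.norm(g, axis=1)
    bad = weighted & (np.abs(norms - 1.0) > 1e-3)
    if np.any(bad):
        if on_bad_gradient == "error":
            raise ValueError(f"{int(bad.sum())} weighted gradient(s) are not unit norm")
        warnings.warn(f"renormalizing {int(bad.sum())} non-unit gradient vector(s)")
        g[bad] /= norms[bad, None]
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return -np.column_stack([
        b * gx * gx, b * gy * gy, b * gz * gz,
        2.0 * b * gx * gy, 2.0 * b * gy * gz, 2.0 * b * gx * gz,
    ])


# ---------------------------------------------------------------------------
# Log-Cholesky parametrization


def omega_to_beta(omega) -> np.ndarray:
    """Map the unrestricted 6-vector omega to tensor coefficients
    (d_xx, d_yy, d_zz, d_xy, d_yz, d_xz)."""
    w1, w2, w3, w4, w5, w6 = np.asarray(omega, dtype=float)
    return np.array([
        np.exp(2 * w1),
        w4 * w4 + np.exp(2 * w2),
        w6 * w6 + w5 * w5 + np.exp(2 * w3),
        w4 * np.exp(w1),
        w4 * w6 + w5 * np.exp(w2),
        w6 * np.exp(w1),
    ])


def beta_jacobian(omega) -> np.ndarray:
    """6 x 6 Jacobian d beta / d omega (rows index beta components)."""
    w1, w2, w3, w4, w5, w6 = np.asarray(omega, dtype=float)
    e1, e2, e3 = np.exp(w1), np.exp(w2), np.exp(w3)
    J = np.zeros((6, 6))
    J[0, 0] = 2.0 * e1 * e1
    J[1, 1] = 2.0 * e2 * e2
    J[1, 3] = 2.0 * w4
    J[2, 2] = 2.0 * e3 * e3
    J[2, 4] = 2.0 * w5
    J[2, 5] = 2.0 * w6
    J[3, 0] = w4 * e1
    J[3, 3] = e1
    J[4, 1] = w5 * e2
    J[4, 3] = w6
    J[4, 4] = e2
    J[4, 5] = w4
    J[5, 0] = w6 * e1
    J[5, 5] = e1
    return J


def beta_hessians(omega) -> np.ndarray:
    """Stack of six 6 x 6 Hessians d2 beta_k / d omega d omega'."""
    w1, w2, w3, w4, w5, w6 = np.asarray(omega, dtype=float)
    e1, e2, e3 = np.exp(w1), np.exp(w2), np.exp(w3)
    H = np.zeros((6, 6, 6))
    H[0, 0, 0] = 4.0 * e1 * e1
    H[1, 1, 1] = 4.0 * e2 * e2
    H[1, 3, 3] = 2.0
    H[2, 2, 2] = 4.0 * e3 * e3
    H[2, 4, 4] = 2.0
    H[2, 5, 5] = 2.0
    H[3, 0, 0] = w4 * e1
    H[3, 0, 3] = H[3, 3, 0] = e1
    H[4, 1, 1] = w5 * e2
    H[4, 1, 4] = H[4, 4, 1] = e2
    H[4, 3, 5] = H[4, 5, 3] = 1.0
    H[5, 0, 0] = w6 * e1
    H[5, 0, 5] = H[5, 5, 0] = e1
    return H


def tensor_from_beta(beta) -> np.ndarray:
    """Assemble the symmetric 3 x 3 tensor from (d_xx, d_yy, d_zz, d_xy, d_yz, d_xz)."""
    dxx, dyy, dzz, dxy, dyz, dxz = np.asarray(beta, dtype=float)
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def omega_from_tensor(D) -> np.ndarray:
    """Invert the Log-Cholesky map for an SPD tensor (positive-diagonal
    upper Cholesky factor, diagonal log-transformed)."""
    D = np.asarray(D, dtype=float)
    lam = np.linalg.eigvalsh(D)
    if lam[0] <= 0:
        raise ValueError("tensor must be symmetric positive definite")
    R = linalg.cholesky(D, lower=False)  # D = R' R, R upper with positive diagonal
    return np.array([np.log(R[0, 0]), np.log(R[1, 1]), np.log(R[2, 2]),
                     R[0, 1], R[1, 2], R[0, 2]])


def tensor_summaries(omega=None, beta=None, D=None) -> TensorSummary:
    """MD and FA from the tensor eigenvalues.

    MD = (l1 + l2 + l3)/3;  FA = sqrt( (3/2) sum (l_i - MD)^2 / sum l_i^2 ).
    Eigenvalues are ordered descending; the principal eigenvector's sign is
    fixed by a positive first nonzero component.
    """
    if D is None:
        if beta is None:
            if omega is None:
                raise ValueError("provide omega, beta, or D")
            beta = omega_to_beta(omega)
        D = tensor_from_beta(beta)
    lam, V = np.linalg.eigh(D)
    lam, V = lam[::-1], V[:, ::-1]
    md = float(lam.mean())
    denom = float(np.sum(lam * lam))
    fa = 0.0 if denom == 0 else float(np.sqrt(1.5 * np.sum((lam - md) ** 2) / denom))
    v1 = V[:, 0]
    nz = np.flatnonzero(np.abs(v1) > 1e-12)
    if nz.size and v1[nz[0]] < 0:
        v1 = -v1
    return TensorSummary(MD=md, FA=min(fa, 1.0), eigenvalues=lam, principal_direction=v1)


# ---------------------------------------------------------------------------
# Voxel fitting


def _omega_block_target(state, omega_ref, data, model, prior):
    """Conditional posterior of (beta0, omega) given the variance side.

    The likelihood depends on omega only through beta(omega); the chain rule
    routes the design-space gradient through the Jacobian d beta/d omega and
    the Hessian additionally picks up the curvature of the map.
    """
    eta_phi = state.alpha0 + data.Z @ state.alpha
    phi = np.exp(eta_phi)
    X, y = data.X, data.y
    m0, s2_0 = prior.m_beta0, prior.s2_beta0
    prior_prec = 1.0 / prior.c  # omega ~ N(0, c I)

    from .noise_models import side_terms

    def eval_all(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            return _eval_inner(theta)

    def _eval_inner(theta):
        beta0, omega = theta[0], theta[1:]
        eta = beta0 + X @ omega_to_beta(omega)
        if not np.all(np.isfinite(eta)):
            d = len(theta)
            return -np.inf, np.zeros(d), -np.eye(d)
        mu = np.exp(eta)
        if np.any(mu <= 0.0) or not np.all(np.isfinite(mu)):
            d = len(theta)
            return -np.inf, np.zeros(d), -np.eye(d)
        ll, d1, d2 = side_terms(y, mu, phi, model, "mu")
        u = d1 * mu                      # dl/d eta
        w = d2 * mu * mu + u             # d2l/d eta2
        J = beta_jacobian(omega)
        design = np.column_stack([np.ones(data.n), X @ J])
        g = design.T @ u
        H = design.T @ (design * w[:, None])
        # curvature of the omega -> beta map
        c_beta = X.T @ u
        H[1:, 1:] += np.einsum("k,kij->ij", c_beta, beta_hessians(omega))
        lp = -0.5 * ((beta0 - m0) ** 2 / s2_0 + np.log(2 * np.pi * s2_0))
        lp += -0.5 * (omega @ omega * prior_prec + 6 * np.log(2 * np.pi * prior.c))
        g[0] += -(beta0 - m0) / s2_0
        g[1:] += -omega * prior_prec
        H[0, 0] += -1.0 / s2_0
        H[1:, 1:] -= np.eye(6) * prior_prec
        return ll + lp, g, H

    return CondTarget(eval_all, 7)


def _init_omega(y, X, b0_mean):
    """Log-linear least squares start, projected to the SPD cone."""
    lr = np.log(np.maximum(y, 1e-12)) - np.log(b0_mean)
    beta_ls, *_ = np.linalg.lstsq(X, lr, rcond=None)
    D = tensor_from_beta(beta_ls)
    lam, V = np.linalg.eigh(D)
    lam = np.maximum(lam, max(1e-6 * float(np.max(np.abs(lam))), 1e-12))
    return omega_from_tensor((V * lam) @ V.T)


def _prepare_voxel(y, scheme: AcquisitionScheme, prior: PriorSpec | None,
                   heteroscedastic: bool):
    """Shared voxel preparation: b = 0 prior calibration and removal, design
    construction, variance-design standardization."""
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != scheme.n:
        raise ValueError("measurement count must match the acquisition scheme")
    b0_mask = scheme.b0_mask
    if prior is None:
        prior = dti_prior(y[b0_mask])
    yw = y[~b0_mask]
    ws = scheme.weighted()
    X = dti_design(ws)
    q = 6 if heteroscedastic else 0
    if len(yw) < 7 + q:
        raise ValueError(f"need at least {7 + q} diffusion-weighted measurements, got {len(yw)}")
    if heteroscedastic:
        Zs = X.std(axis=0, ddof=0)
        if np.any(Zs == 0):
            raise ValueError("degenerate variance design (constant diffusion column)")
        Z = (X - X.mean(axis=0)) / Zs
    else:
        Z = np.empty((len(yw), 0))
    data = MagnitudeDataset(y=yw, X=X, Z=Z, b=ws.b, gradients=ws.g)
    return data, prior, q


def fit_voxel(y, scheme: AcquisitionScheme, model: NoiseModel,
              cfg: MCMCConfig, prior: PriorSpec | None = None,
              heteroscedastic: bool = True) -> PosteriorDraws:
    """Bayesian single-tensor fit of one voxel.

    The b = 0 measurements calibrate the intercept priors and are then
    dropped; the mean-side block samples (ln S0, omega) jointly with the
    tailored t proposal, and the variance-side block samples (alpha0, alpha,
    I_alpha) with the six (standardized) diffusion design columns as the
    variance design.  ``heteroscedastic=False`` drops the variance
    covariates entirely.  Every stored draw is mapped to tensor coefficients,
    MD and FA, stored in ``draws.extras``.
    """
    data, prior, q = _prepare_voxel(y, scheme, prior, heteroscedastic)
    X, yw = data.X, data.y
    rng = np.random.default_rng(cfg.seed)
    omega = _init_omega(yw, X, float(np.exp(prior.m_beta0)))
    state = CoefState(beta0=prior.m_beta0, beta=omega_to_beta(omega),
                      alpha0=prior.m_alpha0, alpha=np.zeros(q))
    cache_a = _PriorCache(prior.Sigma_alpha[:q, :q] if q else np.empty((0, 0)), prior.c)

    keep = cfg.n_iter - cfg.n_burnin
    out = PosteriorDraws(
        beta0=np.empty(keep), beta=np.empty((keep, 6)),
        alpha0=np.empty(keep), alpha=np.empty((keep, q)),
        Ibeta=np.ones((keep, 6), dtype=int), Ialpha=np.empty((keep, q), dtype=int),
        accept_mean=np.zeros(cfg.n_iter), accept_var=np.zeros(cfg.n_iter),
        n_burnin=cfg.n_burnin, config=cfg,
    )
    out.extras["omega"] = np.empty((keep, 6))
    out.extras["MD"] = np.empty(keep)
    out.extras["FA"] = np.empty(keep)

    for it in range(cfg.n_iter):
        # mean-side joint (beta0, omega) update; no selection in omega space
        target = _omega_block_target(state, omega, data, model, prior)
        theta_c = np.concatenate([[state.beta0], omega])
        accepted, theta_p = tailored_exchange(
            theta_c, target, target, theta_c, lambda t: t, 0.0, cfg, rng)
        if accepted:
            state.beta0 = float(theta_p[0])
            omega = theta_p[1:].copy()
            state.beta = omega_to_beta(omega)
        out.accept_mean[it] = accepted
        out.accept_var[it] = _block_update("var", state, data, model, prior,
                                           cfg, rng, cache_a)
        if it >= cfg.n_burnin:
            k = it - cfg.n_burnin
            out.beta0[k] = state.beta0
            out.beta[k] = state.beta
            out.alpha0[k] = state.alpha0
            out.alpha[k] = state.alpha
            if q:
                out.Ialpha[k] = state.Ialpha
            out.extras["omega"][k] = omega
            s = tensor_summaries(beta=state.beta)
            out.extras["MD"][k] = s.MD
            out.extras["FA"][k] = s.FA
    return out


def run_rwm_voxel(y, scheme: AcquisitionScheme, model: NoiseModel,
                  cfg: MCMCConfig, prior: PriorSpec | None = None,
                  heteroscedastic: bool = True) -> PosteriorDraws:
    """Random-walk Metropolis baseline for the single-tensor model.

    Proposes all parameters (ln S0, omega, alpha0, alpha) in one block from
    a multivariate normal centered at the current point, with covariance a
    scaled identity (``cfg.sampler='rwm_identity'``) or the scaled negative
    inverse Hessian at the posterior mode (``'rwm_hessian'``); the scale
    adapts during burn-in only.  Same posterior as ``fit_voxel`` without
    variable selection; used for efficiency comparisons.
    """
    from .sampler import rwm_loop

    if cfg.sampler not in ("rwm_identity", "rwm_hessian"):
        raise ValueError("run_rwm_voxel requires an rwm_* sampler")
    data, prior, q = _prepare_voxel(y, scheme, prior, heteroscedastic)
    X, Z, yw = data.X, data.Z, data.y
    rng = np.random.default_rng(cfg.seed)
    omega0 = _init_omega(yw, X, float(np.exp(prior.m_beta0)))
    d = 8 + q
    theta0 = np.concatenate([[prior.m_beta0], omega0, [prior.m_alpha0], np.zeros(q)])
    prec_omega = 1.0 / prior.c

    def logpost(theta):
        beta0, omega, alpha0, alpha = theta[0], theta[1:7], theta[7], theta[8:]
        eta_mu = beta0 + X @ omega_to_beta(omega)
        eta_phi = alpha0 + (Z @ alpha if q else 0.0)
        if not (np.all(np.isfinite(eta_mu)) and np.all(np.isfinite(np.atleast_1d(eta_phi)))):
            return -np.inf
        mu = np.exp(eta_mu)
        phi = np.exp(eta_phi) if q else np.full_like(mu, np.exp(eta_phi))
        ll = float(np.sum(logpdf(yw, mu, phi, model)))
        lp = (-0.5 * (beta0 - prior.m_beta0) ** 2 / prior.s2_beta0
              - 0.5 * (alpha0 - prior.m_alpha0) ** 2 / prior.s2_alpha0
              - 0.5 * prec_omega * float(omega @ omega)
              - 0.5 * prec_omega * float(alpha @ alpha))
        return ll + lp

    if cfg.sampler == "rwm_hessian":
        # alternate blockwise Newton climbs to reach the joint mode, then use
        # the block-diagonal curvature as the proposal covariance
        from .sampler import _make_block_target, _neg_def_fix, newton_tailored_proposal

        state = CoefState(beta0=theta0[0], beta=omega_to_beta(omega0),
                          alpha0=theta0[7], alpha=np.zeros(q))
        omega = omega0.copy()
        for _ in range(8):
            tgt = _omega_block_target(state, omega, data, model, prior)
            m_mean, _ = newton_tailored_proposal(
                np.concatenate([[state.beta0], omega]), tgt, 2)
            state.beta0, omega = float(m_mean[0]), m_mean[1:]
            state.beta = omega_to_beta(omega)
            cache_a = _PriorCache(prior.Sigma_alpha[:q, :q] if q else np.empty((0, 0)),
                                  prior.c)
            tgt_a = _make_block_target("var", state, data, model, prior,
                                       np.ones(q, dtype=int), cache_a)
            m_var, _ = newton_tailored_proposal(
                np.concatenate([[state.alpha0], state.alpha]), tgt_a, 2)
            state.alpha0, state.alpha = float(m_var[0]), m_var[1:]
        tgt = _omega_block_target(state, omega, data, model, prior)
        _, _, H_mean = tgt.value_grad_hess(np.concatenate([[state.beta0], omega]))
        tgt_a = _make_block_target("var", state, data, model, prior,
                                   np.ones(q, dtype=int), cache_a)
        _, _, H_var = tgt_a.value_grad_hess(np.concatenate([[state.alpha0], state.alpha]))
        H = np.zeros((d, d))
        H[:7, :7] = H_mean
        H[7:, 7:] = H_var
        negH, _ = _neg_def_fix(-H)
        cov = linalg.cho_solve(linalg.cho_factor(negH, lower=True), np.eye(d))
        base_chol = linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(d), lower=True)
        theta0 = np.concatenate([[state.beta0], omega, [state.alpha0], state.alpha])
    else:
        base_chol = np.eye(d)

    thetas, accepts = rwm_loop(logpost, theta0, cfg, rng, base_chol)
    kept = thetas[cfg.n_burnin:]
    keep = len(kept)
    out = PosteriorDraws(
        beta0=kept[:, 0].copy(), beta=np.empty((keep, 6)),
        alpha0=kept[:, 7].copy(), alpha=kept[:, 8:].copy(),
        Ibeta=np.ones((keep, 6), dtype=int), Ialpha=np.ones((keep, q), dtype=int),
        accept_mean=accepts.copy(), accept_var=accepts.copy(),
        n_burnin=cfg.n_burnin, config=cfg,
    )
    out.extras["omega"] = kept[:, 1:7].copy()
    out.extras["MD"] = np.empty(keep)
    out.extras["FA"] = np.empty(keep)
    for k in range(keep):
        out.beta[k] = omega_to_beta(kept[k, 1:7])
        s = tensor_summaries(beta=out.beta[k])
        out.extras["MD"][k] = s.MD
        out.extras["FA"][k] = s.FA
    return out
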