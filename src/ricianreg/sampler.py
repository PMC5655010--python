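"""Metropolis-within-Gibbs with tailored t proposals, plus RWM baselines.

The posterior of the heteroscedastic magnitude regression is intractable, so
it is simulated by alternating two Metropolis–Hastings blocks, one for the
mean-side parameters (beta0, beta, I_beta) and one for the variance-side
parameters (alpha0, alpha, I_alpha).  Each block proposes coefficients from
a multivariate t distribution tailored to the full conditional: its mean is
the terminal point of a small, fixed number of damped Newton steps started
from the current value, and its scale matrix is the negative inverse Hessian
there.  Because the Newton map is deterministic in its starting point, the
reverse proposal density needed by the MH ratio is obtained by re-running
the same map from the proposed point.  Inclusion indicators are proposed
jointly with the coefficients by flipping a random subset (a symmetric move,
so its density cancels from the ratio).

Random-walk Metropolis baselines (scaled identity, and scaled negative
inverse Hessian at the posterior mode) and the inefficiency-factor
diagnostic are provided for efficiency comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import linalg, special

from .noise_models import NoiseModel
from .regression import CoefState, MagnitudeDataset, grad_hess_alpha, grad_hess_beta, loglik
from .priors import PriorSpec, conditional_selection_prior

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "EfficiencyReport",
    "newton_tailored_proposal",
    "tailored_exchange",
    "run_gibbs",
    "run_rwm",
    "rwm_loop",
    "inefficiency_factor",
    "efficiency_report",
]


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``newton_steps`` is the fixed number of damped Newton iterations used to
    tailor each proposal (one or two is typically enough because each climb
    starts from the current draw, already near the mode).  ``t_dof`` is the
    proposal's t degrees of freedom; ``proposal='normal'`` switches to a
    Gaussian proposal.  ``vs_mu``/``vs_phi`` enable variable selection per
    block; ``vs_subset_size`` indicators are proposed per update.
    """

    n_iter: int = 2000
    n_burnin: int = 500
    newton_steps: int = 2
    t_dof: float = 10.0
    proposal: str = "t"
    vs_mu: bool = False
    vs_phi: bool = False
    vs_subset_size: int = 4
    seed: int = 0
    sampler: str = "tailored"
    rwm_target_accept: float = 0.234

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.newton_steps < 1:
            raise ValueError("newton_steps must be >= 1")
        if self.proposal not in ("t", "normal"):
            raise ValueError("proposal must be 't' or 'normal'")
        if self.sampler not in ("tailored", "rwm_identity", "rwm_hessian"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class PosteriorDraws:
    """Post-burn-in draws plus per-iteration acceptance flags.

    ``extras`` holds derived per-draw quantities (for DTI: omega, FA, MD).
    Acceptance flags cover every iteration including burn-in; the
    ``acceptance_rate_*`` properties report the post-burn-in rates.
    """

    beta0: np.ndarray
    beta: np.ndarray
    alpha0: np.ndarray
    alpha: np.ndarray
    Ibeta: np.ndarray
    Ialpha: np.ndarray
    accept_mean: np.ndarray
    accept_var: np.ndarray
    n_burnin: int
    config: MCMCConfig | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.beta0)

    @property
    def acceptance_rate_mean(self) -> float:
        return float(np.mean(self.accept_mean[self.n_burnin:]))

    @property
    def acceptance_rate_var(self) -> float:
        return float(np.mean(self.accept_var[self.n_burnin:]))

    def inclusion_probability_beta(self) -> np.ndarray:
        return self.Ibeta.mean(axis=0)

    def inclusion_probability_alpha(self) -> np.ndarray:
        return self.Ialpha.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = {"beta0": self.beta0, "alpha0": self.alpha0}
        for j in range(self.beta.shape[1]):
            cols[f"beta{j + 1}"] = self.beta[:, j]
            cols[f"Ibeta{j + 1}"] = self.Ibeta[:, j]
        for j in range(self.alpha.shape[1]):
            cols[f"alpha{j + 1}"] = self.alpha[:, j]
            cols[f"Ialpha{j + 1}"] = self.Ialpha[:, j]
        for name, arr in self.extras.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                cols[name] = arr
            else:
                for j in range(arr.shape[1]):
                    cols[f"{name}{j + 1}"] = arr[:, j]
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        """Write draws as CSV with a JSON metadata sidecar."""
        path = str(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "n_burnin": self.n_burnin,
            "acceptance_rate_mean": self.acceptance_rate_mean,
            "acceptance_rate_var": self.acceptance_rate_var,
            "config": asdict(self.config) if self.config else None,
        }
        with open(path + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


@dataclass
class EfficiencyReport:
    """Per-parameter inefficiency factors and acceptance rates for a run."""

    names: list[str]
    inefficiency: np.ndarray
    acceptance_mean: float
    acceptance_var: float
    n_draws: int

    @property
    def independent_draws(self) -> np.ndarray:
        return self.n_draws / self.inefficiency


# ---------------------------------------------------------------------------
# Conditional targets


class CondTarget:
    """Log conditional posterior of one coefficient block.

    Wraps a single fused evaluator returning (value, gradient, Hessian);
    evaluations are memoized per point because the Newton climbs and the MH
    ratio revisit the same points.
    """

    def __init__(self, eval_fn, dim):
        self._eval = eval_fn
        self.dim = dim
        self._memo: dict[bytes, tuple] = {}

    def value_grad_hess(self, theta):
        theta = np.asarray(theta, dtype=float)
        key = theta.tobytes()
        hit = self._memo.get(key)
        if hit is None:
            hit = self._eval(theta)
            self._memo[key] = hit
        return hit

    def value(self, theta):
        return self.value_grad_hess(theta)[0]

    def grad_hess(self, theta):
        _, g, H = self.value_grad_hess(theta)
        return g, H


def _gaussian_prior_terms(theta, m0, s2_0, prec_sel, logdet_sel):
    """Log N(m0, s2_0) on theta[0] plus log N(0, C) on theta[1:].

    ``prec_sel``/``logdet_sel`` are the precision matrix and log determinant
    of the coefficient prior covariance C (None/0 when no coefficient is
    selected).  Returns (logpdf, grad, hess) with the Hessian as the full
    negative-precision matrix to add to the likelihood Hessian.
    """
    d = len(theta) - 1
    dev0 = theta[0] - m0
    lp = -0.5 * (np.log(2.0 * np.pi * s2_0) + dev0 * dev0 / s2_0)
    grad = np.zeros_like(theta)
    grad[0] = -dev0 / s2_0
    hess = np.zeros((len(theta), len(theta)))
    hess[0, 0] = -1.0 / s2_0
    if d:
        b = theta[1:]
        z = prec_sel @ b
        lp += -0.5 * (d * np.log(2.0 * np.pi) + logdet_sel + b @ z)
        grad[1:] = -z
        hess[1:, 1:] = -prec_sel
    return lp, grad, hess


class _PriorCache:
    """Precision and log determinant of c * conditional selection
    covariance, per indicator pattern."""

    def __init__(self, Sigma, c):
        self.Sigma = np.atleast_2d(Sigma)
        self.c = c
        self._cache = {}

    def get(self, I):
        key = tuple(int(v) for v in I)
        if key not in self._cache:
            C = conditional_selection_prior(self.Sigma, np.array(key), self.c)
            if C.size:
                chol = linalg.cholesky(C, lower=True)
                prec = linalg.cho_solve((chol, True), np.eye(C.shape[0]))
                logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
            else:
                prec, logdet = None, 0.0
            self._cache[key] = (prec, logdet)
        return self._cache[key]


def _make_block_target(block, state, data, model, prior, I, prior_cache):
    """Conditional posterior target for (intercept, selected coefficients) of
    one block, the other block's parameters held fixed."""
    sel = np.asarray(I).astype(bool)
    prec_sel, logdet_sel = prior_cache.get(sel)
    if block == "mean":
        design = np.column_stack([np.ones(data.n), data.X[:, sel]])
        eta_other = state.alpha0 + data.Z @ state.alpha
        m0, s2_0 = prior.m_beta0, prior.s2_beta0
    else:
        design = np.column_stack([np.ones(data.n), data.Z[:, sel]])
        eta_other = state.beta0 + data.X @ state.beta
        m0, s2_0 = prior.m_alpha0, prior.s2_alpha0
    other = np.exp(eta_other)
    y = data.y

    from .noise_models import side_terms  # fused hot-path evaluator

    side = "mu" if block == "mean" else "phi"

    def eval_all(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            lin = design @ theta
            par = np.exp(lin)
            # exp under/overflow produces par = 0 or inf; either leaves the
            # density undefined, so report an impossible point
            if not np.all(np.isfinite(par)) or np.any(par <= 0.0):
                d = len(theta)
                return -np.inf, np.zeros(d), -np.eye(d)
            mu, phi = (par, other) if block == "mean" else (other, par)
            ll, d1, d2 = side_terms(y, mu, phi, model, side)
            u = d1 * par
            w = d2 * par * par + u
            g = design.T @ u
            H = design.T @ (design * w[:, None])
            lp, pg, pH = _gaussian_prior_terms(theta, m0, s2_0, prec_sel, logdet_sel)
            return ll + lp, g + pg, H + pH

    return CondTarget(eval_all, int(sel.sum()) + 1)


# ---------------------------------------------------------------------------
# Tailored proposal machinery


def _neg_def_fix(negH):
    """Return a symmetric positive definite version of -H (and whether a fix
    was needed).  Where the conditional posterior is locally non-concave the
    negative curvature directions are reflected (|lambda|, the saddle-free
    Newton modification), which keeps step lengths sensible instead of
    exploding along flat directions; eigenvalues are floored at a tiny
    fraction of the largest magnitude."""
    negH = 0.5 * (negH + negH.T)
    try:
        linalg.cholesky(negH, lower=True, check_finite=False)
        return negH, False
    except linalg.LinAlgError:
        lam, V = linalg.eigh(negH)
        lam = np.abs(lam)
        lam = np.maximum(lam, max(1e-10, 1e-8 * float(lam.max())))
        return (V * lam) @ V.T, True


def newton_tailored_proposal(theta0, target: CondTarget, newton_steps: int = 2):
    """Deterministic Newton map: climb ``newton_steps`` damped steps toward
    the conditional mode, return (proposal mean, proposal covariance).

    Steps that would decrease the conditional log posterior are halved up to
    ten times and abandoned if still downhill, so the map is deterministic
    in its starting point — a requirement for evaluating the reverse
    proposal density in the MH ratio.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    val, g, H = target.value_grad_hess(theta)
    for _ in range(newton_steps):
        negH, _fixed = _neg_def_fix(-H)
        step = linalg.solve(negH, g, assume_a="pos", check_finite=False)
        scale = 1.0
        for _ in range(10):
            trial = theta + scale * step
            tval, tg, tH = target.value_grad_hess(trial)
            if np.isfinite(tval) and tval >= val:
                theta, val, g, H = trial, tval, tg, tH
                break
            scale *= 0.5
        # if every damped trial went downhill we stay put for this step
    negH, _fixed = _neg_def_fix(-H)
    cov = linalg.cho_solve(linalg.cho_factor(negH, lower=True, check_finite=False),
                           np.eye(len(theta)), check_finite=False)
    return theta, 0.5 * (cov + cov.T)


def _prop_draw(mean, cov, dof, rng, kind):
    L = linalg.cholesky(cov + 1e-12 * np.eye(len(mean)), lower=True, check_finite=False)
    z = rng.standard_normal(len(mean))
    if kind == "normal":
        return mean + L @ z
    w = rng.chisquare(dof) / dof
    return mean + (L @ z) / np.sqrt(w)


def _prop_logpdf(x, mean, cov, dof, kind):
    d = len(mean)
    L = linalg.cholesky(cov + 1e-12 * np.eye(d), lower=True, check_finite=False)
    dev = linalg.solve_triangular(L, x - mean, lower=True, check_finite=False)
    q = float(dev @ dev)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if kind == "normal":
        return -0.5 * (d * np.log(2.0 * np.pi) + logdet + q)
    return float(
        special.gammaln((dof + d) / 2.0) - special.gammaln(dof / 2.0)
        - 0.5 * d * np.log(dof * np.pi) - 0.5 * logdet
        - 0.5 * (dof + d) * np.log1p(q / dof)
    )


def tailored_exchange(theta_c, target_c, target_p, start_p, reverse_start_fn,
                      delta_log_prior_I, cfg: MCMCConfig, rng):
    """One tailored MH exchange, possibly across indicator patterns.

    ``target_c``/``target_p`` are the conditional posteriors under the
    current and proposed selections; ``start_p`` is the Newton starting point
    in the proposed frame; ``reverse_start_fn`` maps the proposed draw back
    into the current frame for the reverse Newton climb.  Returns
    (accepted, theta_p).  Numerical failures count as rejections.
    """
    try:
        m_p, S_p = newton_tailored_proposal(start_p, target_p, cfg.newton_steps)
        theta_p = _prop_draw(m_p, S_p, cfg.t_dof, rng, cfg.proposal)
        l_fwd = _prop_logpdf(theta_p, m_p, S_p, cfg.t_dof, cfg.proposal)
        m_r, S_r = newton_tailored_proposal(reverse_start_fn(theta_p), target_c,
                                            cfg.newton_steps)
        l_rev = _prop_logpdf(np.asarray(theta_c, dtype=float), m_r, S_r,
                             cfg.t_dof, cfg.proposal)
        logr = (target_p.value(theta_p) - target_c.value(theta_c)
                + delta_log_prior_I + l_rev - l_fwd)
    except (linalg.LinAlgError, FloatingPointError, ValueError) as exc:
        logger.debug("proposal construction failed, counting as rejection: %s", exc)
        return False, np.asarray(theta_c, dtype=float)
    if not np.isfinite(logr):
        return False, np.asarray(theta_c, dtype=float)
    return bool(np.log(rng.uniform()) < logr), theta_p


def _bernoulli_logprior(I, pi):
    I = np.asarray(I, dtype=float)
    return float(np.sum(I * np.log(pi) + (1.0 - I) * np.log1p(-pi)))


def _propose_indicators(I, subset_size, rng):
    I = np.asarray(I, dtype=int)
    p = len(I)
    k = min(subset_size, p)
    idx = rng.choice(p, size=k, replace=False)
    out = I.copy()
    flips = rng.uniform(size=k) < 0.5
    out[idx[flips]] = 1 - out[idx[flips]]
    return out


def _block_update(block, state, data, model, prior, cfg, rng, prior_cache):
    """Joint (coefficients, indicators) MH update for one block."""
    vs = cfg.vs_mu if block == "mean" else cfg.vs_phi
    if block == "mean":
        I_c, coef_c, icpt_c = state.Ibeta, state.beta, state.beta0
        pi = prior.pi_beta
    else:
        I_c, coef_c, icpt_c = state.Ialpha, state.alpha, state.alpha0
        pi = prior.pi_alpha
    p = len(I_c)
    I_p = _propose_indicators(I_c, cfg.vs_subset_size, rng) if (vs and p) else I_c.copy()

    sel_c = I_c.astype(bool)
    sel_p = I_p.astype(bool)
    theta_c = np.concatenate([[icpt_c], coef_c[sel_c]])
    start_p = np.concatenate([[icpt_c], np.where(sel_c, coef_c, 0.0)[sel_p]])

    target_c = _make_block_target(block, state, data, model, prior, I_c, prior_cache)
    target_p = (target_c if np.array_equal(I_p, I_c)
                else _make_block_target(block, state, data, model, prior, I_p, prior_cache))

    def reverse_start(theta_p):
        coef_p = np.zeros(p)
        coef_p[sel_p] = theta_p[1:]
        return np.concatenate([[theta_p[0]], coef_p[sel_c]])

    dlpI = _bernoulli_logprior(I_p, pi) - _bernoulli_logprior(I_c, pi)
    accepted, theta_p = tailored_exchange(theta_c, target_c, target_p, start_p,
                                          reverse_start, dlpI, cfg, rng)
    if accepted:
        coef_new = np.zeros(p)
        coef_new[sel_p] = theta_p[1:]
        if block == "mean":
            state.beta0, state.beta, state.Ibeta = float(theta_p[0]), coef_new, I_p
        else:
            state.alpha0, state.alpha, state.Ialpha = float(theta_p[0]), coef_new, I_p
    return accepted


def _initial_state(data: MagnitudeDataset, model: NoiseModel, prior: PriorSpec) -> CoefState:
    # moment-based start: E[y^2] = mu^2 + 2 L phi under the magnitude models
    ybar2 = float(np.mean(data.y**2))
    v = float(np.var(data.y)) if data.n > 1 else 0.1
    L = model.effective_L
    phi0 = max(min(v / (2.0 * L), ybar2 / (2.0 * L + 1.0)), 1e-8)
    mu0 = np.sqrt(max(ybar2 - 2.0 * L * phi0, 1e-8))
    return CoefState(
        beta0=float(np.log(mu0)), beta=np.zeros(data.p),
        alpha0=float(np.log(phi0)), alpha=np.zeros(data.q),
    )


def run_gibbs(data: MagnitudeDataset, model: NoiseModel, prior: PriorSpec,
              cfg: MCMCConfig, init: CoefState | None = None) -> PosteriorDraws:
    """Run the two-block Metropolis-within-Gibbs sampler.

    Alternates the mean-side and variance-side joint updates; draws after
    burn-in are stored.  Fully reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    state = init.copy() if init is not None else _initial_state(data, model, prior)
    cache_b = _PriorCache(prior.Sigma_beta, prior.c)
    cache_a = _PriorCache(prior.Sigma_alpha, prior.c)
    keep = cfg.n_iter - cfg.n_burnin
    out = PosteriorDraws(
        beta0=np.empty(keep), beta=np.empty((keep, data.p)),
        alpha0=np.empty(keep), alpha=np.empty((keep, data.q)),
        Ibeta=np.empty((keep, data.p), dtype=int),
        Ialpha=np.empty((keep, data.q), dtype=int),
        accept_mean=np.zeros(cfg.n_iter), accept_var=np.zeros(cfg.n_iter),
        n_burnin=cfg.n_burnin, config=cfg,
    )
    for it in range(cfg.n_iter):
        out.accept_mean[it] = _block_update("mean", state, data, model, prior,
                                            cfg, rng, cache_b)
        out.accept_var[it] = _block_update("var", state, data, model, prior,
                                           cfg, rng, cache_a)
        if it >= cfg.n_burnin:
            k = it - cfg.n_burnin
            out.beta0[k] = state.beta0
            out.beta[k] = state.beta
            out.alpha0[k] = state.alpha0
            out.alpha[k] = state.alpha
            out.Ibeta[k] = state.Ibeta
            out.Ialpha[k] = state.Ialpha
        if (it + 1) % 1000 == 0:
            logger.info("iter %d/%d acc(mean)=%.2f acc(var)=%.2f", it + 1, cfg.n_iter,
                        out.accept_mean[: it + 1].mean(), out.accept_var[: it + 1].mean())
    return out


# ---------------------------------------------------------------------------
# Random-walk Metropolis baselines


def _joint_logpost(theta, data, model, prior, cache_b, cache_a):
    p, q = data.p, data.q
    state = CoefState(theta[0], theta[1:1 + p], theta[1 + p], theta[2 + p:])
    ll = loglik(state, data, model)
    prec_b, logdet_b = cache_b.get(np.ones(p, dtype=int))
    prec_a, logdet_a = cache_a.get(np.ones(q, dtype=int))
    lp_b, _, _ = _gaussian_prior_terms(np.concatenate([[theta[0]], theta[1:1 + p]]),
                                       prior.m_beta0, prior.s2_beta0, prec_b, logdet_b)
    lp_a, _, _ = _gaussian_prior_terms(np.concatenate([[theta[1 + p]], theta[2 + p:]]),
                                       prior.m_alpha0, prior.s2_alpha0, prec_a, logdet_a)
    return ll + lp_b + lp_a


def _joint_grad_hess(theta, data, model, prior, cache_b, cache_a):
    p, q = data.p, data.q
    state = CoefState(theta[0], theta[1:1 + p], theta[1 + p], theta[2 + p:])
    gb, Hb = grad_hess_beta(state, data, model, selected=np.ones(p, dtype=bool))
    ga, Ha = grad_hess_alpha(state, data, model, selected=np.ones(q, dtype=bool))
    prec_b, logdet_b = cache_b.get(np.ones(p, dtype=int))
    prec_a, logdet_a = cache_a.get(np.ones(q, dtype=int))
    _, pgb, pHb = _gaussian_prior_terms(np.concatenate([[theta[0]], theta[1:1 + p]]),
                                        prior.m_beta0, prior.s2_beta0, prec_b, logdet_b)
    _, pga, pHa = _gaussian_prior_terms(np.concatenate([[theta[1 + p]], theta[2 + p:]]),
                                        prior.m_alpha0, prior.s2_alpha0, prec_a, logdet_a)
    g = np.concatenate([gb + pgb, ga + pga])
    H = np.zeros((1 + p + 1 + q, 1 + p + 1 + q))
    H[: 1 + p, : 1 + p] = Hb + pHb
    H[1 + p:, 1 + p:] = Ha + pHa
    return g, H


def run_rwm(data: MagnitudeDataset, model: NoiseModel, prior: PriorSpec,
            cfg: MCMCConfig, init: CoefState | None = None) -> PosteriorDraws:
    """Single-block random-walk Metropolis over all (beta, alpha) parameters.

    ``cfg.sampler`` selects the proposal covariance: ``rwm_identity`` uses a
    scaled identity, ``rwm_hessian`` uses the scaled negative inverse Hessian
    at the (Newton-found) posterior mode.  The scalar step size adapts toward
    ``cfg.rwm_target_accept`` during burn-in only, then is frozen so the kept
    chain is Markovian.  Variable selection is not applied (all indicators 1).
    """
    if cfg.sampler not in ("rwm_identity", "rwm_hessian"):
        raise ValueError("run_rwm requires sampler='rwm_identity' or 'rwm_hessian'")
    rng = np.random.default_rng(cfg.seed)
    state = init.copy() if init is not None else _initial_state(data, model, prior)
    cache_b = _PriorCache(prior.Sigma_beta, prior.c)
    cache_a = _PriorCache(prior.Sigma_alpha, prior.c)
    p, q = data.p, data.q
    d = 2 + p + q
    theta = np.concatenate([[state.beta0], state.beta, [state.alpha0], state.alpha])

    if cfg.sampler == "rwm_hessian":
        # Newton climb to the mode for the proposal covariance
        for _ in range(25):
            g, H = _joint_grad_hess(theta, data, model, prior, cache_b, cache_a)
            negH, _ = _neg_def_fix(-H)
            step = linalg.solve(negH, g, assume_a="pos")
            new = theta + step
            if _joint_logpost(new, data, model, prior, cache_b, cache_a) < \
               _joint_logpost(theta, data, model, prior, cache_b, cache_a):
                step *= 0.5
                new = theta + step
            theta = new
            if np.linalg.norm(step) < 1e-8:
                break
        _, H = _joint_grad_hess(theta, data, model, prior, cache_b, cache_a)
        negH, _ = _neg_def_fix(-H)
        base_chol = linalg.cholesky(
            linalg.cho_solve(linalg.cho_factor(negH, lower=True), np.eye(d)), lower=True)
    else:
        base_chol = np.eye(d)

    def logpost(th):
        try:
            return _joint_logpost(th, data, model, prior, cache_b, cache_a)
        except FloatingPointError:
            return -np.inf

    thetas, accepts = rwm_loop(logpost, theta, cfg, rng, base_chol)
    keep = cfg.n_iter - cfg.n_burnin
    kept = thetas[cfg.n_burnin:]
    return PosteriorDraws(
        beta0=kept[:, 0].copy(), beta=kept[:, 1:1 + p].copy(),
        alpha0=kept[:, 1 + p].copy(), alpha=kept[:, 2 + p:].copy(),
        Ibeta=np.ones((keep, p), dtype=int), Ialpha=np.ones((keep, q), dtype=int),
        accept_mean=accepts.copy(), accept_var=accepts.copy(),
        n_burnin=cfg.n_burnin, config=cfg,
    )


def rwm_loop(logpost, theta0, cfg: MCMCConfig, rng, base_chol):
    """Adaptive-scale random-walk Metropolis core.

    The log step size follows a Robbins–Monro recursion toward
    ``cfg.rwm_target_accept`` during burn-in and is frozen afterwards.  A
    proposal identical to the current point (degenerate zero-variance
    proposal) is counted as a rejection.  Returns (theta trace, accept
    flags), both over all iterations.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    d = len(theta)
    log_s = np.log(2.38 / np.sqrt(d))
    lp = logpost(theta)
    thetas = np.empty((cfg.n_iter, d))
    accepts = np.zeros(cfg.n_iter)
    for it in range(cfg.n_iter):
        with np.errstate(over="ignore", invalid="ignore"):
            prop = theta + np.exp(log_s) * (base_chol @ rng.standard_normal(d))
            lp_prop = logpost(prop) if not np.array_equal(prop, theta) else -np.inf
        accept = np.isfinite(lp_prop) and np.log(rng.uniform()) < lp_prop - lp
        if accept:
            theta, lp = prop, lp_prop
        if it < cfg.n_burnin:
            log_s += (float(accept) - cfg.rwm_target_accept) / max((it + 1) ** 0.6, 1.0)
        accepts[it] = float(accept)
        thetas[it] = theta
    return thetas, accepts


# ---------------------------------------------------------------------------
# Diagnostics


def inefficiency_factor(chain: np.ndarray) -> float:
    """IF = 1 + 2 sum_k rho_k, truncated by Geyer's initial positive
    sequence rule (sum consecutive autocorrelation pairs until a pair sum
    goes non-positive).  The number of effectively independent draws is the
    chain length divided by this factor."""
    x = np.asarray(chain, dtype=float).ravel()
    n = len(x)
    if n < 100:
        raise ValueError("chain too short for an autocorrelation estimate (need >= 100)")
    x = x - x.mean()
    var = float(x @ x) / n
    if var <= 0:
        raise ValueError("constant chain has no defined inefficiency factor")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    total = -1.0  # = 1 + 2*sum_{k>=1} rho_k with rho_0 folded into pair sums
    for m in range(n // 2):
        pair = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if pair <= 0.0:
            break
        total += 2.0 * pair
    return float(max(total, 1.0))


def efficiency_report(draws: PosteriorDraws, names: list[str] | None = None) -> EfficiencyReport:
    """Inefficiency factors for every sampled coefficient in a run."""
    frame = {"beta0": draws.beta0, "alpha0": draws.alpha0}
    for j in range(draws.beta.shape[1]):
        frame[f"beta{j + 1}"] = draws.beta[:, j]
    for j in range(draws.alpha.shape[1]):
        frame[f"alpha{j + 1}"] = draws.alpha[:, j]
    for name, arr in draws.extras.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            for j in range(arr.shape[1]):
                frame[f"{name}{j + 1}"] = arr[:, j]
    if names is not None:
        frame = {k: frame[k] for k in names}
    ifs = []
    used = []
    for k, v in frame.items():
        if np.std(v) == 0:
            continue  # pinned by selection; no IF defined
        used.append(k)
        ifs.append(inefficiency_factor(v))
    return EfficiencyReport(
        names=used, inefficiency=np.array(ifs),
        acceptance_mean=draws.acceptance_rate_mean,
        acceptance_var=draws.acceptance_rate_var,
        n_draws=draws.n_draws,
    )
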