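"""Prior construction: intercept back-out, Fisher-information g-prior with
variable selection, and the DTI stability prior.

Two prior families are supported.  The generic regression prior puts a
log-normal-implied normal on each intercept and a g-prior N(0, c Sigma) on
the standardized-design coefficients, where Sigma is the inverse Fisher
information at the prior mode; c = n gives a unit-information prior.  The
DTI prior instead centers the intercepts on log mean / log variance of the
b = 0 measurements and uses wide isotropic normals on the tensor and
variance coefficients, which is numerically more stable for tensor fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .noise_models import NoiseModel, dlogpdf, logpdf

__all__ = [
    "PriorSpec",
    "intercept_prior_from_mu",
    "fisher_dhat",
    "g_prior_covariance",
    "conditional_selection_prior",
    "dti_prior",
]


@dataclass
class PriorSpec:
    """Gaussian priors for intercepts and coefficients plus Bernoulli
    inclusion probabilities.

    ``Sigma_beta``/``Sigma_alpha`` are the *unscaled* coefficient
    covariances; the prior covariance actually used is ``c * Sigma``.
    """

    m_beta0: float
    s2_beta0: float
    m_alpha0: float
    s2_alpha0: float
    Sigma_beta: np.ndarray
    Sigma_alpha: np.ndarray
    c: float
    pi_beta: float = 0.5
    pi_alpha: float = 0.5
    style: str = "g_prior"
    b0_rows: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.Sigma_beta = np.atleast_2d(np.asarray(self.Sigma_beta, dtype=float))
        self.Sigma_alpha = np.atleast_2d(np.asarray(self.Sigma_alpha, dtype=float))
        for name, S in (("Sigma_beta", self.Sigma_beta), ("Sigma_alpha", self.Sigma_alpha)):
            if S.size and not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
        if not (self.s2_beta0 > 0 and self.s2_alpha0 > 0):
            raise ValueError("intercept prior variances must be positive")
        for pi in (self.pi_beta, self.pi_alpha):
            if not (0.0 < pi < 1.0):
                raise ValueError("inclusion probabilities must lie in (0, 1)")
        if self.style not in ("g_prior", "dti_isotropic"):
            raise ValueError(f"unknown prior style {self.style!r}")


def intercept_prior_from_mu(m_star: float, s_star: float):
    """Back out the N(m, s^2) prior on an intercept from a log-normal prior
    on the linked parameter with mean ``m_star`` and sd ``s_star``.

    s^2 = log[(s*/m*)^2 + 1],  m = log(m*) - s^2 / 2.
    """
    if not (m_star > 0 and s_star > 0):
        raise ValueError("m_star and s_star must be positive")
    s2 = np.log((s_star / m_star) ** 2 + 1.0)
    m = np.log(m_star) - s2 / 2.0
    return float(m), float(s2)


def fisher_dhat(m: float, model: NoiseModel, phi: float = 1.0, side: str = "mu") -> float:
    """Per-observation Fisher information for the linear predictor at the
    prior mode (all coefficients zero, intercept at ``m``).

    For the log link g(t) = log t the information for the predictor is
    ``-E[d2 logp / dt2] * t^2`` with ``t = exp(m)``.  No closed form exists
    for the Rician / NC-chi families, so the expectation is computed by
    adaptive quadrature over y.
    """
    val = float(np.exp(m))
    if side == "mu":
        mu, ph = val, float(phi)
        key = "dmu2"
    elif side == "phi":
        mu, ph = float(phi), val
        key = "dphi2"
    else:
        raise ValueError("side must be 'mu' or 'phi'")
    if model.family == "gaussian":
        info = 1.0 / ph if side == "mu" else 0.5 / val**2
        return info * val * val

    def integrand(y):
        return -dlogpdf(y, mu, ph, model)[key] * np.exp(logpdf(y, mu, ph, model))

    sd = np.sqrt(mu * mu + 2.0 * model.effective_L * ph)
    upper = mu + 12.0 * sd
    info, _ = integrate.quad(integrand, 1e-12, upper, limit=200)
    return float(info) * val * val


def g_prior_covariance(X: np.ndarray, m: float, model: NoiseModel, c: float,
                       phi: float = 1.0, side: str = "mu") -> np.ndarray:
    """Unscaled-then-scaled g-prior covariance c (X' Dhat X)^{-1}.

    ``Dhat`` is diagonal with the per-observation Fisher information for the
    linear predictor at the prior mode; since all rows share the mode the
    matrix is ``dhat * X'X``.  ``X`` must be standardized and full rank.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == 0:
        return np.empty((0, 0))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    dhat = fisher_dhat(m, model, phi=phi, side=side)
    return c * np.linalg.inv(dhat * (X.T @ X))


def conditional_selection_prior(Sigma: np.ndarray, I: np.ndarray, c: float) -> np.ndarray:
    """Covariance of the selected coefficients conditional on the excluded
    ones being zero: c * (Sigma_II - Sigma_IIc Sigma_IcIc^{-1} Sigma_IcI)."""
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    I = np.asarray(I).astype(bool).ravel()
    if I.size != Sigma.shape[0]:
        raise ValueError("indicator length must match Sigma dimension")
    if not I.any():
        return np.empty((0, 0))
    if I.all():
        return c * Sigma
    S11 = Sigma[np.ix_(I, I)]
    S12 = Sigma[np.ix_(I, ~I)]
    S22 = Sigma[np.ix_(~I, ~I)]
    cond = S11 - S12 @ np.linalg.solve(S22, S12.T)
    return c * cond


def dti_prior(y_b0: np.ndarray, p: int = 6, q: int = 6, d: float = 0.01,
              c: float = 100.0, pi_alpha: float = 0.5) -> PriorSpec:
    """Stability prior for single-tensor DTI fitting.

    The intercept prior means are the log of the mean and of the variance of
    the measurements acquired without diffusion weighting (b = 0); those rows
    are then dropped from estimation.  Intercepts get prior variance ``d``
    (default 0.01) and the tensor parameters omega and variance coefficients
    alpha get wide isotropic N(0, c I) priors with ``c`` = 100 by default.
    """
    y_b0 = np.asarray(y_b0, dtype=float).ravel()
    if len(y_b0) < 2:
        raise ValueError("need at least two b = 0 measurements")
    var = float(np.var(y_b0, ddof=1))
    if var <= 0.0:
        raise ValueError("b = 0 measurements are all equal; variance prior mean undefined")
    m_beta = float(np.log(np.mean(y_b0)))
    m_alpha = float(np.log(var))
    return PriorSpec(
        m_beta0=m_beta, s2_beta0=d,
        m_alpha0=m_alpha, s2_alpha0=d,
        Sigma_beta=np.eye(p), Sigma_alpha=np.eye(q),
        c=c, pi_alpha=pi_alpha, style="dti_isotropic",
    )
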