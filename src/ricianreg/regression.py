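"""Heteroscedastic magnitude regression: links, likelihood, derivatives.

The model links both parameters of the observation law to covariates through
log links,

    y_i ~ NC-chi(mu_i, phi_i, L),   ln mu_i = beta0 + x_i' beta,
                                    ln phi_i = alpha0 + z_i' alpha,

with observations conditionally independent given the covariates.  The same
structure with a Gaussian law gives the comparison model.  Gradients and
Hessians with respect to the regression coefficients follow from the chain
rule through the log links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noise_models import NoiseModel, dlogpdf, logpdf

__all__ = ["MagnitudeDataset", "CoefState", "predict_mu_phi", "loglik",
           "grad_hess_beta", "grad_hess_alpha", "read_csv_dataset"]


@dataclass
class MagnitudeDataset:
    """Positive responses with mean-side (X) and variance-side (Z) designs.

    ``X`` and ``Z`` exclude the intercept.  ``standardize()`` centers and
    scales the design columns (prior construction requires standardized
    columns); the statistics are kept so coefficients can be mapped back to
    the original scale.  ``b`` and ``gradients`` carry optional per-row
    diffusion metadata.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    x_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)
    b: np.ndarray | None = None
    gradients: np.ndarray | None = None
    x_center: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    z_center: np.ndarray | None = None
    z_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(len(self.y), 0)
        if self.Z.size == 0:
            self.Z = self.Z.reshape(len(self.y), 0)
        n = len(self.y)
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X and Z must have one row per observation")
        if np.any(~np.isfinite(self.y)) or np.any(self.y <= 0):
            bad = int(np.flatnonzero(~(self.y > 0))[0])
            raise ValueError(f"responses must be positive and finite (row {bad})")
        if not self.x_names:
            self.x_names = [f"x{j}" for j in range(self.X.shape[1])]
        if not self.z_names:
            self.z_names = [f"z{j}" for j in range(self.Z.shape[1])]

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def standardize(self) -> "MagnitudeDataset":
        """Return a copy whose X and Z columns have mean 0 and sd 1."""

        def _std(M):
            if M.shape[1] == 0:
                return M.copy(), np.empty(0), np.empty(0)
            c = M.mean(axis=0)
            s = M.std(axis=0, ddof=0)
            if np.any(s == 0):
                raise ValueError("constant design column cannot be standardized")
            return (M - c) / s, c, s

        X, xc, xs = _std(self.X)
        Z, zc, zs = _std(self.Z)
        return MagnitudeDataset(
            y=self.y.copy(), X=X, Z=Z,
            x_names=list(self.x_names), z_names=list(self.z_names),
            b=None if self.b is None else self.b.copy(),
            gradients=None if self.gradients is None else self.gradients.copy(),
            x_center=xc, x_scale=xs, z_center=zc, z_scale=zs,
        )


@dataclass
class CoefState:
    """Regression coefficients plus inclusion indicators.

    Invariant: ``beta[j] == 0`` wherever ``Ibeta[j] == 0`` (same for alpha);
    the intercepts are always in the model.
    """

    beta0: float
    beta: np.ndarray
    alpha0: float
    alpha: np.ndarray
    Ibeta: np.ndarray | None = None
    Ialpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if self.Ibeta is None:
            self.Ibeta = np.ones(len(self.beta), dtype=int)
        if self.Ialpha is None:
            self.Ialpha = np.ones(len(self.alpha), dtype=int)
        self.Ibeta = np.asarray(self.Ibeta, dtype=int).ravel()
        self.Ialpha = np.asarray(self.Ialpha, dtype=int).ravel()
        if np.any(self.beta[self.Ibeta == 0] != 0.0):
            raise ValueError("beta must be zero where Ibeta is zero")
        if np.any(self.alpha[self.Ialpha == 0] != 0.0):
            raise ValueError("alpha must be zero where Ialpha is zero")

    def copy(self) -> "CoefState":
        return CoefState(self.beta0, self.beta.copy(), self.alpha0,
                         self.alpha.copy(), self.Ibeta.copy(), self.Ialpha.copy())


def predict_mu_phi(state: CoefState, data: MagnitudeDataset):
    """Elementwise exp of the two linear predictors (mu_i, phi_i)."""
    eta_mu = state.beta0 + data.X @ state.beta
    eta_phi = state.alpha0 + data.Z @ state.alpha
    for name, eta in (("mu", eta_mu), ("phi", eta_phi)):
        if np.any(~np.isfinite(eta)):
            bad = int(np.flatnonzero(~np.isfinite(eta))[0])
            raise FloatingPointError(f"non-finite linear predictor for {name} at row {bad}")
    return np.exp(eta_mu), np.exp(eta_phi)


def loglik(state: CoefState, data: MagnitudeDataset, model: NoiseModel) -> float:
    """Sum of per-observation log densities at the linked (mu_i, phi_i)."""
    mu, phi = predict_mu_phi(state, data)
    return float(np.sum(logpdf(data.y, mu, phi, model)))


def _chain_grad_hess(design1, deriv1, deriv2, param):
    """Gradient/Hessian through a log link: eta -> exp(eta) -> log density.

    ``deriv1``/``deriv2`` are d(logp)/d(param) and d2(logp)/d(param)^2 with
    param = exp(eta); per-row chain rule gives dl/deta = deriv1 * param and
    d2l/deta2 = deriv2 * param^2 + deriv1 * param.
    """
    u = deriv1 * param
    w = deriv2 * param * param + u
    grad = design1.T @ u
    hess = design1.T @ (design1 * w[:, None])
    return grad, hess, u


def grad_hess_beta(state: CoefState, data: MagnitudeDataset, model: NoiseModel,
                   selected: np.ndarray | None = None):
    """Gradient and Hessian of the log-likelihood w.r.t. (beta0, beta_selected).

    ``selected`` is a boolean mask over columns of X (defaults to the state's
    indicators).  The variance-side coefficients are held fixed.
    """
    if selected is None:
        selected = state.Ibeta.astype(bool)
    mu, phi = predict_mu_phi(state, data)
    d = dlogpdf(data.y, mu, phi, model)
    X1 = np.column_stack([np.ones(data.n), data.X[:, selected]])
    g, H, _ = _chain_grad_hess(X1, d["dmu"], d["dmu2"], mu)
    return g, H


def grad_hess_alpha(state: CoefState, data: MagnitudeDataset, model: NoiseModel,
                    selected: np.ndarray | None = None):
    """Gradient and Hessian of the log-likelihood w.r.t. (alpha0, alpha_selected)."""
    if selected is None:
        selected = state.Ialpha.astype(bool)
    mu, phi = predict_mu_phi(state, data)
    d = dlogpdf(data.y, mu, phi, model)
    Z1 = np.column_stack([np.ones(data.n), data.Z[:, selected]])
    g, H, _ = _chain_grad_hess(Z1, d["dphi"], d["dphi2"], phi)
    return g, H


def read_csv_dataset(path, y_col="y", x_cols=None, z_cols=None) -> MagnitudeDataset:
    """Read a (y, X, Z) dataset from a headed CSV.

    Columns prefixed ``x_`` map to the mean design and ``z_`` to the variance
    design when explicit column lists are not given.
    """
    df = pd.read_csv(path)
    if y_col not in df.columns:
        raise ValueError(f"column {y_col!r} not found in {path}")
    if x_cols is None:
        x_cols = [c for c in df.columns if c.startswith("x_")]
    if z_cols is None:
        z_cols = [c for c in df.columns if c.startswith("z_")]
    return MagnitudeDataset(
        y=df[y_col].to_numpy(),
        X=df[x_cols].to_numpy() if x_cols else np.empty((len(df), 0)),
        Z=df[z_cols].to_numpy() if z_cols else np.empty((len(df), 0)),
        x_names=list(x_cols), z_names=list(z_cols),
    )
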