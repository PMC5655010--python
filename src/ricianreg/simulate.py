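"""Synthetic data: magnitude regression sets at controlled SNR and
single-tensor DTI measurement sets.

SNR here is the ratio of the average signal to its average noise standard
deviation, mean(mu_i) / mean(sd(y_i)), with sd(y_i) the exact standard
deviation of the magnitude law (computed from its moments, not a Gaussian
approximation).  ``simulate_regression`` solves for the mean intercept that
attains a requested SNR given the variance-side coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dti import AcquisitionScheme
from .noise_models import NoiseModel, magnitude_var, sample_magnitude
from .regression import CoefState, MagnitudeDataset

__all__ = [
    "SimulationDesign",
    "simulate_regression",
    "simulate_dti_voxel",
    "make_multishell_scheme",
    "fibonacci_directions",
    "empirical_snr",
]

DEFAULT_SHELLS = (1000.0, 3000.0, 5000.0, 10000.0)  # s/mm^2


@dataclass
class SimulationDesign:
    """Ground truth for a regression simulation.

    Either ``beta0`` or ``snr`` must be given; with ``snr`` set, the mean
    intercept is solved so that mean(mu)/mean(sd(y)) equals the target.
    """

    n: int = 200
    beta: np.ndarray = field(default_factory=lambda: np.array([0.4, 0.0]))
    alpha: np.ndarray = field(default_factory=lambda: np.array([0.3]))
    beta0: float | None = None
    alpha0: float = 0.0
    snr: float | None = None
    model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if self.beta0 is None and self.snr is None:
            raise ValueError("specify beta0 or a target snr")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")


def empirical_snr(mu, phi, model: NoiseModel) -> float:
    """mean(mu) / mean(exact magnitude noise sd)."""
    sd = np.sqrt(magnitude_var(mu, phi, model))
    return float(np.mean(mu) / np.mean(sd))


def _solve_beta0(design: SimulationDesign, eta_x, eta_z) -> float:
    phi = np.exp(design.alpha0 + eta_z)

    def gap(b0):
        mu = np.exp(b0 + eta_x)
        return empirical_snr(mu, phi, design.model) - design.snr

    lo, hi = -20.0, 20.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target SNR {design.snr} unattainable; attainable range "
            f"[{design.snr + gap(lo):.3g}, {design.snr + gap(hi):.3g}]")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def simulate_regression(design: SimulationDesign):
    """Draw a magnitude regression dataset from the generative model.

    X and Z columns are independent standard normals, standardized to mean 0
    and sd 1 exactly.  Returns ``(MagnitudeDataset, CoefState)`` where the
    second element is the generating truth.
    """
    rng = np.random.default_rng(design.seed)
    p, q = len(design.beta), len(design.alpha)

    def draw_std(k):
        M = rng.standard_normal((design.n, k))
        if k:
            M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)
        return M

    X = draw_std(p)
    Z = draw_std(q)
    eta_x = X @ design.beta
    eta_z = Z @ design.alpha
    beta0 = design.beta0 if design.beta0 is not None else _solve_beta0(design, eta_x, eta_z)
    mu = np.exp(beta0 + eta_x)
    phi = np.exp(design.alpha0 + eta_z)
    if design.snr is not None:
        attained = empirical_snr(mu, phi, design.model)
        if abs(attained - design.snr) > 0.1 * design.snr:
            raise ValueError(f"attained SNR {attained:.3g} misses target {design.snr:.3g}")
    y = sample_magnitude(mu, phi, design.model, rng=rng)
    # the Gaussian family approximates intrinsically positive magnitude
    # data; redraw the (rare) non-positive draws
    for _ in range(100):
        neg = y <= 0
        if not neg.any():
            break
        y[neg] = sample_magnitude(mu[neg], phi[neg], design.model, rng=rng)
    data = MagnitudeDataset(y=y, X=X, Z=Z)
    truth = CoefState(beta0=float(beta0), beta=design.beta.copy(),
                      alpha0=float(design.alpha0), alpha=design.alpha.copy())
    return data, truth


# ---------------------------------------------------------------------------
# DTI simulation


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit directions on the sphere (Fibonacci
    lattice)."""
    i = np.arange(n) + 0.5
    phi_ang = np.pi * (1.0 + 5.0**0.5) * i
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.maximum(1.0 - cos_t * cos_t, 0.0))
    return np.column_stack([np.cos(phi_ang) * sin_t, np.sin(phi_ang) * sin_t, cos_t])


def make_multishell_scheme(n_per_shell=(16, 16, 16, 16), b_shells=DEFAULT_SHELLS,
                           n_b0: int = 6) -> AcquisitionScheme:
    """Multi-shell acquisition with Fibonacci-sphere directions per shell
    plus ``n_b0`` unweighted rows.  Default shells are 1000/3000/5000/10000
    s/mm^2."""
    n_per_shell = tuple(int(v) for v in np.atleast_1d(n_per_shell))
    b_shells = tuple(float(v) for v in np.atleast_1d(b_shells))
    if len(n_per_shell) != len(b_shells):
        raise ValueError("n_per_shell and b_shells must have equal length")
    if max(n_per_shell) < 6:
        raise ValueError("at least one shell needs >= 6 directions")
    bs = [np.zeros(n_b0)]
    gs = [np.tile([1.0, 0.0, 0.0], (n_b0, 1))]  # direction irrelevant at b=0
    for n, b in zip(n_per_shell, b_shells):
        bs.append(np.full(n, b))
        gs.append(fibonacci_directions(n))
    return AcquisitionScheme(np.concatenate(bs), np.vstack(gs))


def simulate_dti_voxel(D_true, S0: float, scheme: AcquisitionScheme,
                       model: NoiseModel, phi=None, alpha0: float | None = None,
                       alpha=None, seed=None):
    """Simulate one voxel's measurements from the single-tensor signal model
    S_i = S0 exp(-b_i g_i' D g_i) under the chosen noise law.

    Noise variance is, in order of precedence: an explicit per-row ``phi``
    vector, or a heteroscedastic log-linear model exp(alpha0 + z_i' alpha)
    over the (standardized) diffusion design columns, or homoscedastic
    exp(alpha0).  Returns ``(y, mu, phi)``.
    """
    from .dti import dti_design  # deferred to avoid cycle at import time

    D_true = np.asarray(D_true, dtype=float)
    lam = np.linalg.eigvalsh(D_true)
    if lam[0] <= 0:
        raise ValueError("D_true must be symmetric positive definite")
    quad = np.einsum("ij,jk,ik->i", scheme.g, D_true, scheme.g)
    mu = S0 * np.exp(-scheme.b * quad)
    if phi is not None:
        phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape).copy()
    else:
        if alpha0 is None:
            raise ValueError("give phi or alpha0")
        if alpha is not None:
            X = dti_design(scheme)
            s = X.std(axis=0, ddof=0)
            s[s == 0] = 1.0
            Zs = (X - X.mean(axis=0)) / s
            phi = np.exp(alpha0 + Zs @ np.asarray(alpha, dtype=float))
        else:
            phi = np.full_like(mu, np.exp(alpha0))
    y = sample_magnitude(mu, phi, model, rng=np.random.default_rng(seed))
    return y, mu, phi
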