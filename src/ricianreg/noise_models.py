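"""Observation models for MR magnitude data.

The magnitude of a complex-valued signal whose real and imaginary parts are
independent Gaussians with common variance ``phi`` follows a Rician
distribution.  When ``L`` independent coil signals are combined by
root-sum-of-squares the magnitude follows the non-central chi (NC-chi)
distribution with ``2L`` degrees of freedom; the Rician model is the ``L = 1``
special case.  A Gaussian model with the same (mu, phi) parametrization is
provided as the comparison baseline.

All densities are evaluated in log space.  Bessel functions enter through
``log I_nu(x)``, computed from the exponentially scaled Bessel function so
that arguments up to ``y*mu/phi ~ 1e6`` neither overflow nor underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "NoiseModel",
    "ObsParams",
    "log_bessel_i",
    "bessel_ratio",
    "rician_logpdf",
    "ncchi_logpdf",
    "gaussian_logpdf",
    "logpdf",
    "dlogpdf",
    "sample_magnitude",
    "magnitude_mean",
    "magnitude_var",
]

_FAMILIES = ("rician", "ncchi", "gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Distribution family tag with the degrees-of-freedom parameter L.

    ``L`` is the number of independent complex coil signals; the NC-chi
    density has ``2L`` degrees of freedom.  ``L`` may be any real >= 1 and is
    ignored for the Gaussian family.
    """

    family: str = "rician"
    L: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "ncchi" and self.L < 1:
            raise ValueError("L must be >= 1 for the ncchi family")
        if self.family == "rician":
            object.__setattr__(self, "L", 1.0)

    @property
    def effective_L(self) -> float:
        return 1.0 if self.family == "rician" else self.L


@dataclass(frozen=True)
class ObsParams:
    """Location ``mu`` and per-component complex variance ``phi``.

    ``mu`` is the modulus of the mean of the underlying complex signal and
    ``phi`` the variance of each of its real and imaginary parts.  The complex
    phase carries no information about the magnitude and is marginalized out
    of every density here.
    """

    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not (self.mu >= 0):
            raise ValueError("mu must be non-negative")
        if not (self.phi > 0):
            raise ValueError("phi must be positive")


# ---------------------------------------------------------------------------
# Bessel helpers


def log_bessel_i(nu, x):
    """log I_nu(x) for x >= 0, stable for both tiny and huge arguments.

    Uses ``ive`` (exponentially scaled Bessel) so large arguments cannot
    overflow; where ``ive`` underflows (tiny x at larger nu) falls back to the
    leading term of the ascending series ``(x/2)^nu / Gamma(nu+1)``.
    """
    nu = np.asarray(nu, dtype=float)
    x = np.asarray(x, dtype=float)
    # dedicated order-0/1 kernels are much faster than generic ive
    if nu.ndim == 0 and nu == 0.0:
        scaled = special.i0e(x)
    elif nu.ndim == 0 and nu == 1.0:
        scaled = special.i1e(x)
    else:
        scaled = special.ive(nu, x)
    with np.errstate(divide="ignore"):
        out = np.log(scaled) + x
    # series fallback where the scaled Bessel underflowed
    tiny = scaled <= 0.0
    if np.any(tiny):
        xt = np.where(tiny, x, 1.0)
        nut = np.broadcast_to(nu, out.shape)
        with np.errstate(divide="ignore"):
            series = nut * np.log(xt / 2.0) - special.gammaln(nut + 1.0)
        out = np.where(tiny, series, out)
    return out


def bessel_ratio(L, t):
    """A(t) = I_L(t) / I_{L-1}(t), the log-derivative kernel of the NC-chi density.

    Satisfies A(t) -> t / (2L) as t -> 0 and A(t) -> 1 as t -> infinity.
    """
    L = np.asarray(L, dtype=float)
    t = np.asarray(t, dtype=float)
    if L.ndim == 0 and L == 1.0:
        num = special.i1e(t)
        den = special.i0e(t)
    else:
        num = special.ive(L, t)
        den = special.ive(L - 1.0, t)
    small = (den <= 0.0) | (t < 1e-8)
    safe_den = np.where(small, 1.0, den)
    ratio = np.where(small, t / (2.0 * L), num / safe_den)
    return ratio


def _dratio_dt(L, t, A):
    """A'(t) from the Bessel recurrences: A' = 1 - A^2 - (2L-1) A / t."""
    t = np.asarray(t, dtype=float)
    L = np.asarray(L, dtype=float)
    A = np.asarray(A, dtype=float)
    small = t < 1e-6
    safe_t = np.where(small, 1.0, t)
    full = 1.0 - A * A - (2.0 * L - 1.0) * A / safe_t
    # limit t->0: A ~ t/(2L) so A' -> 1 - (2L-1)/(2L) = 1/(2L)
    return np.where(small, 1.0 / (2.0 * L), full)


# ---------------------------------------------------------------------------
# Log densities


def _check_pos(name, value):
    value = np.asarray(value, dtype=float)
    if np.any(~(value > 0)):
        raise ValueError(f"{name} must be strictly positive")
    return value


def ncchi_logpdf(y, mu, phi, L=1.0):
    """Log density of the non-central chi distribution with 2L dof.

        p(y | mu, phi, L) = y^L / (phi mu^{L-1}) exp(-(y^2+mu^2)/(2 phi)) I_{L-1}(y mu / phi)

    ``mu = 0`` is handled as the central (Rayleigh / central-chi) limit.
    Broadcasts over all arguments.
    """
    y = _check_pos("y", y)
    phi = _check_pos("phi", phi)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be non-negative")
    L = float(L)
    if L < 1:
        raise ValueError("L must be >= 1")

    t = y * mu / phi
    quad = -(y * y + mu * mu) / (2.0 * phi)
    # split log I_{L-1}(t) as (L-1) log(t) + [log I - (L-1) log t] so the
    # mu^{L-1} prefactor cancels analytically and the mu -> 0 limit is exact
    base = L * np.log(y) - np.log(phi) + quad
    if L == 1.0:
        return base + log_bessel_i(0.0, t)
    central = mu == 0.0
    safe_mu = np.where(central, 1.0, mu)
    val = base - (L - 1.0) * np.log(safe_mu) + log_bessel_i(L - 1.0, y * safe_mu / phi)
    if np.any(central):
        # mu -> 0: p = y^{2L-1} / (2^{L-1} Gamma(L) phi^L) exp(-y^2 / 2 phi)
        lim = (
            (2.0 * L - 1.0) * np.log(y)
            - (L - 1.0) * np.log(2.0)
            - special.gammaln(L)
            - L * np.log(phi)
            - y * y / (2.0 * phi)
        )
        val = np.where(central, lim, val)
    return val


def rician_logpdf(y, mu, phi):
    """Log Rician density p(y|mu, phi) = (y/phi) exp(-(y^2+mu^2)/2phi) I_0(y mu/phi)."""
    return ncchi_logpdf(y, mu, phi, L=1.0)


def gaussian_logpdf(y, mu, phi):
    """Log density of N(mu, phi) — the approximate model used at high SNR."""
    phi = _check_pos("phi", phi)
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return -0.5 * (np.log(2.0 * np.pi * phi) + (y - mu) ** 2 / phi)


def logpdf(y, mu, phi, model: NoiseModel):
    """Dispatch the log density for the given noise model."""
    if model.family == "gaussian":
        return gaussian_logpdf(y, mu, phi)
    return ncchi_logpdf(y, mu, phi, L=model.effective_L)


# ---------------------------------------------------------------------------
# Derivatives with respect to (mu, phi)


def dlogpdf(y, mu, phi, model: NoiseModel):
    """First and second partial derivatives of the log density w.r.t. (mu, phi).

    Returns a dict with keys ``dmu, dphi, dmu2, dphi2, dmudphi``; all entries
    broadcast over the inputs.  For the NC-chi family the derivatives use the
    Bessel ratio ``A(t) = I_L(t)/I_{L-1}(t)`` with ``t = y mu / phi``:

        d/dmu  = A t' - mu/phi                      (t' = y/phi)
        d/dphi = -L/phi + (y^2+mu^2)/(2 phi^2) - A y mu / phi^2

    and the curvature terms follow from A'(t) = 1 - A^2 - (2L-1)A/t.
    Stable in the mu -> 0 limit.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if model.family == "gaussian":
        r = (y - mu) / phi
        return {
            "dmu": r,
            "dphi": -0.5 / phi + 0.5 * r * r,
            "dmu2": -1.0 / phi + np.zeros_like(r),
            "dphi2": 0.5 / phi**2 - r * r / phi,
            "dmudphi": -r / phi,
        }
    L = model.effective_L
    t = y * mu / phi
    A = bessel_ratio(L, t)
    Ap = _dratio_dt(L, t, A)
    dmu = A * y / phi - mu / phi
    dphi = -L / phi + (y * y + mu * mu) / (2.0 * phi**2) - A * y * mu / phi**2
    dmu2 = Ap * (y / phi) ** 2 - 1.0 / phi
    dphi2 = (
        L / phi**2
        - (y * y + mu * mu) / phi**3
        + Ap * (y * mu) ** 2 / phi**4
        + 2.0 * A * y * mu / phi**3
    )
    dmudphi = -Ap * y * y * mu / phi**3 - A * y / phi**2 + mu / phi**2
    return {"dmu": dmu, "dphi": dphi, "dmu2": dmu2, "dphi2": dphi2, "dmudphi": dmudphi}


def side_terms(y, mu, phi, model: NoiseModel, side: str):
    """Fused (sum log density, first, second derivative) for one parameter.

    Computes the Bessel pieces once and returns ``(ll, d1, d2)`` where
    ``ll`` is the summed log density and ``d1``/``d2`` the per-observation
    first and second partial derivatives w.r.t. ``mu`` (side='mu') or
    ``phi`` (side='phi').  This is the sampler's hot path; the standalone
    ``logpdf``/``dlogpdf`` functions remain the reference implementations.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if model.family == "gaussian":
        r = (y - mu) / phi
        ll = float(np.sum(-0.5 * (np.log(2.0 * np.pi * phi) + (y - mu) * r)))
        if side == "mu":
            return ll, r, -1.0 / phi + np.zeros_like(r)
        return ll, -0.5 / phi + 0.5 * r * r, 0.5 / phi**2 - r * r / phi
    L = model.effective_L
    t = y * mu / phi
    if L == 1.0:
        i0 = special.i0e(t)
        i1 = special.i1e(t)
        logI = np.log(i0) + t
        A = i1 / i0
        ll = float(np.sum(np.log(y) - np.log(phi) - (y * y + mu * mu) / (2.0 * phi) + logI))
    else:
        den = special.ive(L - 1.0, t)
        num = special.ive(L, t)
        bad = den <= 0.0
        A = np.where(bad | (t < 1e-8), t / (2.0 * L), num / np.where(bad, 1.0, den))
        logI = np.where(
            bad,
            (L - 1.0) * np.log(np.where(t > 0, t, 1.0) / 2.0) - special.gammaln(L),
            np.log(np.where(bad, 1.0, den)) + t,
        )
        ll = float(np.sum(
            L * np.log(y) - np.log(phi) - (L - 1.0) * np.log(mu)
            - (y * y + mu * mu) / (2.0 * phi) + logI))
    small = t < 1e-6
    Ap = np.where(small, 1.0 / (2.0 * L),
                  1.0 - A * A - (2.0 * L - 1.0) * A / np.where(small, 1.0, t))
    if side == "mu":
        d1 = A * y / phi - mu / phi
        d2 = Ap * (y / phi) ** 2 - 1.0 / phi
    else:
        d1 = -L / phi + (y * y + mu * mu) / (2.0 * phi**2) - A * y * mu / phi**2
        d2 = (L / phi**2 - (y * y + mu * mu) / phi**3
              + Ap * (y * mu) ** 2 / phi**4 + 2.0 * A * y * mu / phi**3)
    return ll, d1, d2


# ---------------------------------------------------------------------------
# Sampling and moments


def sample_magnitude(mu, phi, model: NoiseModel, n=None, rng=None):
    """Draw magnitudes from the chosen observation model.

    Rician draws use the complex-Gaussian construction ``y = |a + b j|`` with
    ``a ~ N(mu cos(theta), phi)``, ``b ~ N(mu sin(theta), phi)`` (the
    magnitude is invariant to theta, drawn uniformly).  NC-chi draws use the
    exact representation ``y^2 ~ phi * chi'^2(2L, mu^2/phi)`` via numpy's
    gamma–Poisson noncentral chi-square sampler, valid for any real L >= 1.
    """
    rng = np.random.default_rng(rng)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    shape = np.broadcast_shapes(mu.shape, phi.shape) if n is None else (n,)
    if model.family == "gaussian":
        return rng.normal(np.broadcast_to(mu, shape), np.sqrt(np.broadcast_to(phi, shape)))
    L = model.effective_L
    if model.family == "rician":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=shape)
        a = rng.normal(mu * np.cos(theta), np.sqrt(phi), size=shape)
        b = rng.normal(mu * np.sin(theta), np.sqrt(phi), size=shape)
        return np.hypot(a, b)
    nc = np.broadcast_to(mu * mu / phi, shape)
    draws = rng.noncentral_chisquare(2.0 * L, nc, size=shape)
    return np.sqrt(np.broadcast_to(phi, shape) * draws)


def magnitude_mean(mu, phi, model: NoiseModel):
    """Exact E[y] under the observation model.

    NC-chi: E[y] = sqrt(2 phi) Gamma(L + 1/2)/Gamma(L) 1F1(-1/2; L; -mu^2/(2 phi)),
    which at L = 1 is the classic Rician mean sqrt(pi phi / 2) L_{1/2}(-mu^2/2phi).
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if model.family == "gaussian":
        return mu + np.zeros_like(phi)
    L = model.effective_L
    z = mu * mu / (2.0 * phi)
    coef = np.exp(special.gammaln(L + 0.5) - special.gammaln(L))
    with np.errstate(over="ignore", invalid="ignore"):
        exact = np.sqrt(2.0 * phi) * coef * special.hyp1f1(-0.5, L, -z)
    # high-SNR asymptote E[y] ~ sqrt(mu^2 + (2L-1) phi); relative error
    # O(snr^-4), well below float precision where the series overflows
    asym = np.sqrt(mu * mu + (2.0 * L - 1.0) * phi)
    return np.where((z > 200.0) | ~np.isfinite(exact), asym, exact)


def magnitude_var(mu, phi, model: NoiseModel):
    """Exact Var[y]; uses E[y^2] = mu^2 + 2 L phi for the NC-chi family."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if model.family == "gaussian":
        return phi + np.zeros_like(mu)
    L = model.effective_L
    m = magnitude_mean(mu, phi, model)
    var = mu * mu + 2.0 * L * phi - m * m
    # at extreme SNR the subtraction cancels catastrophically; the exact
    # limit of the magnitude variance is phi
    z = mu * mu / (2.0 * phi)
    return np.where(z > 200.0, phi + np.zeros_like(var), var)
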