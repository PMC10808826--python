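"""Carreau blood rheology and generalized-Newtonian tube flow.

Blood is shear thinning: its apparent viscosity falls from a zero-shear
plateau μ0 to an infinite-shear plateau μ∞ as the shear rate γ̇ grows. The
Carreau law

    μ(γ̇) = μ∞ + (μ0 − μ∞) · [1 + (λγ̇)²]^((n−1)/2)

captures this with a relaxation time λ (s) and power index n ∈ (0, 1].

For steady, fully developed flow of a generalized Newtonian fluid in a
rigid circular tube, the volumetric flow rate Q and the wall shear stress
τ_w are linked by the Weissenberg–Rabinowitsch–Mooney (WRM) relation

    Q(τ_w) = (πR³ / τ_w³) · ∫₀^{τ_w} τ² γ̇(τ) dτ ,

where γ̇(τ) inverts the monotone stress law τ(γ̇) = μ(γ̇)·γ̇. We solve the
WRM relation for τ_w by bracketed root finding. Internally the integral is
evaluated in the shear-rate variable,

    ∫₀^{τ_w} τ² γ̇ dτ = ∫₀^{γ̇_w} τ(γ̇)² γ̇ τ'(γ̇) dγ̇ ,

which keeps the integrand explicit (no nested inversion) and smooth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import DomainError, NumericalError, ValidationError

#: Relative tolerance of the τ_w root and the γ̇(τ) inversion.
_ROOT_RTOL = 1.0e-12
#: Absolute tolerance of the WRM quadrature.
_QUAD_EPSABS = 1.0e-12
_QUAD_EPSREL = 1.0e-11


@dataclass(frozen=True)
class CarreauParams:
    """Four-parameter Carreau viscosity law (SI units).

    Defaults are the blood parameter set in wide use for large-vessel
    hemodynamics: μ0 = 0.056 Pa·s, μ∞ = 0.00345 Pa·s, λ = 3.313 s,
    n = 0.3568. Setting ``n = 1`` (or ``mu_inf = mu0``) recovers a
    Newtonian fluid; setting ``mu_inf = 0`` with λγ̇ ≫ 1 approaches a
    power-law fluid with consistency K = μ0·λ^(n−1).
    """

    mu0: float = 0.056
    mu_inf: float = 0.00345
    lambda_s: float = 3.313
    n: float = 0.3568

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise ValidationError("mu0 must be > 0")
        if not 0.0 <= self.mu_inf <= self.mu0:
            raise ValidationError("mu_inf must satisfy 0 <= mu_inf <= mu0")
        if not self.lambda_s >= 0:
            raise ValidationError("lambda_s must be >= 0")
        if not 0.0 < self.n <= 1.0:
            raise ValidationError("n must lie in (0, 1]")

    @property
    def newtonian(self) -> bool:
        return self.n == 1.0 or self.mu_inf == self.mu0 or self.lambda_s == 0.0


def carreau_viscosity(gamma_dot, params: CarreauParams = CarreauParams()):
    """Apparent viscosity μ(γ̇) in Pa·s; accepts scalars or arrays."""
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise DomainError("shear rate must be >= 0")
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lambda_s * g) ** 2
    ) ** ((params.n - 1.0) / 2.0)
    return float(mu) if np.isscalar(gamma_dot) else mu


def shear_stress(gamma_dot, params: CarreauParams = CarreauParams()):
    """Shear stress τ(γ̇) = μ(γ̇)·γ̇ in Pa (strictly increasing in γ̇)."""
    g = np.asarray(gamma_dot, dtype=float)
    tau = carreau_viscosity(g, params) * g
    return float(tau) if np.isscalar(gamma_dot) else tau


def _dtau_dgamma(g: np.ndarray, p: CarreauParams) -> np.ndarray:
    """dτ/dγ̇ = μ(γ̇) + γ̇·dμ/dγ̇, positive for all valid parameters."""
    x2 = (p.lambda_s * g) ** 2
    base = (1.0 + x2) ** ((p.n - 1.0) / 2.0)
    dmu = (p.mu0 - p.mu_inf) * (p.n - 1.0) * p.lambda_s**2 * g * (1.0 + x2) ** (
        (p.n - 3.0) / 2.0
    )
    mu = p.mu_inf + (p.mu0 - p.mu_inf) * base
    return mu + g * dmu


def shear_rate_from_stress(tau: float, params: CarreauParams = CarreauParams()) -> float:
    """Invert the stress law: the unique γ̇ ≥ 0 with μ(γ̇)·γ̇ = τ."""
    if tau < 0:
        raise DomainError("shear stress must be >= 0")
    if tau == 0.0:
        return 0.0
    lo = tau / params.mu0  # μ ≤ μ0 ⇒ root ≥ τ/μ0
    if params.mu_inf > 0:
        hi = tau / params.mu_inf  # μ ≥ μ∞ ⇒ root ≤ τ/μ∞
    else:
        hi = lo
        for _ in range(200):
            if shear_stress(hi, params) >= tau:
                break
            hi *= 2.0
        else:
            raise NumericalError(f"could not bracket shear rate for tau={tau}")
    if shear_stress(lo, params) == tau:
        return lo
    return float(
        brentq(lambda g: shear_stress(g, params) - tau, lo, hi, rtol=_ROOT_RTOL, xtol=1e-300)
    )


def _wrm_flow(gamma_w: float, R: float, p: CarreauParams) -> float:
    """Flow rate Q through a tube of radius R at wall shear rate γ̇_w (WRM)."""
    if gamma_w == 0.0:
        return 0.0
    tau_w = shear_stress(gamma_w, p)

    def integrand(g: float) -> float:
        ga = np.asarray(g, dtype=float)
        return float(shear_stress(ga, p) ** 2 * ga * _dtau_dgamma(ga, p))

    integral, _ = quad(
        integrand, 0.0, gamma_w, epsabs=_QUAD_EPSABS * tau_w**3, epsrel=_QUAD_EPSREL,
        limit=200,
    )
    return math.pi * R**3 / tau_w**3 * integral


def wall_shear_stress_tube(
    Q: float, R: float, params: CarreauParams = CarreauParams()
) -> float:
    """Wall shear stress (Pa) for flow rate Q (m³/s) in a tube of radius R (m).

    Solves the WRM relation for τ_w; reduces to the Poiseuille closed form
    τ_w = 4μQ/(πR³) when the fluid is Newtonian.
    """
    if Q < 0:
        raise DomainError("flow rate must be >= 0")
    if not R > 0:
        raise DomainError("radius must be > 0")
    if Q == 0.0:
        return 0.0
    gamma_newt = 4.0 * Q / (math.pi * R**3)  # Newtonian wall shear rate
    if params.newtonian:
        return carreau_viscosity(0.0, params) * gamma_newt
    # for shear-thinning fluids the wall shear rate is >= the Newtonian one;
    # bracket generously and expand if needed
    lo, hi = 0.5 * gamma_newt, 2.0 * gamma_newt * (3.0 * params.n + 1.0) / (4.0 * params.n)
    for _ in range(200):
        if _wrm_flow(lo, R, params) <= Q:
            break
        lo *= 0.5
    else:
        raise NumericalError("could not bracket tau_w from below")
    for _ in range(200):
        if _wrm_flow(hi, R, params) >= Q:
            break
        hi *= 2.0
    else:
        raise NumericalError("could not bracket tau_w from above")
    gamma_w = brentq(
        lambda g: _wrm_flow(g, R, params) - Q, lo, hi, rtol=_ROOT_RTOL, xtol=1e-300
    )
    return shear_stress(float(gamma_w), params)
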