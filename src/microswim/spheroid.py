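"""Prolate-spheroid geometry shared by all three model families.

A cell body of length ``B`` and diameter ``W`` (both µm, ``W <= B``) has
eccentricity ``e = sqrt(1 - (W/B)^2)``.  This module provides the drag
correction ``C_FB`` relating its translational Stokes drag to ``3πηB``, the
slender-filament drag coefficients per unit length, the surface radius
``r(θ)``, the surface area ``S`` and the tangential geometric moment ``I_t``
that converts a uniform tangential surface stress into a propulsive force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate

from .fluid import FluidMedium

__all__ = [
    "SpheroidBody",
    "drag_correction_cfb",
    "slender_drag_coeffs",
    "spheroid_radius",
    "surface_area",
    "tangential_moment",
    "body_drag_b11",
]

# Below this eccentricity the closed forms are 0/0; switch to series.
_E_SERIES = 1e-4
_E_MAX = 1.0 - 1e-12

_QUAD_TOL = 1e-10


@dataclass(frozen=True)
class SpheroidBody:
    """Prolate spheroid: length ``B`` [µm] along the axis, diameter ``W`` [µm]."""

    B: float
    W: float

    def __post_init__(self) -> None:
        if self.W <= 0 or self.B <= 0:
            raise ValueError("B and W must be positive")
        if self.W > self.B:
            raise ValueError("prolate only: need W <= B")

    @property
    def eccentricity(self) -> float:
        return math.sqrt(max(0.0, 1.0 - (self.W / self.B) ** 2))

    @property
    def tau0(self) -> float:
        """1/e, the spheroidal coordinate of the surface (infinite for a sphere)."""
        e = self.eccentricity
        return math.inf if e == 0 else 1.0 / e


def drag_correction_cfb(body: SpheroidBody) -> float:
    """Drag correction C_FB ∈ (0, 1]: translational drag = 3πηB·C_FB.

    C_FB = (8/3) e³ [−2e + (1+e²) ln((1+e)/(1−e))]⁻¹, with a Taylor series
    for e → 0 where the expression is 0/0 (C_FB(0) = 1, the Stokes sphere).
    """
    e = min(body.eccentricity, _E_MAX)
    if e < _E_SERIES:
        e2 = e * e
        return 1.0 / (1.0 + 0.4 * e2 + (9.0 / 35.0) * e2 * e2)
    denom = -2.0 * e + (1.0 + e * e) * math.log((1.0 + e) / (1.0 - e))
    return (8.0 / 3.0) * e**3 / denom


def body_drag_b11(body: SpheroidBody, fluid: FluidMedium) -> float:
    """Translational resistance b11 = 3πηB·C_FB [mPa·s·µm]."""
    return 3.0 * math.pi * fluid.eta * body.B * drag_correction_cfb(body)


def slender_drag_coeffs(L: float, b: float, fluid: FluidMedium) -> tuple[float, float]:
    """Per-unit-length drag (c_perp, c_par) [mPa·s] of a slender rod.

    c⊥ = 4πη/(ln(L/b) + 1/2), c∥ = 2πη/(ln(L/b) − 1/2); valid for b ≪ L,
    where the ratio c∥/c⊥ approaches 1/2.
    """
    if b >= L:
        raise ValueError("slender theory requires filament radius b < length L")
    logr = math.log(L / b)
    c_perp = 4.0 * math.pi * fluid.eta / (logr + 0.5)
    c_par = 2.0 * math.pi * fluid.eta / (logr - 0.5)
    if c_par <= 0:
        raise ValueError(f"L/b = {L / b:.3g} too small for slender-body drag")
    return c_perp, c_par


def spheroid_radius(theta: float, body: SpheroidBody) -> float:
    """Polar radius r(θ) = (W/2)/sqrt(1 − e²cos²θ), origin midway between foci."""
    e = body.eccentricity
    return 0.5 * body.W / math.sqrt(1.0 - (e * math.cos(theta)) ** 2)


def _radius_deriv(theta: float, body: SpheroidBody) -> float:
    # dr/dθ, analytic
    e2 = body.eccentricity ** 2
    u = 1.0 - e2 * math.cos(theta) ** 2
    return -0.5 * body.W * e2 * math.cos(theta) * math.sin(theta) * u ** -1.5


def surface_area(body: SpheroidBody) -> float:
    """Surface area S = (πW²/2)[1 + arcsin(e)/(e·sqrt(1−e²))] [µm²]."""
    e = min(body.eccentricity, _E_MAX)
    W = body.W
    if e < _E_SERIES:
        # arcsin(e)/(e sqrt(1-e^2)) = 1 + (2/3) e^2 + O(e^4)
        return 0.5 * math.pi * W * W * (2.0 + (2.0 / 3.0) * e * e)
    return 0.5 * math.pi * W * W * (1.0 + math.asin(e) / (e * math.sqrt(1.0 - e * e)))


def tangential_moment(body: SpheroidBody) -> float:
    """Geometric moment I_t = 2π ∫₀^π [ (r sinθ)² − r r' sinθ cosθ ] dθ [µm²].

    For a uniform tangential surface stress τ the total propulsive force is
    τ·I_t; for a sphere of radius R this reduces to π²R².
    """

    def integrand(theta: float) -> float:
        r = spheroid_radius(theta, body)
        rp = _radius_deriv(theta, body)
        s, c = math.sin(theta), math.cos(theta)
        return (r * s) ** 2 - r * rp * s * c

    val, err = integrate.quad(integrand, 0.0, math.pi, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL)
    if not math.isfinite(val) or err > max(_QUAD_TOL, 1e-8 * abs(val)):
        raise RuntimeError(f"tangential-moment quadrature did not converge (err={err:.2e})")
    return 2.0 * math.pi * val


def surface_area_quadrature(body: SpheroidBody) -> float:
    """Brute-force S = ∫ r sinθ sqrt(r² + r'²) dθ dφ (oracle for surface_area)."""

    def integrand(theta: float) -> float:
        r = spheroid_radius(theta, body)
        rp = _radius_deriv(theta, body)
        return r * math.sin(theta) * math.hypot(r, rp)

    val, _ = integrate.quad(integrand, 0.0, math.pi, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL)
    return 2.0 * math.pi * val
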