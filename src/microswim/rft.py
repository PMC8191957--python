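"""Resistive-force-theory model of a flagellated prokaryote.

A rigid helical filament (contour length ``L``, pitch ``lam``, helix radius
``h``, filament radius ``b``) rotated at angular rate ω relative to the cell
body propels a prolate-spheroid body.  Anisotropic drag on the filament
couples rotation to translation through a symmetric 2×2 resistance matrix;
force and torque balance on the whole cell then fixes the swimming speed U,
the body counter-rotation Ω and the motor torque T_m.

Dropping the (provably ≤ 1/9) off-diagonal coupling term and fixing the pitch
angle at π/4 collapses the full solution into a single morphological factor
ξ² with U = T_m/(η ξ²), which is what the per-species torque estimator uses.

Units: resistance entries are in mPa·s·µm (force rows) and mPa·s·µm³ (torque
rows); with speeds in µm s⁻¹ and rates in rad s⁻¹ the resulting torques are
directly in pN·nm (1 mPa·µm³ = 10⁻²¹ N·m = 1 pN·nm) and forces in
10⁻³ pN (1 mPa·µm² = 10⁻¹⁵ N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fluid import FluidMedium, WATER_25C
from .records import CollapsePolicy, DEFAULT_POLICY, OrganismRecord
from .results import EstimateResult
from .spheroid import SpheroidBody, drag_correction_cfb, slender_drag_coeffs

__all__ = [
    "HelicalFlagellum",
    "ResistanceMatrix",
    "SwimSolution",
    "filament_resistance",
    "coupling_ratio",
    "solve_swimming",
    "body_rotational_drag_b22",
    "morphological_factor",
    "estimate_motor_torque",
    "DEFAULT_FILAMENT_RADIUS",
]

#: Default filament radius [µm]; the bundled filament is taken to be
#: 2b = 0.02 µm thick for every species (its effect is only logarithmic).
DEFAULT_FILAMENT_RADIUS = 0.01


@dataclass(frozen=True)
class HelicalFlagellum:
    """Rigid helix: contour length L, pitch lam, helix radius h, filament
    radius b (all µm)."""

    L: float
    lam: float
    h: float
    b: float = DEFAULT_FILAMENT_RADIUS

    def __post_init__(self) -> None:
        if min(self.L, self.lam, self.h, self.b) <= 0:
            raise ValueError("all helix dimensions must be positive")

    @property
    def pitch_angle(self) -> float:
        """θ = arctan(2πh/λ) ∈ (0, π/2)."""
        return math.atan2(2.0 * math.pi * self.h, self.lam)


@dataclass(frozen=True)
class ResistanceMatrix:
    """Filament (f11, f12, f22) and body (b11, b22) resistance coefficients."""

    f11: float
    f12: float
    f22: float
    b11: float
    b22: float

    def __post_init__(self) -> None:
        for name in ("f11", "f22", "b11", "b22"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.f12 ** 2 >= self.f11 * self.f22:
            raise ValueError("need f12^2 < f11*f22 (positive-definite filament matrix)")


@dataclass(frozen=True)
class SwimSolution:
    """Signed solution of the force/torque balance.

    Signs follow the propulsion convention: a right-handed helix driven at
    ω > 0 gives U < 0 (the cell swims towards −x) and Ω < 0 (the body
    counter-rotates); the motor torque T_m = f12·U + f22·(Ω+ω) is positive.
    ``speed`` and ``torque`` expose the magnitudes.
    """

    U: float
    Omega: float
    Tm: float

    @property
    def speed(self) -> float:
        return abs(self.U)

    @property
    def torque(self) -> float:
        return abs(self.Tm)


def filament_resistance(
    flag: HelicalFlagellum, fluid: FluidMedium
) -> tuple[float, float, float]:
    """Helix resistance coefficients from local slender-body drag:

    f11 = (c∥cos²θ + c⊥sin²θ)L,  f12 = (c⊥−c∥)sinθ cosθ hL,
    f22 = (c⊥cos²θ + c∥sin²θ)h²L.
    """
    c_perp, c_par = slender_drag_coeffs(flag.L, flag.b, fluid)
    th = flag.pitch_angle
    s2, c2 = math.sin(th) ** 2, math.cos(th) ** 2
    sc = math.sin(th) * math.cos(th)
    f11 = (c_par * c2 + c_perp * s2) * flag.L
    f12 = (c_perp - c_par) * sc * flag.h * flag.L
    f22 = (c_perp * c2 + c_par * s2) * flag.h ** 2 * flag.L
    return f11, f12, f22


def coupling_ratio(theta: float, gamma: float) -> float:
    """f12²/(f11·f22) as a function of pitch angle θ and γ = c∥/c⊥.

    Equals (1−γ)²sin²θcos²θ / [(γcos²θ+sin²θ)(γsin²θ+cos²θ)]; maximised at
    θ = π/4 where it equals ((1−γ)/(1+γ))² — 1/9 for the slender value γ=1/2.
    """
    if not (0.0 <= theta <= math.pi / 2):
        raise ValueError("theta must lie in [0, pi/2]")
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma = c_par/c_perp must lie in (0, 1]")
    s2, c2 = math.sin(theta) ** 2, math.cos(theta) ** 2
    num = (1.0 - gamma) ** 2 * s2 * c2
    den = (gamma * c2 + s2) * (gamma * s2 + c2)
    return num / den


def body_rotational_drag_b22(body: SpheroidBody, fluid: FluidMedium) -> float:
    """Rotational resistance of a prolate spheroid about its long axis
    [mPa·s·µm³]: b22 = (16/3)πη a c² · e-dependent factor, the standard
    axisymmetric Stokes result; reduces to 8πηR³ for a sphere.

    The published model never needs this coefficient (U/T_m is independent of
    it); it is supplied so the full linear system can be solved and checked.
    """
    a = 0.5 * body.B  # polar semi-axis
    c = 0.5 * body.W  # equatorial semi-axis (note: c <= a)
    e = body.eccentricity
    if e < 1e-6:
        return 8.0 * math.pi * fluid.eta * c ** 3
    # T = 32/3 πη a c² e³ / [2e − (1−e²) ln((1+e)/(1−e))] per unit rate
    denom = 2.0 * e - (1.0 - e * e) * math.log((1.0 + e) / (1.0 - e))
    return (32.0 / 3.0) * math.pi * fluid.eta * a * c * c * e ** 3 / denom


def solve_swimming(
    omega: float,
    fil: tuple[float, float, float],
    body: tuple[float, float],
) -> SwimSolution:
    """Solve the 2×2 force/torque balance for (U, Ω), then T_m.

    [[b11+f11, f12], [f12, b22+f22]] · (U, Ω) = −(f12, f22)·ω, and
    T_m = f12·U + f22·(Ω+ω).  At ω = 0 everything vanishes.
    """
    f11, f12, f22 = fil
    b11, b22 = body
    if omega == 0.0:
        return SwimSolution(0.0, 0.0, 0.0)
    A = np.array([[b11 + f11, f12], [f12, b22 + f22]], float)
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if det <= 0 or not math.isfinite(det):
        raise ValueError("singular or indefinite resistance system")
    U, Om = np.linalg.solve(A, np.array([-f12 * omega, -f22 * omega]))
    Tm = f12 * U + f22 * (Om + omega)
    return SwimSolution(float(U), float(Om), float(Tm))


def speed_torque_ratio(fil: tuple[float, float, float], b11: float) -> float:
    """Closed-form U/T_m = f12/(f12² − f22(b11+f11)) — independent of b22."""
    f11, f12, f22 = fil
    return f12 / (f12 ** 2 - f22 * (b11 + f11))


def speed_torque_ratio_simplified(fil: tuple[float, float, float], b11: float) -> float:
    """|U/T_m| ≈ f12/(f22(b11+f11)), neglecting the ≤ 1/9 coupling term."""
    f11, f12, f22 = fil
    return f12 / (f22 * (b11 + f11))


def morphological_factor(
    body: SpheroidBody, L: float, h: float, b: float = DEFAULT_FILAMENT_RADIUS
) -> float:
    """Morphology-only factor ξ² [µm²] linking speed to motor torque.

    ξ² = 9πh·(B·C_FB(W/B) + L/(ln(L/b)+1/2)), obtained from the simplified
    speed–torque ratio with pitch angle fixed at π/4 and the slender-limit
    c∥ ≈ c⊥/2; then U = T_m/(η ξ²).
    """
    if L <= 0 or h <= 0:
        raise ValueError("flagellum length L and helix radius h must be positive")
    cfb = drag_correction_cfb(body)
    return 9.0 * math.pi * h * (body.B * cfb + L / (math.log(L / b) + 0.5))


def morphological_factor_variant(
    body: SpheroidBody, L: float, h: float, b: float = DEFAULT_FILAMENT_RADIUS
) -> float:
    """Alternative ξ² using the tangential coefficient directly
    (ln(L/b) − 1/2 in place of ln(L/b) + 1/2); provided for sensitivity
    checks, not used by the reference estimates."""
    cfb = drag_correction_cfb(body)
    return 9.0 * math.pi * h * (body.B * cfb + L / (math.log(L / b) - 0.5))


_REQUIRED = ("B", "W", "L", "h", "U")


def estimate_motor_torque(
    rec: OrganismRecord,
    fluid: FluidMedium = WATER_25C,
    policy: CollapsePolicy = DEFAULT_POLICY,
    b: float = DEFAULT_FILAMENT_RADIUS,
) -> EstimateResult:
    """Effective motor torque T_m = U·η·ξ² [pN·nm] for one species.

    Records missing any of B, W, L, h, U are skipped (only species with the
    full morphology enter the published torque bounds).  With the unit
    convention above no numeric conversion factor is needed.
    """
    vals: dict[str, float] = {}
    imputations: list[str] = []
    missing: list[str] = []
    for name in _REQUIRED:
        got = rec.get(name, policy)
        if got is None:
            missing.append(name)
            continue
        vals[name], rule = got
        if rule != "point":
            imputations.append(f"{name}: collapsed by {rule}")
    if missing:
        return EstimateResult(
            rec.species, "Tm", "pN nm",
            skip_reason=f"insufficient data: missing {', '.join(missing)}",
        )
    imputations.append(f"filament radius b = {b} um (fixed default)")
    body = SpheroidBody(B=vals["B"], W=vals["W"])
    xi_sq = morphological_factor(body, vals["L"], vals["h"], b)
    Tm = vals["U"] * fluid.eta * xi_sq
    inputs = dict(vals, b=b, eta=fluid.eta, xi_sq=xi_sq)
    return EstimateResult(rec.species, "Tm", "pN nm", value=Tm,
                          inputs=inputs, imputations=imputations)
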