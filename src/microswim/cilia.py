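"""Three coarse-grained models of ciliary propulsion and their inverses.

A ciliate is a prolate spheroid (length B, diameter W) covered by many short
cilia.  Each model assumes a different quantity is uniform over the surface
and balances the resulting propulsive force against the body drag
3πηB·C_FB·U:

* model A — constant tangential stress τ [mPa]:      U = τ·I_t/(3πηB·C_FB)
* model B — constant force F [pN] per cilium, N cilia uniformly distributed:
                                                     U = F·N·I_t/(3πηB·S·C_FB)
* model C — constant effective surface slip û_s [µm s⁻¹] (squirmer):
            U = û_s·g(e), with g(e) = [1 − ((1−e²)/e)·artanh e]/e²
            rising from 2/3 (sphere) to 1 (needle).

Models A and B are algebraically identical under τ = F·N/S.  Inverting each
relation for the observed swimming speed turns them into per-species
estimators of τ, F and û_s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from scipy import integrate

from .fluid import FluidMedium, WATER_25C
from .records import CollapsePolicy, DEFAULT_POLICY, OrganismRecord
from .results import EstimateResult
from .spheroid import SpheroidBody, drag_correction_cfb, surface_area, tangential_moment

__all__ = [
    "CiliaryArray",
    "SurfaceVelocityProfile",
    "uniform_slip_profile",
    "cilia_count",
    "speed_constant_stress",
    "speed_constant_force",
    "squirmer_speed_quadrature",
    "speed_surface_velocity",
    "estimate_tau",
    "estimate_force_per_cilium",
    "estimate_surface_speed",
]

_QUAD_TOL = 1e-11
#: mPa·µm² → pN (model-B force conversion)
_FORCE_TO_PN = 1e-3
_E_SERIES = 1e-4


@dataclass(frozen=True)
class CiliaryArray:
    """Ciliation descriptors: total count N, areal density kappa [µm⁻²],
    nearest-neighbour spacing d [µm], cilium length ell [µm] (informational).

    Any one of N / kappa / d suffices; when both N and kappa are given their
    consistency with N = κS is checked by :func:`cilia_count`.
    """

    N: float | None = None
    kappa: float | None = None
    d: float | None = None
    ell: float | None = None

    def __post_init__(self) -> None:
        for name in ("N", "kappa", "d", "ell"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")


def cilia_count(array: CiliaryArray, S: float) -> tuple[float, str, list[str]]:
    """Resolve the cilia count N for a cell of surface area S [µm²].

    Precedence: explicit N, then N = κ·S, then N = S/d² (spacing rule
    κ_d ≈ 1/d²).  Returns ``(N, route, warnings)``.
    """
    warnings: list[str] = []
    if array.N is not None:
        if array.kappa is not None:
            implied = array.kappa * S
            if abs(implied - array.N) > 0.5 * array.N:
                warnings.append(
                    f"N = {array.N:.3g} inconsistent with kappa*S = {implied:.3g}"
                )
        return array.N, "direct", warnings
    if array.kappa is not None:
        return array.kappa * S, "kappa*S", warnings
    if array.d is not None:
        return S / array.d ** 2, "S/d^2", warnings
    raise ValueError("no ciliation information: need one of N, kappa, d")


def speed_constant_stress(tau: float, body: SpheroidBody, fluid: FluidMedium) -> float:
    """Model A speed U_τ = τ·I_t/(3πηB·C_FB) [µm s⁻¹] for stress τ [mPa]."""
    It = tangential_moment(body)
    return tau * It / (3.0 * math.pi * fluid.eta * body.B * drag_correction_cfb(body))


def speed_constant_force(F: float, N: float, body: SpheroidBody, fluid: FluidMedium) -> float:
    """Model B speed U_F = F·N·I_t/(3πηB·S·C_FB) [µm s⁻¹], F in pN."""
    if N < 1:
        raise ValueError("need at least one cilium")
    It = tangential_moment(body)
    S = surface_area(body)
    return (
        (F / _FORCE_TO_PN) * N * It
        / (3.0 * math.pi * fluid.eta * body.B * S * drag_correction_cfb(body))
    )


@dataclass(frozen=True)
class SurfaceVelocityProfile:
    """Axisymmetric tangential slip u_s(ζ) [µm s⁻¹], ζ = cosθ ∈ [−1, 1].

    The sign convention is that of the tangent vector pointing towards
    increasing θ (front to back): negative u_s means rearward surface flow,
    which propels the cell forward.
    """

    u_s: Callable[[float], float]

    def __call__(self, zeta: float) -> float:
        return self.u_s(zeta)


def uniform_slip_profile(u_hat: float, body: SpheroidBody) -> SurfaceVelocityProfile:
    """The canonical near-uniform squirmer profile with scale û_s:

    u_s(ζ) = −τ0·û_s·sqrt((1−ζ²)/(τ0²−ζ²)), rearward (negative) everywhere.
    """
    t0 = body.tau0
    if not math.isfinite(t0):
        raise ValueError("profile needs e > 0 (use a slightly prolate body)")
    return SurfaceVelocityProfile(
        lambda z: -t0 * u_hat * math.sqrt(max(0.0, (1.0 - z * z)) / (t0 * t0 - z * z))
    )


def squirmer_speed_quadrature(profile: SurfaceVelocityProfile, body: SpheroidBody) -> float:
    """Swimming speed from the reciprocal theorem:

    U_s = −(τ0/2) ∫₋₁¹ sqrt((1−ζ²)/(τ0²−ζ²)) u_s(ζ) dζ.

    Rearward (negative) slip gives forward (positive) U_s.  The integrand's
    endpoint square-root vanishes (τ0 > 1), so the quadrature is regular.
    """
    t0 = body.tau0
    if not math.isfinite(t0):
        raise ValueError("squirmer quadrature needs e > 0")

    def integrand(z: float) -> float:
        return math.sqrt(max(0.0, 1.0 - z * z) / (t0 * t0 - z * z)) * profile(z)

    val, err = integrate.quad(integrand, -1.0, 1.0, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL)
    if not math.isfinite(val) or err > max(1e-9, 1e-7 * abs(val)):
        raise RuntimeError(f"squirmer quadrature did not converge (err={err:.2e})")
    return -0.5 * t0 * val


def speed_surface_velocity(u_hat: float, e: float) -> float:
    """Model C closed form U_s = (û_s/e²)·[1 − ((1−e²)/e)·artanh e].

    Series for e → 0: U_s = û_s·(2/3 + (2/15)e² + ...); limit û_s as e → 1.
    """
    if not (0.0 <= e < 1.0):
        raise ValueError("eccentricity must lie in [0, 1)")
    if e < _E_SERIES:
        return u_hat * (2.0 / 3.0 + (2.0 / 15.0) * e * e)
    return (u_hat / (e * e)) * (1.0 - (1.0 - e * e) / e * math.atanh(e))


def _geometry(rec, policy):
    """Collapse B, W, U; impute nothing. Returns (vals, imputations) or a skip string."""
    vals: dict[str, float] = {}
    imputations: list[str] = []
    for name in ("B", "W", "U"):
        got = rec.get(name, policy)
        if got is None:
            return None, f"missing {name}"
        vals[name], rule = got
        if rule != "point":
            imputations.append(f"{name}: collapsed by {rule}")
    if vals["W"] > vals["B"]:
        vals["W"] = vals["B"]
        imputations.append("W clipped to B (treated as sphere)")
    return vals, imputations


def estimate_tau(
    rec: OrganismRecord,
    fluid: FluidMedium = WATER_25C,
    policy: CollapsePolicy = DEFAULT_POLICY,
) -> EstimateResult:
    """Model A inverse: τ = 3πηB·C_FB·U/I_t [mPa] from the observed speed."""
    vals, imp = _geometry(rec, policy)
    if vals is None:
        return EstimateResult(rec.species, "tau", "mPa", skip_reason=imp)
    body = SpheroidBody(B=vals["B"], W=vals["W"])
    if vals["U"] == 0.0:
        imp.append("observed speed is zero")
        return EstimateResult(rec.species, "tau", "mPa", value=0.0,
                              inputs=vals, imputations=imp)
    tau = (
        3.0 * math.pi * fluid.eta * body.B * drag_correction_cfb(body) * vals["U"]
        / tangential_moment(body)
    )
    return EstimateResult(rec.species, "tau", "mPa", value=tau,
                          inputs=dict(vals, eta=fluid.eta), imputations=imp)


def estimate_force_per_cilium(
    rec: OrganismRecord,
    fluid: FluidMedium = WATER_25C,
    policy: CollapsePolicy = DEFAULT_POLICY,
) -> EstimateResult:
    """Model B inverse: F = 3πηB·S·C_FB·U/(N·I_t) [pN].

    N comes from the record's N, κ or d (in that order); records with no
    ciliation information are skipped, mirroring the sparse coverage of
    cilia counts in the source tables.
    """
    vals, imp = _geometry(rec, policy)
    if vals is None:
        return EstimateResult(rec.species, "F", "pN", skip_reason=imp)
    body = SpheroidBody(B=vals["B"], W=vals["W"])
    S = surface_area(body)

    array_vals: dict[str, float | None] = {}
    for name in ("N", "kappa", "d"):
        got = rec.get(name, policy)
        if got is None:
            array_vals[name] = None
        else:
            array_vals[name], rule = got
            if rule != "point":
                imp.append(f"{name}: collapsed by {rule}")
                if name == "kappa" and rule == "midpoint":
                    q = rec.kappa
                    if q.hi is not None and q.lo is not None and q.hi > 3.0 * q.lo:
                        imp.append("kappa range spans >3x: wide-uncertainty flag")
    try:
        N, route, warn = cilia_count(CiliaryArray(**array_vals), S)
    except ValueError:
        return EstimateResult(rec.species, "F", "pN",
                              skip_reason="no ciliation information (N, kappa or d)")
    imp.extend(warn)
    if route != "direct":
        imp.append(f"N = {N:.3g} imputed via {route}")
    if vals["U"] == 0.0:
        imp.append("observed speed is zero")
        return EstimateResult(rec.species, "F", "pN", value=0.0,
                              inputs=dict(vals, N=N), imputations=imp)
    F = _FORCE_TO_PN * (
        3.0 * math.pi * fluid.eta * body.B * S * drag_correction_cfb(body) * vals["U"]
        / (N * tangential_moment(body))
    )
    return EstimateResult(rec.species, "F", "pN", value=F,
                          inputs=dict(vals, N=N, S=S, eta=fluid.eta), imputations=imp)


def estimate_surface_speed(
    rec: OrganismRecord,
    policy: CollapsePolicy = DEFAULT_POLICY,
) -> EstimateResult:
    """Model C inverse: û_s = U/g(e) [µm s⁻¹]; purely geometric (no fluid)."""
    vals, imp = _geometry(rec, policy)
    if vals is None:
        return EstimateResult(rec.species, "u_hat", "um/s", skip_reason=imp)
    e = SpheroidBody(B=vals["B"], W=vals["W"]).eccentricity
    if vals["U"] == 0.0:
        imp.append("observed speed is zero")
        return EstimateResult(rec.species, "u_hat", "um/s", value=0.0,
                              inputs=vals, imputations=imp)
    u_hat = vals["U"] / (speed_surface_velocity(1.0, e))
    return EstimateResult(rec.species, "u_hat", "um/s", value=u_hat,
                          inputs=dict(vals, e=e), imputations=imp)
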