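"""Planar travelling-wave propulsion for flagellated eukaryotes and sperm.

The flagellum beats as a single plane sine wave y(x,t) = h sin(2π(x+ct)/λ)
with wave speed c = λf travelling tip-to-base, pushing the cell towards +x.
Period-averaging the local resistive-force balance over one wavelength gives
the net thrust in terms of three dimensionless integrals Λ(a), I1(a), I2(a)
of the wave steepness a = 2πh/λ; balancing thrust against prolate-spheroid
body drag yields the predicted swimming speed.

Two evaluation modes are provided: ``exact`` evaluates the integrals by
quadrature and solves the thrust balance directly; ``approx`` uses the
printed closed-form approximations (accurate to 13% for h/λ < 1) assembled
into a single explicit speed formula.  Spermatozoa use the same balance with
N = 1 and their own default aspect ratio and filament radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate, optimize, special

from .fluid import FluidMedium, WATER_25C
from .records import CollapsePolicy, DEFAULT_POLICY, OrganismRecord
from .results import EstimateResult
from .spheroid import SpheroidBody, drag_correction_cfb, slender_drag_coeffs

__all__ = [
    "PlanarWave",
    "FlagellateGeometry",
    "wave_integrals",
    "wave_integrals_approx",
    "wave_count",
    "impute_wave_parameter",
    "net_thrust",
    "predict_speed",
    "FLAGELLATE_ASPECT",
    "SPERM_ASPECT",
    "FLAGELLATE_FILAMENT_RADIUS",
    "SPERM_FILAMENT_RADIUS",
    "MAX_STEEPNESS",
]

#: Default body aspect ratio W/B when W is missing (cohort averages).
FLAGELLATE_ASPECT = 0.60
SPERM_ASPECT = 0.47
#: Default flagellum radii [µm]: flagellates b = 0.2; sperm 2b = 0.4.
FLAGELLATE_FILAMENT_RADIUS = 0.2
SPERM_FILAMENT_RADIUS = 0.2
#: The 13% accuracy statement for the closed forms covers h/λ < 1, i.e.
#: a < 2π; larger steepness triggers a warning flag in outputs.
MAX_STEEPNESS = 2.0 * math.pi

_QUAD_TOL = 1e-11
#: mPa·µm² → pN
_FORCE_TO_PN = 1e-3


@dataclass(frozen=True)
class PlanarWave:
    """Sine wave of amplitude h, wavelength lam [µm], frequency f [cycles/s]."""

    lam: float
    h: float
    f: float

    def __post_init__(self) -> None:
        if min(self.lam, self.h, self.f) <= 0:
            raise ValueError("lam, h and f must be positive")

    @property
    def steepness(self) -> float:
        """a = 2πh/λ."""
        return 2.0 * math.pi * self.h / self.lam

    @property
    def wave_speed(self) -> float:
        """c = λf [µm s⁻¹]."""
        return self.lam * self.f


@dataclass(frozen=True)
class FlagellateGeometry:
    """Body plus N identical beating flagella of length L and radius b [µm]."""

    body: SpheroidBody
    N: int
    L: float
    b: float = FLAGELLATE_FILAMENT_RADIUS

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("need at least one flagellum")
        if self.L <= 0 or self.b <= 0:
            raise ValueError("L and b must be positive")


def wave_integrals(a: float) -> tuple[float, float, float]:
    """Exact period-averaged integrals (Λ, I1, I2) of the wave steepness a.

    With A(α) = a·cosα the local slope of the sine wave,

    Λ(a)  = (1/2π)∫ sqrt(1 + A²) dα          (arc length per wavelength)
    I1(a) = (1/2π)∫ A²/sqrt(1 + A²) dα       (thrust integral)
    I2(a) = (1/2π)∫ (1 + 2A²)/sqrt(1 + A²) dα   (drag integral)

    The 1/sqrt(1+A²) weight is the product of the two slope projections and
    the arc element δs = sqrt(1+A²)δx of the local force balance; it implies
    the exact identity I2 = I1 + Λ.  All three are evaluated by adaptive
    quadrature; the independent complete-elliptic-integral route is
    :func:`wave_integrals_elliptic`.
    """
    if a < 0:
        raise ValueError("steepness a must be non-negative")
    if a == 0.0:
        return 1.0, 0.0, 1.0

    def _avg(f):
        val, err = integrate.quad(f, 0.0, 2.0 * math.pi,
                                  epsabs=_QUAD_TOL, epsrel=_QUAD_TOL)
        if not math.isfinite(val) or err > 1e-8 * max(1.0, abs(val)):
            raise RuntimeError(f"wave-integral quadrature failed (err={err:.2e})")
        return val / (2.0 * math.pi)

    Lam = _avg(lambda al: math.sqrt(1.0 + (a * math.cos(al)) ** 2))
    I1 = _avg(
        lambda al: (a * math.cos(al)) ** 2 / math.sqrt(1.0 + (a * math.cos(al)) ** 2)
    )
    return Lam, I1, I1 + Lam


def wave_integrals_elliptic(a: float) -> tuple[float, float, float]:
    """(Λ, I1, I2) via complete elliptic integrals, m = a²/(1+a²):

    Λ = (2/π)·sqrt(1+a²)·E(m),  I1 = Λ − (2/π)·K(m)/sqrt(1+a²),  I2 = I1 + Λ.
    Independent special-function route used to cross-check the quadrature."""
    if a == 0.0:
        return 1.0, 0.0, 1.0
    m = a * a / (1.0 + a * a)
    root = math.sqrt(1.0 + a * a)
    Lam = (2.0 / math.pi) * root * special.ellipe(m)
    I1 = Lam - (2.0 / math.pi) * special.ellipk(m) / root
    return Lam, I1, I1 + Lam


def wave_integrals_approx(a: float) -> tuple[float, float, float]:
    """Closed-form approximations (drop the cos 2α cross-terms):

    Λ ≈ sqrt(1 + a²/2),  I1 ≈ (a²/2)/sqrt(1 + a²/2),
    I2 ≈ (1 + a²)/sqrt(1 + a²/2).
    Accurate to within 13% for all a ≤ 2π (h/λ < 1); they preserve the
    identity I2 = I1 + Λ exactly.
    """
    if a < 0:
        raise ValueError("steepness a must be non-negative")
    root = math.sqrt(1.0 + 0.5 * a * a)
    return root, (0.5 * a * a) / root, (1.0 + a * a) / root


def wave_count(L: float, lam: float, h: float) -> float:
    """Number of full waves on a flagellum: n_w = L/(λ·Λ(2πh/λ)).

    The arc length of one wavelength is λΛ, so n_w is constant in time.
    h = 0 gives the straight-line count L/λ.
    """
    if min(L, lam) <= 0 or h < 0:
        raise ValueError("need L, lam > 0 and h >= 0")
    Lam = wave_integrals(2.0 * math.pi * h / lam)[0] if h > 0 else 1.0
    return L / (lam * Lam)


class WaveImputationError(ValueError):
    """No physically admissible value solves the wave-count relation."""


def impute_wave_parameter(
    L: float,
    lam: float | None = None,
    h: float | None = None,
    n_w: float | None = None,
) -> tuple[str, float]:
    """Solve n_w = L/(λΛ(2πh/λ)) for whichever of (lam, h, n_w) is missing.

    Returns ``(name, value)``.  Uniqueness on the physical branch follows
    from Λ being strictly increasing in a.  When the target is infeasible
    (e.g. n_w·λ > L requires Λ < 1) a :class:`WaveImputationError` is raised.
    """
    unknown = [n for n, v in (("lam", lam), ("h", h), ("n_w", n_w)) if v is None]
    if len(unknown) != 1:
        raise ValueError("exactly one of lam, h, n_w must be unknown")
    if L <= 0:
        raise ValueError("L must be positive")
    name = unknown[0]
    if name == "n_w":
        return name, wave_count(L, lam, h)
    if name == "h":
        target = L / (n_w * lam)  # required Λ
        if target < 1.0 - 1e-12:
            raise WaveImputationError(
                f"n_w*lam = {n_w * lam:.4g} exceeds flagellum length L = {L:.4g}: "
                "no amplitude gives arc-length factor below 1"
            )
        if target <= 1.0:
            return name, 0.0
        f = lambda a: wave_integrals(a)[0] - target
        hi = 1.0
        while f(hi) < 0.0:
            hi *= 2.0
            if hi > 1e6:
                raise WaveImputationError("amplitude bracket exceeded")
        a = optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14)
        return name, a * lam / (2.0 * math.pi)
    # name == "lam": n_w and h known; λΛ(2πh/λ) = L/n_w, monotone in λ
    target = L / n_w
    g = lambda lam_: lam_ * wave_integrals(2.0 * math.pi * h / lam_)[0] - target
    # λΛ → 2πh·(2/π)/... as λ→0 gives arc ≈ 4h per wave; λΛ → λ as λ→∞
    lo_arc = 4.0 * h  # infimum of λΛ as λ → 0
    if target <= lo_arc:
        raise WaveImputationError(
            f"L/n_w = {target:.4g} below the minimum arc length 4h = {lo_arc:.4g}"
        )
    lo, hi = 1e-9 * target, target
    if g(hi) < 0.0:  # numerical safety; λΛ(λ) > λ always
        raise WaveImputationError("wavelength bracket failed")
    while g(lo) > 0.0:
        lo *= 0.5
        if lo < 1e-15 * target:
            raise WaveImputationError("wavelength bracket failed")
    return name, optimize.brentq(g, lo, hi, xtol=1e-14 * target, rtol=1e-14)


def net_thrust(
    wave: PlanarWave,
    geom: FlagellateGeometry,
    fluid: FluidMedium,
    U: float,
) -> float:
    """Total propulsive thrust [pN] of N flagella at swimming speed U.

    Thrust = N·n_w·c∥·λ·(c·I1(a) − U·I2(a)); positive when the wave outruns
    the cell, zero at the force-balance speed of a body-less swimmer.
    """
    _, c_par = slender_drag_coeffs(geom.L, geom.b, fluid)
    a = wave.steepness
    _, I1, I2 = wave_integrals(a)
    n_w = wave_count(geom.L, wave.lam, wave.h)
    per = c_par * wave.lam * (wave.wave_speed * I1 - U * I2)
    return _FORCE_TO_PN * geom.N * n_w * per


def _speed_exact(wave: PlanarWave, geom: FlagellateGeometry, fluid: FluidMedium) -> float:
    """U from the thrust balance with exact integrals:

    U/(λf) = I1 / (I2 + 3πη·B·C_FB·Λ/(N·c∥·L)).
    """
    a = wave.steepness
    Lam, I1, I2 = wave_integrals(a)
    _, c_par = slender_drag_coeffs(geom.L, geom.b, fluid)
    cfb = drag_correction_cfb(geom.body)
    body_term = 3.0 * math.pi * fluid.eta * geom.body.B * cfb * Lam / (geom.N * c_par * geom.L)
    return wave.wave_speed * I1 / (I2 + body_term)


def _speed_approx(wave: PlanarWave, geom: FlagellateGeometry, fluid: FluidMedium) -> float:
    """Printed explicit formula (closed-form integrals, c∥ substituted):

    U = (2π²h²f/λ) / [1 + 4π²h²/λ² +
        (3B/(2NL))·C_FB·(1 + 2π²h²/λ²)·(ln(L/b) − 1/2)].
    """
    h2 = wave.h ** 2
    lam = wave.lam
    cfb = drag_correction_cfb(geom.body)
    pi2 = math.pi ** 2
    denom = (
        1.0
        + 4.0 * pi2 * h2 / lam ** 2
        + (3.0 * geom.body.B / (2.0 * geom.N * geom.L))
        * cfb
        * (1.0 + 2.0 * pi2 * h2 / lam ** 2)
        * (math.log(geom.L / geom.b) - 0.5)
    )
    return 2.0 * pi2 * h2 * wave.f / (lam * denom)


def predict_speed(
    rec: OrganismRecord,
    mode: str = "exact",
    fluid: FluidMedium = WATER_25C,
    policy: CollapsePolicy = DEFAULT_POLICY,
) -> EstimateResult:
    """Predicted swimming speed [µm s⁻¹] for a flagellate or spermatozoon.

    Imputation rules: a missing body width W is filled from the group-average
    aspect ratio (0.60 flagellate, 0.47 sperm); one missing wave parameter
    among (λ, h, n_w) is recovered from the wave-count relation; sperm always
    use N = 1.  Every applied rule is recorded on the result.
    """
    if mode not in ("exact", "approx"):
        raise ValueError("mode must be 'exact' or 'approx'")
    is_sperm = rec.group == "spermatozoon"
    aspect = SPERM_ASPECT if is_sperm else FLAGELLATE_ASPECT
    b = SPERM_FILAMENT_RADIUS if is_sperm else FLAGELLATE_FILAMENT_RADIUS

    imputations: list[str] = []
    vals: dict[str, float] = {}
    for name in ("B", "L", "f"):
        got = rec.get(name, policy)
        if got is None:
            return EstimateResult(rec.species, "U_pred", "um/s",
                                  skip_reason=f"missing {name}")
        vals[name], rule = got
        if rule != "point":
            imputations.append(f"{name}: collapsed by {rule}")

    got_w = rec.get("W", policy)
    if got_w is None:
        vals["W"] = aspect * vals["B"]
        imputations.append(f"W imputed from group aspect ratio <W/B> = {aspect}")
    else:
        vals["W"], rule = got_w
        if rule != "point":
            imputations.append(f"W: collapsed by {rule}")
    vals["W"] = min(vals["W"], vals["B"])  # guard: treat round bodies as spheres

    wave_vals: dict[str, float | None] = {}
    for name in ("lam", "h", "n_w"):
        got = rec.get(name, policy)
        if got is None:
            wave_vals[name] = None
        else:
            wave_vals[name], rule = got
            if rule != "point":
                imputations.append(f"{name}: collapsed by {rule}")
    missing = [n for n, v in wave_vals.items() if v is None]
    if "lam" in missing and "h" in missing:
        return EstimateResult(rec.species, "U_pred", "um/s",
                              skip_reason="missing both wavelength and amplitude")
    if len(missing) == 1 and missing[0] != "n_w":
        try:
            name, value = impute_wave_parameter(
                vals["L"],
                lam=wave_vals["lam"],
                h=wave_vals["h"],
                n_w=wave_vals["n_w"],
            )
        except WaveImputationError as exc:
            return EstimateResult(rec.species, "U_pred", "um/s",
                                  skip_reason=f"wave imputation failed: {exc}")
        wave_vals[name] = value
        imputations.append(f"{name} = {value:.4g} imputed from the wave-count relation")

    if wave_vals["h"] == 0.0:
        return EstimateResult(rec.species, "U_pred", "um/s", value=0.0,
                              inputs=vals, imputations=imputations)

    if is_sperm:
        N = 1
        if rec.N is not None:
            imputations.append("N forced to 1 (single-flagellum sperm model)")
    else:
        got_n = rec.get("N", policy)
        N = max(1, round(got_n[0])) if got_n is not None else 1
        if got_n is None:
            imputations.append("N defaulted to 1")

    wave = PlanarWave(lam=wave_vals["lam"], h=wave_vals["h"], f=vals["f"])
    if wave.steepness > MAX_STEEPNESS:
        imputations.append(
            f"steepness a = {wave.steepness:.3g} exceeds 2*pi: closed-form "
            "accuracy statement does not cover this regime"
        )
    geom = FlagellateGeometry(body=SpheroidBody(B=vals["B"], W=vals["W"]),
                              N=N, L=vals["L"], b=b)
    speed = (_speed_exact if mode == "exact" else _speed_approx)(wave, geom, fluid)
    inputs = dict(vals, N=N, b=b, lam=wave.lam, h=wave.h, mode=mode)
    return EstimateResult(rec.species, "U_pred", "um/s", value=speed,
                          inputs=inputs, imputations=imputations)
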