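"""Fluid constants and Reynolds numbers.

Internal unit convention: lengths in µm, speeds in µm s⁻¹, angular rates in
rad s⁻¹, density in kg m⁻³ and dynamic viscosity in mPa·s.  With those units
Re = ρUB/η carries a factor 10⁻⁹ to become dimensionless, which is applied
here so callers never see it.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FluidMedium", "WATER_25C", "reynolds_steady", "reynolds_oscillatory"]

#: (µm · µm/s · kg/m³ / mPa·s) → dimensionless
_RE_SCALE = 1e-9


@dataclass(frozen=True)
class FluidMedium:
    """A Newtonian medium: density ``rho`` [kg m⁻³], viscosity ``eta`` [mPa·s]."""

    rho: float
    eta: float

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.eta <= 0:
            raise ValueError("rho and eta must be positive")


#: Water at 25 °C.  These values reproduce the published Reynolds numbers and
#: motor torques exactly (see tests/test_fluid_shape.py::test_water_constants).
WATER_25C = FluidMedium(rho=997.0, eta=0.89)


def reynolds_steady(fluid: FluidMedium, U: float, B: float) -> float:
    """Steady Reynolds number ρUB/η for a swimmer of size ``B`` [µm] moving
    at ``U`` [µm s⁻¹]."""
    if B <= 0:
        raise ValueError("body length B must be positive")
    if U < 0:
        raise ValueError("speed U must be non-negative")
    return _RE_SCALE * fluid.rho * U * B / fluid.eta


def reynolds_oscillatory(fluid: FluidMedium, omega: float, ell: float) -> float:
    """Oscillatory Reynolds number ρωℓ²/η for an appendage of length ``ell``
    [µm] beating at angular rate ``omega`` [rad s⁻¹]."""
    if ell <= 0:
        raise ValueError("appendage length ell must be positive")
    if omega < 0:
        raise ValueError("angular rate omega must be non-negative")
    return _RE_SCALE * fluid.rho * omega * ell * ell / fluid.eta
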