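"""Per-species estimate container used by every inference routine."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["EstimateResult"]


@dataclass
class EstimateResult:
    """One inferred dynamic quantity for one species.

    Exactly one of ``value`` / ``skip_reason`` is set.  ``inputs`` records the
    collapsed numbers the estimate consumed and ``imputations`` the rules and
    defaults that produced them (range midpoints, default aspect ratios,
    wave-relation inversions, ...), so every output row is auditable.
    """

    species: str
    kind: str  # one of: Re, Re_omega, Tm, U_pred, tau, F, u_hat
    units: str
    value: float | None = None
    inputs: dict = field(default_factory=dict)
    imputations: list = field(default_factory=list)
    skip_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.skip_reason is None):
            raise ValueError("exactly one of value / skip_reason must be set")

    @property
    def ok(self) -> bool:
        return self.value is not None
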