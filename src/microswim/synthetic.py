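"""Seeded synthetic cohorts with the statistical structure of the real groups.

Body sizes and swimming speeds across microswimmer groups are strongly
right-skewed (the published histograms are dominated by their low-value
tails), so the generator draws them from log-normal distributions whose
parameters are obtained by inverting the requested arithmetic mean and
standard deviation.  Per-group defaults carry the published cohort moments
(mean ± s.d. of B, U and the aspect ratio W/B).

:func:`forward_observe` turns a cohort into a recovery benchmark: it fills
each record's swimming speed with the forward prediction of a chosen model
at a known ground-truth parameter (motor torque, surface stress, per-cilium
force or surface slip), optionally perturbed by multiplicative log-normal
noise, so the inverse estimators can be tested against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cilia import speed_constant_force, speed_constant_stress, speed_surface_velocity, cilia_count, CiliaryArray
from .fluid import FluidMedium, WATER_25C
from .records import OrganismRecord, Quantity
from .rft import morphological_factor
from .spheroid import SpheroidBody, surface_area

__all__ = ["CohortConfig", "GROUP_DEFAULTS", "generate_cohort", "forward_observe"]


@dataclass(frozen=True)
class CohortConfig:
    """Moments and missingness for one synthetic cohort.

    ``size_mean/size_sd`` parameterise body length B [µm], ``speed_mean/
    speed_sd`` the swimming speed U [µm s⁻¹], ``aspect_mean/aspect_sd`` the
    ratio W/B (truncated to (0, 1]).  ``missingness`` maps field names to the
    probability that the generated value is blanked.
    """

    group: str
    n: int
    size_mean: float
    size_sd: float
    speed_mean: float
    speed_sd: float
    aspect_mean: float
    aspect_sd: float
    missingness: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name in ("size_mean", "speed_mean", "aspect_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for p in self.missingness.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("missingness rates must lie in [0, 1]")


#: Published cohort moments (mean, s.d.) per taxonomic group.
GROUP_DEFAULTS: dict[str, dict] = {
    "bacteria": dict(size=(5.79, 9.33), speed=(48.33, 98.47), aspect=(0.33, 0.20)),
    "spirochaete": dict(size=(18.59, 13.02), speed=(17.94, 18.84), aspect=(0.02, 0.01)),
    "spiroplasma": dict(size=(5.72, 0.28), speed=(1.69, 0.81), aspect=(0.03, 0.005)),
    "archaea": dict(size=(2.71, 2.12), speed=(89.18, 126.57), aspect=(0.11, 0.06)),
    "flagellate": dict(size=(38.87, 56.64), speed=(186.70, 208.77), aspect=(0.60, 0.27)),
    "spermatozoon": dict(size=(12.21, 17.25), speed=(127.23, 78.49), aspect=(0.47, 0.30)),
    "ciliate": dict(size=(194.87, 207.45), speed=(1147.57, 1375.64), aspect=(0.49, 0.22)),
}


def default_config(group: str, n: int, seed: int = 0, missingness: dict | None = None) -> CohortConfig:
    """Cohort config pre-filled with the published group moments."""
    d = GROUP_DEFAULTS[group]
    return CohortConfig(
        group=group, n=n,
        size_mean=d["size"][0], size_sd=d["size"][1],
        speed_mean=d["speed"][0], speed_sd=d["speed"][1],
        aspect_mean=d["aspect"][0], aspect_sd=d["aspect"][1],
        missingness=missingness or {}, seed=seed,
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of ln X for a log-normal with the given arithmetic moments."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def _draw_lognormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    mu, sigma = _lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=n)


def generate_cohort(config: CohortConfig) -> list[OrganismRecord]:
    """Draw ``config.n`` organism records; fully deterministic given the seed.

    Sizes and speeds are log-normal with the configured arithmetic moments;
    aspect ratios are normal draws truncated (by redraw) into (0, 1]; flagellar
    geometry (L, λ, h) scales with the body so that downstream models always
    receive physically sensible inputs.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child)
               for name, child in zip(
                   ("B", "U", "aspect", "L", "lam", "h", "f", "miss"),
                   ss.spawn(8))}
    n = config.n
    B = _draw_lognormal(streams["B"], config.size_mean, config.size_sd, n)
    U = _draw_lognormal(streams["U"], config.speed_mean, config.speed_sd, n)
    aspect = streams["aspect"].normal(config.aspect_mean, config.aspect_sd, size=n)
    for _ in range(100):  # redraw out-of-range aspects; (0, 1] support
        bad = (aspect <= 0.0) | (aspect > 1.0)
        if not bad.any():
            break
        aspect[bad] = streams["aspect"].normal(config.aspect_mean, config.aspect_sd, size=int(bad.sum()))
    aspect = np.clip(aspect, 1e-3, 1.0)

    # Appendage geometry scaled to the body: flagellum ~2x body length for
    # prokaryotes/flagellates, ~5x for sperm, short cilia for ciliates.
    L_scale = {"spermatozoon": 5.0, "ciliate": 0.08}.get(config.group, 2.0)
    L = B * L_scale * streams["L"].lognormal(0.0, 0.25, size=n)
    lam = 0.45 * L * streams["lam"].lognormal(0.0, 0.2, size=n)
    h = 0.12 * lam * streams["h"].lognormal(0.0, 0.2, size=n)
    f = streams["f"].lognormal(math.log(30.0), 0.4, size=n)

    miss_rng = streams["miss"]
    records: list[OrganismRecord] = []
    for i in range(n):
        fields = {
            "B": B[i],
            "W": aspect[i] * B[i],
            "U": U[i],
            "L": L[i],
            "lam": lam[i],
            "h": h[i],
            "f": f[i],
        }
        for name, p in config.missingness.items():
            if name in fields and p > 0.0 and miss_rng.random() < p:
                fields[name] = None
        kw = {k: Quantity(point=float(v)) for k, v in fields.items() if v is not None}
        records.append(
            OrganismRecord(species=f"synthetic {config.group} {i:04d}",
                           group=config.group, notes="synthetic cohort", **kw)
        )
    return records


_MODELS = ("rft_torque", "stress", "force", "surface")


def forward_observe(
    records: list[OrganismRecord],
    model: str,
    truth: float | tuple[float, float],
    fluid: FluidMedium = WATER_25C,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[list[OrganismRecord], list[float]]:
    """Fill each record's U with a forward-model prediction at known truth.

    ``model`` selects the forward map: ``rft_torque`` (motor torque T_m*
    [pN·nm] through the morphological factor), ``stress`` (τ* [mPa]),
    ``force`` (F* [pN] per cilium), ``surface`` (û_s* [µm s⁻¹]).  ``truth``
    is either a single value shared by every record or a ``(lo, hi)``
    log-uniform range sampled per record.  Multiplicative log-normal noise
    with coefficient of variation ``noise_cv`` perturbs the speeds.

    Records lacking the geometry the model needs are passed through
    unchanged (truth entry NaN).  Returns ``(new_records, truths)``.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {_MODELS}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _MODELS.index(model)]))
    out: list[OrganismRecord] = []
    truths: list[float] = []
    for rec in records:
        if isinstance(truth, tuple):
            lo, hi = truth
            t = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        else:
            t = float(truth)
        try:
            u = _forward_speed(rec, model, t, fluid)
        except (ValueError, KeyError):
            out.append(rec)
            truths.append(math.nan)
            continue
        if noise_cv > 0.0:
            sigma = math.sqrt(math.log1p(noise_cv ** 2))
            u *= float(rng.lognormal(-0.5 * sigma * sigma, sigma))
        out.append(replace(rec, U=Quantity(point=u)))
        truths.append(t)
    return out, truths


def _collapsed(rec: OrganismRecord, name: str) -> float:
    got = rec.get(name)
    if got is None:
        raise KeyError(name)
    return got[0]


def _forward_speed(rec: OrganismRecord, model: str, truth: float, fluid: FluidMedium) -> float:
    B = _collapsed(rec, "B")
    W = min(_collapsed(rec, "W"), B)
    body = SpheroidBody(B=B, W=W)
    if model == "rft_torque":
        xi_sq = morphological_factor(body, _collapsed(rec, "L"), _collapsed(rec, "h"))
        return truth / (fluid.eta * xi_sq)
    if model == "stress":
        return speed_constant_stress(truth, body, fluid)
    if model == "force":
        N, _, _ = cilia_count(
            CiliaryArray(
                N=rec.get("N")[0] if rec.N is not None else None,
                kappa=rec.get("kappa")[0] if rec.kappa is not None else None,
                d=rec.get("d")[0] if rec.d is not None else None,
            ),
            surface_area(body),
        )
        return speed_constant_force(truth, N, body, fluid)
    # surface
    return speed_surface_velocity(truth, body.eccentricity)
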