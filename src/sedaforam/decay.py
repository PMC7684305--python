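"""Burial model for planktonic vs benthic foraminiferal DNA in sediment.

The model captures the competition between two DNA pools down a sediment
core. Living benthic foraminifera inhabit the top of the sediment (the
inhabited zone, by default 0-10 cm) with a standing stock that declines
linearly from ``B_surface`` (default 99, arbitrary units) at the surface to
``B_bottom`` (default 1) at the bottom of the inhabited zone. Planktonic
eDNA arrives at the seafloor and decays exponentially with burial,

    N(z) = N0 * exp(-lambda_p * tau_scale * z),

while below the inhabited zone the remaining benthic DNA decays by the same
law with a smaller decay constant ``lambda_b`` (benthic DNA is buried with
its cells and never transits the water column). The observable is the
planktonic amplicon fraction P/(P+B): near zero at the surface where living
benthic DNA dominates, maximal at the base of the inhabited zone, and slowly
declining below it because lambda_b < lambda_p.

The printed decay law has no explicit depth variable; depth enters through
``tau_scale`` (decay-coordinate units per cm, default 0.02), which makes the
default fraction profile increase through the inhabited zone. Only the shape
of the profile is asserted by this parameterization, not the field
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DecayParams",
    "DepthProfile",
    "FitResult",
    "benthic_abundance",
    "planktonic_abundance",
    "fraction_profile",
    "fit_params",
]


@dataclass
class DecayParams:
    """Parameters of the burial-decay model (abundances in arbitrary units)."""

    N0: float = 1.0  #: planktonic eDNA abundance delivered at the surface
    lambda_p: float = 1.0  #: planktonic decay constant
    tau_scale: float = 0.02  #: decay-coordinate units per cm of depth
    B_surface: float = 99.0  #: living benthic abundance at 0 cm
    B_bottom: float = 1.0  #: living benthic abundance at the zone bottom
    z_inhabited: float = 10.0  #: depth (cm) of the inhabited zone
    lambda_b: float = 0.9  #: benthic eDNA decay constant below the zone

    def __post_init__(self) -> None:
        if min(self.N0, self.B_surface, self.B_bottom) <= 0:
            raise ValueError("abundances must be positive")
        if self.B_surface <= self.B_bottom:
            raise ValueError("B_surface must exceed B_bottom")
        if self.z_inhabited <= 0:
            raise ValueError("z_inhabited must be positive")
        if not self.lambda_b < self.lambda_p:
            raise ValueError("lambda_b must be smaller than lambda_p")


@dataclass
class DepthProfile:
    depths: np.ndarray
    planktonic: np.ndarray
    benthic: np.ndarray
    fraction: np.ndarray


@dataclass
class FitResult:
    params: DecayParams
    free: tuple[str, ...]
    rss: float
    residuals: np.ndarray
    converged: bool


def _check_depth(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    return z


def planktonic_abundance(z, params: DecayParams = DecayParams()):
    """Planktonic eDNA abundance at depth ``z`` cm: N0 * exp(-lambda_p * tau * z)."""
    z = _check_depth(z)
    return params.N0 * np.exp(-params.lambda_p * params.tau_scale * z)


def benthic_abundance(z, params: DecayParams = DecayParams()):
    """Benthic DNA abundance at depth ``z`` cm.

    Linear decline through the inhabited zone, exponential decay (constant
    ``lambda_b``) below it, continuous at the boundary.
    """
    z = _check_depth(z)
    slope = (params.B_bottom - params.B_surface) / params.z_inhabited
    living = params.B_surface + slope * z
    buried = params.B_bottom * np.exp(
        -params.lambda_b * params.tau_scale * (z - params.z_inhabited)
    )
    return np.where(z <= params.z_inhabited, living, buried)


def fraction_profile(depths, params: DecayParams = DecayParams()) -> DepthProfile:
    """Planktonic amplicon fraction P/(P+B) over a sorted depth grid."""
    z = _check_depth(depths)
    if np.any(np.diff(z) < 0):
        raise ValueError("depths must be sorted ascending")
    p = planktonic_abundance(z, params)
    b = benthic_abundance(z, params)
    return DepthProfile(z, p, b, p / (p + b))


_FIT_BOUNDS = {
    "N0": (1e-9, np.inf),
    "lambda_p": (1e-9, np.inf),
    "tau_scale": (1e-9, np.inf),
    "B_surface": (1e-9, np.inf),
    "lambda_b": (1e-9, np.inf),
}


def fit_params(
    depths,
    fractions,
    free: tuple[str, ...] = ("lambda_p", "tau_scale"),
    start: DecayParams | None = None,
) -> FitResult:
    """Least-squares fit of decay parameters to observed (depth, fraction) points.

    The residual is taken on the logit of the fraction, which respects the
    (0, 1) range and linearizes the exponential tails. Parameters named in
    ``free`` are estimated (positivity-bounded); all others are held at the
    values in ``start``. ``lambda_p`` is additionally bounded below by
    ``lambda_b`` so the fitted parameters remain a valid :class:`DecayParams`.
    Non-convergence is reported through ``converged``, never raised.
    """
    z = _check_depth(depths)
    y = np.asarray(fractions, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("fractions must lie strictly inside (0, 1)")
    if len(z) != len(y):
        raise ValueError("depths and fractions differ in length")
    unknown = [p for p in free if p not in _FIT_BOUNDS]
    if unknown:
        raise ValueError(f"cannot fit parameters: {unknown}")
    if len(z) < len(free):
        raise ValueError(f"need at least {len(free)} points to fit {len(free)} params")
    base = start if start is not None else DecayParams()

    target = np.log(y / (1 - y))

    def build(x: np.ndarray) -> DecayParams:
        return replace(base, **dict(zip(free, x)))

    def resid(x: np.ndarray) -> np.ndarray:
        p = replace_unchecked(base, dict(zip(free, x)))
        f = _raw_fraction(z, p)
        f = np.clip(f, 1e-12, 1 - 1e-12)
        return np.log(f / (1 - f)) - target

    lo = [
        base.lambda_b * (1 + 1e-9) if name == "lambda_p" else _FIT_BOUNDS[name][0]
        for name in free
    ]
    hi = [_FIT_BOUNDS[name][1] for name in free]
    x0 = np.clip([getattr(base, name) * 1.5 for name in free], lo, hi)
    sol = least_squares(resid, x0=x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
    fitted = build(sol.x)
    res = resid(sol.x)
    return FitResult(
        params=fitted,
        free=tuple(free),
        rss=float(np.sum(res**2)),
        residuals=res,
        converged=bool(sol.success),
    )


def replace_unchecked(base: DecayParams, updates: dict[str, float]) -> DecayParams:
    """`dataclasses.replace` variant that tolerates transiently invalid
    combinations explored by the optimizer (bounds keep the final result valid)."""
    obj = object.__new__(DecayParams)
    for f in base.__dataclass_fields__:
        object.__setattr__(obj, f, updates.get(f, getattr(base, f)))
    return obj


def _raw_fraction(z: np.ndarray, params: DecayParams) -> np.ndarray:
    p = params.N0 * np.exp(-params.lambda_p * params.tau_scale * z)
    slope = (params.B_bottom - params.B_surface) / params.z_inhabited
    b = np.where(
        z <= params.z_inhabited,
        params.B_surface + slope * z,
        params.B_bottom
        * np.exp(-params.lambda_b * params.tau_scale * (z - params.z_inhabited)),
    )
    return p / (p + b)
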