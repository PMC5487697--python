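"""Reduce vertical sensor casts to per-station, per-occasion scalars.

A survey cast is a list of (depth, variable, value) samples taken while an
instrument package is lowered through the water column.  Two reductions are
supported:

* a depth-band arithmetic mean (e.g. the 0-3 m surface layer) for scalar
  variables such as salinity, temperature, oxygen, CDOM and chlorophyll *a*;
* a log-linear least-squares fit of the light attenuation model
  ``I(d) = I0 * exp(-k * d)`` for PAR profiles, yielding the extinction
  coefficient ``k`` (m^-1).

Both operations are pure and format-agnostic; the long-format reader in
:mod:`monalloc.io` produces the :class:`Cast` objects consumed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import EmptyBandError, ProfileFitError

__all__ = [
    "Cast",
    "LightProfile",
    "ExtinctionFit",
    "band_mean",
    "fit_extinction",
    "euphotic_depth",
]


@dataclass(frozen=True)
class Cast:
    """One station visit: samples of several variables along the depth axis.

    ``samples`` holds (depth_m, variable, value) triples with depth >= 0.
    """

    station_id: str
    day: float
    samples: Sequence[tuple[float, str, float]] = field(default_factory=tuple)

    def __post_init__(self):
        for depth, variable, _ in self.samples:
            if depth < 0:
                raise ValueError(
                    f"negative depth {depth} in cast {self.station_id!r} day {self.day}"
                )
            if not variable:
                raise ValueError("empty variable name in cast sample")


@dataclass(frozen=True)
class LightProfile:
    """A vertical irradiance profile used to fit the attenuation coefficient."""

    station_id: str
    day: float
    depths: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self):
        depths = np.asarray(self.depths, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "irradiance", irr)
        if depths.ndim != 1 or depths.shape != irr.shape:
            raise ValueError("depths and irradiance must be 1-D arrays of equal length")
        if depths.size and depths.min() < 0:
            raise ValueError("depths must be non-negative")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("depths must be strictly increasing")


class ExtinctionFit(NamedTuple):
    """Result of the log-linear attenuation fit."""

    k: float
    i0: float
    r_squared: float


def band_mean(cast: Cast, variable: str, depth_min: float, depth_max: float) -> float:
    """Arithmetic mean of ``variable`` over the closed depth band [depth_min, depth_max].

    Boundary samples are included.  Raises :class:`EmptyBandError` when the cast
    holds no sample of the variable inside the band.
    """
    if not depth_min < depth_max:
        raise ValueError(f"depth_min must be < depth_max (got {depth_min}, {depth_max})")
    values = [
        v
        for depth, var, v in cast.samples
        if var == variable and depth_min <= depth <= depth_max
    ]
    if not values:
        raise EmptyBandError(cast.station_id, cast.day, variable, depth_min, depth_max)
    return float(np.mean(values))


def fit_extinction(
    profile: LightProfile,
    detection_floor: float = 0.0,
    min_r_squared: float | None = None,
) -> ExtinctionFit:
    """Fit ``I(d) = I0 * exp(-k*d)`` by ordinary least squares on log irradiance.

    Points with irradiance at or below ``detection_floor`` (default 0, i.e. only
    nonpositive readings are invalid) are rejected: with the default floor any
    nonpositive irradiance raises, because its logarithm is undefined; with a
    positive floor, dim readings are silently dropped before fitting.  At least
    3 usable points are required.

    Returns (k, i0, r_squared) where ``k = -slope`` of the log-linear fit and
    ``i0 = exp(intercept)``.  If ``min_r_squared`` is given and the fit quality
    falls below it, a warning is emitted (the fit is still returned; dropping is
    the caller's decision).
    """
    depths = profile.depths
    irr = profile.irradiance
    if detection_floor <= 0 and np.any(irr <= 0):
        raise ProfileFitError(
            f"nonpositive irradiance in profile {profile.station_id!r} day "
            f"{profile.day}: log-linear fit undefined"
        )
    usable = irr > detection_floor
    if usable.sum() < 3:
        raise ProfileFitError(
            f"fewer than 3 usable points above detection floor {detection_floor} "
            f"in profile {profile.station_id!r} day {profile.day}"
        )
    d = depths[usable]
    y = np.log(irr[usable])
    # OLS of ln(I) on depth: design matrix [d, 1]
    coeffs, *_ = np.linalg.lstsq(np.column_stack([d, np.ones_like(d)]), y, rcond=None)
    slope, intercept = coeffs
    resid = y - (slope * d + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    fit = ExtinctionFit(k=float(-slope), i0=float(math.exp(intercept)), r_squared=r2)
    if min_r_squared is not None and fit.r_squared < min_r_squared:
        warnings.warn(
            f"extinction fit r^2 = {fit.r_squared:.3f} below {min_r_squared} "
            f"(station {profile.station_id!r}, day {profile.day})",
            stacklevel=2,
        )
    return fit


def euphotic_depth(k: float, fraction: float = 0.01) -> float:
    """Depth (m) at which irradiance falls to ``fraction`` of the surface value.

    With the default ``fraction = 0.01`` this is the conventional euphotic
    depth, ``-ln(0.01)/k``.
    """
    if k <= 0:
        raise ValueError("no positive attenuation: k must be > 0")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return -math.log(fraction) / k
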