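"""Depth standardization of per-Gy yields.

Converts per-Gy yields into depth distributions standardized to a common
irradiation time, using the dose rate at each depth:

    quantity(depth) = yield_per_Gy(LET(depth)) * dose_rate(depth) * t/60

The LET-to-depth mapping is a user-supplied (or synthetic) table; beam
transport is not modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DomainError

#: Standard exposure used for replotting, seconds.
DEFAULT_EXPOSURE_S = 60.0


@dataclass(frozen=True)
class DepthPoint:
    """One depth position of a scan: depth (mm), LET (keV/µm), dose rate (Gy/min)."""

    depth_mm: float
    let_keV_um: float
    dose_rate_Gy_min: float

    def __post_init__(self) -> None:
        if self.depth_mm < 0:
            raise DomainError(f"depth must be >= 0 mm, got {self.depth_mm}")
        if self.dose_rate_Gy_min <= 0:
            raise DomainError(f"dose rate must be > 0 Gy/min, got {self.dose_rate_Gy_min}")


@dataclass(frozen=True)
class DepthProfile:
    """Standardized quantity vs depth for one yield label."""

    depths_mm: tuple[float, ...]
    values_uM: tuple[float, ...]
    quantity: str
    exposure_s: float

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise DomainError("exposure must be > 0 s")
        d = np.asarray(self.depths_mm, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise DomainError("depths must be strictly increasing")


def standardize_by_time(yield_per_gray: float, dose_rate_Gy_min: float,
                        exposure_s: float = DEFAULT_EXPOSURE_S) -> float:
    """Amount produced in ``exposure_s`` seconds at the given dose rate.

    yield_per_gray * dose_rate * (exposure_s / 60).
    """
    if dose_rate_Gy_min <= 0:
        raise DomainError(f"dose rate must be > 0 Gy/min, got {dose_rate_Gy_min}")
    if exposure_s <= 0:
        raise DomainError(f"exposure must be > 0 s, got {exposure_s}")
    return yield_per_gray * dose_rate_Gy_min * (exposure_s / 60.0)


def _resolve_yield(let: float, yields_by_let: Mapping[float, float],
                   mode: str, let_tolerance: float) -> float:
    lets = sorted(yields_by_let)
    if mode == "nearest":
        nearest = min(lets, key=lambda l: abs(l - let))
        if abs(nearest - let) > let_tolerance:
            raise DomainError(
                f"LET {let} keV/µm not within {let_tolerance} of any tabulated LET")
        return yields_by_let[nearest]
    if mode == "interp":
        return float(np.interp(let, lets, [yields_by_let[l] for l in lets]))
    raise DomainError(f"unknown LET lookup mode {mode!r}")


def build_profile(
    points: Sequence[DepthPoint],
    yields_by_let: Mapping[float, float],
    quantity: str = "total_oh",
    exposure_s: float = DEFAULT_EXPOSURE_S,
    mode: str = "nearest",
    let_tolerance: float = 10.0,
) -> DepthProfile:
    """Standardized depth profile from a scan and a per-Gy yield table.

    Each point's LET is resolved in ``yields_by_let`` either by nearest
    tabulated LET within ``let_tolerance`` keV/µm or by linear interpolation
    (``mode="interp"``); an unresolvable LET raises an error naming the
    offending depth.
    """
    if not points:
        raise DomainError("depth scan is empty")
    if not yields_by_let:
        raise DomainError("per-Gy yields mapping is empty")
    ordered = sorted(points, key=lambda p: p.depth_mm)
    depths, values = [], []
    for p in ordered:
        try:
            y = _resolve_yield(p.let_keV_um, yields_by_let, mode, let_tolerance)
        except DomainError as exc:
            raise DomainError(f"depth {p.depth_mm} mm: {exc}") from exc
        depths.append(p.depth_mm)
        values.append(standardize_by_time(y, p.dose_rate_Gy_min, exposure_s))
    return DepthProfile(tuple(depths), tuple(values), quantity, exposure_s)
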