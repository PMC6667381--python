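"""Conversions between concentration, linear trap density, and molecular spacing.

Track-localized radicals sample spin traps along a line, not a volume, so the
relevant "how many detectors" quantity is a *linear* density: the cube root of
the molecular number density, expressed per micrometre.  This module fixes that
convention for the whole package and provides the exact forward/inverse
conversions plus the derived mean inter-molecule spacing (``1/rho``) and the
count of water molecules fitting in such a gap.

All conversions are exact (no display rounding); rounding to the significant
figures used in reports happens only at the presentation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DomainError

#: Avogadro constant (CODATA exact), 1/mol.
AVOGADRO = 6.02214076e23

#: Default effective diameter of a water molecule, nm (documented assumption).
WATER_DIAMETER_NM = 0.30

_CONC_UNITS = {"mol/L": 1.0, "mmol/L": 1e-3, "umol/L": 1e-6, "µmol/L": 1e-6}


@dataclass(frozen=True)
class Concentration:
    """Amount-of-substance concentration with an explicit unit tag.

    Parameters
    ----------
    value:
        Non-negative magnitude in ``unit``.
    unit:
        One of ``mol/L``, ``mmol/L``, ``umol/L`` (``µmol/L`` accepted).
    """

    value: float
    unit: str = "mol/L"

    def __post_init__(self) -> None:
        if self.unit not in _CONC_UNITS:
            raise DomainError(f"unknown concentration unit {self.unit!r}")
        if not math.isfinite(self.value) or self.value < 0:
            raise DomainError(f"concentration must be finite and >= 0, got {self.value}")

    @property
    def molar(self) -> float:
        """Value expressed in mol/L."""
        return self.value * _CONC_UNITS[self.unit]

    def to(self, unit: str) -> "Concentration":
        if unit not in _CONC_UNITS:
            raise DomainError(f"unknown concentration unit {unit!r}")
        return Concentration(self.molar / _CONC_UNITS[unit], unit)


@dataclass(frozen=True)
class LinearDensity:
    """Count of molecules per unit length along a track, in 1/µm."""

    per_um: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.per_um) or self.per_um < 0:
            raise DomainError(f"linear density must be finite and >= 0, got {self.per_um}")


@dataclass(frozen=True)
class Spacing:
    """Mean distance between neighbouring molecules, in nm."""

    nm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.nm) or self.nm <= 0:
            raise DomainError(f"spacing must be finite and > 0, got {self.nm}")


# ---------------------------------------------------------------------------
# float-level kernels (mol/L <-> 1/µm); the typed API wraps these
# ---------------------------------------------------------------------------

def molar_to_per_um(c_molar: float) -> float:
    """Linear density (1/µm) of a solute at molar concentration ``c_molar``.

    rho = (c * N_A * 1e3 / m^3)^(1/3), scaled from 1/m to 1/µm.
    """
    if not math.isfinite(c_molar) or c_molar < 0:
        raise DomainError(f"concentration must be finite and >= 0, got {c_molar}")
    return (c_molar * AVOGADRO * 1e3) ** (1.0 / 3.0) * 1e-6


def per_um_to_molar(rho_per_um: float) -> float:
    """Inverse of :func:`molar_to_per_um`: c = rho^3 / (N_A * 1e3)."""
    if not math.isfinite(rho_per_um) or rho_per_um < 0:
        raise DomainError(f"linear density must be finite and >= 0, got {rho_per_um}")
    return (rho_per_um * 1e6) ** 3 / (AVOGADRO * 1e3)


# ---------------------------------------------------------------------------
# typed operations
# ---------------------------------------------------------------------------

def concentration_to_linear_density(c: Concentration) -> LinearDensity:
    """Convert a concentration to the linear (per-µm) trap density."""
    return LinearDensity(molar_to_per_um(c.molar))


def linear_density_to_concentration(rho: LinearDensity) -> Concentration:
    """Convert a linear trap density back to a molar concentration."""
    return Concentration(per_um_to_molar(rho.per_um), "mol/L")


def mean_spacing(rho: LinearDensity) -> Spacing:
    """Mean gap between neighbouring molecules: 1/rho, in nm."""
    if rho.per_um <= 0:
        raise DomainError("mean spacing undefined for zero density")
    return Spacing(1e3 / rho.per_um)  # 1 µm = 1000 nm


def water_molecules_in_gap(gap: Spacing, water_diameter: Spacing | None = None) -> int:
    """Number of water molecules fitting end-to-end in ``gap``.

    floor(gap / diameter) with a 1e-9 relative guard so that quotients that
    are integers up to floating-point error (e.g. 6.6/0.3) count fully.
    """
    diameter = water_diameter if water_diameter is not None else Spacing(WATER_DIAMETER_NM)
    q = gap.nm / diameter.nm
    return int(math.floor(q + 1e-9))
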