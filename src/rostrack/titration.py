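"""Three-phase analysis of spin-trap titration curves.

A titration of DMPO against a fixed dose produces, on the linear-density axis,
a characteristic three-phase profile: a linear rise through the origin, a
plateau-like segment, and a second linear rise through the origin.  The
intersection of the first two fitted lines estimates the density and amount of
the sparse radical population; the third-phase line evaluated at a reference
density (1,000 µm^-1 by default) estimates total radical generation.

Segmentation is an exhaustive search over contiguous three-way partitions of
the density-ordered points, minimising the summed squared residual of the
three per-phase fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import units
from .exceptions import DomainError, FitError, NoPlateauError

#: Reference density at which the third-phase line is read off, 1/µm.
REFERENCE_DENSITY_PER_UM = 1000.0


@dataclass(frozen=True)
class TitrationCurve:
    """Paired (DMPO concentration, DMPO-OH concentration) points at one dose.

    dmpo_mM are spin-trap concentrations in mmol/L (strictly increasing),
    dmpoh_uM are adduct concentrations in µmol/L, dose_Gy is the absorbed
    dose, modality is ``"xray"`` or ``"carbon"`` and let_keV_um is required
    only for carbon.
    """

    dmpo_mM: tuple[float, ...]
    dmpoh_uM: tuple[float, ...]
    dose_Gy: float
    modality: str = "xray"
    let_keV_um: float | None = None

    def __post_init__(self) -> None:
        dmpo = np.asarray(self.dmpo_mM, dtype=float)
        dmpoh = np.asarray(self.dmpoh_uM, dtype=float)
        if dmpo.size != dmpoh.size:
            raise DomainError("dmpo_mM and dmpoh_uM must have equal length")
        if dmpo.size < 6:
            raise DomainError(f"titration curve needs >= 6 points, got {dmpo.size}")
        if np.any(dmpo < 0) or np.any(dmpoh < 0):
            raise DomainError("titration concentrations must be >= 0")
        if np.any(np.diff(dmpo) <= 0):
            raise DomainError("dmpo_mM must be strictly increasing")
        if not self.dose_Gy > 0:
            raise DomainError(f"dose must be > 0 Gy, got {self.dose_Gy}")
        if self.modality not in {"xray", "carbon"}:
            raise DomainError(f"modality must be 'xray' or 'carbon', got {self.modality!r}")

    def __len__(self) -> int:
        return len(self.dmpo_mM)


@dataclass(frozen=True)
class DensityCurve:
    """Titration points on the linear-density axis (1/µm vs µmol/L)."""

    density_per_um: tuple[float, ...]
    dmpoh_uM: tuple[float, ...]
    dose_Gy: float
    modality: str = "xray"
    let_keV_um: float | None = None


@dataclass(frozen=True)
class PhaseModel:
    """Phase assignment and fitted line parameters of a three-phase curve.

    s1 and s3 are slopes of the origin-constrained first/third-phase lines,
    (a2, b2) are intercept and slope of the free second-phase line, sse is
    the total squared residual over all three fits.
    """

    assignment: tuple[int, ...]
    s1: float
    a2: float
    b2: float
    s3: float
    sse: float
    density_per_um: tuple[float, ...] = field(default=(), repr=False)
    dmpoh_uM: tuple[float, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class SparseDenseEstimate:
    """Derived sparse/total radical quantities for one titration."""

    sparse_density_per_um: float
    sparse_concentration_mM: float
    sparse_amount_uM: float
    total_amount_uM: float
    dose_Gy: float
    model: PhaseModel


def to_density_axis(curve: TitrationCurve) -> DensityCurve:
    """Replace each DMPO concentration by its linear density (order kept)."""
    dens = tuple(units.molar_to_per_um(c * 1e-3) for c in curve.dmpo_mM)
    return DensityCurve(dens, curve.dmpoh_uM, curve.dose_Gy, curve.modality, curve.let_keV_um)


def _origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope through the origin, clamped at 0 with a warning."""
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise FitError("origin-constrained fit needs a non-zero abscissa")
    s = float(np.dot(x, y)) / sxx
    if s < 0:
        warnings.warn("negative origin-constrained slope clamped to 0", stacklevel=3)
        s = 0.0
    return s


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares intercept and slope."""
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise FitError("OLS design is degenerate (constant abscissa)")
    b = float(np.sum((x - xbar) * (y - ybar))) / sxx
    a = float(ybar - b * xbar)
    del n
    return a, b


def fit_phase_lines(
    density_per_um: Sequence[float],
    dmpoh_uM: Sequence[float],
    assignment: Sequence[int],
) -> PhaseModel:
    """Fit the three per-phase lines for a given contiguous phase assignment.

    Phase 1 and 3: least squares through the origin (slope = Σxy/Σx²).
    Phase 2: ordinary least squares with free intercept.
    """
    x = np.asarray(density_per_um, dtype=float)
    y = np.asarray(dmpoh_uM, dtype=float)
    lab = np.asarray(assignment, dtype=int)
    if not (x.size == y.size == lab.size):
        raise DomainError("points and assignment must have equal length")
    if sorted(set(lab.tolist())) != [1, 2, 3]:
        raise FitError("assignment must use exactly the phase labels 1, 2, 3")
    if np.any(np.diff(lab) < 0):
        raise FitError("assignment must be contiguous in density order")
    for phase in (1, 2, 3):
        if int(np.sum(lab == phase)) < 2:
            raise FitError(f"phase {phase} has fewer than 2 points")

    m1, m2, m3 = lab == 1, lab == 2, lab == 3
    s1 = _origin_slope(x[m1], y[m1])
    a2, b2 = _ols_line(x[m2], y[m2])
    s3 = _origin_slope(x[m3], y[m3])
    sse = (
        float(np.sum((y[m1] - s1 * x[m1]) ** 2))
        + float(np.sum((y[m2] - (a2 + b2 * x[m2])) ** 2))
        + float(np.sum((y[m3] - s3 * x[m3]) ** 2))
    )
    return PhaseModel(tuple(lab.tolist()), s1, a2, b2, s3, sse,
                      tuple(x.tolist()), tuple(y.tolist()))


def _has_plateau(model: PhaseModel) -> bool:
    scale = max(abs(model.s1), abs(model.b2), 1e-30)
    return model.s1 - model.b2 > 1e-9 * scale


def segment_phases(curve: DensityCurve, min_per_phase: int = 2) -> PhaseModel:
    """Exhaustive minimum-SSE contiguous three-way segmentation.

    Enumerates every contiguous partition with at least ``min_per_phase``
    points per phase, fits the three lines for each, and returns the valid
    partition (first-phase slope exceeding the plateau slope) with the
    smallest total SSE.  Ties are broken toward the widest plateau span.
    """
    if min_per_phase < 2:
        raise DomainError("min_per_phase must be >= 2")
    order = np.argsort(curve.density_per_um)
    x = np.asarray(curve.density_per_um, dtype=float)[order]
    y = np.asarray(curve.dmpoh_uM, dtype=float)[order]
    n = x.size
    if n < 3 * min_per_phase:
        raise DomainError(f"need >= {3 * min_per_phase} points, got {n}")
    if np.any(np.diff(x) <= 0):
        raise DomainError("densities must be distinct")

    best: PhaseModel | None = None
    best_key: tuple[float, float] | None = None
    for i in range(min_per_phase, n - 2 * min_per_phase + 1):
        for j in range(i + min_per_phase, n - min_per_phase + 1):
            lab = np.empty(n, dtype=int)
            lab[:i], lab[i:j], lab[j:] = 1, 2, 3
            model = fit_phase_lines(x, y, lab)
            if not _has_plateau(model):
                continue
            span = x[j - 1] - x[i]
            key = (model.sse, -span)
            if best_key is None or key < best_key:
                best, best_key = model, key
    if best is None:
        raise NoPlateauError("no plateau detected: no contiguous partition has s1 > b2")
    return best


def intersect_sparse(model: PhaseModel) -> tuple[float, float]:
    """Intersection of the phase-1 and phase-2 lines.

    Returns ``(density 1/µm, amount µmol/L)``; the x-coordinate estimates the
    local density of the sparse population and the y-coordinate its amount.
    """
    if not _has_plateau(model):
        raise FitError("phase-1 slope does not exceed plateau slope; no intersection")
    x_star = model.a2 / (model.s1 - model.b2)
    y_star = model.s1 * x_star
    return x_star, y_star


def total_oh(model: PhaseModel,
             reference_density: float = REFERENCE_DENSITY_PER_UM) -> float:
    """Third-phase line evaluated at the reference density (µmol/L)."""
    return model.s3 * reference_density


def analyze_titration(
    curve: TitrationCurve,
    phases: tuple[int, int, int] | None = None,
    min_per_phase: int = 2,
    plateau_flat: bool = False,
    reference_density: float = REFERENCE_DENSITY_PER_UM,
) -> SparseDenseEstimate:
    """Full titration analysis: density axis, segmentation, fits, estimates.

    Parameters
    ----------
    curve:
        Input titration curve on the concentration axis.
    phases:
        Optional manual phase sizes ``(n1, n2, n3)`` overriding segmentation.
    min_per_phase:
        Minimum points per phase for the exhaustive search.
    plateau_flat:
        Force the plateau slope ``b2`` to zero (phase 2 as a constant).
    reference_density:
        Density at which total generation is read off, 1/µm.
    """
    dcurve = to_density_axis(curve)
    if phases is not None:
        if sum(phases) != len(curve):
            raise DomainError(f"manual phases {phases} do not sum to {len(curve)} points")
        lab = np.repeat([1, 2, 3], phases)
        order = np.argsort(dcurve.density_per_um)
        x = np.asarray(dcurve.density_per_um, dtype=float)[order]
        y = np.asarray(dcurve.dmpoh_uM, dtype=float)[order]
        model = fit_phase_lines(x, y, lab)
    else:
        model = segment_phases(dcurve, min_per_phase=min_per_phase)
    if plateau_flat:
        lab = np.asarray(model.assignment)
        x = np.asarray(model.density_per_um)
        y = np.asarray(model.dmpoh_uM)
        m2 = lab == 2
        a2 = float(np.mean(y[m2]))
        sse = (model.sse
               - float(np.sum((y[m2] - (model.a2 + model.b2 * x[m2])) ** 2))
               + float(np.sum((y[m2] - a2) ** 2)))
        model = PhaseModel(model.assignment, model.s1, a2, 0.0, model.s3, sse,
                           model.density_per_um, model.dmpoh_uM)

    d_star, a_star = intersect_sparse(model)
    total = total_oh(model, reference_density)
    if a_star > total:
        warnings.warn(
            f"sparse amount {a_star:.3g} exceeds total {total:.3g} µmol/L "
            "(noise-level inversion)", stacklevel=2)
    sparse_conc_mM = units.per_um_to_molar(d_star) * 1e3
    return SparseDenseEstimate(
        sparse_density_per_um=d_star,
        sparse_concentration_mM=sparse_conc_mM,
        sparse_amount_uM=a_star,
        total_amount_uM=total,
        dose_Gy=curve.dose_Gy,
        model=model,
    )
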