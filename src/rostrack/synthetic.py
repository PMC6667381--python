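"""Synthetic input generators for every pipeline stage.

The raw experimental tables (titration points, decay series, calibration
signals, budget scans) are not deposited anywhere, so each analysis stage is
exercised on generated data whose statistical structure matches what the
analysis assumes:

* titration: two localized radical populations with distinct site densities,
  each captured with a saturating ``min(x/d, 1)`` response on the
  linear-density axis — this produces the three-phase profile;
* decay: exponential post-irradiation loss with multiplicative noise;
* calibration: linear response with additive noise;
* budget/depth: monotone LET trends, a knee-constrained hypoxic oxidation
  line, and a toy monotone depth-LET map with a Bragg-like dose-rate peak.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .decay import DecaySeries
from .exceptions import DomainError
from .titration import TitrationCurve

#: The spin-trap concentration series used by the titration protocol, mmol/L.
PAPER_DMPO_GRID_MM: tuple[float, ...] = (
    0.5, 1.6, 3.3, 7.7, 13.3, 26.0, 61.6, 208.0, 600.0, 1685.0)

#: Default generative truth reproducing the X-ray worked example's scale.
DEFAULT_XRAY_TRUTH_KWARGS = dict(
    sparse_amount_uM=6.1, sparse_density_per_um=160.0,
    dense_amount_uM=51.7, dense_density_per_um=1e4)


@dataclass(frozen=True)
class TitrationTruth:
    """Generative parameters of a two-population titration curve.

    ``sparse_*`` describe the low-density population (amount in µmol/L, site
    density in 1/µm); ``dense_*`` the high-density one (density >= 1000/µm).
    """

    sparse_amount_uM: float
    sparse_density_per_um: float
    dense_amount_uM: float
    dense_density_per_um: float
    noise_sd_uM: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.sparse_density_per_um > 0:
            raise DomainError("sparse density must be > 0")
        if not self.dense_density_per_um > self.sparse_density_per_um:
            raise DomainError("dense density must exceed sparse density")
        if self.dense_density_per_um < 1000.0:
            raise DomainError("dense density must be >= 1000 per µm")
        if self.sparse_amount_uM < 0 or self.dense_amount_uM < 0:
            raise DomainError("amounts must be >= 0")
        if self.noise_sd_uM < 0:
            raise DomainError("noise sd must be >= 0")


def xray_truth(noise_sd_uM: float = 0.0, seed: int | None = None) -> TitrationTruth:
    """Truth calibrated so the noiseless end-to-end analysis reproduces the
    X-ray worked example's scale (sparse at 160/µm, total near 11.3 µmol/L)."""
    return TitrationTruth(noise_sd_uM=noise_sd_uM, seed=seed,
                          **DEFAULT_XRAY_TRUTH_KWARGS)


def titration_response(truth: TitrationTruth, density_per_um: np.ndarray) -> np.ndarray:
    """Noiseless adduct concentration at the given trap densities (µmol/L)."""
    x = np.asarray(density_per_um, dtype=float)
    return (truth.sparse_amount_uM * np.minimum(x / truth.sparse_density_per_um, 1.0)
            + truth.dense_amount_uM * np.minimum(x / truth.dense_density_per_um, 1.0))


def generate_titration(
    truth: TitrationTruth,
    dmpo_grid_mM: tuple[float, ...] = PAPER_DMPO_GRID_MM,
    dose_Gy: float = 32.0,
    modality: str = "xray",
    let_keV_um: float | None = None,
) -> TitrationCurve:
    """Generate a titration curve from the two-population truth model.

    Gaussian noise of sd ``truth.noise_sd_uM`` is added to each adduct
    concentration; values are clamped at zero.
    """
    dens = np.array([units.molar_to_per_um(c * 1e-3) for c in dmpo_grid_mM])
    y = titration_response(truth, dens)
    if truth.noise_sd_uM > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd_uM, size=y.size)
    y = np.maximum(y, 0.0)
    return TitrationCurve(tuple(dmpo_grid_mM), tuple(y.tolist()), dose_Gy,
                          modality, let_keV_um)


def generate_decay_series(
    c0: float,
    k_per_min: float,
    t_start_min: float = 3.0,
    n: int = 11,
    dt_min: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    irradiation_duration_min: float | None = None,
) -> DecaySeries:
    """Exponentially decaying series with multiplicative Gaussian noise.

    Times follow the measurement protocol default: start 3 min after
    irradiation, one reading per minute, 11 readings.
    """
    if k_per_min < 0:
        raise DomainError("decay rate must be >= 0")
    if c0 <= 0:
        raise DomainError("initial concentration must be > 0")
    t = t_start_min + dt_min * np.arange(n)
    y = c0 * np.exp(-k_per_min * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + rng.normal(0.0, noise_sd, size=n))
    y = np.maximum(y, 1e-12)  # keep log-fit defined under extreme noise draws
    return DecaySeries(tuple(t.tolist()), tuple(y.tolist()), irradiation_duration_min)


def generate_calibration(
    slope: float,
    intercept: float = 0.0,
    conc_grid_uM: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Linear calibration standards table (columns ``conc_uM, signal``).

    The default grid spans the standard series 0-980 µmol/L in 8 steps.
    """
    if slope <= 0:
        raise DomainError("calibration slope must be > 0")
    if conc_grid_uM is None:
        conc_grid_uM = np.linspace(0.0, 980.0, 8)
    conc = np.asarray(conc_grid_uM, dtype=float)
    signal = slope * conc + intercept
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=conc.size)
    return pd.DataFrame({"conc_uM": conc, "signal": signal})


@dataclass(frozen=True)
class BudgetScan:
    """Bundle of generated budget, hypoxic-oxidation, and depth-scan tables."""

    budget: pd.DataFrame
    hypoxic: pd.DataFrame
    depth_scan: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_budget_scan(
    let_grid: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 110.0),
    plateau_level: float = 0.35,
    plateau_onset_keV_um: float = 70.0,
    hypoxic_slope: float = 0.002,
    bragg_depth_mm: float = 147.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> BudgetScan:
    """Generate LET/depth-dependent per-Gy yield tables.

    Yields decrease monotonically with LET; hypoxic total oxidation lies on a
    line through ``(plateau_onset, plateau_level)`` below the onset and on the
    plateau above it; the depth scan has a monotone depth-LET map and a
    Bragg-like dose-rate peak at ``bragg_depth_mm``.
    """
    rng = np.random.default_rng(seed)
    let = np.asarray(let_grid, dtype=float)
    if let.size == 0:
        raise DomainError("LET grid is empty")
    if np.any(let <= 0):
        raise DomainError("LET values must be > 0")

    def jitter(v: np.ndarray, scale: float) -> np.ndarray:
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd * scale, size=np.shape(v))
        return np.maximum(v, 0.0)

    total_oh = jitter(0.35 - 0.0006 * let, 0.35)
    sparse_oh = jitter(0.17 - 0.0008 * let, 0.17)
    sparse_density = jitter(147.0 + 0.0 * let, 147.0)
    sparse_conc = np.array([units.per_um_to_molar(d) * 1e3 for d in sparse_density])
    h2o2 = jitter(0.26 - 0.0009 * let, 0.26)
    o2 = jitter(0.45 - 0.0036 * let, 0.45)
    total_ox = jitter(0.30 + 2.44 * np.exp(-let / 25.0), 1.0)

    budget = pd.DataFrame({
        "condition": [f"{l:g} keV/um" for l in let],
        "let_keV_um": let,
        "total_oh": total_oh,
        "sparse_oh": sparse_oh,
        "sparse_density": sparse_density,
        "sparse_conc": sparse_conc,
        "h2o2": h2o2,
        "o2_consumption": o2,
        "total_oxidation": total_ox,
    })

    hyp_let = np.unique(np.concatenate([let, [plateau_onset_keV_um]]))
    hyp_total = np.where(
        hyp_let >= plateau_onset_keV_um, plateau_level,
        plateau_level + hypoxic_slope * (hyp_let - plateau_onset_keV_um))
    hyp_total = jitter(hyp_total, 0.35)
    hypoxic = pd.DataFrame({"let_keV_um": hyp_let, "total_oxidation": hyp_total})

    depth = np.arange(0.0, 151.0, 1.0)
    scan_let = 13.0 + (190.0 - 13.0) * (depth / depth.max()) ** 5
    dose_rate = 3.0 + 20.0 * np.exp(-0.5 * ((depth - bragg_depth_mm) / 5.0) ** 2)
    if noise_sd > 0:
        dose_rate = np.maximum(
            dose_rate * (1.0 + rng.normal(0.0, noise_sd, size=depth.size)), 1e-3)
    depth_scan = pd.DataFrame({
        "depth_mm": depth,
        "let_keV_um": scan_let,
        "dose_rate_Gy_min": dose_rate,
    })

    truth = {
        "plateau_level": plateau_level,
        "plateau_onset_keV_um": plateau_onset_keV_um,
        "hypoxic_slope": hypoxic_slope,
        "bragg_depth_mm": bragg_depth_mm,
    }
    return BudgetScan(budget, hypoxic, depth_scan, truth)
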