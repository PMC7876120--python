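"""Absolute quantification of pairwise complex formation.

SMLM sees only a fraction of the true molecules (labeling efficiency LE,
detection efficiency DE), so an observed colocalization percentage cannot
be read as a complexed fraction directly.  This module provides:

* the observed colocalization fraction (nearest cross-species neighbor
  within a distance threshold, default 25 nm);
* efficiency-aware Monte-Carlo calibration curves mapping the true
  complexed fraction c in [0, 1] to the expected observed colocalization,
  and their monotone inversion back to c with propagated uncertainty;
* sensitivity sweeps over molecular density and labeling efficiencies;
* the absolute-density extrapolation  rho_true = rho_measured / (LE * DE)
  and the best/intermediate/worst scenario summary (mean +- population SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._utils import as_rng
from .loc_data import RegionMask
from .paint_sim import MoleculeSet, apply_labeling, gen_complex_population


@dataclass
class EfficiencyScenario:
    """One LE/DE assumption with its measured density."""

    labeling_efficiency: float
    detection_efficiency: float
    measured_density_um2: float

    def __post_init__(self) -> None:
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling efficiency outside (0, 1]")
        if not 0 < self.detection_efficiency <= 1:
            raise ValueError("detection efficiency outside (0, 1]")
        if self.measured_density_um2 < 0:
            raise ValueError("density must be >= 0")


def extrapolate_density(scenario: EfficiencyScenario) -> float:
    """Absolute molecular density: measured / (LE x DE).

    Exactly multiplicative — halving either efficiency doubles the
    estimate.  Returns the raw value; displayed values are conventionally
    truncated to integers (see :func:`truncate_density`).
    """
    return scenario.measured_density_um2 / (
        scenario.labeling_efficiency * scenario.detection_efficiency)


def truncate_density(value: float) -> int:
    """Display rule for extrapolated densities: truncate to integer."""
    return int(math.floor(value))


def scenario_summary(densities: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and population (divide-by-n) SD of scenario densities."""
    if len(densities) == 0:
        raise ValueError("need at least one density")
    arr = np.asarray(densities, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# colocalization fraction


def coloc_fraction(source, reference, threshold_nm: float = 25.0) -> float:
    """Fraction of source molecules with a reference molecule within threshold.

    Accepts (N, 2) coordinate arrays or MoleculeSets (whose *labeled*
    molecules are used — the observable population).
    """
    src = _coords(source)
    ref = _coords(reference)
    if len(src) == 0:
        raise ValueError("empty source set")
    if len(ref) == 0:
        raise ValueError("empty reference set")
    d, _ = cKDTree(ref).query(src, k=1)
    return float((d <= threshold_nm).mean())


def _coords(obj) -> np.ndarray:
    if isinstance(obj, MoleculeSet):
        return obj.labeled_points
    return np.asarray(obj, dtype=float).reshape(-1, 2)


def csr_coloc_fraction(reference_density_um2: float, threshold_nm: float = 25.0) -> float:
    """Closed-form CSR baseline: 1 - exp(-pi rho r^2).

    Probability that a point has at least one neighbor of an independent
    Poisson field of the given density within the threshold (void
    probability of the disc).
    """
    rho_nm = reference_density_um2 / 1e6
    return 1.0 - math.exp(-math.pi * rho_nm * threshold_nm**2)


# ---------------------------------------------------------------------------
# calibration curve


@dataclass
class CalibrationCurve:
    """Mapping true complexed fraction -> expected observed colocalization."""

    c_grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.c_grid = np.asarray(self.c_grid, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not np.all(np.diff(self.c_grid) > 0):
            raise ValueError("c grid must be strictly increasing")

    def monotone_mean(self) -> np.ndarray:
        """Means forced non-decreasing (isotonic clean-up of MC noise)."""
        return np.maximum.accumulate(self.mean)


def build_calibration_curve(density_a: float = 611.0, density_b: float = 611.0,
                            le_a: float = 0.30, le_b: float = 0.20,
                            dist_range_nm: Tuple[float, float] = (12.0, 16.0),
                            threshold_nm: float = 25.0,
                            c_grid: Optional[Sequence[float]] = None,
                            replicates: int = 20,
                            roi: Optional[RegionMask] = None,
                            seed=None, apply_de: Optional[float] = None,
                            direction: str = "lower") -> CalibrationCurve:
    """Monte-Carlo calibration of observed colocalization vs complexed fraction.

    For each c on the grid (default 0–100% in 10% steps): simulate the
    two-species complex population at the given densities (default the
    extrapolated absolute density, 611 molecules/µm², for both species),
    thin each species by its LE (defaults: 30% HaloTag / 20% SNAP-tag),
    optionally thin both by a common DE, and record the colocalization
    fraction within the threshold; aggregate over replicates.

    direction='lower' uses the species with the lower labeled density as
    source (its partner population is the denser one); 'pooled' averages
    the two directed fractions weighted by labeled counts.
    """
    if c_grid is None:
        c_grid = np.linspace(0.0, 1.0, 11)
    c_grid = np.asarray(c_grid, dtype=float)
    if roi is None:
        roi = RegionMask.rectangle(10_000.0, 10_000.0)
    rng = as_rng(seed)
    means, sds = [], []
    for c in c_grid:
        vals = [
            observed_coloc(density_a, density_b, c, le_a, le_b, roi, rng,
                           dist_range_nm=dist_range_nm, threshold_nm=threshold_nm,
                           apply_de=apply_de, direction=direction)
            for _ in range(replicates)
        ]
        means.append(np.mean(vals))
        sds.append(np.std(vals, ddof=1) if replicates > 1 else 0.0)
    cfg = dict(density_a=density_a, density_b=density_b, le_a=le_a, le_b=le_b,
               dist_range_nm=tuple(dist_range_nm), threshold_nm=threshold_nm,
               replicates=replicates, roi_area_um2=roi.area_um2,
               apply_de=apply_de, direction=direction)
    return CalibrationCurve(c_grid, np.array(means), np.array(sds), config=cfg)


def observed_coloc(density_a: float, density_b: float, c: float,
                   le_a: float, le_b: float, roi: RegionMask, seed=None,
                   dist_range_nm: Tuple[float, float] = (12.0, 16.0),
                   threshold_nm: float = 25.0, apply_de: Optional[float] = None,
                   direction: str = "lower") -> float:
    """One simulated observation of the colocalization fraction at complexed
    fraction c under the given labeling (and optional detection) efficiencies."""
    rng = as_rng(seed)
    set_a, set_b = gen_complex_population(density_a, density_b, c, roi, rng,
                                          dist_range_nm=dist_range_nm)
    lab_a = apply_labeling(set_a, le_a, rng)
    lab_b = apply_labeling(set_b, le_b, rng)
    if apply_de is not None:
        lab_a = apply_labeling(lab_a, apply_de, rng)
        lab_b = apply_labeling(lab_b, apply_de, rng)
        lab_a = MoleculeSet(lab_a.species, lab_a.points[lab_a.labeled])
        lab_b = MoleculeSet(lab_b.species, lab_b.points[lab_b.labeled])
    a_pts, b_pts = lab_a.labeled_points, lab_b.labeled_points
    if len(a_pts) == 0 or len(b_pts) == 0:
        return float("nan")
    if direction == "pooled":
        fa = coloc_fraction(a_pts, b_pts, threshold_nm)
        fb = coloc_fraction(b_pts, a_pts, threshold_nm)
        return (fa * len(a_pts) + fb * len(b_pts)) / (len(a_pts) + len(b_pts))
    src, ref = (b_pts, a_pts) if len(b_pts) <= len(a_pts) else (a_pts, b_pts)
    return coloc_fraction(src, ref, threshold_nm)


def invert_calibration(observed_fraction: float, curve: CalibrationCurve,
                       observed_se: float = 0.0) -> dict:
    """Invert the calibration curve at an observed colocalization fraction.

    Monotone piecewise-linear interpolation of the replicate means; the
    uncertainty interval is where observed -+ its SE crosses the curve
    shifted by +-1 SD.  Out-of-range observations are clipped to [0, 1]
    and flagged.
    """
    mono = curve.monotone_mean()
    lo_curve = np.maximum.accumulate(curve.mean - curve.sd)
    hi_curve = np.maximum.accumulate(curve.mean + curve.sd)
    out_of_range = not (mono[0] - 2 * curve.sd[0] <= observed_fraction
                        <= mono[-1] + 2 * curve.sd[-1])
    c_hat = _monotone_invert(observed_fraction, curve.c_grid, mono)
    c_lo = _monotone_invert(observed_fraction - observed_se, curve.c_grid, hi_curve)
    c_hi = _monotone_invert(observed_fraction + observed_se, curve.c_grid, lo_curve)
    return {"c": c_hat, "ci": (min(c_lo, c_hi), max(c_lo, c_hi)),
            "out_of_range": bool(out_of_range)}


def _monotone_invert(y: float, x_grid: np.ndarray, y_grid: np.ndarray) -> float:
    if y <= y_grid[0]:
        return float(x_grid[0])
    if y >= y_grid[-1]:
        return float(x_grid[-1])
    return float(np.interp(y, y_grid, x_grid))


def sensitivity_sweep(densities: Sequence[float] = (100, 300, 600, 1000),
                      le_a_values: Sequence[float] = (0.20, 0.60, 1.00),
                      le_b_values: Sequence[float] = (0.13, 0.40, 0.66),
                      c_grid: Optional[Sequence[float]] = None,
                      replicates: int = 5, seed=None,
                      roi: Optional[RegionMask] = None) -> pd.DataFrame:
    """Calibration curves across density and LE ranges.

    Returns one row per (density, le_a, le_b, c) with the mean/SD observed
    colocalization, plus the curve's dynamic range curve(1) - curve(0) —
    the quantity that shrinks as labeling degrades and grows with density
    contrast.
    """
    rng = as_rng(seed)
    rows = []
    for rho in densities:
        for le_a in le_a_values:
            for le_b in le_b_values:
                curve = build_calibration_curve(
                    density_a=rho, density_b=rho, le_a=le_a, le_b=le_b,
                    c_grid=c_grid, replicates=replicates, roi=roi, seed=rng)
                dyn = curve.mean[-1] - curve.mean[0]
                for c, m, s in zip(curve.c_grid, curve.mean, curve.sd):
                    rows.append({"density_um2": rho, "le_a": le_a, "le_b": le_b,
                                 "c": c, "coloc_mean": m, "coloc_sd": s,
                                 "dynamic_range": dyn})
    return pd.DataFrame(rows)
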