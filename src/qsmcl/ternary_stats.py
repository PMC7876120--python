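"""Ternary complex analysis: anchored nearest-neighbor tuples and the
two-sample 2D Kolmogorov–Smirnov bootstrap.

For every anchor molecule (e.g. an active integrin receptor) the tuple of
distances to its nearest molecule of two other species (nearest kindlin,
nearest talin) is recorded.  Tuple clouds from experiment-style data and
from complete-spatial-randomness simulations at matched densities are
compared with a two-sample 2D K–S statistic (Fasano–Franceschini style:
quadrant-probability differences maximized over the data points) inside a
subsampling bootstrap; the p-value is calibrated against a within-dataset
self-bootstrap null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._utils import as_rng
from .spatial_stats import nnd


@dataclass
class TupleSet:
    """Per-anchor (distance to nearest K, distance to nearest T) pairs (nm)."""

    d_k: np.ndarray
    d_t: np.ndarray
    anchor_species: str = ""
    k_species: str = ""
    t_species: str = ""

    def __post_init__(self) -> None:
        self.d_k = np.asarray(self.d_k, dtype=float)
        self.d_t = np.asarray(self.d_t, dtype=float)
        if self.d_k.shape != self.d_t.shape:
            raise ValueError("tuple components must have equal length")

    def __len__(self) -> int:
        return len(self.d_k)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.d_k, self.d_t])


@dataclass
class KSResult:
    """Bootstrapped 2D K–S comparison of two tuple clouds."""

    d_mean: float
    d_sd: float
    pvalue: float
    d_values: np.ndarray
    null_values: np.ndarray
    subsample: int
    runs: int


def i2kt_tuples(anchors: np.ndarray, set_k: np.ndarray, set_t: np.ndarray,
                anchor_species: str = "I", k_species: str = "K",
                t_species: str = "T") -> TupleSet:
    """Exact nearest-neighbor distance tuples for each anchor molecule."""
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 2)
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    dk = nnd(anchors, k=1, reference=set_k).distances
    dt = nnd(anchors, k=1, reference=set_t).distances
    return TupleSet(dk, dt, anchor_species=anchor_species,
                    k_species=k_species, t_species=t_species)


def tuple_heatmap(tuples: TupleSet, bin_width_nm: float = 10.0,
                  extent_nm: Optional[float] = None
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized 2D relative-frequency grid of (I2K, I2T) tuples (sums to 1)."""
    if len(tuples) == 0:
        raise ValueError("empty tuple set")
    hi = extent_nm if extent_nm is not None else max(tuples.d_k.max(), tuples.d_t.max()) + bin_width_nm
    edges = np.arange(0.0, hi + bin_width_nm, bin_width_nm)
    grid, ex, ey = np.histogram2d(tuples.d_k, tuples.d_t, bins=[edges, edges])
    return grid / grid.sum(), ex, ey


# ---------------------------------------------------------------------------
# 2D Kolmogorov–Smirnov


def _cum_fractions(eval_pts: np.ndarray, sample: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P(x<=ex, y<=ey), P(x<=ex), P(y<=ey) for each eval point.

    Boundary points count toward the closed lower-left quadrant.
    """
    n = len(sample)
    le_x = sample[None, :, 0] <= eval_pts[:, None, 0]
    le_y = sample[None, :, 1] <= eval_pts[:, None, 1]
    f_ll = (le_x & le_y).sum(axis=1) / n
    return f_ll, le_x.sum(axis=1) / n, le_y.sum(axis=1) / n


def ks2d(sample_a, sample_b) -> float:
    """Two-sample 2D K–S statistic.

    Maximum over all data points of both samples and the four quadrant
    orientations of the difference in empirical quadrant fractions.
    Symmetric in its arguments and invariant under a common monotone
    rescaling of both coordinates.
    """
    a = _as_xy(sample_a)
    b = _as_xy(sample_b)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    if np.ptp(a, axis=0).max() == 0 and np.ptp(b, axis=0).max() == 0:
        warnings.warn("ks2d: degenerate (all-identical) samples")
    pts = np.concatenate([a, b])
    d_max = 0.0
    for chunk in np.array_split(pts, max(1, len(pts) // 2048)):
        fa_ll, fa_x, fa_y = _cum_fractions(chunk, a)
        fb_ll, fb_x, fb_y = _cum_fractions(chunk, b)
        # four quadrants from the three cumulative fractions
        diffs = np.stack([
            fa_ll - fb_ll,
            (fa_x - fa_ll) - (fb_x - fb_ll),
            (fa_y - fa_ll) - (fb_y - fb_ll),
            (1 - fa_x - fa_y + fa_ll) - (1 - fb_x - fb_y + fb_ll),
        ])
        d_max = max(d_max, float(np.abs(diffs).max()))
    return d_max


def _as_xy(obj) -> np.ndarray:
    if isinstance(obj, TupleSet):
        return obj.xy
    return np.asarray(obj, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# bootstrap comparison


def bootstrap_compare(sample_a, sample_b, subsample: int = 1000,
                      runs: int = 1000, seed=None) -> KSResult:
    """Subsampling bootstrap of the 2D K–S statistic with a self-bootstrap null.

    Per run, ``subsample`` tuples are drawn without replacement from each
    dataset and the K–S statistic computed, giving the cross-comparison
    distribution (mean D +- SD).  The null distribution is built the same
    way *within* each dataset (two disjoint subsamples of itself, the
    "sim vs sim" / "exp vs exp" controls); the p-value is the fraction of
    null draws with D at least the mean cross D.
    """
    a = _as_xy(sample_a)
    b = _as_xy(sample_b)
    n_min = min(len(a), len(b))
    if n_min < 10:
        raise ValueError("samples too small for bootstrap comparison")
    if subsample > n_min:
        warnings.warn(f"subsample reduced from {subsample} to {n_min}")
        subsample = n_min
    rng = as_rng(seed)
    d_vals = np.array([
        ks2d(a[rng.choice(len(a), subsample, replace=False)],
             b[rng.choice(len(b), subsample, replace=False)])
        for _ in range(runs)
    ])
    null_vals = np.concatenate([
        _self_null(a, subsample, runs, rng),
        _self_null(b, subsample, runs, rng),
    ])
    d_mean = float(d_vals.mean())
    d_sd = float(d_vals.std(ddof=1)) if runs > 1 else float("nan")
    pvalue = float((null_vals >= d_mean).mean())
    return KSResult(d_mean=d_mean, d_sd=d_sd, pvalue=pvalue,
                    d_values=d_vals, null_values=null_vals,
                    subsample=subsample, runs=runs)


def _self_null(x: np.ndarray, subsample: int, runs: int,
               rng: np.random.Generator) -> np.ndarray:
    """Within-dataset D distribution: two disjoint subsamples per run
    (independent subsamples when the dataset is too small to split)."""
    n = len(x)
    disjoint = n >= 2 * subsample
    if not disjoint:
        warnings.warn("dataset too small for disjoint null subsamples; "
                      "using independent draws")
    out = np.empty(runs)
    for i in range(runs):
        if disjoint:
            idx = rng.choice(n, 2 * subsample, replace=False)
            s1, s2 = idx[:subsample], idx[subsample:]
        else:
            s1 = rng.choice(n, subsample, replace=False)
            s2 = rng.choice(n, subsample, replace=False)
        out[i] = ks2d(x[s1], x[s2])
    return out
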