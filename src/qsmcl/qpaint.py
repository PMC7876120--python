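"""Molecular counting from DNA-PAINT blinking kinetics (qPAINT).

The binding of imager strands to one docking site is a Poisson process
with influx rate xi, so the dark times between successive binding events
are exponential with mean tau_d = 1/xi.  A localization cloud containing
n independent binding sites shows the superposition of n such processes,
i.e. a mean dark time tau_d/n.  Calibrating xi on known single sites
(e.g. manually validated DNA-origami docking strands) therefore turns the
mean dark time of any cloud into an estimate of its binding-site number:

    n_hat = tau_d_cal / tau_d_cloud = 1 / (xi * tau_d_cloud)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cluster_pipeline import ClusterRecord
from .loc_data import LocalizationTable
from .paint_sim import KineticTrace


@dataclass
class QPaintCalibration:
    """Single-binding-site influx calibration.

    influx_rate is per binding site; dispersion is the SD of per-site mean
    dark times across the reference set.
    """

    influx_rate: float           # events/s
    mean_dark_s: float           # tau_d,cal = 1/influx_rate
    n_reference_sites: int
    dispersion_s: float

    def __post_init__(self) -> None:
        if self.influx_rate <= 0 or self.mean_dark_s <= 0:
            raise ValueError("calibration rate and dark time must be positive")
        if self.n_reference_sites < 1:
            raise ValueError("need at least one reference site")


def extract_dark_times(trace: KineticTrace, exposure_s: Optional[float] = None) -> np.ndarray:
    """Dark durations (seconds) between successive binding events.

    The censored intervals before the first and after the last event are
    excluded; a trace with fewer than two events yields an empty array.
    """
    exposure = trace.exposure_s if exposure_s is None else exposure_s
    return trace.dark_intervals_frames().astype(float) * exposure


def mean_dark_time(trace: KineticTrace, method: str = "mean",
                   exposure_s: Optional[float] = None,
                   n_frames: Optional[int] = None) -> float:
    """Mean dark time of one trace.

    method='mean' averages the uncensored gaps; method='mle' is the
    censored-exponential maximum-likelihood estimate (total dark time
    including the leading — and, when ``n_frames`` is given, trailing —
    censored gap, divided by the number of uncensored gaps), which removes
    the small downward bias of discarding long censored intervals.
    """
    gaps = extract_dark_times(trace, exposure_s)
    if len(gaps) == 0:
        return float("nan")
    if method == "mean":
        return float(gaps.mean())
    if method == "mle":
        exposure = trace.exposure_s if exposure_s is None else exposure_s
        ev = np.asarray(trace.events, dtype=float)
        censored = ev[0, 0] * exposure
        if n_frames is not None:
            censored += max(0.0, (n_frames - (ev[-1, 0] + ev[-1, 1])) * exposure)
        return float((gaps.sum() + censored) / len(gaps))
    raise ValueError(f"unknown method {method!r}")


def calibrate_influx(reference_traces: Sequence[KineticTrace],
                     method: str = "mean") -> QPaintCalibration:
    """Estimate the influx rate from single-binding-site reference traces.

    Pools all uncensored dark times across sites: tau_d,cal is their mean
    and xi = 1/tau_d,cal — the "one unit per binding site" normalization.
    """
    pooled = []
    per_site = []
    for tr in reference_traces:
        gaps = extract_dark_times(tr)
        if len(gaps):
            pooled.append(gaps)
            per_site.append(gaps.mean())
    if not pooled:
        raise ValueError("no usable dark times in the reference set")
    all_gaps = np.concatenate(pooled)
    tau = float(all_gaps.mean())
    return QPaintCalibration(
        influx_rate=1.0 / tau,
        mean_dark_s=tau,
        n_reference_sites=len(per_site),
        dispersion_s=float(np.std(per_site)) if len(per_site) > 1 else 0.0,
    )


def count_binding_sites(trace: KineticTrace, calibration: QPaintCalibration,
                        method: str = "mean") -> float:
    """Estimated binding sites in one cloud: tau_d,cal / tau_d(trace).

    Returns NaN when the trace has no uncensored dark time (fewer than two
    binding events).
    """
    tau = mean_dark_time(trace, method=method)
    if not np.isfinite(tau) or tau <= 0:
        return float("nan")
    return calibration.mean_dark_s / tau


def cluster_to_trace(cluster: ClusterRecord, table: LocalizationTable,
                     exposure_s: float = 0.1) -> KineticTrace:
    """Convert a localization cloud into a binding-event trace.

    The member localizations' frames mark occupied frames; consecutive
    occupied frames merge into one binding event.
    """
    frames = np.unique(table.frames[cluster.members])
    events = []
    if len(frames):
        breaks = np.flatnonzero(np.diff(frames) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(frames) - 1]])
        events = [(int(frames[s]), int(frames[e] - frames[s] + 1))
                  for s, e in zip(starts, ends)]
    return KineticTrace(site_id=cluster.id, events=events, exposure_s=exposure_s)


def count_clusters(clusters: Sequence[ClusterRecord], table: LocalizationTable,
                   calibration: QPaintCalibration, exposure_s: float = 0.1,
                   method: str = "mean") -> pd.DataFrame:
    """qPAINT counting for every cloud; raw and rounded estimates."""
    rows = []
    for c in clusters:
        tr = cluster_to_trace(c, table, exposure_s)
        raw = count_binding_sites(tr, calibration, method=method)
        rows.append({
            "cluster_id": c.id,
            "n_events": tr.n_events,
            "mean_dark_s": mean_dark_time(tr, method=method),
            "sites_raw": raw,
            "sites_rounded": int(round(raw)) if np.isfinite(raw) else -1,
        })
    return pd.DataFrame(rows)


def count_traces(traces: Sequence[KineticTrace], calibration: QPaintCalibration,
                 method: str = "mean") -> pd.DataFrame:
    """qPAINT counting directly on simulator traces."""
    rows = []
    for tr in traces:
        raw = count_binding_sites(tr, calibration, method=method)
        rows.append({
            "cluster_id": tr.site_id,
            "n_events": tr.n_events,
            "mean_dark_s": mean_dark_time(tr, method=method),
            "sites_raw": raw,
            "sites_rounded": int(round(raw)) if np.isfinite(raw) else -1,
        })
    return pd.DataFrame(rows)
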