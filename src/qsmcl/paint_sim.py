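"""Synthetic DNA-PAINT data generator.

Emulates the study conditions this package is designed for: homogeneous 2D
Poisson molecule fields (50–1000 molecules/µm²), two-species populations
with a tunable complexed fraction paired at 12–16 nm, DNA-origami grids
(20 nm spacing, one or three concatenated binding sequences per site),
frame-quantized imager binding kinetics over 80,000–160,000 frames at
100 ms exposure, and isotropic Gaussian localization noise (~7 nm).

Molecule layouts, binding kinetics, and localization rendering are three
separate stages so each can be validated against its own closed form
(Poisson counts, exponential renewal statistics, Gaussian scatter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._utils import as_rng
from .loc_data import LocalizationTable, RegionMask


@dataclass
class MoleculeSet:
    """Ground-truth molecule coordinates of one species.

    ``labeled`` marks molecules carrying a functional docking strand
    (labeling efficiency thinning); ``partner_index`` links complexed
    molecules to their partner in another set (-1 = unpaired).
    """

    species: str
    points: np.ndarray                       # (N, 2) nm
    labeled: np.ndarray = None               # (N,) bool
    partner_index: np.ndarray = None         # (N,) int, -1 unpaired

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        n = len(self.points)
        if self.labeled is None:
            self.labeled = np.ones(n, dtype=bool)
        self.labeled = np.asarray(self.labeled, dtype=bool)
        if self.partner_index is None:
            self.partner_index = np.full(n, -1, dtype=np.int64)
        self.partner_index = np.asarray(self.partner_index, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def labeled_points(self) -> np.ndarray:
        return self.points[self.labeled]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.points[:, 0], "y": self.points[:, 1],
            "labeled": self.labeled, "partner_index": self.partner_index,
            "species": self.species,
        })


@dataclass
class SiteLayout:
    """Docking-site coordinates plus binding-sequence multiplicity.

    ``sites_per_position`` is the number of concatenated binding sequences
    per docking strand (1x or 3x); it scales the event rate in
    :func:`simulate_kinetics`.
    """

    coords: np.ndarray                        # (N, 2) nm
    sites_per_position: int = 1
    spacing_nm: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if self.sites_per_position < 1:
            raise ValueError("sites_per_position must be >= 1")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class KineticTrace:
    """Binding-event record of one docking site.

    Events are (start_frame, duration_frames) tuples, non-overlapping and
    sorted; zero-frame gaps have been merged during frame quantization.
    """

    site_id: int
    events: List[Tuple[int, int]] = field(default_factory=list)
    exposure_s: float = 0.1

    @property
    def n_events(self) -> int:
        return len(self.events)

    def occupied_frames(self) -> np.ndarray:
        if not self.events:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([np.arange(s, s + d, dtype=np.int64) for s, d in self.events])

    def dark_intervals_frames(self) -> np.ndarray:
        """Gaps (frames) between successive events; censored ends excluded."""
        if len(self.events) < 2:
            return np.empty(0, dtype=np.int64)
        ev = np.asarray(self.events, dtype=np.int64)
        return ev[1:, 0] - (ev[:-1, 0] + ev[:-1, 1])

    def bright_intervals_frames(self) -> np.ndarray:
        return np.asarray([d for _, d in self.events], dtype=np.int64)


@dataclass
class KineticsConfig:
    """Imager binding kinetics and acquisition parameters.

    influx_rate is the binding-event rate per single binding sequence
    (events/s); the default 0.02/s gives a mean dark time of 50 s, a
    plausible DNA-PAINT regime at calibration imager concentration.
    mean_bright_s = 0.5 s is a typical 9-nt duplex dwell time.
    """

    influx_rate: float = 0.02          # events/s per binding sequence
    mean_bright_s: float = 0.5
    n_frames: int = 80_000             # 160_000 for qPAINT-style runs
    exposure_s: float = 0.1
    sigma_nm: float = 7.0              # localization precision
    mean_photons: float = 5000.0
    min_frame_overlap: float = 0.5     # fraction of exposure for a frame to count

    def __post_init__(self) -> None:
        if self.influx_rate < 0 or self.mean_bright_s <= 0 or self.exposure_s <= 0:
            raise ValueError("rates and times must be positive")
        if self.sigma_nm < 0:
            raise ValueError("sigma_nm must be >= 0")

    @property
    def total_time_s(self) -> float:
        return self.n_frames * self.exposure_s

    def expected_locs_per_site(self, sites_per_position: int = 1) -> float:
        """Expected localization count for one docking site over the run."""
        mean_bright_frames = self.mean_bright_s / self.exposure_s
        return (self.influx_rate * sites_per_position
                * self.total_time_s * mean_bright_frames)


# ---------------------------------------------------------------------------
# spatial layouts


def gen_random_field(density_um2: float, roi: RegionMask, seed=None,
                     species: str = "A") -> MoleculeSet:
    """Homogeneous Poisson molecule field at ``density_um2`` molecules/µm².

    Points are i.i.d. uniform over the ROI polygon; the count is Poisson
    with mean density x area.
    """
    if density_um2 < 0:
        raise ValueError("density must be >= 0")
    rng = as_rng(seed)
    n = rng.poisson(density_um2 * roi.area_um2)
    pts = _uniform_in_polygon(n, roi, rng)
    return MoleculeSet(species, pts)


def _uniform_in_polygon(n: int, roi: RegionMask, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n uniform points inside the ROI polygon."""
    if n == 0:
        return np.empty((0, 2))
    x0, y0, x1, y1 = roi.bounds()
    out = []
    need = n
    while need > 0:
        cand = np.column_stack([rng.uniform(x0, x1, size=2 * need + 16),
                                rng.uniform(y0, y1, size=2 * need + 16)])
        inside = roi.contains(cand)
        got = cand[inside][:need]
        out.append(got)
        need -= len(got)
    return np.concatenate(out)


def gen_complex_population(density_a: float, density_b: float, complex_fraction: float,
                           roi: RegionMask, seed=None,
                           dist_range_nm: Tuple[float, float] = (12.0, 16.0),
                           species: Tuple[str, str] = ("A", "B"),
                           ) -> Tuple[MoleculeSet, MoleculeSet]:
    """Two-species field with a fraction of B molecules complexed to A.

    Species A is a plain random field.  A fraction ``complex_fraction`` of
    species-B molecules is reassigned to sit at a distance drawn uniformly
    from ``dist_range_nm`` (uniform angle) from a distinct A molecule,
    emulating direct molecular complex formation at the 12–16 nm scale of
    an intracellular binary complex; the rest of B stays uniform.
    """
    if not 0 <= complex_fraction <= 1:
        raise ValueError("complex_fraction must be in [0, 1]")
    lo, hi = dist_range_nm
    if lo <= 0 or hi < lo:
        raise ValueError("dist_range_nm must be positive with low <= high")
    rng = as_rng(seed)
    set_a = gen_random_field(density_a, roi, rng, species=species[0])
    set_b = gen_random_field(density_b, roi, rng, species=species[1])
    n_b = len(set_b)
    n_pair = int(round(complex_fraction * n_b))
    n_pair = min(n_pair, len(set_a))  # each B pairs with a distinct A
    if n_pair > 0:
        b_idx = rng.choice(n_b, size=n_pair, replace=False)
        a_idx = rng.choice(len(set_a), size=n_pair, replace=False)
        r = rng.uniform(lo, hi, size=n_pair)
        theta = rng.uniform(0, 2 * np.pi, size=n_pair)
        offset = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        set_b.points[b_idx] = set_a.points[a_idx] + offset
        set_b.partner_index[b_idx] = a_idx
        set_a.partner_index[a_idx] = b_idx
    return set_a, set_b


def gen_ternary_population(density_t: float = 611.0, density_k: float = 611.0,
                           density_i: float = 150.0, roi: RegionMask = None,
                           seed=None, complex_fraction: float = 1.0,
                           engaged_fraction: float = 1.0,
                           dist_range_nm: Tuple[float, float] = (12.0, 16.0),
                           ) -> Tuple[MoleculeSet, MoleculeSet, MoleculeSet]:
    """Ternary scenario: anchor species engaged with binary complexes.

    Species T and K form binary complexes (fraction ``complex_fraction``
    at 12–16 nm, as in :func:`gen_complex_population`); a fraction
    ``engaged_fraction`` of anchor molecules (e.g. active integrin
    receptors, default 150/µm²) is then placed 12–16 nm from a distinct
    complexed K molecule, the rest uniform.  ``engaged_fraction=0`` gives
    three mutually independent random fields — the null of no ternary
    association.

    Returns (anchors, set_k, set_t).
    """
    if not 0 <= engaged_fraction <= 1:
        raise ValueError("engaged_fraction must be in [0, 1]")
    rng = as_rng(seed)
    if roi is None:
        roi = RegionMask.rectangle(10_000.0, 10_000.0)
    set_t, set_k = gen_complex_population(density_t, density_k, complex_fraction,
                                          roi, rng, dist_range_nm=dist_range_nm,
                                          species=("T", "K"))
    anchors = gen_random_field(density_i, roi, rng, species="I")
    paired_k = np.flatnonzero(set_k.partner_index >= 0)
    n_engage = min(int(round(engaged_fraction * len(anchors))), len(paired_k))
    if n_engage > 0:
        a_idx = rng.choice(len(anchors), size=n_engage, replace=False)
        k_idx = rng.choice(paired_k, size=n_engage, replace=False)
        r = rng.uniform(*dist_range_nm, size=n_engage)
        theta = rng.uniform(0, 2 * np.pi, size=n_engage)
        anchors.points[a_idx] = set_k.points[k_idx] + np.column_stack(
            [r * np.cos(theta), r * np.sin(theta)])
        anchors.partner_index[a_idx] = k_idx
    return anchors, set_k, set_t


def apply_labeling(mol_set: MoleculeSet, labeling_efficiency: float, seed=None) -> MoleculeSet:
    """Independent Bernoulli thinning by the labeling efficiency.

    Models incomplete tag labeling (e.g. 30% for HaloTag, 20% for
    SNAP-tag): each molecule keeps a functional docking strand with
    probability ``labeling_efficiency``.
    """
    if not 0 <= labeling_efficiency <= 1:
        raise ValueError("labeling efficiency must be in [0, 1]")
    rng = as_rng(seed)
    labeled = rng.random(len(mol_set)) < labeling_efficiency
    return MoleculeSet(mol_set.species, mol_set.points.copy(),
                       labeled=labeled, partner_index=mol_set.partner_index.copy())


def gen_origami_grid(rows: int, cols: int, spacing_nm: float = 20.0,
                     sites_per_position: int = 1, origin=(0.0, 0.0)) -> SiteLayout:
    """Square-lattice DNA-origami docking-site layout (default 20 nm pitch)."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if spacing_nm <= 0:
        raise ValueError("spacing must be positive")
    gx, gy = np.meshgrid(np.arange(cols) * spacing_nm, np.arange(rows) * spacing_nm)
    coords = np.column_stack([gx.ravel(), gy.ravel()]) + np.asarray(origin, dtype=float)
    return SiteLayout(coords, sites_per_position=sites_per_position, spacing_nm=spacing_nm)


def gen_site_pairs(n_pairs: int, separation_nm: float, pitch_nm: float = 1000.0,
                   sites_per_position: int = 1) -> SiteLayout:
    """n_pairs of docking sites separated by ``separation_nm``.

    Pair centers sit on a coarse square grid (``pitch_nm`` apart) so pairs
    never interact; used for resolution benchmarks over 20–35 nm spacings.
    """
    if separation_nm <= 0 or pitch_nm <= 2 * separation_nm:
        raise ValueError("need positive separation well below the pair pitch")
    side = int(np.ceil(np.sqrt(n_pairs)))
    centers = []
    for i in range(n_pairs):
        r, c = divmod(i, side)
        centers.append((c * pitch_nm + pitch_nm / 2, r * pitch_nm + pitch_nm / 2))
    centers = np.asarray(centers)
    half = separation_nm / 2
    coords = np.empty((2 * n_pairs, 2))
    coords[0::2] = centers - [half, 0.0]
    coords[1::2] = centers + [half, 0.0]
    return SiteLayout(coords, sites_per_position=sites_per_position,
                      spacing_nm=separation_nm)


def gen_striped_field(density_stripe: float, density_gap: float, roi: RegionMask,
                      seed=None, stripe_width_nm: float = 1000.0,
                      gap_width_nm: float = 2000.0, species: str = "A") -> MoleculeSet:
    """Piecewise-homogeneous field emulating micropatterned adhesive stripes.

    Vertical stripes of width ``stripe_width_nm`` at ``density_stripe``
    alternate with passivated gaps of width ``gap_width_nm`` at
    ``density_gap`` (1 µm fibronectin stripes / 2 µm passivation by
    default).
    """
    if stripe_width_nm <= 0 or gap_width_nm <= 0:
        raise ValueError("widths must be positive")
    if density_stripe < 0 or density_gap < 0:
        raise ValueError("densities must be >= 0")
    rng = as_rng(seed)
    dmax = max(density_stripe, density_gap)
    if dmax == 0:
        return MoleculeSet(species, np.empty((0, 2)))
    candidates = gen_random_field(dmax, roi, rng, species=species).points
    period = stripe_width_nm + gap_width_nm
    in_stripe = np.mod(candidates[:, 0], period) < stripe_width_nm
    p_keep = np.where(in_stripe, density_stripe / dmax, density_gap / dmax)
    keep = rng.random(len(candidates)) < p_keep
    return MoleculeSet(species, candidates[keep])


def in_stripe(xy: np.ndarray, stripe_width_nm: float = 1000.0,
              gap_width_nm: float = 2000.0) -> np.ndarray:
    """Boolean mask: which points fall on the adhesive stripes."""
    xy = np.atleast_2d(xy)
    return np.mod(xy[:, 0], stripe_width_nm + gap_width_nm) < stripe_width_nm


# ---------------------------------------------------------------------------
# binding kinetics and localization rendering


def simulate_kinetics(layout: SiteLayout, cfg: KineticsConfig, seed=None) -> List[KineticTrace]:
    """Alternating dark/bright renewal process per docking site.

    Dark durations are exponential with rate influx_rate x
    sites_per_position (superposition of identical sequences); bright
    durations are exponential with mean ``mean_bright_s``.  Events are
    quantized to frames: a frame counts as occupied when the event overlaps
    it by at least ``min_frame_overlap`` of the exposure, and events
    touching after quantization are merged.
    """
    rng = as_rng(seed)
    rate = cfg.influx_rate * layout.sites_per_position
    total = cfg.total_time_s
    traces = []
    for site_id in range(len(layout)):
        traces.append(KineticTrace(site_id, _one_site_events(rate, cfg, total, rng),
                                   exposure_s=cfg.exposure_s))
    return traces


def _one_site_events(rate: float, cfg: KineticsConfig, total: float,
                     rng: np.random.Generator) -> List[Tuple[int, int]]:
    if rate == 0:
        return []
    events_s: List[Tuple[float, float]] = []
    t = rng.exponential(1.0 / rate)
    while t < total:
        dur = rng.exponential(cfg.mean_bright_s)
        events_s.append((t, min(dur, total - t)))
        t += dur + rng.exponential(1.0 / rate)
    # frame quantization with the >= min_frame_overlap rule
    out: List[Tuple[int, int]] = []
    for start, dur in events_s:
        f0 = int(np.floor(start / cfg.exposure_s))
        f1 = int(np.floor((start + dur) / cfg.exposure_s))
        frames = []
        best_f, best_ov = None, -1.0
        for f in range(f0, min(f1, cfg.n_frames - 1) + 1):
            lo = max(start, f * cfg.exposure_s)
            hi = min(start + dur, (f + 1) * cfg.exposure_s)
            if (hi - lo) > best_ov:
                best_f, best_ov = f, hi - lo
            if (hi - lo) >= cfg.min_frame_overlap * cfg.exposure_s:
                frames.append(f)
        if not frames:
            if best_f is None:
                continue
            frames = [best_f]  # every event yields at least one localization
        s, d = frames[0], frames[-1] - frames[0] + 1
        if out and s <= out[-1][0] + out[-1][1]:  # merge zero-frame gaps
            prev_s, prev_d = out.pop()
            s, d = prev_s, max(prev_s + prev_d, frames[-1] + 1) - prev_s
        out.append((s, d))
    return out


def render_localizations(traces: Sequence[KineticTrace], layout: SiteLayout,
                         cfg: KineticsConfig, seed=None,
                         species: str = "") -> LocalizationTable:
    """One localization per occupied frame per site.

    Positions are the site coordinate plus isotropic Gaussian noise of SD
    ``sigma_nm``; photon counts follow a geometric distribution with the
    configured mean (positive-integer noise, irrelevant downstream except
    for precision weighting).
    """
    rng = as_rng(seed)
    xs, ys, frames, sites = [], [], [], []
    for trace in traces:
        occ = trace.occupied_frames()
        if len(occ) == 0:
            continue
        base = layout.coords[trace.site_id]
        noise = rng.normal(0.0, cfg.sigma_nm, size=(len(occ), 2)) if cfg.sigma_nm > 0 \
            else np.zeros((len(occ), 2))
        xs.append(base[0] + noise[:, 0])
        ys.append(base[1] + noise[:, 1])
        frames.append(occ)
        sites.append(np.full(len(occ), trace.site_id, dtype=np.int64))
    if not xs:
        df = pd.DataFrame({"x": [], "y": [], "frame": [], "photons": [],
                           "precision": [], "site_id": []})
        df["frame"] = df["frame"].astype(np.int64)
        return LocalizationTable(df, n_frames=cfg.n_frames,
                                 exposure_ms=cfg.exposure_s * 1e3)
    x = np.concatenate(xs)
    n = len(x)
    photons = rng.geometric(1.0 / cfg.mean_photons, size=n).astype(np.int64)
    df = pd.DataFrame({
        "x": x, "y": np.concatenate(ys),
        "frame": np.concatenate(frames),
        "photons": photons,
        "precision": np.full(n, cfg.sigma_nm),
        "site_id": np.concatenate(sites),
    })
    if species:
        df["species"] = species
    df = df.sort_values(["frame", "x", "y"], kind="mergesort").reset_index(drop=True)
    return LocalizationTable(df, n_frames=cfg.n_frames, exposure_ms=cfg.exposure_s * 1e3)


def simulate_imaging(layout: SiteLayout, cfg: KineticsConfig, seed=None,
                     species: str = "") -> Tuple[LocalizationTable, List[KineticTrace]]:
    """Convenience wrapper: kinetics + rendering with one seed."""
    rng = as_rng(seed)
    traces = simulate_kinetics(layout, cfg, rng)
    table = render_localizations(traces, layout, cfg, rng, species=species)
    return table, traces
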