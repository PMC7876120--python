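# Methods

This note documents the models behind `qsmcl`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Units and conventions

All lengths are nanometres internally; camera-pixel units exist only at
the I/O boundary (`px_to_nm`/`nm_to_px`, default pixel size 130 nm —
typical for an sCMOS TIRF system after 2×2 binning).  Densities are
molecules/µm².  Frames are 0-based over `[0, n_frames)`; times in
seconds.  Coordinates are continuous with the origin at the ROI corner.

## Synthetic data (`paint_sim`)

The generator stands in for all experimental data and defines the
conditions under which the pipeline is validated:

* **Molecule layouts.** Homogeneous Poisson fields (counts Poisson in
  the ROI area, positions i.i.d. uniform); two-species populations in
  which a fraction *c* of species B is re-placed at a distance drawn
  uniformly from 12–16 nm (uniform angle) from a distinct species-A
  molecule — the distance scale of a directly bound binary complex;
  ternary populations in which anchor molecules (e.g. active receptors,
  default 150/µm²) are additionally placed 12–16 nm from complexed
  pairs; striped fields (1 µm adhesive / 2 µm passivated) for
  patterned-substrate scenarios; square origami grids (default 20 nm
  pitch) with 1 or 3 concatenated binding sequences per site.
  Uniform sampling of the 12–16 nm pair distance is the neutral reading
  of that range; a different complex-distance law can be passed through
  `dist_range_nm`.
* **Labeling.** Incomplete labeling is independent Bernoulli thinning
  at the labeling efficiency (defaults 30% HaloTag, 20% SNAP-tag — the
  published values for these tags).  Detection-efficiency thinning can
  be applied the same way where a scenario calls for it.
* **Kinetics.** Each docking site alternates exponentially distributed
  dark (mean `1/(ξ·s)`, with *s* concatenated sequences) and bright
  (mean 0.5 s) periods.  Defaults: influx ξ = 0.02/s per sequence
  (mean dark time 50 s — a plausible DNA-PAINT regime at calibration
  imager concentration), 80,000 frames at 100 ms exposure for
  NND-style runs and 160,000 frames for qPAINT-style runs.  All
  parameters are overridable; the defaults are the package's declared
  study conditions, not fitted values.
* **Frame quantization.** An event marks every frame it overlaps by at
  least half the exposure, and always at least its maximum-overlap
  frame — an event never disappears entirely, which keeps the detected
  event rate equal to the generative influx rate (dropping sub-half-
  frame events would bias dark times ~10% upward at the default bright
  time).  Events that touch after quantization are merged.
* **Rendering.** One localization per occupied frame per site, at the
  site coordinate plus isotropic Gaussian noise of SD σ (default 7 nm);
  photon counts are geometric around the configured mean and do not
  enter any downstream statistic.

What the generator does **not** emulate: camera frames and spot fitting
(the package consumes localization tables, not movies), drift, uneven
illumination, imager concentration gradients, multi-valent antibody
labeling, sticking/background localizations (these can be injected
explicitly when testing the filters), and 3D.  Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
declared model, not robustness to every experimental artifact.

## Cluster pipeline (`cluster_pipeline`)

**NeNA precision.** Localizations of the same site in consecutive frames
differ by a displacement whose density is
`p(d) = d/(2σ²) · exp(−d²/4σ²)` when each localization carries precision
σ.  The estimator collects nearest-neighbor distances between
consecutive-frame localizations and uses the closed-form MLE
`σ² = ⟨d²⟩/4`, iterated three times with a 5·σ√2 cut to reject
cross-site background pairs (the cut removes ~3·10⁻⁴ of the true pair
mass, so its bias is negligible while making the estimate robust to
sparse background).

**DBSCAN.** Standard core/border/noise semantics via scikit-learn.
Defaults: ε = the dataset's NeNA precision; `min_pts = max(10, 0.3 ×
expected localizations per site)`, where the expectation follows from
the binding kinetics (ξ · acquisition time · mean bright frames).  Input
is sorted by (frame, x, y) before clustering so border-point assignment
is independent of row order.  Convex-hull areas come from scipy's
ConvexHull (0 for clouds with < 3 points).

**Mean-frame filter.** Clouds are kept when their mean frame lies within
`multiplier × spread` of the population center (median of all cloud mean
frames).  The default spread convention is the *uniform-window scale*
`n_frames/√12` — the SD of a uniform frame distribution over the
acquisition.  A genuine site revisited over the whole run has a mean
frame tightly concentrated near `n_frames/2` (SD ≈ 0.29·n_frames/√n_events),
so it always passes; unspecific signals confined to one part of the
acquisition fall outside.  Conventions that estimate the spread from the
cloud population itself ("robust": 1.4826×MAD; "population": plain SD)
are provided but not default: a ±1×population-SD cut removes ~32% of a
clean unimodal population by construction, costing detection efficiency
on artifact-free data and making the filter non-idempotent.  The
uniform-window cut is idempotent up to the (tiny) drift of the median.

**Std-frame filter.** Clouds are kept when the SD of their frame numbers
is at least `0.2 × n_frames`.  A uniformly revisited site sits at
`n_frames/√12 ≈ 0.289 n_frames`; one contiguous sticking event of length
L has SD `L/√12`, orders of magnitude below the cutoff for any realistic
L.  The 0.2 default leaves a wide margin on both sides.

**Detection efficiency.** Cluster centroids are matched one-to-one to
labeled ground-truth molecules within a 50 nm radius by optimal
assignment (maximum number of matches, ties broken by minimal total
distance, via the Hungarian algorithm); DE = matched/labeled.  A greedy
distance-ordered variant is available for very large matchings; it
agrees with the optimal matching on sparse instances but can drop pairs
on dense radius graphs.

**Resolution benchmark.** Pairs of docking sites at a set separation are
placed on a coarse grid (1 µm pitch), imaged with the default kinetics,
clustered with ε = NeNA precision and filtered; a pair counts as
resolved when exactly two retained clouds lie in its neighborhood.  With
7 nm noise and 80,000 frames the pipeline resolves ≥ 90% of pairs at
25 nm and above while 20 nm pairs merge — the per-pair success
probability at 25 nm is ≈ 0.95, so benchmarks use ≥ 60 pairs per
separation to keep binomial noise well below the 90% margin.

## qPAINT (`qpaint`)

Binding of imagers to one site is Poisson, so uncensored dark times are
exponential with mean `τ_d = 1/ξ`.  Calibration pools the dark times of
single-site reference traces: `τ_d,cal` = pooled mean, `ξ = 1/τ_d,cal`
("one unit per binding site").  A cloud containing *n* independent sites
is the superposition of *n* Poisson processes, hence
`n̂ = τ_d,cal / τ̄_d(cloud)`.  The default dark-time estimator is the
arithmetic mean of uncensored gaps (unbiased under the exponential
model); an `mle` option includes the censored leading/trailing gaps
(total dark time ÷ number of uncensored gaps), which removes a small
downward bias on traces with few events.  Clouds detected by DBSCAN are
converted to traces by marking their member frames occupied and merging
consecutive frames into events.  Estimates are reported raw and rounded;
traces with fewer than two events yield a flagged NaN.

## Spatial statistics (`spatial_stats`)

Nearest-neighbor distances are exact (scipy cKDTree; the query point is
excluded for self-NND; points lacking a k-th neighbor are excluded and
counted, never imputed).  Experimental-style NNDs carry no edge
correction; simulation benchmarks may use the toroidal `boxsize` option
to isolate estimator bias from edge effects.

The order-k Poisson fit uses the closed-form MLE
`ρ̂ = k·n / (π Σ rᵢ²)` (for k = 1 this reduces to the standard
first-neighbor law), a Wald interval from the Fisher information
(`var ≈ ρ²/(nk)`), and a Kolmogorov–Smirnov goodness-of-fit p-value
against the fitted CDF `P(k, πρr²)` (regularized incomplete gamma).  A
histogram least-squares option on log-spaced bins exists for parity with
figure-style fitting; the two agree within sampling noise on CSR fields.
Closed forms used in validation: mean order-k NND
`Γ(k+½)/((k−1)!√(πρ))`, i.e. `0.5/√ρ` at k = 1 (20.41 nm at 600/µm²).

## Complex-fraction calibration (`coloc_quant`)

The observed colocalization fraction is the share of source molecules
whose nearest reference molecule lies within 25 nm.  The default source
is the species with the lower labeled density (its fraction has the
larger dynamic range); a pooled symmetric mode (count-weighted average
of both directions) is available.

Calibration curves simulate, for each c on a grid (default 0–100% in 10%
steps, 20 replicates, 10×10 µm ROI — MC error of the mean < 1 point),
the complex population at the configured densities (default 611/µm² for
both species — the extrapolated absolute density scale), thin by the
LEs, and record the observed fraction.  The c = 0 endpoint reproduces
the analytic CSR baseline `1 − exp(−πρ_labeled r²)`; DE thinning is off
by default (complexes survive detection loss identically on both
species, so LE dominates the mapping) and can be switched on.

Inversion uses monotone piecewise-linear interpolation of the replicate
means (isotonically cleaned); the uncertainty interval is where the
observation ± its SE crosses the curve ± its SD.  Observations outside
the curve range are clipped to [0, 1] and flagged.  Absolute density
extrapolation is exact arithmetic `ρ_measured/(LE·DE)`; extrapolated
densities are displayed integer-truncated, and scenario summaries report
the arithmetic mean with the population (÷n) SD.

## Ternary statistics (`ternary_stats`)

Tuples are exact nearest-neighbor distances from each anchor to two
reference species.  The two-sample 2D Kolmogorov–Smirnov statistic is
the maximum, over the data points of both samples and the four quadrant
orientations, of the difference in empirical quadrant fractions; points
on a quadrant boundary count toward the closed lower-left quadrant.  The
statistic is symmetric and invariant under common monotone rescalings of
both coordinates.

The bootstrap draws `subsample` tuples (default 1000) without
replacement from each dataset per run (default 1000 runs) and reports
the mean D ± SD.  The null distribution is built the same way *within*
each dataset (two disjoint subsamples per run); the p-value is the
fraction of null draws ≥ the mean cross D.  This construction is
deliberately conservative: under the null the mean cross D concentrates
at the center of the null distribution, so p ≈ 0.5 rather than uniform,
and the false-rejection rate at any α is essentially zero.  It cleanly
separates the intended cases — self-comparisons of one population give
high p, while anchored-complex tuples against CSR tuples at matched
densities give D an order of magnitude above the subsampling noise floor
and p = 0 to bootstrap resolution.  Subsampling without replacement
avoids duplicate points degenerating the quadrant counts.

## Problem sizes and determinism

Simulation-backed tests and the acceptance script run at desk scale:
10×10 µm ROIs (≈ 6·10⁴ molecules at 600/µm²), 10⁴-point fields for
density-recovery checks (replicate-averaged, since a single fit has ~1%
sampling SD), 200 reference sites for qPAINT calibration, 60–100 site
pairs per separation for the resolution benchmark, and bootstrap runs of
100–250 where the full 1000×1000 procedure is statistically redundant.
Every stochastic stage takes an integer seed or a numpy Generator;
identical seeds reproduce outputs bit-identically.  CLI runs expand one
global seed into per-stage seeds by hashing the stage name, so adding a
stage never perturbs earlier stages' streams, and every run writes a
manifest (resolved config, seeds, SHA-256 digests of inputs/outputs).

## Known limitations

* The pipeline is 2D throughout.
* NeNA assumes repeated visits dominate consecutive-frame pairs; it
  degrades at very high cluster densities where cross-site pairs enter
  the core of the displacement distribution.
* qPAINT assumes site-independent, stationary kinetics; photophysics
  (imager depletion, photodamage) is not modeled.
* The calibration-curve inversion propagates Monte-Carlo and replicate
  spread but not uncertainty in the assumed LEs; mis-specified LEs shift
  the recovered complexed fraction systematically.
* The bootstrap p-value is conservative by construction (see above); it
  is a goodness-of-separation summary, not a calibrated frequentist
  test.
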