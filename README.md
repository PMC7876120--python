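# qsmcl — quantitative single-molecule colocalization analysis

`qsmcl` is a Python library (plus a thin `qsmcl` command-line tool) for
absolute quantification of DNA-PAINT single-molecule localization data.
Techniques with single-protein resolution see only a fraction of the true
molecules: typical labeling efficiencies (LE) are 20–30% per tag and
automated cluster detection recovers another ~50–60% (detection
efficiency, DE).  Any raw colocalization percentage between two imaged
species is therefore confounded by both efficiencies and by a
density-driven random baseline.  This package implements the full
analysis chain that turns such data into absolute molecular quantities —
molecular densities, binding-site numbers per localization cloud, true
complexed fractions, and significance tests for ternary association —
exercised end-to-end on a built-in synthetic-data generator, since the
kind of experimental data it targets (adhesion-protein localization
tables) is not publicly deposited.

It is aimed at microscopists and image analysts working with
localization tables (Picasso-style CSV/HDF5) from DNA-PAINT or similar
SMLM experiments.

## What it computes

* **Cluster detection** (`cluster_pipeline`): DBSCAN on localization
  coordinates with ε set to the data's own NeNA localization-precision
  estimate, followed by two temporal filters — a *mean-frame* filter
  (genuine docking sites are revisited over the whole acquisition, so
  their mean frame sits near `n_frames/2`) and a *std-frame* filter
  (a single long sticking event has a small frame SD, a uniformly
  revisited site has SD `n_frames/√12 ≈ 0.289 n_frames`).
* **qPAINT counting** (`qpaint`): imager binding on one site is Poisson
  with influx rate ξ, so dark times are exponential with mean
  `τ_d = 1/ξ`; a cloud with *n* sites shows mean dark time `τ_d/n`.
  After calibrating ξ on single-site references, the number of binding
  sites in a cloud is `n̂ = τ_d,cal / τ̄_d(cloud)`.
* **Spatial statistics** (`spatial_stats`): exact k-d-tree nearest-
  neighbor distances (within and across species) and maximum-likelihood
  fits of the homogeneous-Poisson order-k neighbor law

  `P_k(r) = 2(πρ)^k r^(2k−1) e^(−πρr²) / (k−1)!`

  (for k = 1 the familiar `P(r) = 2πrρ e^(−πρr²)`), giving the molecular
  density ρ and a goodness-of-fit test against complete spatial
  randomness; molecular density per region mask.
* **Complex-fraction calibration** (`coloc_quant`): Monte-Carlo
  calibration curves mapping a true complexed fraction c ∈ [0, 1] (pairs
  placed 12–16 nm apart, both species thinned by their LE) to the
  expected observed 25 nm colocalization, with monotone inversion back
  to c; absolute-density extrapolation `ρ_true = ρ_measured/(LE × DE)`.
* **Ternary statistics** (`ternary_stats`): per-anchor nearest-neighbor
  distance tuples (e.g. integrin → nearest kindlin, nearest talin), 2D
  two-sample Kolmogorov–Smirnov statistics (quadrant fractions maximized
  over data points), and a subsampling bootstrap with a within-dataset
  self-comparison null.
* **Synthetic data** (`paint_sim`): Poisson molecule fields
  (50–1000/µm²), complexed two-species and anchored ternary populations,
  DNA-origami grids with 1× or 3× concatenated binding sequences,
  frame-quantized exponential blinking kinetics over 80,000–160,000
  frames at 100 ms exposure, and Gaussian localization noise (7 nm).

## Worked example

Counting binding sites per localization cloud
(`python examples/02_qpaint_counting.py`):

```
calibrated influx rate: 0.0201/s (mean dark time 49.9 s from 200 sites)
1x binding sequences: median count 1 (raw 1.00 +- 0.05)
2x binding sequences: median count 2 (raw 1.98 +- 0.09)
3x binding sequences: median count 3 (raw 2.97 +- 0.08)
```

The influx rate recovered from 200 simulated single-site references
matches the generative 0.02/s, and clouds carrying two or three
concatenated binding sequences count 2 and 3 — the estimator is linear
in the true site number, which is what lets a single-site calibration
count molecules inside crowded structures.

Recovering an absolute complexed fraction
(`python examples/04_coloc_calibration.py`):

```
complexed fraction -> 0% 10% 20% 30% 40% 50% 60% 70% 80% 90% 100%
observed coloc     -> 30% 32% 34% 37% 39% 40% 43% 45% 47% 49% 51%
baseline curve(0) = 0.302; CSR closed form 1-exp(-pi rho r^2) = 0.302
simulated truth c = 55%: observed 41.5% -> inverted c = 55% (CI 53%-56%)
```

At 611 molecules/µm² with 30%/20% labeling, even zero complexation shows
30% colocalization (pure density effect, matching the analytic
`1 − e^(−πρr²)` baseline), and full complexation saturates near 51%
because most partners are unlabeled.  Inverting an observed 41.5%
through the curve recovers the simulated truth of 55% complexed.

The other examples cover cluster detection with NeNA-derived parameters
(`01`), nearest-neighbor density fitting (`03`), and ternary bootstrap
statistics (`05`).  The same stages are available as shell commands:
`qsmcl simulate|cluster|qpaint|nnd|coloc|ternary|pipeline` (each run
writes a JSON manifest with the resolved configuration, seeds, and file
digests).

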