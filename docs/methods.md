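# Methods

`dropvol` implements the measurement chain behind absolute DNA quantification
by droplet digital PCR (ddPCR), from droplet sizing in bright-field
micrographs to volume-corrected copy numbers. This note documents the models,
the defaults and why, the numerical choices, and what the synthetic data do
and do not establish.

## The quantification model

A ddPCR reaction partitions a 20 µL mix into ~nL water-in-oil droplets. With
target molecules randomly distributed over partitions, the number of copies
per droplet is Poisson, and the mean occupancy is recovered from the fraction
of negative droplets:

    Tc = -ln(1 - P/R) · (1/Vd) · D

with `P` positive partitions, `R` accepted partitions, `Vd` the droplet
volume and `D` the sample dilution factor. `Tc` is linear in `1/Vd`, so a
relative error in the assumed droplet volume propagates one-to-one into the
copy number: re-expressing a concentration under a different volume is the
exact rescaling `Tc' = Tc · Vd/Vd'`, and using a fixed volume `V_f` when the
true volume is `V_m` understates copy numbers by `100·(V_f − V_m)/V_f` %.
Two consequences the package makes explicit:

* **GM%** (transgene/endogene copy ratio × 100, the regulatory quantity in
  GMO testing) is invariant to any common volume error. The pipeline
  computes it directly from the partition counts of the duplex pair,
  `100 · ln(1−P_gm/R) / ln(1−P_endo/R)`, where `Vd` and `D` cancel
  *algebraically* — so fixed-volume and measured-volume reports carry
  identical floats, not merely approximately equal ones.
* **Generator bias** between two droplet generators is reported with the
  automated-generator group as the reference (denominator); the reference is
  configurable (`RunConfig.reference_generator`, default: alphabetically
  first generator name).

Reactions with fewer than 10,000 accepted partitions per 20 µL are rejected
before any statistics; the rule is a strict inequality (exactly 10,000
passes). Negative template controls are reported separately and raise a
contamination warning above a configurable positive-droplet threshold
(default 5).

## Droplet sizing from bright-field micrographs

Droplets in a monolayer appear as a bright interior bounded by a darker
interfacial ring. The automatic measurement chain:

1. background = median grey level of the frame; work on |image − background|,
   which captures interior and ring alike;
2. Gaussian smoothing (σ = 1 px default), then a global threshold at
   `threshold_scale` (default 0.5) × the Otsu level of the deviation image.
   Otsu separates background from droplet interior; half of it sits near the
   half-amplitude of the ring — the outermost droplet feature — which keeps
   the measured boundary on the true rim rather than inside it (a full Otsu
   cut biases diameters low by ~2 %);
3. hole filling and removal of sub-droplet speckle;
4. touching droplets split by a distance-transform watershed seeded at
   > 0.6 × each component's EDT maximum (per-component seeding avoids the
   plateau ambiguities of local-maximum detection on near-perfect disks);
5. region measurement with scikit-image, the µm/px calibration carrying all
   quantities to physical units. Area-equivalent diameter is `2·√(A/π)`;
   perimeters use the 4-direction Crofton estimate (circularity is
   convention-sensitive, so the convention is fixed and recorded).

Filters, all configurable: border-touching rejected; diameter gate
[50, 200] µm (droplets cluster near 111 µm; gates are generous but exclude
debris); circularity ≥ 0.9 (discretisation can push a perfect disk slightly
above 1; values are reported as computed); aspect-ratio (sphericity) gate
(major − minor)/major ≤ 0.05 — reference profilometry of such droplets finds
mean axis differences below 2 %, so 5 % is deliberately permissive. Counts
are conserved: accepted + rejected = detected. A blank or saturated frame
returns zero records with a `low-contrast` flag instead of raising.

Coordinates are pixel centres, origin top-left, x right / y down. Droplets
are measured per frame; no cross-frame deduplication is attempted.

## Volumes and the uncertainty budget

Volumes assume spherical droplets, `V = (π/6)d³` (µm³ → nL at 1e6 µm³/nL).
Per-well summaries average **per-droplet volumes**, never the volume of the
mean diameter: the cube is convex, so the two differ (Jensen), and published
per-well mean volumes exceed `(π/6)d̄³`, the signature of per-droplet
averaging.

Well mean volumes are screened with iterative two-sided Grubbs tests
(α = 0.05 default; critical values from the Student-t form
`G = (n−1)/√n · √(t²/(n−2+t²))`, `t = t_{α/2n, n−2}`); flagged wells are
excluded from all downstream statistics. An all-identical group yields no
outliers, and the screen is idempotent after convergence.

The bottom-up budget for the mean droplet volume uses one-way ANOVA mean
squares:

    u_r   = √MS_within / √n
    u_ip1 = √((MS_between − MS_within)/(n·N))    if MS_between > MS_within
    u_ip2 = √(MS_within/n) · (2/(N(n−1)))^¼ / √N  otherwise
    u_c   = √(u_r² + u_ip²),    U = k·u_c

The branch rule is strict (`ip1` iff MS_between > MS_within). The coverage
factor defaults to k = 2.1 (≈95 % confidence at the effective degrees of
freedom of a 6×3 design); configurable.

**Grouping.** By default the ANOVA is computed on *per-droplet volumes
grouped by measurement day* (all measurements taken into account: N = days,
n = droplets per day, harmonic mean when unbalanced after outlier removal).
This is the only grouping that yields expanded uncertainties in the
~0.013–0.016 nL range observed for such studies while remaining consistent
with inter-well volume RSDs of a few percent; treating wells as the
replicates (n = 6) would inflate U to ~0.03 nL at those RSDs. A
`budget_level="well_means"` mode (groups = days, replicates = well means) is
provided for sensitivity analysis, along with wells-as-groups ANOVA/Tukey
for intra/inter-cartridge effect tests.

## Synthetic data: what it emulates, what it does not

The generators exist so every stage is testable without any instrument data;
they are first-class, tested code.

* **Micrographs**: droplets rendered as bright disks with a darker ring
  (default width 3 px) *inside* the true boundary, so the ground-truth disk
  is exactly the region deviating from background; edges are anti-aliased by
  linear coverage; additive Gaussian noise; non-overlapping dart-throwing
  placement (explicit centres may touch or cross the frame for edge-case
  tests; infeasible packing raises rather than silently truncating). Not
  modelled: optical PSF/defocus, illumination gradients, multi-focal stacks.
  Segmentation accuracy measured on these images (≤0.05 % per droplet
  noiseless, ≤1 % mean at 10 % noise) is an upper bound on real-image
  performance, where focus and illumination dominate.
* **Hierarchical diameters**: grand mean + normal day, well and droplet
  effects (the diameter distribution family is an assumption; only means and
  SDs of real droplet populations are published). Defaults are the study
  conditions: grand mean 110.94 µm (0.715 nL sphere), within-well SD 2 µm
  (≈0.04 nL), between-well SD 1 µm, between-day SD 0.36 µm, 6 wells × 3 days
  × 172 droplets. The well/day components are calibrated so day-mean volumes
  spread by ≈0.0105 nL, matching the observed day-to-day variation (and
  hence U ≈ 0.013 nL); this puts the inter-well RSD near 3 %, below the
  ~5 % such studies report — the two published observables are mutually
  inconsistent under an additive normal hierarchy, and the day-level spread
  is the one that drives the budget.
* **Partition counts**: exact inverse of the estimator — occupancy
  `m = (c/D)·Vd`, positives Binomial(R, 1−e^(−m)); saturation (p → 1) warns.
  The duplex wells generator adds a `deterministic` mode (positives =
  rounded expectation) that pins group means to ~0.01 % for worked-example
  reproduction; it models no inter-replicate pipetting variance, so
  realistic ~5 % repeatability RSDs are *not* reproduced by counting noise
  alone (binomial RSDr at R = 15,000 is ~0.2 %).

A single simulated 6×3 study estimates the between-day variance with 2
degrees of freedom, so its U scatters roughly twofold around the population
value; stochastic checks therefore aggregate replicate studies (mean of
recovered means; RMS of U, since variances — not SDs — add).

## Numerical and degenerate-input choices

* `−ln(1−P/R)` is computed as `−log1p(−P/R)` for accuracy at low occupancy;
  P = R raises a `SaturationError` (estimator unbounded), P > R a
  `ValueError`.
* Sample SDs everywhere (ddof = 1); a single-droplet well reports SD 0 with
  a flag rather than NaN.
* ANOVA mean squares are computed directly (scipy's `f_oneway` hides them)
  and cross-checked against scipy in tests; Tukey HSD comes from
  `scipy.stats.tukey_hsd`.
* Grubbs on < 3 values raises; zero-variance groups yield no outliers.
* Bias and RSDs against a zero reference are NaN inside aggregated reports
  and errors in the scalar functions.
* Report rounding: concentrations to nearest integer copies/µL, bias and
  GM% to two decimals.

## Problem sizes used in tests and the acceptance script

Imaging recovery uses 10 frames × 100 droplets at 0.5 µm/px (3200² px);
volume-study checks use 60 replicate 6×3×172 studies; the Poisson round trip
uses 100 seeded experiments of 6 reactions at R = 15,000. These sizes match
the scale of the emulated study while keeping each stage to seconds or a few
minutes.

## Known limitations

* No optical simulation, so imaging accuracy claims transfer to real
  micrographs only up to focus/illumination effects.
* The expanded uncertainty of GM% is reported as k·s/√n over replicate
  wells — a pragmatic convention, not a full bottom-up budget.
* No within-reaction droplet-volume dispersion correction (volume
  variability *within* a reaction biases the Poisson estimate; only
  between-reaction/generator volume differences are handled).
* Dilution-factor semantics: concentrations are always copies/µL of the
  undiluted sample; `D` defaults to 1 and is explicit in all I/O.
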