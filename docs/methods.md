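# Methods

## The estimator

The nuclear fractal dimension of a core image is the global maximum,
over an intensity-threshold sweep, of box-counting dimensions of nuclear
*outline* images. The procedure assumes a single-channel grayscale image
in which nuclei are bright on a dark background (DAPI-like,
background-subtracted fluorescence), with a known pixel calibration.
It is deliberately set-level: no nucleus instance segmentation, no
per-nucleus features. Color/brightfield inputs and multi-channel images
are rejected rather than converted, so acquisition errors surface
immediately.

Steps, with every numerical choice stated:

* **Thresholds.** 64 equally spaced integer levels strictly between the
  image's 1st intensity percentile and its maximum, duplicates removed.
  Anchoring on observed intensities adapts the sweep to 8- vs 16-bit
  ranges without per-image tuning. The upper anchor is the maximum
  rather than a high percentile so that images whose foreground occupies
  a tiny pixel fraction (thin calibration structures on a dark field)
  still receive separating thresholds; for typical tissue images the two
  choices give near-identical sweeps. Binarization is inclusive
  (foreground iff intensity ≥ threshold).
* **Outline.** Inner boundary under 4-connectivity: a foreground pixel
  with at least one background 4-neighbour, off-image treated as
  background. This is the thinnest standard boundary.
* **Box sizes.** Dyadic pixel sizes whose physical extent lies in
  3.5–62 μm — at the reference calibration of 0.468 μm/px (20×
  acquisition) that is {8, 16, 32, 64, 128} px, spanning 3.74–59.9 μm.
  The band brackets nuclear-scale structure: single nuclei (~7 μm)
  through small nuclear neighbourhoods. At least 4 sizes are required;
  coarser calibrations that cannot fit 4 dyadic sizes raise an error.
* **Counting.** Occupied cells of an axis-aligned grid anchored at the
  image origin, single placement. An optional refinement (minimum count
  over the four {0, s/2}² offsets) exists but is off by default; the
  single-anchor grid is the textbook method.
* **Fit.** Unweighted OLS of ln N(s) on ln(1/s); the slope is the FD.
  A fit with r² < 0.95 logs a warning but is never excluded —
  low-threshold masks of noisy tissue legitimately bend the log–log
  curve, and excluding them would add a hidden parameter.
* **Skip rule.** Thresholds whose outline is empty, or whose count curve
  is flat (N equal at the smallest and largest box), are skipped: a
  0-point or flat log–log set has no meaningful slope. If every
  threshold is skipped the core raises a no-signal error and is flagged,
  never silently dropped.
* **Maximum.** nFD is the exact arithmetic maximum of the fitted values;
  no smoothing of the FD-versus-threshold curve. Ties resolve to the
  smallest threshold, for reproducibility.
* **Shared-mask shortcut.** Thresholds falling between the same pair of
  observed intensity levels induce identical masks; each distinct mask
  is computed once and its FD assigned to every such threshold. This is
  bit-identical to the naive per-threshold loop (asserted in the tests)
  and makes binary fixtures ~60× cheaper.

### Calibration validity

Box-counting calibration on prefractal fixtures is only meaningful when
the fixture's truncation scale (its finest rendered feature) is smaller
than the smallest box. A Sierpinski carpet rendered with 9-px solid
cells under 8-px boxes violates this: after outline extraction, 8-px
boxes falling inside solid cells count nothing and the smallest-scale
point drops below the asymptotic power law, biasing the slope low
(≈1.75 instead of ≈1.89; kept as a regression test). The calibration
suite therefore renders the carpet at iteration 5 on a 729-px grid
(3-px cells), the Koch curve at iteration 5, and obtains: line 1.000,
circle outline 0.978, Koch 1.207 (truth 1.262), carpet 1.881 (truth
1.893). The Koch deficit is the familiar finite-resolution bias of
1-px polyline renderings; it sits within the ±0.08 calibration band.

## Cohort analysis

Cores failing quality control are excluded: out of focus, folded
tissue, or fewer than 100 tumor cells. Patients keep the mean nFD over
their remaining cores (three by design; fewer tolerated, minimum one)
and the maximum lymphocytic-infiltration (LI) grade over cores. LI is a
four-tier pathologist grade (0–3); for two-group analyses grades {0,1}
are "low" and {2,3} "high" by default (configurable), since the source
analyses dichotomize LI without stating the split.

**Cut-point.** The continuous per-patient score is dichotomized at the
value maximizing the two-group log-rank chi-square on 5-year
disease-specific survival — an emulation of X-tile's optimal cut-point
exploration as an exhaustive scan over midpoints of adjacent distinct
scores, constrained so both groups hold ≥ 10% of patients. Group
assignment at the boundary is strictly-greater-than → high (candidates
are midpoints, so real data never sits on one). Ties in the maximum
resolve to the smaller cut. The naive p-value at an optimized cut is
anti-conservative and is not reported; a Miller–Siegmund-corrected p is
attached as advisory only. The scan is vectorized over candidates
(at-risk × candidate matrices); the test suite pins it exactly to
per-candidate log-rank tests and to a second, independently coded scan.
A maximally selected cut-point is intrinsically noisy: on synthetic
cohorts (n = 300) the selected cut fluctuates around the true class
boundary with an interquartile spread of a few hundredths, so recovery
is summarized by the median over seeded replicates.

**Survival.** The 5-year restriction is applied before everything:
follow-up capped at 60 months; disease-specific death within 60 months
is an event; other-cause deaths and later disease deaths are censored.
Kaplan–Meier estimation, the log-rank test and Cox fits are delegated to
lifelines. Cox models use Efron tie handling and 95% Wald intervals on
the log-hazard scale. Binary codings: high nFD vs low (reference),
T3/T4 vs T1/T2, N1/N2 vs N0, surgery+RT vs surgery. The multivariate
model is {nFD group, pT-stage, pN-status}; because the source reports
two slightly different multivariate effects (with and without a
radiotherapy adjustment), both specifications are exposed via the
`adjust_for_rt` toggle. Radiotherapy-subgroup curves reuse the
cohort-wide cut-point rather than re-optimizing per subgroup — one
dichotomization across all analyses.

**Associations.** Covariate-by-group tables are complete-case per
covariate (a patient missing pT-stage is excluded from pT-stage tests
only). Fisher's exact test uses the point-probability two-sided rule
(sum of hypergeometric probabilities ≤ the observed table's), the
convention of mainstream statistical software; tables with more than two
rows use a full-enumeration generalization for totals ≤ 200 and fall
back to chi-square (logged) beyond. Continuous-score comparisons
between Ki67 or LI groups use the two-sided Wilcoxon rank-sum test by
default, Welch's t as a configurable alternative, with the test used
always labelled — the source does not name its test. No
multiple-testing correction is applied across association rows,
matching the source analyses' convention (α = 0.05).

## Synthetic data

The generator provides every input the pipeline consumes, seeded and
bit-reproducible.

**Core images.** A circular core footprint (diameter 0.94 × image side;
a 0.6 mm core at 0.468 μm/px is ~1280 px) is populated with elliptical
nuclei (semi-axes ~ N(3.5, 0.8) μm, floor 1.5 μm, random orientation)
with Gaussian intensity falloff (σ = semi-axis/2, peak 220 on a
background of 2), max-composited so touching nuclei overlap as in real
tissue, then Gaussian-blurred (σ = 1.2 px) and corrupted with additive
truncated-Gaussian noise (non-negative, capped at 3σ, σ = 1). The
truncation emulates the near-black background of background-subtracted
fluorescence imaging and keeps the noise ceiling below the lowest sweep
threshold. Placement processes: uniform Poisson, Thomas clusters, or
the support of a rendered prefractal — the latter gives images whose
pipeline nFD rank-orders with the support's dimension (the monotone
validity check uses small nuclei, 2 μm, so the support geometry stays
resolvable at the box scales). A guard rejects configurations whose
total nucleus area exceeds 1.5× the footprint area. The generator does
not model photorealistic nuclear texture, chromatin substructure,
staining gradients or imaging vignettes; passing tests demonstrate the
estimator's scaling behaviour, not performance on real slides.

**Cohorts.** Each patient draws a latent class (high with probability
0.234, the published high-nFD fraction), per-core scores
~ N(class mean, 0.125) with means 1.40/1.70, exponential
disease-specific event times with hazard 0.0085/month × HR^[high]
(default true HR 0.1, the protective direction and order of magnitude
of the published univariate effect), independent exponential censoring
(0.005/month) plus administrative censoring at 60 months, and
categorical covariates with class-conditional frequencies loosely
matching the published cohort. The per-core spread (0.125) makes the
marginal score distribution span the published range (1.19–1.84, IQR
1.42–1.64); tighter classes leave the log-rank surface flat across the
inter-class gap so maximal-selection noise, not signal, picks the cut.
The hazard matches the published ~31% five-year disease-death fraction.
Exponential times satisfy the proportional-hazards assumption the
analysis fits; a Weibull shape parameter exists for robustness
experiments. Ground truth (class, latent scores, pre-censoring times)
travels in a separate truth object that analysis code never reads
(enforced by the import graph and tested).

**Margin-exact published cohort.** For recomputing every quantity
derivable from the published contingency tables, `table1_cohort`
constructs a 107-patient cohort whose covariate-by-group counts equal
the printed tables *exactly by construction*: group sizes 82/25,
covariate levels dealt within each group by seeded permutation (so
two-way margins are exact while the joint covariate structure is
randomized), scores placed on the proper side of the 1.55 cut, and a
strongly protective high-class hazard. This is the package's synthetic
stand-in for the unavailable patient-level data — distributional
quantities that depend on more than the printed margins (e.g. the exact
published quartiles) are not reproduced by it.

## Problem sizes

The test suite and acceptance script choose sizes that exercise every
code path at meaningful power: calibration fixtures of 512–1024 px;
image panels of 384–1280 px; cohort recovery at n = 300 with 15
replicates (median-summarized); log-rank type-I error at n = 2000 over
100 replicates; Cox recovery at n = 1000–1500. The full suite runs in a
few minutes on one CPU.

## Known limitations

* The threshold sweep takes a *global maximum*, so any threshold whose
  mask is dense speckle (e.g. untruncated sensor noise above the sweep's
  lower anchor) pushes nFD toward 2. Real deployments should
  background-subtract and rely on the cellularity QC gate; the generator
  models noise below the sweep floor for this reason.
* A maximally selected cut-point has optimistic chi-square and unstable
  location; only the corrected p is attached, and recovery claims are
  median-over-replicates.
* Compartment-restricted scores (tumor-only, stroma-only) accept
  precomputed masks; mask construction (e.g. from pan-cytokeratin
  staining) is out of scope.
* Ki67 grouping and LI grading are consumed as inputs; the package does
  not quantify proliferation or score infiltration.
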