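# nfdim — nuclear fractal dimension scoring for TMA cores

`nfdim` implements a digital-pathology prognostic pipeline for oral
squamous cell carcinoma (OSCC) built around the **nuclear fractal
dimension (nFD)**: a single set-level score that quantifies how densely
DAPI-stained nuclei fill a tissue microarray (TMA) core, integrating
tumor and stromal architecture without segmenting individual nuclei.

## The score

For a grayscale core image, nFD is computed by a multi-threshold
box-counting procedure:

1. **Threshold sweep.** A series of intensity thresholds *t* converts the
   image into binary masks (pixel foreground iff intensity ≥ *t*).
2. **Outline extraction.** Each mask is reduced to the outlines of its
   nuclear regions (inner 4-connected boundary).
3. **Box counting.** For box sizes *s* spanning ~4–60 μm (dyadic pixel
   sizes, {8, 16, 32, 64, 128} px at 0.468 μm/px), the number of occupied
   grid cells *N(s)* is counted, and the fractal dimension is the
   ordinary-least-squares slope of log *N(s)* versus log(1/*s*).
4. **Global maximum.** The core's nFD is the maximum fitted dimension
   over the threshold sweep; the per-patient score is the mean over the
   patient's (quality-passing) triplicate cores.

Downstream, the continuous score is dichotomized at the cut-point
maximizing the two-group log-rank statistic on 5-year disease-specific
survival (an X-tile-style exhaustive scan), and the groups enter
Fisher's-exact association tests, Kaplan–Meier curves and Cox
proportional-hazards models (univariate and multivariate with pT-stage
and pN-status; optionally adjusted for radiotherapy).

Because no cohort data were published, the package ships a first-class
synthetic-data module: analytic prefractal fixtures with known dimension
(line, circle, Koch curve, Sierpinski carpet), rendered DAPI-like core
images with controllable spatial structure, and seeded cohorts with a
known class structure and hazard ratio for end-to-end recovery testing.

## Worked example

```bash
nfd simulate --out-dir demo --n-patients 300 --seed 3
nfd analyze --core-csv demo/cores.csv --clinical-csv demo/clinical.csv --out-dir demo/out
nfd report --out-dir demo/out
```

prints (abridged):

```
optimal cut-point: 1.4449 (chi-square 36.22; 199 low / 101 high)
  univariate nfd_group  HR 0.07 (95% CI 0.02-0.22, P = 0.000)
  univariate pt_stage   HR 1.04 (95% CI 0.65-1.66, P = 0.862)
  univariate pn_status  HR 1.21 (95% CI 0.76-1.93, P = 0.426)
multivariate nfd_group  HR 0.06 (95% CI 0.02-0.20, P = 0.000)
```

The cut-point is the nFD value whose dichotomization maximizes the
log-rank chi-square; HR < 1 for `nfd_group` means patients above the cut
(high nFD) die of disease at a fraction of the low-group rate — here the
pipeline recovers the protective direction and magnitude of the
generator's true hazard ratio (0.1). `demo/out/` also contains the
patient table, the full cut-point scan audit, the association table and
tidy Kaplan–Meier step functions (whole cohort and radiotherapy
subgroups).

The numbered drivers under `analysis/` run the same stages as a
narrative: estimator calibration on prefractals (`01`), synthetic cohort
and image-panel generation (`02`), image scoring (`03`), cut-point and
survival analysis (`04`), and association tests plus recomputation of
every quantity derivable from the published contingency tables (`05`).
Their tables land in `results/`.

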