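# Methods

This note documents the models, conventions and numerical choices behind
`radiomics_repro`: a 2D radiomics pipeline for multi-parametric MRI that
extracts 85 features per region of interest (ROI), selects features by
inter- and intra-observer reproducibility, and reduces redundancy by
correlation clustering — together with the synthetic cohort generator used
to validate every stage end to end.

## The analysis pipeline

### Design

The unit of analysis is one 2D slice of one MR sequence with a manually
delineated ROI (here, a whole lacrimal gland). Six sequence contrasts are
handled: `T1`, `ADC` (derived from b0/b1000 diffusion weightings),
`ipDIXON_T2`, `wDIXON_T2`, and the post-contrast pair `PC_ipDIXON_T1`,
`PC_wDIXON_T1`. Each ROI is delineated three times: `L1` by reader 1, and
`L2.1`/`L2.2` by reader 2 in two sessions, giving inter-observer pairings
(L1/L2.1, L1/L2.2) and an intra-observer pairing (L2.1/L2.2). The full
design is 37 patients x 2 glands x 6 sequences = 444 ROIs per reading, or
37,740 feature values per reading.

### ADC computation

The apparent diffusion coefficient is the per-pixel log-linear slope of
signal decay between two diffusion weightings:

    ADC = ln(S_b_low / S_b_high) / (b_high - b_low)    [mm^2/s]

with defaults b_low = 0, b_high = 1000 s/mm^2. Pixels with non-positive
signal are flagged missing (NaN); negative ADC (signal increase, i.e.
noise) is preserved, not clipped. ADC images carry values in units of
10^-3 mm^2/s.

### Discretization

Grey levels are discretized with an *absolute* (fixed-bin-size) scheme
anchored at zero: `level(x) = floor(x / w) + 1` with bin width w = 20
signal units; [0, 20) is level 1, [20, 40) level 2, and so on. The number
of grey levels used to size texture matrices is the maximum occupied level
within the ROI (no global cap). Discretization is monotone by
construction.

Two edge conventions, both recorded in extraction provenance:

* **ADC rescaling.** An absolute bin width of 20 is degenerate for ADC
  values of order 10^-3: every pixel would land in level 1. ADC maps are
  therefore multiplied by 1000 before feature computation (to
  10^-6 mm^2/s, the convention scanners use when storing ADC as
  integers), so w = 20 corresponds to 0.02 x 10^-3 mm^2/s per bin. This
  is a declared convention — nothing in the fixed-bin-width rule itself
  dictates the ADC unit.
* **Negative values.** The binning rejects negative inputs; in the
  extraction pipeline, pixels below the anchor (noisy ADC) are assigned
  to the first bin, while raw-value statistics (mean, skewness, ...) keep
  the negative values as-is.

### The 85 features

The schema is frozen at 85 names in six families, with family prefixes
disambiguating duplicate short names (e.g. `glcm_Contrast` vs
`ngtdm_Contrast`):

* **Shape (13)** — Convex Area, Deficit, Eccentricity, Elongation,
  Extension, Major/Minor Axis Length, Maximum Diameter, Maximum Geodesic
  Diameter, Perimeter, Perimeter Solidity, Solidity, Surface Area. Shape
  features consume only the mask and pixel spacing (lengths in mm, areas
  in mm^2) and are invariant to grid translation and equivariant under
  spacing scaling. Conventions: perimeters are lengths of the 0.5-level
  marching-squares contour (applied identically to the ROI and its convex
  hull, so Perimeter Solidity = hull perimeter / perimeter is consistent);
  axis lengths are 4*sqrt(eigenvalue) of the pixel-center covariance; the
  geodesic diameter is the longest shortest path between boundary pixels
  on the 8-connected pixel graph with physical edge lengths. "Perimeter
  Solidity" is implemented as the perimeter ratio; the name sometimes
  circulates with a contradictory "(Eccentricity)" gloss, which we do not
  follow.
* **First-order (15)** — population-moment statistics of the raw ROI
  values (STD with divisor N; Kurtosis as the raw fourth standardized
  moment, not excess-corrected), plus Entropy and Uniformity computed on
  the discretized-level histogram. Npix is the delineated pixel count.
  Skewness/Kurtosis of a constant or single-pixel ROI are flagged missing.
* **GLCM (26)** — built at distance 1 over the four 2D angles, counts
  *summed* over angles into one symmetric matrix before normalisation
  (merged-matrix convention), pairs restricted to ROI pixels. Formulas
  follow IBSI where the name is standard. Non-standard names are declared
  conventions (written out in `features/texture.py`): Agreement is
  Cohen's kappa of the matrix against its marginals; Homogeneity 1 /
  Homogeneity 2 are inverse difference and inverse difference moment (the
  latter therefore numerically equal to IDM — the schema retains both);
  Correlation 1 / Correlation 2 are the centered-product and
  product-minus-means parameterizations, which coincide analytically on a
  symmetric matrix; Sum Mean is Sum Average / 2; Variance 1 is the joint
  grey-level variance and Variance 2 the variance of the difference
  distribution p_{x-y}. Because the schema is frozen, such analytic
  duplicates are kept as columns; they are constant multiples or exact
  copies of one another and simply always co-cluster downstream.
* **GLRLM (13)** — runs of equal level along the four angles, truncated at
  the ROI boundary, matrices summed over angles; IBSI emphases. For the
  merged matrix, Run Percentage divides the run count by (pixels x 4
  directions) so a fully fragmented ROI scores exactly 1.
* **GLSZM (13)** — zones are 8-connected components of equal level; single
  matrix, IBSI emphases; Zone Percentage = zones / pixels.
* **NGTDM (5)** — Amadasun–King busyness, coarseness, complexity,
  contrast, strength, with neighbourhoods restricted to the ROI;
  Coarseness is capped at 10^6 when its denominator vanishes.

Degenerate computations (single-pixel ROI, all-missing ROI, zero-variance
matrix) yield flagged missing values (NaN) — never silently dropped
columns or silent zeros.

### Reproducibility selection

For each (feature, sequence) pair, all ROIs of the cohort (both glands,
all patients, pooled as independent subjects) form the observation vector
of each reading. Three pairwise ICCs and one CCC are computed:

* **ICC(A,k)** — McGraw–Wong two-way model, absolute agreement,
  average-measures, k = 2 raters, written out from the ANOVA mean squares
  (rows = ROIs, columns = readings):

      ICC = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

  Negative values are reported as computed. Degenerate designs (zero
  denominator, constant feature) are flagged missing.
* **Lin's CCC** on the intra-reader pair (L2.1/L2.2), with population
  moments:

      rho_c = 2 s_xy / (s_x^2 + s_y^2 + (x̄ - ȳ)^2)

A pair is **reproducible** iff all three ICCs >= 0.8, the CCC >= 0.9, and
no input value is flagged missing. ROIs missing a reading are dropped from
all pairings with a logged warning. Both statistics are symmetric in
their arguments and invariant under a joint positive affine transform of
both readings; the ICC implementation is cross-checked against pingouin's
ICC(A,k) to 10^-10 in the test suite.

### Redundancy clustering

Reproducible features are clustered with agglomerative hierarchical
clustering on distance d = 1 - rho (Spearman rank correlation, average
ranks for ties), **complete** linkage, dendrogram cut just below height
1 - 0.9. Complete linkage is the one linkage for which "grouped when
pairwise rho > 0.9" is literally true for every within-cluster pair, and
the cut is placed at the largest representable value below 0.1 so that
rho exactly equal to the cutoff does not merge. Choices that were
genuinely open and are fixed here:

* **Signed correlation** — anti-correlated features are *not* merged
  (an `absolute=True` switch is provided).
* **Observation vectors use reading L1 only**, so reader variance does
  not leak into the redundancy structure.
* **Constant columns** (undefined rank correlation) become singleton
  clusters, numbered after the linkage clusters.
* Items are processed in canonical sorted order, making the result
  invariant to input order; SciPy's linkage resolves equal-height merges
  deterministically under that ordering.

Clustering is run per sequence and pooled over all reproducible
(feature, sequence) items; the pooled result records which sequences
co-occur within clusters.

### Overlap summary and threshold sweep

The overlap summary reports, for every non-empty subset of sequences, the
number of features reproducible in *exactly* that subset (UpSet
semantics), split by category (shape / first-order / texture); subset
counts partition the features reproducible in at least one sequence. The
threshold sweep re-applies a grid of ICC thresholds {0.5 ... 0.9} x CCC
thresholds {0.5 ... 0.95 in steps of 0.05} to the once-computed agreement
statistics — thresholding is a pure filter, so the sweep costs one
selection run plus cheap re-counting — and clusters each cell's selection
with the main run's configuration. The exact CCC grid is a package
choice; any grid can be passed.

## The synthetic cohort generator

No public dataset accompanies this design, so validation runs on a
synthetic cohort whose ground truth is known by construction.

### What it emulates

* **Anatomy.** Each gland is an ellipse (semi-axes uniform in 7–15 px at
  0.5 x 0.5 mm spacing, random orientation and center jitter in a 96 x 96
  image) deformed once by a per-gland smooth radial perturbation of RMS
  magnitude uniform in [0, 3] px. This anatomical irregularity is what
  gives ratio-type shape features (Solidity, Eccentricity, ...) genuine
  between-subject variance: real glands and lesions differ in shape, and
  without it those features would be pure reader noise and trivially
  non-reproducible.
* **Texture.** A per-gland Gaussian random field (white noise smoothed
  with a Gaussian kernel, correlation length 2 px) is shared across
  sequences as the gland's "tissue", mapped through a per-sequence affine
  contrast transform plus additive Gaussian noise, on a darker smooth
  background. A per-gland tissue-intensity factor (SD 15%) provides
  biological between-subject intensity variation.
* **Diffusion.** The ADC contrast is *not* drawn directly: a smooth true
  ADC field in [0.8, 1.8] x 10^-3 mm^2/s (glandular tissue is relatively
  homogeneous) generates a signal pair S_b1000 = S_b0 exp(-b ADC), both
  signals receive noise (b0 SNR ~ 16, clinically plausible for DWI), and
  the emitted ADC image is computed by the package's own `compute_adc`.
  In the noise-free limit this inverts exactly (tested to 10^-10); with
  noise the ADC map is the noise-dominated contrast, as in practice.
* **Readers.** The three delineations are smooth random radial
  deformations of the truth: L1 at the inter-reader magnitude; reader 2
  draws one base delineation at the inter-reader magnitude, and L2.1 and
  L2.2 perturb that shared base independently at the (smaller)
  intra-reader magnitude — reproducing the intra < inter variability
  hierarchy. Defaults: inter = 2.0 px RMS and intra = 0.6 px RMS, chosen
  to match published inter-observer Dice values for small-organ manual
  delineation (the defaults realize Dice ~ 0.81 inter, ~ 0.93 intra).
  The DIXON in-phase/water pairs of one acquisition share their
  delineations (one acquisition, one geometry); the other acquisitions
  are delineated independently.

The boundary perturbation itself thresholds the mask's signed Euclidean
distance against a low-frequency angular displacement field (4 random
Fourier harmonics with RMS amplitude = the magnitude in pixels), fills
holes, keeps the component at the centroid, and retries with damped
magnitude if the mask would empty. Magnitude 0 is an exact identity,
which yields the identity limit used in testing: with zero perturbation
all three readings coincide and every non-degenerate pair attains
ICC = CCC = 1.

### What it does not emulate

* **Slice choice.** Real readers each pick their own 2D slice from a 3D
  volume; a different slice re-samples noise and fine texture entirely.
  Here all readings share one frozen image and differ only through the
  mask. Consequently the frozen noise pattern acts as a stable per-gland
  fingerprint and texture agreement is governed by the mask-overlap
  fraction — synthetic texture reproducibility is therefore optimistic
  relative to a real multi-slice study, and passing recovery tests show
  ordering properties (shape vs texture on noisy contrasts, degradation
  with perturbation), not absolute selection rates.
* MR artifacts (bias field, motion, chemical shift), pathology classes,
  3D ROIs, and scanner/protocol variation are out of scope.

### Determinism

The cohort is bit-reproducible for a fixed seed: a `SeedSequence` is
spawned per gland, so results do not depend on generation order, and the
full pipeline writes byte-identical CSV artifacts across repeated runs
with the same configuration.

## Numerical and scaling choices

* Feature tables round-trip CSV losslessly: written at 17 significant
  digits and parsed with round-trip float precision.
* Tests run on reduced cohorts (5–8 patients) except the full-design
  yield check (37 patients, one reading), keeping the default suite at
  about 1–2 minutes; the acceptance script runs the complete
  default-design pipeline (three readings, 1332 extractions, selection,
  clustering, sweep) in well under a minute per seed on one core.
* The sweep's monotonicity (counts non-increasing in each threshold) is
  asserted empirically on every generated cohort. For feature counts it
  is a theorem (thresholding is a filter); for cluster counts it is a
  property of complete linkage on these data rather than a general
  theorem, and it is checked, not assumed.
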