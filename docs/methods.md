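# Methods

## Data model and preprocessing

Spectra are absorbance values on a shared wavenumber axis stored in
descending order (instrument convention). Two containers exist: a
`SpectrumTable` (bulk ATR spectra of pulverized shoot bases, with
per-sample genotype, rooting group and three rooting-percentage traits)
and a `HyperCube` (rows × cols × channels FTIR image with a boolean
tissue mask and pixel size, default 11 µm).

Preprocessing follows vibrational-spectroscopy practice: channels are
truncated to the fingerprint region (closed interval, default
1800–800 cm⁻¹) and every spectrum is scaled to unit Euclidean norm
("vector normalization"). The pipeline order is truncate → normalize, so
the normalization is over the fingerprint region only; both steps are
configurable. Zero-norm spectra are an error naming the offending
sample/pixel, never silently passed.

ENVI (text header + raw binary; BSQ/BIL/BIP interleaves; float32,
float64, int16 with optional reflectance scale factor; both byte orders)
and CSV (wide and long layouts, metadata sidecar) are the ingestion
formats. Proprietary instrument formats are out of scope — acquisition
software is assumed to have exported ENVI and applied atmospheric
corrections. ENVI carries no tissue mask, so the imaging pipeline can
recover one by thresholding total fingerprint absorbance at a
configurable quantile (`background_quantile`); cubes passed in memory
keep their own masks.

## EMSC with chemical components

Each spectrum is modelled as

s = a·m̄ + Σᵢ₌₀..p dᵢ·Pᵢ + Σⱼ cⱼ·Kⱼ + e

* m̄ — reference spectrum, the channel-wise mean of the batch under
  analysis (a dedicated reference set can be supplied instead);
* Pᵢ — Legendre polynomials of the wavenumber rescaled to [−1, 1] over
  the truncated range. Legendre rather than monomial terms purely for
  conditioning; the span, and hence the fit, is identical. Default
  polynomial order p = 2 (offset, tilt, curvature), the common FTIR
  baseline default;
* Kⱼ — reference component spectra, unit-normalized at library
  construction so coefficients are comparable across components;
* a — multiplicative scatter scale; e — residual.

The per-spectrum fit is ordinary least squares on the design
[m̄ | P₀..Pₚ | K₁..K_J] (a single precomputed pseudoinverse applied to
all pixels of a cube at once). Two alternative solvers are provided:
`nnls_components` (component coefficients constrained ≥ 0) and `pls`
(NIPALS partial least squares; with latent variables equal to the design
rank it reproduces OLS, with fewer it trades bias for noise robustness —
the latent-variable count is a free choice, so OLS is the default).

**Identifiability.** The reference spectrum itself carries chemistry: at
model build, m̄ is regressed once on [P | K], giving its composition uⱼ.
The raw cⱼ are then deviations from a·uⱼ, and the chemistry-only loading
of component j is tⱼ = cⱼ + a·uⱼ. Whenever the fit residual is zero this
decomposition is exact and unique (the baseline+component block is
required to be full rank — collinear library components are a build
error). When m̄ is nearly inside the baseline+component span — which
happens for very clean batches — the design becomes ill-conditioned (a
warning is issued above condition number 1e8) and the raw split between
a·m̄ and c is unstable, but tⱼ is invariant along the unstable direction
and remains the well-determined quantity. Quantification therefore uses
tⱼ throughout.

**Relative absorbance** of component j is |tⱼ| / Σⱼ|tⱼ| — the compound's
absorbance in relation to the total fitted chemical absorbance
(baseline and scatter excluded, making the ratio chemistry-only). It
sums to one and is invariant to global rescaling of the input spectrum.

Degenerate fits (a ≤ 0, which arises when noise pushes the unstable
reference direction negative) are flagged, counted, and excluded from
all downstream statistics; they are never imputed.

A mean-centred PCA of vector-normalized tables is provided for
exploratory use (deterministic full-SVD solver; sign convention: the
largest-magnitude loading element is positive).

## Tissue clustering

Unmasked pixel fingerprints (vector-normalized, 1800–800 cm⁻¹) are
clustered with agglomerative linkage — Ward on Euclidean distances by
default, the standard choice for spectral histology; average and
complete linkage are options. k is a required parameter with no
automatic selection: the study design chose k = 7 by tissue
interpretability (epidermis, shoot cortex, root cap, meristematic tip,
root vasculature, root cortex, pith + vascular ring), and the
cluster → tissue naming is a user-supplied map since the algorithm
cannot know anatomy.

Genotype pairs are clustered **jointly**: unmasked pixels of both cubes
are concatenated before linkage and the labels split back per cube, so
cluster ids are directly comparable. Above `max_pixels` (default 20 000)
a seeded uniform subsample is clustered and the remaining pixels are
assigned to the nearest cluster centroid. Labels are renumbered by
descending cluster area; 0 marks masked pixels. Very small tissue
regions (~100 px) can lose their identity under aggressive subsampling —
the subsample then carries only a few dozen of their pixels and Ward may
absorb them — so `max_pixels` should stay well above the smallest
expected region size divided by the subsampling fraction.

## Two-group statistics

Per (cluster, component), the pixel distributions of relative absorbance
are compared between genotypes:

* **Mann–Whitney U** with U = #(x>y pairs) + ½#(ties). Exact mode
  enumerates the permutation distribution of U over all label
  assignments (automatic when n_x+n_y ≤ 16 and tie-free; ties use the ½
  convention); otherwise the tie-corrected normal approximation with
  continuity correction is used (via scipy).
* **Divergence effect size** D = |x̄ − ȳ| / s_pooled — Cohen's
  standardized mean difference, matching the small/medium/strong
  thresholds 0.2/0.5/0.8 — with R²_D = D²/(D²+4), strictly increasing in
  D (D > 2 ⇔ R² > 0.5). A robust variant (median difference over scaled
  pooled QAD) is available behind a flag.
* **Verdict**: significant ⇔ p < p_thresh AND (D > d_thresh OR
  R²_D > r2_thresh). Imaging defaults (0.001, 0.8, 0.5); the bulk
  screening stage uses α = 0.05.
* **Descriptives**: median, interquartile range, and QAD — the median of
  absolute deviations from the median (unscaled). Relative difference is
  100·(A − B)/B with the reference genotype B as 100%, computed on
  medians by default (means optional).

The sampling unit is the pixel, not the biological replicate: p-values
inherit the pseudo-replication caveat of image statistics and should be
read jointly with the effect sizes, which is exactly what the dual
verdict rule does. No multiple-testing correction is applied across the
(cluster × component) grid by default; a Benjamini–Hochberg option is
deliberately not provided here because the verdict rule's effect-size
arm already guards against p-value-only flags at image sample sizes.
Area-weighted means (Σ valueᵢ·areaᵢ / Σ areaᵢ) support aggregating
merged clusters, e.g. root cap + meristem analysed collectively.

Because relative absorbances are compositional (they sum to one per
pixel), a genuine increase of one component in one tissue necessarily
depresses the *shares* of all other components there; with hundreds of
pixels those compensatory shifts are themselves significant. Flags must
therefore be read per component across clusters, not as independent
discoveries within a cluster.

## Compound screening (bulk panel)

Per genotype, relative absorbances are averaged over its (non-degenerate)
spectra; the genotype, not the spectrum, is the observation unit — the
screening correlates *mean* relative compound absorbance with
genotype-level rooting percentages. A compound is **eligible** when

1. RPD = 100·|m_easy − m_difficult| / ((m_easy + m_difficult)/2) > 3
   (the standard symmetric relative percent difference; a
   reference-denominator variant is available), and
2. its Pearson correlation with the rooting percentage is significant
   (two-sided p < 0.05) for at least two of the three rooting traits
   (10 d +IBA, 21 d +IBA, 21 d −IBA).

Only eligible compounds receive the easy-vs-difficult Mann–Whitney test
(exact for the tie-free 15-genotype panel). Constant compounds have an
undefined correlation, which counts as not significant. Records are
sorted by descending RPD. No multiple-testing correction across
compounds is applied. A `predictive_performance` reporting column is
present but left blank: no defensible criterion for it is defined here.

## Synthetic data generator

The generator is the study-design stand-in and the source of all test
fixtures; every artifact is fully determined by one seed (all random
streams are derived, named substreams of it).

* **Component library** — 10 components named for the cell-wall
  chemistry they emulate (arabinose/galactose/mannose/xylose
  hemicellulose signatures, cellulose, G-rich and OHG-rich lignin,
  pectin, two protein types), each a sum of 3–8 Gaussian bands (centres
  inside the fingerprint region, widths 8–40 cm⁻¹), unit-normalized,
  with pairwise cosine similarity < 0.95 enforced by regeneration.
  Axis: 1800–800 cm⁻¹ at 6 cm⁻¹ (167 channels), the imaging spectral
  resolution.
* **Forward model** — every spectrum is s = a·(Σⱼ wⱼKⱼ) + Σᵢ bᵢPᵢ + ε
  with lognormal scatter a (σ = 0.15), Gaussian baseline coefficients on
  the same Legendre basis the EMSC model uses (σ = 0.002/0.001/0.001
  absorbance units — a residual drift of roughly 8% of signal norm,
  emulating instrument-corrected data), and i.i.d. channel noise
  (σ = 0.001). Because the generative model *is* the EMSC forward model,
  decomposition of noiseless output recovers the planted chemistry to
  numerical precision — the central oracle linking the generator and the
  estimator.
* **Genotype panel** — 5 easy / 10 difficult genotypes × 6 replicate
  spectra. Compound weights per genotype are a fixed base profile (the
  planted compound held at a 5% share so that compositional compensation
  stays below the RPD threshold) perturbed by lognormal
  genotype-to-genotype variation (σ = 0.15); easy-rooters get the
  planted multiplier (default mannose ×1.4). The three rooting
  percentages are logistic-squashed linear functions of the planted
  compound's standardized weight plus noise, targeting r = 0.8 — traits
  are generated *from* weights so the screening ground truth is well
  defined.
* **Tissue cubes** — the `rings_with_primordia` layout paints a stem
  disk (masked background outside): pith + vascular core, shoot-cortex
  annulus, epidermis rim, plus two primordium domes subdivided into
  root-cap shell, meristem band, root-vasculature core and root cortex —
  seven labelled regions, ids matching the tissue-cluster numbering.
  Each region has a fixed, deliberately contrastive mixing profile
  (synthetic values, not measured chemistry). Planted effects multiply a
  component's weight within a region (default pair: +50% mannose in the
  root cap of the "effect" cube, independent noise streams per cube).
  `blocks` and `uniform` layouts support simpler tests. Default image
  96×96 at 11 µm pixels keeps a full pair analysis around twenty
  seconds.

What the generator does **not** emulate: spatial partial-volume mixing
at region boundaries (pixels are pure region profiles), detector-
correlated or wavelength-dependent noise, Mie-type scattering
distortions, anatomical variability of real sections, and biological
replicate structure. Passing tests therefore demonstrate correctness of
the estimators and decision rules under the assumed noise model, not
robustness to instrument physics beyond it.

## Verification problem sizes

The verification suite (mirrored by `scripts/acceptance.py`) uses: 50
noiseless + 200 noisy (40 dB) spectra for EMSC accuracy; full
enumeration for all Mann–Whitney sample splits with n ≤ 10; the default
96×96 cube for seven-region recovery (ARI) and for the planted-pair
detection run; 20 null genotype pairs at 72×72 with max_pixels = 3000
for false-flag specificity; 50 replicate panels for screening rates; and
2000 replicates for Pearson type-I calibration at n = 5 and 15.

## Known limitations

* The reference direction of the EMSC design is ill-determined for very
  clean batches; raw (a, d, c) should not be interpreted individually
  there (the chemical loadings tⱼ should).
* About 5–10% of bulk spectra in the default panel are flagged
  degenerate (a ≤ 0) through that same mechanism and are excluded from
  genotype means; this exclusion is noise-driven and chemistry-neutral.
* Exact Mann–Whitney enumeration is combinatorial; it is automatically
  limited to n_x + n_y ≤ 16.
* Joint clustering assumes the two genotypes share tissue spectral
  signatures apart from the effects of interest; a global chemistry
  shift would split tissues into genotype-specific clusters.
* No spatial regularization of label maps and no registration between
  sections.
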