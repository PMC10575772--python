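# Methods

This note documents the models, numerical choices, and limitations of the
pipeline: what is simulated, what is estimated, and what passing tests do and
do not establish.

## Outcome stratification

Adaptive-behaviour change is the difference of age-normed VABS-II composite
standard scores, ∆V = T2 − T1 (scores are already age-normed; no additional
norming is simulated).  Classification against the MCID threshold (default
4 standard-score points) is literal about boundaries: ∆V ≥ 4 → Increaser,
∆V ≤ −4 → Decreaser, the open interval in between → No-changer.  Alternative
stratifications (VABS-II domain change, ADOS calibrated-severity change)
reuse the same rule on a different score column; no published MCID exists for
ADOS severity scores, so the ADOS threshold is a configuration parameter
(analyses using it are exploratory by nature).

Cohort summary tables use one-way fixed-effects ANOVA computed from group
summaries (between-SS from group means about the weighted grand mean,
within-SS = Σ(nᵢ−1)sdᵢ²) and Pearson χ² without continuity correction, with
uncorrected p-values — the conventions under which the reference cohort
table's printed statistics reproduce from their printed means/SDs/counts.
Agreement there is limited by the two-decimal rounding of the printed
summaries (≈ 0.2 % observed, tested at 2 %).

## Synthetic cohort generator

The generator is labels-first: each autistic subject's outcome label is fixed
by design (default sizes 53/42/66), then ∆V is drawn from a normal
distribution truncated to the label's MCID interval (exact inverse-CDF
truncated-normal sampling), so classification recovers the generated label by
construction — the same consistency the real data has.  Default ∆V parameters
(−11.23 ± 8.0 / 0.05 ± 2.0 / 9.86 ± 5.5), FSIQ, sex fractions, ages
(uniform 6–30), inter-visit intervals (1.6 ± 0.3 y, truncated > 0.5 y), and
VABS/ADOS score distributions are the reference cohort's published marginals
(see `outcomesurf/cohort_reference.py`).  Sex is assigned with exact
per-group counts; intellectual disability is defined as FSIQ < 70 rather
than planted as a count; medication is Bernoulli (30 % autistic, 2 %
neurotypical) — the study reports no site or medication structure, so site
offsets (4 sites, equal allocation, additive Gaussian offsets) and the
medication rate are generator conventions, exposed on the generator dataclasses.

Vertex maps live on an icosphere (subdivision 4, radius 100 mm by default:
2562 vertices, area ≈ 1257 cm², one-hemisphere scale).  Each feature map is

  population mean + age slope + sex effect + site offset + subject intercept
  + smooth spatial noise (+ planted effects),

with T2 = T1 + change, where change has its own mean, subject intercept and
smooth noise.  Magnitudes default so that subject totals match the reference
distributions (total SA ≈ 2293 ± 232 cm², mean CT ≈ 2.69 ± 0.1 mm).  Total
SA and mean CT are computed from the generated maps, never drawn separately,
so the total-brain covariates are consistent with the maps.  Planted effects
are geodesic patches (BFS balls of k edge-hops) added to one subgroup in one
feature; `effect_size` is Cohen's d in units of the feature's within-group
SD √(subject_sd² + noise_sd²) (change SDs for ∆ effects).  A T1 effect is
added at both visits (a persistent baseline offset — so ∆ maps stay clean);
∆ and T2 effects are added at the second visit only.  With two visits,
∆ = T2 − T1 exactly, so a change effect is necessarily also visible at T2;
the planted analogues are interpreted accordingly.

What the generator does **not** emulate: cortical folding and areal
inhomogeneity, spatially structured (non-stationary) noise, missing visits,
site-by-age interactions, scanner artefacts, or realistic gene co-expression
modules.  Passing calibration and power tests therefore establishes the
correctness of the statistical machinery under its stated assumptions, not
performance on real MRI data.

## Smoothing and its calibration

Surface smoothing is iterated neighbour averaging (vertex ← mean of itself
and its neighbours), mesh-native with no volumetric resampling, plus one
fractional step (1−λ)I + λA so that the effective FWHM is continuous rather
than quantized by integer iteration counts.  "FWHM" always means the
random-field-theory smoothness measure: the edge-derivative variance of a
unit-standardized field, FWHM = √(4 ln 2 / v̄).  The schedule (k, λ) for a
requested FWHM is calibrated by measuring exactly that estimator on a fixed,
seeded block of 512 white-noise probe maps (sampling error < 1 %,
deterministic, cached per mesh).  Noise fields for simulation are white
noise passed through the same schedule and rescaled by the operator's row
norms, giving exactly unit variance per vertex.  Map smoothing preserves the
map mean exactly (re-centred after averaging; irregular vertex degrees would
otherwise drift it) and can only shrink variance.  Requested FWHMs at or
below the lattice floor (the FWHM measured on unsmoothed white noise,
≈ 1.2 × mean edge length) degrade to the identity.

## Vertex-wise GLM

Ordinary least squares per vertex with a shared design; t = cᵀβ̂/SE(cᵀβ̂)
with the residual variance of that vertex.  Continuous covariates are
mean-centred within each fitted model and quadratic age is the square of the
centred age (conditioning only; the group contrast is unaffected).  Site is
a fixed-effect dummy block.  Each subgroup is compared with neurotypicals in
its own two-group model rather than one omnibus model, and the dimensional
variant regresses on continuous ∆V within the autistic group.  Vertices with
(numerically) zero residual variance get a ±∞ sentinel t and a flag; they
are excluded from clustering rather than silently dropped.  Residuals are
returned standardized to unit empirical variance per vertex for smoothness
estimation.  Rank-deficient designs abort with the offending columns listed.

## RFT cluster correction

Smoothness is estimated locally from the standardized residuals (per-edge
derivative variances → per-face resel densities), so cluster extents —
Σ over touched faces of r_f weighted by the fraction of the face's three
vertices inside the cluster — adapt to non-isotropic smoothness.  Clusters
are maximal edge-connected components of same-sign suprathreshold vertices
(vertices are the cluster unit; fractional face weighting removes border
ambiguity).  The cluster-forming threshold is the two-tailed α_form Student-t
quantile at the model df.  Cluster-level p uses the Poisson clumping
heuristic with exponential cluster sizes (the 2-D case): m = R·ρ₂(t*),
E[A] = R·P(T > t*), n̄ = E[A]/m, p₁ = 1 − exp(−m·exp(−s/n̄)).  Two-tailed
inference treats the sign families separately at α/2 each; the reported
p_cluster is min(1, 2·p₁), compared against α_cluster, which keeps cluster
signs interpretable while controlling the joint family-wise error.  No
pooling or correction is ever applied across the SA/CT features or across
the three subgroup contrasts (asserted on the run manifest).

Continuum RFT on a lattice requires the kernel to be oversampled: with ~1.5
vertices per FWHM the Poisson-clumping p is an order of magnitude
conservative and cluster counts fall short of R·ρ₂(t*) (suprathreshold
components merge at lattice scale).  Calibration simulations therefore use a
mesh with ≈ 7 vertices per FWHM (icosphere-4 at radius 20 mm for 10-mm
fields), where 1000-run family-wise error at nominal two-tailed 0.01 lands
at 0.012–0.018 and observed cluster counts match expectation within
Monte-Carlo error.  The generator's defaults (radius 100 mm, 20-mm fields,
≈ 3 vertices per FWHM) remain mildly conservative — acceptable for the
power analyses, where planted d ≈ 1.2 effects are recovered essentially
always.  Analyses of meshes that under-resolve their smoothness should be
expected to be conservative, not optimistic.

## Imaging transcriptomics

Decoding correlates the unthresholded contrast t-map, reduced to unweighted
parcel means (~200 roughly equal parcels from farthest-point seeding), with
each gene's per-gene-standardized expression profile; an option exists to
decode the RFT-masked map instead.  Significance uses a spin test: the same
seeded sequence of uniform 3-D rotations is applied to the parcel centroids
for all genes (preserving gene–gene dependence under the null), each rotated
centroid is matched to its nearest original centroid, and
p = (1 + #{|r_null| ≥ |r|})/(1 + n_spins), two-sided.  Genes at BH q < 0.05
form the decoded list; the spin null is used because spatial autocorrelation
inflates parametric correlation p-values.  Enrichment is a two-sided Fisher
exact test on the 2×2 decoded-by-set table over the background universe
(OR = ad/bc with 0 / ∞ sentinels; empty decoded lists or sets yield an
undefined-OR flag with p = 1), and BH-FDR runs once, jointly, over every
contrast × gene-set pair in the run.  A restricted background (e.g.
cortically expressed genes) shrinks the universe; decoded genes outside it
are dropped from all margins.

The synthetic atlas plants signal sets by mixing the standardized target map
with an independent smooth map at weights (r, √(1−r²)); smooth null maps are
Gaussian-process draws on the parcel centroids with length scale 1.5 × the
mean nearest-centroid spacing.  Realized per-gene correlations scatter
around the target r (they are not orthogonalized to it), which is what the
concentration tests check.  Real atlas preprocessing (probe selection, donor
normalization) is out of scope.

## Pipeline and determinism

`RunConfig` is a single JSON-serializable document (unknown keys rejected).
The default grid is 3 subgroups × 2 features × 3 analyses = 18 contrasts;
sensitivity toggles cover the medication covariate, dropping total-brain
covariates, ID exclusion, age bands ([6,12), [12,18), [18,31) by default —
the age-group bounds are a convention, not a published value — and
alternative stratification bases.  All randomness in a run derives from one
integer seed; outputs are plain text with fixed names, wall-clock timings
are kept out of checksummed files, and two runs with the same config are
byte-identical.

## Problem sizes

Test-suite and acceptance-script simulation sizes: 200 null GLM simulations
(n = 120, 2562 vertices) for t-calibration; 1000 null RFT simulations
(n = 60 per group, 10-mm fields) for family-wise error; 100 cohorts for
planted-cluster power (d = 1.2, n = 50 per group, 3-hop patches); 200
phenotype cohorts for label round-trips; 200 decode/enrich runs for the
global-null FDR check; 500 spins for decoding.  These sizes put Monte-Carlo
standard errors well inside the tested tolerance bands while keeping the
full suite under a few minutes on one CPU.

## Known limitations

- Two-visit change scores only; no mixed-effects or spline growth modelling.
- The RFT variant is the classical resel-based Poisson-clumping correction;
  no peak-level, TFCE, or permutation inference (permutation is used only as
  a test oracle).
- The spin test assumes a spherical geometry with parcels of comparable
  size; strongly unequal parcels would need area-weighted matching.
- Printed-summary reproduction inherits the rounding of published tables.
- Synthetic-data realism limits are listed under the generator section; in
  particular, planted effect sizes are homogeneous within a patch, which
  favours cluster-level inference relative to real, graded effects.
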