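# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `ioncoloc`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Preprocessing chain (`peakflow`)

**Centroiding.** Local maxima of a profile spectrum with prominence
strictly greater than 5 (so shoulder peaks survive) are centroided as the
intensity-weighted mean m/z over the half-prominence support — the
contiguous points around the apex with intensity ≥ apex − prominence/2.
The cited centroiding literature does not fix this definition; ours is
declared, deterministic and symmetric for symmetric peaks.

**"Relaxed" ppm matching.** Peak matching at 50 ppm (intra-run), 20 ppm
(inter-run) and 10 ppm (isotopologues) uses single-linkage gap splitting:
all masses are sorted and a new bin opens wherever consecutive masses are
more than the tolerance apart. This is deterministic and independent of
pixel or run order (a property the suite asserts). When one pixel
contributes several peaks to a bin, only the most intense is retrieved;
the bin mass is the intensity-weighted mean.

**Spatial filtering.** A feature is discarded when the largest
eight-connected component of its presence image has fewer than 9 pixels,
or when less than half of its presence lies on tissue. The tissue mask is
an explicit input; without one it is derived by Otsu-thresholding the
total ion count. After filtering, off-tissue pixels leave the table.

**Recalibration.** The ppm error of detected reference ions is modeled
per pixel as a linear function of m/z (least squares over that pixel's
references, run-level pooled fit as fallback) and subtracted. This
recovers constant and mass-proportional drifts; the suite plants both and
requires residual median |error| < 5 ppm.

**Consensus and normalization.** A common mass is kept only if its mean
intensity (arithmetic mean over all pixels, zeros included) is positive
in every run. Pixel spectra are divided by the median of their non-zero
intensities, then multiplied by the global median of those medians so the
table stays on the original intensity scale (the divisor is prescribed;
the restoring factor is our choice, recorded in provenance). All-zero
pixels are flagged and left unscaled.

**Batch correction.** Parametric empirical-Bayes location/scale
adjustment per feature per batch (batch = acquisition run): standardize
against the weighted grand mean and pooled variance, shrink per-batch
means toward a normal prior and per-batch variances toward an
inverse-gamma prior (method-of-moments hyperparameters, iterated to
convergence), remove, and restore the grand scale. Batches of one pixel
are an error. Shrinkage leaves batch-mean residuals of order
1/√(batch size) — the planted-offset test is run at a size where this is
below 1% of the pooled SD.

## Consensus modules (`netmods`)

Networks are estimated from pure-clone pixels only; mixed-clone pixels
never enter (asserted by a corruption test). The scale-free fit index is
the R² of log₁₀ p(k) against log₁₀ k over 10 connectivity bins, signed
negative for positive slopes. On small feature panels the degree
histogram is too coarse for this criterion to stabilize; when no power in
1..20 qualifies, the pipeline falls back (with a warning) to the power
maximizing the worst-run fit, while the low-level selector keeps the
strict error contract.

**Module cut.** Average-linkage tree on 1 − TOM. The static cut scans
every merge height and keeps the partition with the most clusters of size
≥ min_size (ties: more assigned features, then the lower height);
features in smaller clusters start unassigned. We found the alternative
rule "lowest height at which *all* clusters reach min_size" degenerates
to the tree root whenever a single outlier feature exists, so it cannot
express more than one module on realistic tables. A PAM-like refinement
follows: a feature whose correlation with its own module eigenmetabolite
(computed leave-one-out for members, so a feature cannot vote for its own
echo) is below 0.3 becomes unassigned, then unassigned features join the
best-correlated module when that correlation exceeds 0.3. Modules
falling below min_size dissolve. The default min_size is 20; parameter-
recovery runs on the 10-feature planted modules use min_size = 5.

**Eigenmetabolites.** Features are centered and unit-scaled over the
training pixels (the convention of the weighted-correlation-network
framework; recorded in provenance), the first right-singular vector gives
loadings and pixel scores, and the sign is anchored so the score
correlates non-negatively with the module's mean intensity image. Scaling
parameters are retained so mixed-clone pixels can be projected exactly.

**Association.** Each ME is binarized at its inter-run median (ties count
as low); per-tissue high-ME fractions are regressed on binary genotype
with the logit-link beta model below; Wald p-values are BH-adjusted
across modules. Merging of modules with ME correlation > 0.85 uses
transitive closure (identity is transitive); MEs are recomputed after
merging.

## Isotope tracing (`isotrace`)

Natural abundance is anchored on the raw monoisotopic image: the natural
m+k component is raw₀ · Binom(k; N, P)/Binom(0; N, P) with P = 0.01109,
and the labeled component is the non-negative remainder. Only carbon is
corrected. The permutation null shuffles every ion image independently
within each run at each of the 10,000 iterations and recomputes the
consensus — the strictest exchangeable null consistent with shuffling
individual images; it destroys spatial autocorrelation, so the p-values
are calibrated against an i.i.d. null, not a spatially correlated one.
P-values use the printed (ΣI + 1)/(n_perm + 1) estimator, so the floor is
exactly 1/10,001 at 10,000 permutations. The two-cluster cut uses
`cut_tree`, which still yields two groups on tied (zero-height) trees —
that degenerate case warns and is otherwise arbitrary but deterministic.

Display convention: ion images are clipped at their 99.9th percentile and
scaled to [0, 1]; the proxy predominance map labels each pixel by the
larger of two max-normalized images, with ties (including both-zero)
labeled "none" rather than forcing a dominance claim.

## Shared statistics (`clonstat`)

**Beta regression.** Mean logit link, Beta(μφ, (1−μ)φ) likelihood.
Boundary proportions are shrunk by (y(n−1)+0.5)/n before likelihood
evaluation. Fixed-effects fits use maximum likelihood with Wald tests;
when a near-saturated fit leaves a singular Hessian (non-finite standard
error), the coefficient is scored by a likelihood-ratio test instead, so
strong effects are never silently lost. Random intercepts: one grouping
factor is integrated by adaptive Gauss–Hermite quadrature (7 nodes,
recentered at the per-group conditional mode); crossed factors (run ×
tissue) use a Laplace approximation with analytic gradient and Hessian in
the inner Newton loop. The implementation reproduces glmmTMB's
beta-family fits on shared data (slope to ~0.001, variance component to
a few percent; a tolerant cross-check against `Rscript`/glmmTMB is part
of the suite). Wald tests on variance-component models are
anti-conservative in very small designs (≈0.17 at 6 tissues in our null
simulations) — an expected small-sample property; calibration is verified
where asymptotics apply (40 two-region tissues: rejection 0.072 at
α = 0.05 over 500 fits).

**Other pieces.** BH adjustment delegates to statsmodels. Conditional
coexpression discretizes intensities at the pooled 33rd/66th percentiles
(linear interpolation — the convention matters at small n and is recorded
here) over pure-genotype pixels only; columns always sum to 1 and the
discretization is invariant to monotone rescaling. The CoV filter keeps a
feature when SD/mean < 0.30 within at least one replicate class. Pathway
enrichment counts significant features per direction (which genotype the
fold change favors), takes the one-sided Fisher exact p of the 2×2
in-pathway × significant-in-direction table, and reports
score = (observed/expected hits) · (−log₁₀ p) *together with both
factors*, because the source method's exact composition is not published;
users can recompose. Pathways with fewer than 2 mapped features drop.

## IHC co-registration (`ihcreg`)

Thresholding is strict (< 230 positive on the 8-bit deconvolved DAB green
channel). 16×16 binning drops trailing partial blocks so every proportion
shares the 256-pixel denominator. k-means (k = 2, 10 restarts, fixed
seed) labels the higher-centroid cluster "high". Registration is an input
contract — a 2×3 affine from MSI pixel coordinates to block coordinates,
identity by default — because no registration algorithm is specified
upstream; resampling is nearest-neighbor and artifact-masked pixels are
excluded. The region contrast rescales per-tissue region means into (0,1)
by the per-run maximum (proportion framing) and fits the mixed beta
model; a single-tissue design falls back to a fixed-effects fit on pixels
with an explicit caveat.

## GC–MS (`gcmsen`)

The forward matrix M[j,k] = Binom(j−k; i−k, P) convolves a labeling
distribution with natural abundance on the unlabeled carbons; correction
solves M x = observed under x ≥ 0 (non-negative least squares), which is
exactly consistent with the binomial model used in the imaging branch and
inverts the synthetic generator's forward model to < 1e-8 in the
noise-free limit. Total carbon enrichment is Σ_k k·Enrichment(m+k)/i —
the printed source formula is typographically corrupted, and this reading
is the only one consistent with its stated meaning ("percentage of
carbons enriched"); it is linear in isotopologue mixing and bounded in
[0, 100]. Derivatization-atom corrections (Si/H/O/N) are out of scope.

## Synthetic data (`synthio`)

The generator emulates the study design: per run, a pure MYC-high, a pure
MYC-low and a zoned 1:1 mixed section (one-pixel off-tissue border), with

* **modules** as smoothed Gaussian random fields (σ = tissue size/8)
  shared by a module's features with per-feature loadings; module M1 is
  restricted to the MYC-high clone zone (×0.05 elsewhere) and is the
  genotype-linked module. Each field's per-tissue mean is anchored at 0.5
  so module *level* is comparable across tumors while the spatial
  *pattern* varies — without this, whole tissues fall on one side of the
  inter-run ME median and the n = 6 association design saturates on
  chance orderings;
* **background ions** (250 by default): spatially unstructured,
  feature-independent intensities that anchor the per-pixel non-zero
  median. Median scaling is compositional: with few total ions, the 10
  genotype-linked ions shift the median in MYC-high tissue and plant a
  spurious negative association in every other module. Real DEFFI tables
  carry on the order of 10³ ions; 250 background ions put the generator
  in the same ratio regime (we measured the spurious unlinked-module
  slope shrink from ≈ −6 at 30 background ions to ≈ 0 at 250);
* **scattered noise ions**: one random blob of 3–8 eight-connected pixels
  per run — below the 9-pixel filter threshold by construction;
* **batch effects**: per-run multiplicative factor (batch_scale^U(−1,1))
  and additive offset (U(0, batch_shift)) on present intensities;
* **isotopologues**: per pixel, a multinomial draw (depth 2000) around
  the convolution of tracer labeling with binomial natural abundance
  (P = 0.01109). The tracer puts label_k carbons on a labeled molecule;
  the labeled fraction is max_labeled_fraction·(1 − 1/label_effect) in
  the linked clone and label_effect-fold lower in the other, so
  label_effect = 1 means no labeling at all. Defaults: two Krebs-cycle
  proxies linked to the MYC-high clone, two lactagenic proxies to the
  MYC-low clone;
* **intensity noise**: log-normal multiplicative (σ = 0.25), keeping
  intensities strictly positive as in MSI; m/z jitter 3 ppm per peak,
  plus optional per-run calibration shifts for recalibration tests.

What the generator does *not* emulate: profile-mode spectra (peaks are
emitted centroided; centroiding is tested on synthetic Gaussians),
histological texture, chemical noise with m/z structure (adducts,
in-source fragments), spatially correlated detector drift, and real
inter-feature abundance correlations beyond the planted modules. Passing
tests therefore demonstrate algorithmic correctness and parameter
recovery under the declared model, not robustness to every artifact of
real DEFFI data.

## Problem sizes and determinism

All stochastic tests fix their seeds. Parameter-recovery acceptance runs
use the full design (3 runs, 64×64 sections, 2×10 planted features, 20
noise ions, 20 replicate seeds); the permutation-uniformity check uses 50
pairs at 400 permutations (the exact 10,000-permutation floor is asserted
separately); null calibration uses 500 fixed-effect and 500 mixed fits.
`scripts/acceptance.py` reports means over 8 pipeline replicates and 5
tracing replicates — enough for stable summary statistics while keeping a
single-CPU run in the minutes range. Unit-test fixtures use 32×32
sections for speed.

## Known limitations

* The "relaxed" matching, centroiding, recalibration and dynamic-hybrid
  cut reproduce the *behavioral contracts* of their cited tools, not
  their exact implementations.
* The permutation null ignores spatial autocorrelation (by construction,
  as specified); p-values for spatially smooth images are optimistic
  against a spatially-aware null.
* Wald inference in the beta models is anti-conservative for designs
  with ≲10 tissues; treat borderline q-values there with caution.
* The pathway score's algebraic composition is an interpretation (both
  factors are reported separately).
* Registration quality is the caller's responsibility; only the resampling
  and masking are handled here.
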