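# ioncoloc

Consensus ion-colocalization analysis for multi-run mass spectrometry
imaging (MSI) of biclonal tumors, with stable-isotope tracing, IHC
co-registration and bulk GC–MS enrichment.

## Who this is for

Spatial-metabolomics groups imaging tumors that contain genetically
distinct clones — here a MYC-activated ("MYC-high") and a control
("MYC-low") clone grown pure or as a 1:1 mixture — who want to ask, across
several acquisition runs:

* which ions colocalize into reproducible spatial **modules**, and which
  modules track the MYC genotype;
* which **¹³C-labeled metabolites** (from glucose or glutamine tracers)
  occupy the same tissue zones once natural isotope abundance is stripped;
* whether a metabolite of interest (pantothenate, vitamin B5) is elevated
  in **MYC-high regions** segmented from IHC and mapped onto the MSI grid;
* how much of a metabolite pool is **isotopically enriched** in bulk GC–MS.

## The model at the core

**Preprocessing** (`peakflow`): per pixel, centroided peaks (prominence
> 5) are matched within a run at 50 ppm, spatially filtered (features
whose largest eight-connected presence blob has < 9 pixels, or that live
off tissue, are discarded), recalibrated against reference ions, and
summarized per run as mean-intensity representative lists. Runs are
matched at 20 ppm into a common mass set P′; a feature survives only if
its mean intensity is non-zero in *every* run. Pixel spectra are divided
by the median of their non-zero intensities and batch-corrected with
empirical-Bayes location/scale adjustment (batch = run).

**Consensus modules** (`netmods`): per run, a signed-hybrid adjacency
a_ij = max(cor(x_i, x_j), 0)^β on pure-clone pixels only, with β the
smallest power whose scale-free fit R² > 0.85 in every run. After
single-quantile (0.95) scaling, the consensus adjacency is the entrywise
minimum across runs; modules are cut from the topological overlap matrix

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

by average-linkage clustering. Each module is summarized by its
eigenmetabolite (ME, first principal component of the standardized module
ions); modules with ME correlation > 0.85 merge. The fraction of high-ME
pixels per tissue is regressed on genotype with a logit-link beta model
(Wald test, Benjamini–Hochberg), and mixed-clone pixels are scored by
projecting onto the module loadings.

**Tracing** (`isotrace`): isotopologues m+k (k = 0..5, spacing
1.003355 Th) are matched at 10 ppm; natural ¹³C signal is estimated from
the monoisotopic image via Binom(k; N, P)/Binom(0; N, P) with P = 0.01109
and subtracted (negative remainders → 0). Labeled images are correlated
over mixed-clone pixels within each run, combined by entrywise minimum,
tested against 10,000 pixel permutations (p = (ΣI + 1)/10,001), and cut
into two clusters on distance 1 − consensus.

**IHC co-registration** (`ihcreg`): DAB green channel < 230 marks
MYC-positive pixels; 16×16 block sums are clustered by k = 2 k-means;
the high cluster is resampled onto the MSI grid through a supplied affine
transform; region contrasts use a mixed-effects beta regression with
random intercepts for run and tissue.

**GC–MS** (`gcmsen`): the observed isotopologue vector is deconvolved
through the binomial natural-abundance matrix (non-negative least
squares); Enrichment(m+x) = C_{m+x}/Σ_j C_{m+j} × 100 and total carbon
enrichment Σ_k k·Enrichment(m+k)/i.

All stages are exercised end to end on a synthetic biclonal generator
(`synthio`) with known ground truth — planted modules, batch effects,
scattered noise ions, binomial isotopologues and genotype-dependent
labeling — so every claim the pipeline makes is testable without any
external data.

## Worked example

```bash
python examples/03_detect_modules.py
```

prints (abridged):

```
soft power: 7
planted-partition ARI: 1.000  (1.0 = exact recovery)
         slope      se  wald_p    bh_q  associated
module
M1      4.7958     NaN  0.0000  0.0000        True
M2      0.1110  0.0895  0.2145  0.2145       False
projected ME on 11532 mix pixels: range [-3.24, 5.50]
```

The planted two-module partition is recovered exactly (ARI 1.0); only the
genotype-linked module M1 is flagged (positive slope: its eigenmetabolite
is elevated in MYC-high tissue; the NaN standard error marks a saturated
fit scored by likelihood ratio), and mixed-clone pixels get projected
module scores that map the clonal zonation. The other examples cover
generation (`01`), preprocessing (`02`), isotope tracing (`04`), IHC
co-registration (`05`), GC–MS enrichment (`06`) and
coexpression/pathway statistics (`07`).

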