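# Methods

`spaceclone` analyses spatial tumor heterogeneity in multiple myeloma from
paired bone-marrow samples — a random iliac-crest aspirate (RBM) and an
imaging-guided focal lesion (FL) — across four data layers: bulk WGS variant
tables, single-cell RNA and ATAC matrices, TCR contigs, and microenvironment
annotations. Because the corresponding patient data are controlled-access,
every stage runs end-to-end on a synthetic cohort generator whose ground
truth (clone tree, multiplicities, cell labels, clonotype frequencies) is
retained, making each stage's recovery measurable.

## Cancer clonal fraction

For a variant with VAF `f_s` in a sample of purity `p` on a locus of total
tumor copy number `n_locus`, the mutation copy number is

    n_mut = f_s * (1/p) * [p * n_locus + 2 * (1 - p)]

The multiplicity `n_chr` is the maximum-likelihood candidate `C` in
`{1..n_locus}` under `Binomial(alt | total, C*p / (p*n_locus + 2(1-p)))`,
with expected VAFs capped at 1 before evaluation and likelihood ties broken
toward the smallest `C` (this makes "exact agreement with brute force"
well-defined when several capped candidates coincide). `CCF = n_mut / n_chr`,
reported uncapped.

The 95% CI is a Wilson score interval on `f_s` mapped through the equation
with `n_chr` held fixed — the map is monotone, so the interval transforms
directly. The method for the CI is a design choice of this package; it is
closed-form and behaves sensibly at extreme VAFs.

### Paired-site classes

SNVs are *filtered* unless CCF > 0.15 at ≥ 1 site. At the dominant site a
variant is *major* when its CCF CI upper bound reaches 1, else *minor*.
*Unshared*: the partner site shows no detectable signal — here defined as
CCF < 0.05 with alt reads ≤ 1 + expected error reads (sequencing error
`1e-3` per base), mirroring a recount-in-both-samples step. *Enriched*:
detected at both sites, major at the dominant one, CCF ratio ≥ 3 (ties at
exactly 3.0 count; the ratio is on CCF point estimates, not VAFs). Everything
else retained is *shared*. The heterogeneous fraction is
(unshared + enriched) / retained.

CNAs use segment CCF with a 0.6 major/minor cut-off and a > 200 kb length
filter; cross-sample events are matched by 50% reciprocal overlap with
same-direction copy change. A dominant (> 0.6) event that is a minor
subclone (≤ 0.6) in the partner is the "dominant in one sample" class.

## Synthetic cohort

The generator inverts the CCF equation: expected VAF =
`m * CCF * p / (p*n_locus + 2(1-p))`, alt reads binomial at that VAF plus a
symmetric substitution error (default `1e-3`), total depth Poisson around
85x (typical tumor WGS coverage). Purities are drawn per site from
[0.5, 0.9].

Design choices that make expectations exact and recovery measurable:

- **Clone tree.** Clone prevalences (disjoint fractions summing to 1 per
  site) are Dirichlet-distributed with a 0.1 floor so every subclone's SNVs
  are detectable. Site-unique subclones are leaves (a descendant would leak
  their mutations to the other site) and dominate their home site
  (prevalence ~U(0.75, 0.9)) — the pattern reported for FL-dominant
  subclones. Without home-site dominance, unshared-*major* calls are
  statistically unreachable at 85x because the CCF CI cannot reach 1.
  Topology is random by default; a star (all siblings) topology is available.
- **SNVs sit on clonal copy-number backgrounds** (diploid or truncal CNA),
  so `n_locus` is sample-wide and the binomial mean oracle is closed-form.
  Subclonal CNAs are SNV-free and drive the single-cell dosage signal.
- **Genome model.** Fully synthetic: 22 chromosomes, 100 → 40 Mb, 5
  genes/Mb on a jittered grid (~7,700 genes, ~200 genes per 40 Mb CNA
  region). The scale keeps per-cell detected genes inside the 200–5,000 QC
  window while CNA regions keep ≥ 200 informative features.
- **Single-cell counts.** RNA: gamma-Poisson (negative binomial, dispersion
  10) with lognormal per-gene base means (median 1.0) and per-cell depth
  factors; ATAC: Poisson per 2 Mb tile, expanded to a BED-like fragments
  table. In carrier cells, feature means inside an event scale by the
  dosage effect (1.5× per copy gained, 0.5× per copy lost). A block of
  neutral "normal plasma cell" reference cells is appended. QC metadata are
  drawn to pass thresholds except for a configurable failing fraction (5%).
- **Dispersion** of real samples is unknown; it is a free config parameter.
- **Doublets** exist only as score columns (threshold-testable); mixed
  transcriptomes are not simulated.
- **TCR.** Cells draw clonotypes multinomially from per-site frequency
  vectors; CDR3 pairs are unique per clonotype and seeded from the config
  seed alone so identity is stable across sites; 15% of cells emit a single
  chain.
- **TME.** Per-cell type annotations multinomial from per-site proportion
  vectors; the default cohort plants a ~2.8-fold monocyte/macrophage
  depletion in the FL.

What the generator does *not* emulate: read-level alignment artifacts,
germline variation, phasing, cell-cycle and batch effects, ambient RNA,
real LD/genome structure. Passing tests therefore demonstrate correctness
of the estimators and decision rules under their stated models, not
robustness to every real-data pathology.

## Single-cell subclone detection

Regions are restricted to WGS-subclonal CNAs. RNA signal: counts per 10k,
log1p, per-gene centering on the reference-cell mean, running mean over 51
genes along genomic order (edge-truncated), then the mean over a region's
genes (midpoint containment; regions with < 20 expressed genes are
dropped). ATAC signal: overlapping 10 Mb bins at 5 Mb step from the
fragments file, per-cell bin fractions, z-scores against the normal
plasma-cell reference (zero-variance bins excluded), mean z over bins
overlapping the region.

Cells are clustered by Ward linkage on Euclidean distances (equivalent to
ward.D2 on these signals); `k` is chosen by maximal mean silhouette over
[2, n_candidates + 1] — a reproducible surrogate for cutting the dendrogram
at visually identified subclones. Each cluster is genotyped by
sign-thresholded mean region signal and matched to the WGS candidate with
the identical carrier pattern; unmatched clusters stay provisional. The
threshold τ is scale-dependent: 0.1 on the log-expression scale, 1.0 on the
ATAC z-scale — carrier z magnitudes are ~2–3 while a genome-wide
compositional bias of ~0.2 z arises because carrying a CNA anywhere shifts
every bin's fragment fraction.

A subclone is *confirmed* when its genotype is WGS-matched or the identical
carrier pattern appears in the other modality; provisional genotypes seen in
a single modality are excluded from the confirmed set. Site composition
reports per-site proportions with a site-unique flag (< 1% of the other
site's cells and < 5 cells — site uniqueness is inherently qualitative, the
floor is this package's operationalization) and a plasticity-eligible flag
(> 50 cells at both sites).

Single-cell SNV calls (per-cell ref/alt read counts at WGS positions) are
tested per variant for site enrichment with a two-sided Fisher exact test
over covered cells, BH-adjusted.

## Co-accessibility

Peak accessibility is binarized (count > 0; raw-count mode available) and
every within-window peak pair (center-to-center ≤ 250 kb by default) is
Pearson-correlated across single cells without aggregation. The null
threshold permutes all accessibility values jointly over cells × peaks,
recomputes within-window correlations, records each shuffle's maximum, and
takes the 99th percentile over shuffles (default 100). The alternative
reading — pooled shuffled correlations' 99th percentile — is implemented as
`mode="pooled"`. Significant links additionally need both peaks accessible
in ≥ 5% of cells. Group-restricted analysis repeats this per cell group.

## TCR repertoire

Clonotypes are (TRA, TRB) CDR3 pairs of productive chains; a single-chain
cell merges into a clonotype iff its chain matches exactly one clonotype's
corresponding chain (ambiguous matches stay singletons — the original
analysis does not describe its tie-breaking). Expanded: ≥ 1% of a site's
T cells (per-site denominators; the pooled-per-patient reading is exposed
as an option) with ≥ 5 cells in one of the paired samples; hyperexpanded:
≥ 5%. Paired comparison considers clonotypes with ≥ 10 cells at a site;
≥ 3-fold proportion ratio flags spatial variation, with a 0.5-cell
pseudocount when a zero count is involved.

Module scores (exhaustion: TIGIT, HAVCR2, CTLA4, PDCD1, LAG3, LAYN;
cytotoxicity: NKG7, CCL4, CST7, PRF1, GZMA, GZMB, IFNG, CCL3) bin genes by
average expression (24 bins), sample 100 control genes per target gene from
its bin excluding the target set, and score cells as target mean minus
control mean.

## Composition and reports

Cell-type proportions per patient and site are compared across patients
with the exact two-sided Wilcoxon signed-rank test (exact null — at the 6–8
pairs typical of paired-site cohorts the normal approximation is
inappropriate); fold
change is on means of per-patient proportions; depletion/enrichment flags
at ≥ 2.5-fold with p < 0.05; BH is applied across cell types within the
family (raw p is also reported so unadjusted comparisons stay possible). Patient reports aggregate stage outputs into JSON that
round-trips losslessly; reruns with the same config are byte-identical
(all randomness flows from the config seed through independent
`SeedSequence` streams per stage and site).

## Problem sizes and verification

The default cohort is 6 patients × 2 sites with 3 subclones each (2
patients with a site-unique subclone), 120 SNVs/patient at 85x, 300–500
cells/site/modality plus 120–150 reference cells, 800 T cells/site over 300
clonotypes, and 500 TME cells/site — sizes chosen so a full run completes
in well under a minute while every rule operates away from small-sample
degeneracy. `scripts/acceptance.py` re-measures, from fresh simulations:
the analytic CCF identity (189 grid points, < 1e-9), multiplicity agreement
with brute force (1,000 tuples), pooled classification accuracy on an
8-patient cohort (typically ~96%), subclone ARI for both modalities
(typically ≥ 0.95) with identical genotype sets, artifact exclusion from
the confirmed set (100% in 20 runs; cluster-level detection of the planted
artifact is additionally reported and is occasionally missed when it
differs from a candidate by a single weak gain), the co-accessibility null
rate (≤ 2% by construction of the threshold), TCR rule agreement with brute
force (200 tables including boundary cases), the exact signed-rank p for
six uniformly-directed pairs (0.03125 = 2/2^6), and byte-identical pipeline
reruns.

## Known limitations

- Iterative, patient-specific rounds of subclone clustering are replaced
  by a single silhouette-selected pass; deeply nested subclones may need the exposed
  re-clustering of a cell subset.
- Purity is a required input; re-estimation from VAF histograms is not
  implemented.
- CNA cross-sample matching is automatic (50% reciprocal overlap), with
  no manual event curation step.
- The detection floor for "unshared", the site-unique cell floors, and the
  ATAC-scale τ are operationalizations of qualitative statements; all are
  exposed in config.
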