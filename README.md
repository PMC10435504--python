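# spaceclone

Spatial clonal heterogeneity analysis for paired-site multiple myeloma
samples. Given a random iliac-crest bone-marrow aspirate (RBM) and an
imaging-guided focal lesion (FL) from the same patient, the package

- estimates per-variant **cancer clonal fractions** (CCF) from bulk WGS
  read counts and classifies SNVs/CNAs into *shared*, *unshared*, and
  *enriched* paired-site classes;
- detects **CNA-defined subclones** in single-cell RNA and ATAC data,
  supervised by the WGS-subclonal regions, and confirms them across
  modalities;
- computes single-cell-resolution **peak co-accessibility** with a
  shuffled-background significance threshold;
- builds **TCR clonotypes**, classifies expansion, and flags spatially
  variable clones between sites;
- compares paired-site **microenvironment composition** with an exact
  signed-rank test.

Because the corresponding patient data are controlled-access, the package
ships a synthetic cohort generator with full ground truth, and every stage
is validated against it. It is aimed at computational cancer-genomics
researchers working with multi-region tumor designs.

## The statistic at the core

For a variant with VAF *f*ₛ, tumor purity *p*, and locus total copy number
*n*ₗₒ꜀ᵤₛ, the mutation copy number is

&nbsp;&nbsp;&nbsp;&nbsp;*n*ₘᵤₜ = *f*ₛ · (1/*p*) · [*p·n*ₗₒ꜀ᵤₛ + 2(1 − *p*)]

The multiplicity *n*꜀ₕᵣ (copies carrying the mutation) is chosen by maximum
binomial likelihood over candidates 1..*n*ₗₒ꜀ᵤₛ, and CCF = *n*ₘᵤₜ / *n*꜀ₕᵣ.
SNVs with CCF > 0.15 in at least one site are retained; a variant is
*major* when its 95% CI upper bound reaches 1, *unshared* when undetectable
at the partner site, *enriched* at a ≥ 3-fold CCF ratio when major. CNAs
use segment CCF with a 0.6 cut-off and a > 200 kb filter. See
`docs/methods.md` for every rule and default.

## Worked example

The numbered scripts under `analysis/` run the full study on the synthetic
cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_ccf_heterogeneity.py
```

prints, for the default six-patient cohort (seed 7):

```
P01: 120 retained SNVs, 34.2% heterogeneous (unshared + enriched)
P02: 120 retained SNVs, 25.8% heterogeneous (unshared + enriched)
P03: 120 retained SNVs, 10.0% heterogeneous (unshared + enriched)
...
cohort mean heterogeneous fraction: 14.5%
```

P01 and P02 carry a planted FL-dominant site-unique subclone — their
heterogeneous fractions (the share of retained SNVs that are unshared or
enriched between sites) are correspondingly high, while patients without
one sit near the read-noise floor. `analysis/03_sc_subclones.py` then
recovers the same subclones from single cells:

```
rna:  3 clusters (silhouette 0.75), genotypes {'sub2': (1, 1), 'sub1': (1, 0), 'sub0': (0, 0)}
atac: 3 clusters (silhouette 0.69), genotypes {'sub2': (1, 1), 'sub1': (1, 0), 'sub0': (0, 0)}
confirmed subclones: {'sub2': ['ATAC', 'RNA', 'WGS'], ...}
site-unique subclone: sub2 at RBM (386 cells)
```

and `analysis/06_tme_composition.py` finds the planted microenvironment
shift:

```
monocyte_macrophage  RBM 19.0% vs FL 7.2%  fold 2.63  p 0.0312  DEPLETED in FL
```

(exact two-sided Wilcoxon signed-rank over six patient pairs; 0.0312 =
2/2⁶ is the smallest attainable two-sided p at n = 6). The same machinery
is available as a library (`spaceclone.ccf`, `.subclones`, `.coaccess`,
`.repertoire`, `.report`) and as a CLI:

```bash
spaceclone run --seed 7 --out results/pipeline
spaceclone ccf --variants merged.tsv --purity-a 0.7 --purity-b 0.6 --out ccf.tsv
```

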