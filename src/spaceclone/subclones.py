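"""WGS-supervised subclone detection in single-cell RNA and ATAC data.

Subclones are defined by subclonal CNAs called from bulk WGS. Single-cell
matrices are reduced to per-cell signals over exactly those WGS regions —
smoothed, reference-centered expression averages for RNA (the InferCNV-style
signal) and 10 Mb-bin fragment z-scores against a normal plasma-cell
reference for ATAC — then Ward-linkage hierarchical clustering partitions
the cells, each cluster is genotyped by thresholded mean region signal, and
genotypes are confirmed across WGS and the second single-cell modality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SubclonalRegion",
    "SubcloneGenotype",
    "SubcloneAssignment",
    "qc_filter_cells",
    "region_signal_rna",
    "region_signal_atac",
    "cluster_subclones",
    "confirm_subclones",
    "site_composition",
    "sc_snv_site_test",
]

# QC thresholds (single-cell)
RNA_MAX_MITO = 0.05
RNA_MIN_GENES = 200
RNA_MAX_GENES = 5000
RNA_MAX_DOUBLET = 0.3
ATAC_MIN_TSS = 8.0
ATAC_MIN_FRAGMENTS = 3000
ATAC_MAX_DOUBLET_ENRICH = 6.0
ATAC_MAX_PREDICTED_DOUBLET = 200.0

MIN_GENES_PER_REGION = 20
SMOOTH_WINDOW = 51
ATAC_BIN_BP = 10_000_000
ATAC_BIN_STEP = 5_000_000
GENOTYPE_TAU = 0.1  # log-expression scale (RNA signals)
GENOTYPE_TAU_Z = 1.0  # z-score scale (ATAC signals)


@dataclass(frozen=True)
class SubclonalRegion:
    """A WGS-subclonal CNA interval admitted as a clustering feature."""

    event_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    direction: str  # "gain" | "loss"
    seg_ccf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain/loss, got {self.direction!r}")
        if self.start >= self.end:
            raise ValueError("region start must be < end")


@dataclass(frozen=True)
class SubcloneGenotype:
    """Carrier pattern over the WGS subclonal events."""

    label: str
    carriers: tuple[int, ...]  # 0/1 per region, aligned with the region list


@dataclass
class SubcloneAssignment:
    """Cluster labels per cell plus per-cluster inferred genotypes."""

    labels: pd.Series  # cell id -> subclone label
    genotypes: dict[str, tuple[int, ...]]
    provisional: dict[str, bool]
    k: int
    silhouette: float
    region_ids: tuple[str, ...]
    confirmed: dict[str, set[str]] = field(default_factory=dict)  # label -> evidence


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

_RNA_QC = ("mito_fraction", "n_detected_features", "doublet_score")
_ATAC_QC = ("tss_score", "fragment_count", "doublet_enrichment", "predicted_doublet_score")


def qc_filter_cells(adata, modality: str):
    """Remove cells failing the modality's QC thresholds.

    RNA: mitochondrial fraction <= 5%, 200–5000 detected genes, doublet
    score <= 0.3. ATAC: TSS enrichment >= 8, >= 3000 fragments, doublet
    enrichment <= 6, predicted doublet score <= 200. Removal reasons are
    logged and returned in ``adata.uns["qc_removed"]``.
    """
    required = _RNA_QC if modality == "rna" else _ATAC_QC
    for col in required:
        if col not in adata.obs.columns:
            raise ValueError(f"missing QC column {col!r} for modality {modality!r}")
    obs = adata.obs
    reasons = pd.Series("", index=obs.index, dtype=object)

    def _flag(mask: pd.Series, reason: str) -> None:
        nonlocal reasons
        reasons[mask] = reasons[mask] + reason + ";"

    if modality == "rna":
        _flag(obs["mito_fraction"] > RNA_MAX_MITO, "high_mito")
        _flag(obs["n_detected_features"] < RNA_MIN_GENES, "few_genes")
        _flag(obs["n_detected_features"] > RNA_MAX_GENES, "many_genes")
        _flag(obs["doublet_score"] > RNA_MAX_DOUBLET, "doublet")
    elif modality == "atac":
        _flag(obs["tss_score"] < ATAC_MIN_TSS, "low_tss")
        _flag(obs["fragment_count"] < ATAC_MIN_FRAGMENTS, "few_fragments")
        _flag(obs["doublet_enrichment"] > ATAC_MAX_DOUBLET_ENRICH, "doublet_enrichment")
        _flag(obs["predicted_doublet_score"] > ATAC_MAX_PREDICTED_DOUBLET, "predicted_doublet")
    else:
        raise ValueError(f"unknown modality {modality!r}")

    keep = reasons == ""
    removed = pd.DataFrame({"reason": reasons[~keep]})
    if len(removed):
        logger.info("qc_filter_cells: removed %d/%d cells", len(removed), len(obs))
    out = adata[keep.to_numpy()].copy()
    out.uns["qc_removed"] = removed
    return out


# ---------------------------------------------------------------------------
# region signals
# ---------------------------------------------------------------------------


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Edge-truncated running mean along the last axis (odd window)."""
    if x.shape[-1] == 0 or window <= 1:
        return x
    kernel = np.ones(window)
    counts = np.convolve(np.ones(x.shape[-1]), kernel, mode="same")
    return np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same") / counts, -1, x
    )


def region_signal_rna(
    adata,
    regions: list[SubclonalRegion],
    *,
    min_genes: int = MIN_GENES_PER_REGION,
    window: int = SMOOTH_WINDOW,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """InferCNV-style per-cell signal over the WGS subclonal regions.

    Counts are depth-normalized (counts per ``target_sum``), log1p
    transformed, centered per gene on the reference-cell mean, smoothed by a
    running mean over ``window`` genes along genomic order within each
    chromosome, and averaged over the genes of each region (gene assigned by
    midpoint containment). Regions with fewer than ``min_genes`` expressed
    genes are dropped with a warning. Reference-cell signals center at 0 by
    construction.
    """
    if not adata.obs["is_reference"].any():
        raise ValueError("reference cells required for centering")
    X = adata.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    expressed = X.sum(axis=0) > 0
    X = X[:, expressed]
    var = adata.var[expressed]

    depth = X.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    logX = np.log1p(X / depth * target_sum)
    ref = adata.obs["is_reference"].to_numpy()
    centered = logX - logX[ref].mean(axis=0, keepdims=True)

    mids = ((var["start"].to_numpy() + var["end"].to_numpy()) // 2).astype(np.int64)
    chroms = var["chrom"].to_numpy()
    smoothed = np.empty_like(centered)
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        order = idx[np.argsort(mids[idx])]
        smoothed[:, order] = _running_mean(centered[:, order], window)

    out = {}
    for reg in regions:
        member = (chroms == reg.chrom) & (mids >= reg.start) & (mids < reg.end)
        if member.sum() < min_genes:
            logger.warning(
                "region %s dropped: %d expressed genes < %d",
                reg.event_id, int(member.sum()), min_genes,
            )
            continue
        out[reg.event_id] = smoothed[:, member].mean(axis=1)
    return pd.DataFrame(out, index=adata.obs_names)


def make_bins(chrom_lengths: dict[str, int], bin_bp: int = ATAC_BIN_BP,
              step_bp: int = ATAC_BIN_STEP) -> pd.DataFrame:
    """Overlapping genome-wide bins (default 10 Mb, 5 Mb step)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + bin_bp, length)))
            start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def region_signal_atac(
    fragments: pd.DataFrame,
    regions: list[SubclonalRegion],
    chrom_lengths: dict[str, int],
    reference_cells: set[str] | pd.Index,
    *,
    bin_bp: int = ATAC_BIN_BP,
    step_bp: int = ATAC_BIN_STEP,
) -> pd.DataFrame:
    """Per-cell z-score signal over WGS subclonal regions from ATAC fragments.

    Fragments are counted into overlapping 10 Mb bins (a fragment is
    assigned to every bin containing its midpoint), converted to per-cell
    bin fractions, standardized per bin against the normal plasma-cell
    reference (z = (x - ref mean) / ref sd; zero-variance bins are excluded
    and logged), and averaged over the bins overlapping each region.
    """
    ref_set = set(reference_cells)
    bins = make_bins(chrom_lengths, bin_bp, step_bp)
    cells = pd.Index(pd.unique(fragments["barcode"]), name="cell_id")
    cell_idx = pd.Series(np.arange(len(cells)), index=cells)

    bin_lookup: dict[str, np.ndarray] = {}
    for chrom in chrom_lengths:
        mask = bins["chrom"] == chrom
        bin_lookup[chrom] = bins.index[mask].to_numpy()

    counts = np.zeros((len(cells), len(bins)))
    for chrom, grp in fragments.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in chrom_lengths:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        length = chrom_lengths[chrom]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts < 0).any() or (ends > length).any():
            bad = grp[(starts < 0) | (ends > length)].iloc[0]
            raise ValueError(
                f"fragment beyond chromosome end: {chrom}:{bad['start']}-{bad['end']}"
            )
        mids = (starts + ends) // 2
        rows = cell_idx[grp["barcode"]].to_numpy()
        weights = grp["count"].to_numpy() if "count" in grp else np.ones(len(grp))
        local_bins = bin_lookup[chrom]
        # bins are on a step_bp grid; a midpoint falls into bins k and k-1
        k = mids // step_bp
        span = bin_bp // step_bp
        for off in range(span):
            idx = k - off
            ok = idx >= 0
            ok &= idx < len(local_bins)
            np.add.at(counts, (rows[ok], local_bins[idx[ok].astype(int)]), weights[ok])

    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    frac = counts / totals

    ref_mask = np.array([c in ref_set for c in cells])
    if not ref_mask.any():
        raise ValueError("reference cells required for z-scores")
    mu = frac[ref_mask].mean(axis=0)
    sd = frac[ref_mask].std(axis=0, ddof=1)
    valid = sd > 0
    if (~valid).any():
        logger.info("excluding %d zero-variance bins", int((~valid).sum()))
    z = np.full_like(frac, np.nan)
    z[:, valid] = (frac[:, valid] - mu[valid]) / sd[valid]

    out = {}
    bin_mids_start = bins["start"].to_numpy()
    bin_mids_end = bins["end"].to_numpy()
    bin_chrom = bins["chrom"].to_numpy()
    for reg in regions:
        overlap = (
            (bin_chrom == reg.chrom)
            & (bin_mids_start < reg.end)
            & (bin_mids_end > reg.start)
            & valid
        )
        if not overlap.any():
            logger.warning("region %s has no usable bins", reg.event_id)
            continue
        out[reg.event_id] = z[:, overlap].mean(axis=1)
    return pd.DataFrame(out, index=cells)


# ---------------------------------------------------------------------------
# clustering and confirmation
# ---------------------------------------------------------------------------


def cluster_subclones(
    signal: pd.DataFrame,
    regions: list[SubclonalRegion],
    candidates: list[SubcloneGenotype],
    *,
    k_range: tuple[int, int] | None = None,
    tau: float = GENOTYPE_TAU,
    min_cells: int = 50,
) -> SubcloneAssignment:
    """Ward-linkage clustering of cells over region signals, genotype-matched.

    ``k`` is selected by maximal mean silhouette over ``k_range`` (default
    [2, n_candidates + 1]). Each cluster's genotype is inferred by
    sign-thresholded mean region signal (carrier of a gain when the mean
    exceeds +tau, of a loss when below -tau) and matched to the candidate
    with an identical carrier pattern; clusters matching no candidate keep a
    provisional label.
    """
    if signal.shape[1] < 1:
        raise ValueError("empty region set")
    region_ids = tuple(signal.columns)
    region_by_id = {r.event_id: r for r in regions}
    n = len(signal)
    if n < min_cells:
        raise ValueError(f"need >= {min_cells} cells, got {n}")
    X = signal.to_numpy(dtype=float)
    if k_range is None:
        k_range = (2, max(2, len(candidates) + 1))
    k_lo, k_hi = k_range
    if n <= k_hi:
        raise ValueError("fewer cells than the upper end of k_range")

    if np.allclose(X, X[0], atol=1e-12):
        labels = np.ones(n, dtype=int)
        best_k, best_sil = 1, float("nan")
    else:
        Z = linkage(X, method="ward")  # Ward on Euclidean == ward.D2
        best_k, best_sil, labels = None, -np.inf, None
        for k in range(k_lo, k_hi + 1):
            lab = fcluster(Z, t=k, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            sil = silhouette_score(X, lab)
            if sil > best_sil:
                best_k, best_sil, labels = k, float(sil), lab
        if labels is None:  # degenerate: everything merged
            labels = np.ones(n, dtype=int)
            best_k, best_sil = 1, float("nan")

    genotypes: dict[str, tuple[int, ...]] = {}
    provisional: dict[str, bool] = {}
    mapped = pd.Series(index=signal.index, dtype=object)
    by_pattern = {tuple(c.carriers): c.label for c in candidates}
    prov_counter = 0
    for cl in np.unique(labels):
        mask = labels == cl
        means = X[mask].mean(axis=0)
        pattern = []
        for rid, m in zip(region_ids, means):
            direction = region_by_id[rid].direction if rid in region_by_id else "gain"
            if direction == "gain":
                pattern.append(1 if m > tau else 0)
            else:
                pattern.append(1 if m < -tau else 0)
        pattern = tuple(pattern)
        if pattern in by_pattern:
            label = by_pattern[pattern]
            prov = False
        else:
            label = f"provisional_{prov_counter}"
            prov_counter += 1
            prov = True
        genotypes[label] = pattern
        provisional[label] = prov
        mapped[mask] = label

    return SubcloneAssignment(
        labels=mapped,
        genotypes=genotypes,
        provisional=provisional,
        k=int(best_k),
        silhouette=best_sil,
        region_ids=region_ids,
    )


def confirm_subclones(
    rna: SubcloneAssignment,
    atac: SubcloneAssignment | None,
    wgs_regions: list[SubclonalRegion],
) -> dict[str, set[str]]:
    """Confirm genotypes by WGS support or by the second single-cell modality.

    A genotype matched to a WGS candidate (non-provisional) is confirmed
    with WGS evidence. A provisional genotype is confirmed only when the
    identical carrier pattern appears in the other modality; one-modality
    artifacts are excluded. Returns label -> evidence set for confirmed
    subclones and records it on the assignments.
    """
    wgs_ids = {r.event_id for r in wgs_regions}
    confirmed: dict[str, set[str]] = {}

    def _other_patterns(asgn: SubcloneAssignment | None) -> set[tuple[int, ...]]:
        return set(asgn.genotypes.values()) if asgn is not None else set()

    for asgn, modality, other in ((rna, "RNA", atac), (atac, "ATAC", rna)):
        if asgn is None:
            continue
        other_pats = _other_patterns(other)
        for label, pattern in asgn.genotypes.items():
            evidence = {modality}
            defining = {
                rid for rid, c in zip(asgn.region_ids, pattern) if c == 1
            }
            if not asgn.provisional[label] and (not defining or defining <= wgs_ids):
                evidence.add("WGS")
            if pattern in other_pats:
                evidence.add("RNA" if modality == "ATAC" else "ATAC")
            if "WGS" in evidence or len(evidence) >= 2:
                confirmed.setdefault(label, set()).update(evidence)
        asgn.confirmed = {
            lbl: ev for lbl, ev in confirmed.items() if lbl in asgn.genotypes
        }
    return confirmed


def site_composition(
    assignment: SubcloneAssignment,
    sites: pd.Series,
    *,
    confirmed_only: bool = True,
    unique_max_fraction: float = 0.01,
    unique_max_cells: int = 5,
    plasticity_min_cells: int = 50,
) -> pd.DataFrame:
    """Per-site subclone proportions with site-unique and plasticity flags.

    A subclone is unique to a site when its cell count at the other site is
    below both floors (< 1% of that site's cells and < 5 cells); it is
    plasticity-eligible when it has > 50 cells at both sites.
    """
    labels = assignment.labels
    if confirmed_only and assignment.confirmed:
        keep = labels.isin(assignment.confirmed)
        labels = labels[keep]
        sites = sites.loc[labels.index]
    df = pd.DataFrame({"subclone": labels, "site": sites.loc[labels.index]})
    counts = df.groupby(["subclone", "site"], observed=True).size().unstack(fill_value=0)
    site_totals = counts.sum(axis=0)
    rows = []
    for sub in counts.index:
        for site in counts.columns:
            total = site_totals[site]
            if total == 0:
                rows.append((sub, site, 0, float("nan"), False, False))
                continue
            n_here = int(counts.loc[sub, site])
            others = [s for s in counts.columns if s != site]
            unique = bool(others) and all(
                counts.loc[sub, o] < unique_max_cells
                and (site_totals[o] == 0 or counts.loc[sub, o] / site_totals[o] < unique_max_fraction)
                for o in others
            ) and n_here > 0
            plastic = bool(others) and all(
                counts.loc[sub, o] > plasticity_min_cells for o in others
            ) and n_here > plasticity_min_cells
            rows.append((sub, site, n_here, n_here / total, unique, plastic))
    return pd.DataFrame(
        rows,
        columns=["subclone", "site", "n_cells", "proportion", "site_unique", "plasticity_eligible"],
    )


# ---------------------------------------------------------------------------
# single-cell SNV site test
# ---------------------------------------------------------------------------


def sc_snv_site_test(
    cell_calls: pd.DataFrame, *, site_a: str = "RBM", site_b: str = "FL",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher exact test of per-variant mutant-cell enrichment between sites.

    ``cell_calls`` has one row per (cell, variant) with ``ref_reads``,
    ``alt_reads`` and ``site``; only cells with >= 1 read covering the
    position count as covered. Benjamini-Hochberg adjustment is applied over
    the tested variants; a variant is site-enriched at adjusted p < 0.05.
    """
    covered = cell_calls[(cell_calls["ref_reads"] + cell_calls["alt_reads"]) >= 1]
    rows = []
    for var, grp in covered.groupby("variant", sort=False):
        res = {"variant": var}
        tables = {}
        for site in (site_a, site_b):
            g = grp[grp["site"] == site]
            mut = int((g["alt_reads"] > 0).sum())
            tot = int(len(g))
            tables[site] = (mut, tot)
            res[f"mutant_{site}"] = mut
            res[f"covered_{site}"] = tot
        (m_a, t_a), (m_b, t_b) = tables[site_a], tables[site_b]
        if t_a == 0 and t_b == 0:
            res.update(odds_ratio=float("nan"), p=float("nan"), testable=False)
        else:
            table = [[m_a, t_a - m_a], [m_b, t_b - m_b]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            res.update(odds_ratio=float(odds), p=float(p), testable=True)
        rows.append(res)
    out = pd.DataFrame(rows)
    if len(out):
        testable = out["testable"].to_numpy()
        padj = np.full(len(out), np.nan)
        if testable.any():
            padj[testable] = multipletests(
                out.loc[testable, "p"].to_numpy(), method="fdr_bh"
            )[1]
        out["p_adj"] = padj
        out["site_enriched"] = (out["p_adj"] < alpha) & testable
    return out
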