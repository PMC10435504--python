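"""TCR clonotype assembly, expansion classes and paired-site comparison.

Clonotypes are defined by the (TRA, TRB) CDR3 amino-acid pair of cells with
both chains sequenced; a cell with only one productive chain is merged into
a clonotype when its chain matches exactly one clonotype's corresponding
chain. A clonotype is *expanded* when it reaches >= 1% of a site's T cells
with at least 5 cells in one of the paired samples, *hyperexpanded* at
>= 5%. Paired-site comparison considers clonotypes with >= 10 cells at one
site and flags a >= 3-fold proportion difference as spatial variation.

Module scores (exhaustion: TIGIT, HAVCR2, CTLA4, PDCD1, LAG3, LAYN;
cytotoxicity: NKG7, CCL4, CST7, PRF1, GZMA, GZMB, IFNG, CCL3) are per-cell
mean target-set expression minus the mean of expression-matched control
genes drawn from average-expression bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "EXHAUSTION_GENES",
    "CYTOTOXICITY_GENES",
    "assign_clonotypes",
    "classify_expansion",
    "compare_sites",
    "module_score",
]

EXHAUSTION_GENES = ("TIGIT", "HAVCR2", "CTLA4", "PDCD1", "LAG3", "LAYN")
CYTOTOXICITY_GENES = ("NKG7", "CCL4", "CST7", "PRF1", "GZMA", "GZMB", "IFNG", "CCL3")

EXPANDED_MIN_PROP = 0.01
EXPANDED_MIN_CELLS = 5
HYPEREXPANDED_MIN_PROP = 0.05
PAIRING_MIN_CELLS = 10
SPATIAL_FOLD = 3.0


def assign_clonotypes(
    contigs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build clonotypes from chain-level contig records.

    Only productive records with a non-empty CDR3 enter clonotyping. Returns
    ``(clonotypes, cell_map)``: a per-clonotype table with per-site cell
    counts and the cell -> clonotype assignment. Single-chain cells merging
    ambiguously (their chain matches several clonotypes) stay singletons;
    conflicting duplicate (cell, chain) CDR3s raise.
    """
    rec = contigs[
        contigs["productive"].astype(bool)
        & contigs["junction_aa"].notna()
        & (contigs["junction_aa"] != "")
    ]
    dup = rec.groupby(["cell_id", "locus"])["junction_aa"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        cells = sorted({c for c, _ in conflicts.index})
        raise ValueError(f"conflicting chain CDR3s within cells: {cells}")

    chains = (
        rec.drop_duplicates(["cell_id", "locus"])
        .pivot(index="cell_id", columns="locus", values="junction_aa")
        .reindex(columns=["TRA", "TRB"])
    )
    site_of = rec.drop_duplicates("cell_id").set_index("cell_id")["site"]

    paired = chains.dropna(subset=["TRA", "TRB"])
    keys = list(dict.fromkeys(zip(paired["TRA"], paired["TRB"])))
    key_to_id = {k: f"clonotype_{i}" for i, k in enumerate(keys)}
    cell_map = pd.Series(index=chains.index, dtype=object)
    for cell, row in paired.iterrows():
        cell_map[cell] = key_to_id[(row["TRA"], row["TRB"])]

    by_tra: dict[str, set[str]] = {}
    by_trb: dict[str, set[str]] = {}
    for (tra, trb), cid in key_to_id.items():
        by_tra.setdefault(tra, set()).add(cid)
        by_trb.setdefault(trb, set()).add(cid)

    n_merged = 0
    singleton_counter = 0
    for cell, row in chains.iterrows():
        if pd.notna(row["TRA"]) and pd.notna(row["TRB"]):
            continue
        chain_val, lookup = (
            (row["TRA"], by_tra) if pd.notna(row["TRA"]) else (row["TRB"], by_trb)
        )
        matches = lookup.get(chain_val, set())
        if len(matches) == 1:
            cell_map[cell] = next(iter(matches))
            n_merged += 1
        else:
            cell_map[cell] = f"singleton_{singleton_counter}"
            singleton_counter += 1

    df = pd.DataFrame({"clonotype_id": cell_map, "site": site_of.reindex(cell_map.index)})
    counts = (
        df.groupby(["clonotype_id", "site"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    id_to_key = {v: k for k, v in key_to_id.items()}
    table = counts.reset_index()
    table["tra_cdr3"] = table["clonotype_id"].map(lambda c: id_to_key.get(c, (None, None))[0])
    table["trb_cdr3"] = table["clonotype_id"].map(lambda c: id_to_key.get(c, (None, None))[1])
    n_paired_assigned = int(cell_map.str.startswith("clonotype_").sum())
    table.attrs["assignment_rate"] = n_paired_assigned / len(cell_map) if len(cell_map) else 0.0
    table.attrs["n_merged_single_chain"] = n_merged
    return table, cell_map


def classify_expansion(
    clonotypes: pd.DataFrame, site_totals: dict[str, int], *, pooled: bool = False
) -> pd.DataFrame:
    """Label clonotypes none / expanded / hyperexpanded.

    Expanded: >= 1% of a site's T cells at >= 1 site with >= 5 cells in one
    of the paired samples. Hyperexpanded: >= 5% of a site's T cells (the
    5-cell floor carries over). With ``pooled=True`` the proportion
    denominator is the patient's pooled T-cell total across sites instead of
    the per-site total.
    """
    sites = [s for s in site_totals if s in clonotypes.columns]
    for s in sites:
        if site_totals[s] <= 0:
            raise ValueError(f"site total for {s} must be positive")
        if (clonotypes[s] > site_totals[s]).any():
            raise ValueError(f"clonotype count exceeds site total at {s}")
    out = clonotypes.copy()
    if pooled:
        pooled_total = sum(site_totals[s] for s in sites)
        pooled_counts = sum(out[s] for s in sites)
        props = pd.DataFrame({s: pooled_counts / pooled_total for s in sites})
    else:
        props = pd.DataFrame({s: out[s] / site_totals[s] for s in sites})
    count_floor = pd.DataFrame({s: out[s] >= EXPANDED_MIN_CELLS for s in sites}).any(axis=1)
    expanded = (props >= EXPANDED_MIN_PROP).any(axis=1) & count_floor
    hyper = (props >= HYPEREXPANDED_MIN_PROP).any(axis=1) & count_floor
    out["expansion"] = np.where(hyper, "hyperexpanded", np.where(expanded, "expanded", "none"))
    for s in sites:
        out[f"prop_{s}"] = props[s]
    return out


def compare_sites(
    clonotypes: pd.DataFrame,
    site_totals: dict[str, int],
    *,
    site_a: str = "RBM",
    site_b: str = "FL",
) -> pd.DataFrame:
    """Paired-site spatial comparison of clonotypes.

    Pairing-eligible: >= 10 cells at >= 1 site. Site-unique: eligible with 0
    cells at the other site. Spatial variation: proportion ratio >= 3 between
    sites; a 0.5-cell pseudocount replaces a zero count for the ratio (the
    zero case is already covered by uniqueness).
    """
    out = clonotypes.copy()
    for s in (site_a, site_b):
        if s not in out.columns:
            out[s] = 0
    eligible = (out[site_a] >= PAIRING_MIN_CELLS) | (out[site_b] >= PAIRING_MIN_CELLS)
    out["pairing_eligible"] = eligible
    out["unique_site"] = None
    out.loc[eligible & (out[site_b] == 0), "unique_site"] = site_a
    out.loc[eligible & (out[site_a] == 0), "unique_site"] = site_b

    pa = np.maximum(out[site_a].to_numpy(float), 0.5) / site_totals[site_a]
    pb = np.maximum(out[site_b].to_numpy(float), 0.5) / site_totals[site_b]
    pa_raw = out[site_a].to_numpy(float) / site_totals[site_a]
    pb_raw = out[site_b].to_numpy(float) / site_totals[site_b]
    num = np.where(out[site_a] > 0, pa_raw, pa)
    den = np.where(out[site_b] > 0, pb_raw, pb)
    ratio = np.maximum(num / den, den / num)
    out["proportion_ratio"] = ratio
    out["spatial_variation"] = eligible & (ratio >= SPATIAL_FOLD)
    return out


def module_score(
    adata,
    gene_set: list[str],
    *,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    target_sum: float = 1e4,
    layer_is_normalized: bool = False,
) -> pd.Series:
    """Per-cell gene-set module score (set mean minus matched-control mean).

    Expression is depth-normalized and log1p transformed, genes are binned
    into ``n_bins`` by average expression, and for each target gene
    ``n_ctrl`` control genes are sampled from its bin (seeded). The score is
    the difference between the mean over the target set and the mean over
    the pooled controls, per cell.
    """
    present = [g for g in gene_set if g in adata.var_names]
    missing = [g for g in gene_set if g not in adata.var_names]
    if not present:
        raise ValueError(f"no gene of the set found in the matrix: missing {missing}")
    X = adata.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    if not layer_is_normalized:
        depth = X.sum(axis=1, keepdims=True)
        depth[depth == 0] = 1.0
        X = np.log1p(X / depth * target_sum)
    gene_idx = pd.Index(adata.var_names)
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    ranks = np.empty(len(avg), dtype=int)
    ranks[order] = np.arange(len(avg))
    bins = (ranks * n_bins) // len(avg)

    rng = np.random.default_rng(seed)
    target_cols = np.array([gene_idx.get_loc(g) for g in present])
    ctrl_cols: list[int] = []
    for col in target_cols:
        pool = np.setdiff1d(np.where(bins == bins[col])[0], target_cols)
        if pool.size == 0:  # bin holds only set genes; fall back to the rest
            pool = np.setdiff1d(np.arange(len(avg)), target_cols)
        if pool.size == 0:
            continue
        take = rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False)
        ctrl_cols.extend(int(t) for t in take)
    ctrl_cols = np.unique(ctrl_cols)
    ctrl_mean = X[:, ctrl_cols].mean(axis=1) if ctrl_cols.size else 0.0
    score = X[:, target_cols].mean(axis=1) - ctrl_mean
    return pd.Series(score, index=adata.obs_names, name="module_score")
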