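"""Single-cell peak co-accessibility with a shuffled-background threshold.

Co-accessibility is the Pearson correlation of two peaks' accessibility
across single cells, computed without any cell aggregation. Significance is
calibrated by permutation: accessibility values are shuffled jointly over
cells and peaks, all within-window correlations are recomputed, and the
per-shuffle maximum is recorded; the 99th percentile of those maxima is the
threshold for true links. Links are further required to be accessible in a
minimum percentage of cells in both peaks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "compute_links",
    "shuffled_threshold",
    "filter_links",
    "coaccess_by_group",
]

DEFAULT_WINDOW = 250_000
DEFAULT_SHUFFLES = 100
DEFAULT_MIN_PCT = 0.05


def _dense_matrix(adata, binarize: bool) -> np.ndarray:
    X = adata.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    X = X.astype(float)
    return (X > 0).astype(float) if binarize else X


def _peak_centers(var: pd.DataFrame) -> np.ndarray:
    return ((var["start"].to_numpy() + var["end"].to_numpy()) // 2).astype(np.int64)


def _window_pairs(var: pd.DataFrame, window: int) -> list[tuple[int, int]]:
    centers = _peak_centers(var)
    chroms = var["chrom"].to_numpy()
    pairs = []
    n = len(var)
    for i in range(n):
        for j in range(i + 1, n):
            if chroms[i] != chroms[j]:
                continue
            if abs(int(centers[j]) - int(centers[i])) <= window:
                pairs.append((i, j))
    return pairs


def _pair_correlations(
    X: np.ndarray, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Pearson correlation per peak pair; NaN where either vector is constant."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = np.zeros_like(X)
    ok = sd > 0
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    out = np.empty(len(pairs))
    n = X.shape[0]
    for k, (i, j) in enumerate(pairs):
        if sd[i] == 0 or sd[j] == 0:
            out[k] = np.nan
        else:
            out[k] = float(Z[:, i] @ Z[:, j]) / n
    return out


def compute_links(
    adata, window: int = DEFAULT_WINDOW, *, binarize: bool = True
) -> pd.DataFrame:
    """Correlate every within-window peak pair across single cells.

    Accessibility is binarized (count > 0) by default; ``binarize=False``
    correlates raw counts. Pairs involving a zero-variance vector are
    excluded (correlation undefined).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if adata.n_vars < 2:
        raise ValueError("need at least 2 peaks")
    if adata.n_obs < 20:
        raise ValueError("need at least 20 cells")
    X = _dense_matrix(adata, binarize)
    pairs = _window_pairs(adata.var, window)
    corr = _pair_correlations(X, pairs)
    acc_pct = (X > 0).mean(axis=0)
    rows = []
    names = adata.var_names
    for (i, j), r in zip(pairs, corr):
        if np.isnan(r):
            continue
        rows.append(
            {
                "peak_i": names[i],
                "peak_j": names[j],
                "correlation": float(r),
                "pct_accessible_i": float(acc_pct[i]),
                "pct_accessible_j": float(acc_pct[j]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["peak_i", "peak_j", "correlation", "pct_accessible_i", "pct_accessible_j"],
    )


def shuffled_threshold(
    adata,
    window: int = DEFAULT_WINDOW,
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    *,
    binarize: bool = True,
    mode: str = "max_per_shuffle",
) -> float:
    """99th percentile of the shuffled-background co-accessibility score.

    Each shuffle permutes the accessibility values jointly over the whole
    cells-by-peaks matrix and recomputes all within-window correlations.
    ``mode="max_per_shuffle"`` (default) takes each shuffle's maximum and
    returns the 99th percentile across shuffles; ``mode="pooled"`` pools all
    shuffled correlations and takes their 99th percentile.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    X = _dense_matrix(adata, binarize)
    if np.all(X == X.flat[0]):
        raise ValueError("degenerate matrix: all accessibility values equal")
    pairs = _window_pairs(adata.var, window)
    rng = np.random.default_rng(seed)
    flat = X.ravel()
    stats_per_shuffle = []
    pooled = []
    for _ in range(n_shuffles):
        perm = rng.permutation(flat).reshape(X.shape)
        corr = _pair_correlations(perm, pairs)
        corr = corr[~np.isnan(corr)]
        if corr.size == 0:
            continue
        if mode == "max_per_shuffle":
            stats_per_shuffle.append(corr.max())
        elif mode == "pooled":
            pooled.append(corr)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    values = (
        np.asarray(stats_per_shuffle) if mode == "max_per_shuffle" else np.concatenate(pooled)
    )
    if values.size == 0:
        raise ValueError("no finite shuffled correlations")
    return float(np.percentile(values, 99))


def filter_links(
    links: pd.DataFrame, threshold: float, min_pct: float = DEFAULT_MIN_PCT
) -> pd.DataFrame:
    """Keep links at or above the threshold, accessible in >= min_pct of cells."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = links.copy()
    out["significant"] = (
        (out["correlation"] >= threshold)
        & (out["pct_accessible_i"] >= min_pct)
        & (out["pct_accessible_j"] >= min_pct)
    )
    return out[out["significant"]].drop(columns="significant").reset_index(drop=True)


def coaccess_by_group(
    adata,
    window: int = DEFAULT_WINDOW,
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    *,
    group_key: str = "group",
    min_pct: float = DEFAULT_MIN_PCT,
    min_cells: int = 20,
    binarize: bool = True,
) -> dict[str, pd.DataFrame]:
    """Significant links computed separately per cell group (site or subclone)."""
    out = {}
    for k, group in enumerate(pd.unique(adata.obs[group_key])):
        sub = adata[(adata.obs[group_key] == group).to_numpy()].copy()
        if sub.n_obs < min_cells:
            continue
        links = compute_links(sub, window, binarize=binarize)
        thr = shuffled_threshold(
            sub, window, n_shuffles, seed=seed + k, binarize=binarize
        )
        out[str(group)] = filter_links(links, thr, min_pct)
    return out
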