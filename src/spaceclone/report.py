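"""Pipeline orchestration, paired TME composition tests and patient reports.

``compare_tme_composition`` runs the cohort-level test for cell-type shifts
between the random bone-marrow aspirate and the focal lesion: per-patient
per-site cell-type proportions, an exact two-sided Wilcoxon signed-rank test
on the paired proportions across patients, fold change of the per-site means,
and a depletion/enrichment flag at >= 2.5-fold with p < 0.05.

``run_pipeline`` drives the whole synthetic-cohort analysis: simulate ->
CCF/heterogeneity -> single-cell subclones -> co-accessibility -> TCR ->
composition -> one JSON report per patient. Reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import ccf as ccf_mod
from . import coaccess as coaccess_mod
from . import repertoire as rep_mod
from . import subclones as sub_mod
from . import synthetic as syn_mod
from .genome import default_genome

logger = logging.getLogger(__name__)

__all__ = [
    "compare_tme_composition",
    "PatientReport",
    "build_patient_report",
    "run_pipeline",
    "default_pipeline_config",
]

TME_FOLD_CUTOFF = 2.5
TME_ALPHA = 0.05


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p value (zeros dropped)."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 1.0
    res = stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided", method="exact")
    return float(res.pvalue)


def compare_tme_composition(
    annotations: pd.DataFrame,
    *,
    site_a: str = "RBM",
    site_b: str = "FL",
    fold_cutoff: float = TME_FOLD_CUTOFF,
    alpha: float = TME_ALPHA,
) -> pd.DataFrame:
    """Compare paired-site cell-type composition across the cohort.

    ``annotations`` has one row per cell: (patient, site, cell_id,
    cell_type). Patients missing either site are excluded with a warning.
    Returns one row per cell type with per-site mean proportions, fold
    change (site_a mean / site_b mean), raw and BH-adjusted exact signed-rank
    p values, and flags: ``depleted`` (lower at site_b by >= fold_cutoff,
    p < alpha) and ``enriched`` (higher at site_b by >= fold_cutoff).
    """
    have_both = annotations.groupby("patient")["site"].nunique() >= 2
    excluded = have_both[~have_both].index.tolist()
    if excluded:
        logger.warning("patients missing one site excluded: %s", excluded)
    ann = annotations[annotations["patient"].isin(have_both[have_both].index)]
    patients = sorted(ann["patient"].unique())
    if len(patients) < 2:
        raise ValueError("need >= 2 patients with both sites")

    counts = (
        ann.groupby(["patient", "site", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    rows = []
    for ct in props.columns:
        a = np.array([props.loc[(p, site_a), ct] if (p, site_a) in props.index else np.nan for p in patients])
        b = np.array([props.loc[(p, site_b), ct] if (p, site_b) in props.index else np.nan for p in patients])
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        p_raw = exact_signed_rank_p(a - b)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if mean_a > 0 and mean_b > 0:
            fold = mean_a / mean_b
        else:
            fold = float("inf") if mean_a > 0 else (0.0 if mean_b > 0 else 1.0)
        rows.append(
            {
                "cell_type": ct,
                f"mean_prop_{site_a}": mean_a,
                f"mean_prop_{site_b}": mean_b,
                "fold_change": fold,
                "p": p_raw,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["depleted"] = (out["fold_change"] >= fold_cutoff) & (out["p"] < alpha)
    with np.errstate(divide="ignore"):
        inv = 1.0 / out["fold_change"]
    out["enriched"] = (inv >= fold_cutoff) & (out["p"] < alpha)
    return out


# ---------------------------------------------------------------------------
# patient report
# ---------------------------------------------------------------------------


@dataclass
class PatientReport:
    """Aggregated per-patient summary; every count traces to a stage table."""

    patient: str
    confirmed_subclone_count: int = 0
    site_unique_subclones: list[str] = field(default_factory=list)
    heterogeneous_snv_fraction_pct: float = float("nan")
    snv_class_counts: dict[str, int] = field(default_factory=dict)
    cna_class_counts: dict[str, int] = field(default_factory=dict)
    significant_links_per_group: dict[str, int] = field(default_factory=dict)
    expanded_clonotypes: int = 0
    hyperexpanded_clonotypes: int = 0
    tcr_assignment_rate: float = float("nan")
    composition_flags: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "PatientReport":
        return cls(**json.loads(text))


def build_patient_report(
    patient: str,
    snv_summary: ccf_mod.HeterogeneitySummary,
    cna_summary: ccf_mod.HeterogeneitySummary,
    composition: pd.DataFrame,
    links_by_group: dict[str, pd.DataFrame],
    clonotypes: pd.DataFrame,
    tme_flags: dict[str, str] | None = None,
) -> PatientReport:
    """Aggregate the per-stage outputs of one patient into a report."""
    confirmed = sorted(composition["subclone"].unique()) if len(composition) else []
    unique_rows = composition[composition["site_unique"]] if len(composition) else composition
    unique_labels = sorted(
        f"{r.subclone}@{r.site}" for r in unique_rows.itertuples()
    ) if len(composition) else []
    exp_counts = clonotypes["expansion"].value_counts() if "expansion" in clonotypes else pd.Series(dtype=int)
    return PatientReport(
        patient=patient,
        confirmed_subclone_count=len(confirmed),
        site_unique_subclones=unique_labels,
        heterogeneous_snv_fraction_pct=round(snv_summary.heterogeneous_pct, 4)
        if snv_summary.retained
        else float("nan"),
        snv_class_counts=dict(snv_summary.counts),
        cna_class_counts=dict(cna_summary.counts),
        significant_links_per_group={g: int(len(t)) for g, t in links_by_group.items()},
        expanded_clonotypes=int(exp_counts.get("expanded", 0)),
        hyperexpanded_clonotypes=int(exp_counts.get("hyperexpanded", 0)),
        tcr_assignment_rate=round(float(clonotypes.attrs.get("assignment_rate", float("nan"))), 6),
        composition_flags=tme_flags or {},
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def default_pipeline_config(seed: int = 7) -> dict:
    """Default study conditions for the synthetic cohort run."""
    return {
        "seed": seed,
        "n_patients": 6,
        "sites": ["RBM", "FL"],
        "n_subclones": 3,
        "n_site_unique_patients": 2,
        "purity_range": [0.5, 0.9],
        "depth": 85.0,
        "n_truncal_snvs": 60,
        "n_snvs_per_subclone": 30,
        "n_cells_rna": 300,
        "n_cells_atac": 300,
        "n_ref_cells": 120,
        "include_atac": True,
        "dosage_gain": 1.5,
        "dosage_loss": 0.5,
        "genome": {"n_chroms": 22, "genes_per_mb": 5.0},
        "tcr": {"n_cells_per_site": 800, "n_clonotypes": 300, "single_chain_fraction": 0.15},
        "coaccess": {
            "n_cells": 400,
            "n_peaks": 30,
            "window": 250000,
            "n_shuffles": 50,
            "min_pct": 0.05,
        },
        "tme": {
            "n_cells_per_site": 500,
            "cell_types": {
                "RBM": {
                    "monocyte_macrophage": 0.20,
                    "CD8_T": 0.20,
                    "CD4_T": 0.20,
                    "NK": 0.10,
                    "B": 0.15,
                    "DC": 0.05,
                    "erythroid": 0.10,
                },
                "FL": {
                    "monocyte_macrophage": 0.07,
                    "CD8_T": 0.24,
                    "CD4_T": 0.23,
                    "NK": 0.11,
                    "B": 0.17,
                    "DC": 0.06,
                    "erythroid": 0.12,
                },
            },
        },
    }


def _validate_config(cfg: dict) -> None:
    problems = []
    if cfg.get("n_patients", 0) < 1:
        problems.append("n_patients: must be >= 1")
    lo, hi = cfg.get("purity_range", [0, 0])
    if not (0 < lo <= hi <= 1):
        problems.append("purity_range: need 0 < low <= high <= 1")
    if cfg.get("n_subclones", 0) < 1:
        problems.append("n_subclones: must be >= 1")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))


def _clonotype_freqs(n_clonotypes: int, site: str) -> np.ndarray:
    """Fixed repertoire conditions: one hyperexpanded, a few expanded clones,
    a uniform tail; one expanded clone shifted 3-fold between sites."""
    freqs = np.full(n_clonotypes, np.nan)
    head = {0: 0.06, 1: 0.02, 2: 0.015, 3: 0.012}
    if site == "FL":
        head[1] = 0.06  # 3-fold spatial shift of clone 1
    for i, f in head.items():
        freqs[i] = f
    tail = 1.0 - sum(head.values())
    freqs[len(head):] = tail / (n_clonotypes - len(head))
    return freqs


def run_patient(patient: str, cfg: dict, seed: int, site_unique: bool) -> dict:
    """Run every analysis stage for one synthetic patient; returns stage outputs."""
    rng = np.random.default_rng(seed)
    sites = tuple(cfg["sites"])
    lo, hi = cfg["purity_range"]
    purity = {s: float(np.round(rng.uniform(lo, hi), 3)) for s in sites}
    genome = default_genome(seed=seed, **{
        k: v for k, v in cfg.get("genome", {}).items()
        if k in ("n_chroms", "genes_per_mb", "max_length", "min_length")
    })
    n_sub = cfg["n_subclones"]
    flags = [False] * n_sub
    if site_unique and n_sub > 1:
        flags[-1] = True
    tree = syn_mod.simulate_clone_tree(
        n_sub,
        n_sites=len(sites),
        site_unique=flags,
        seed=seed,
        sites=sites,
        genome=genome,
        n_truncal_snvs=cfg["n_truncal_snvs"],
        n_snvs_per_subclone=cfg["n_snvs_per_subclone"],
    )
    tcr_cfg = cfg["tcr"]
    n_ct = tcr_cfg["n_clonotypes"]
    config = syn_mod.SimulationConfig(
        seed=seed,
        sites=sites,
        purity=purity,
        depth=cfg["depth"],
        genome=genome,
        n_cells_rna=cfg["n_cells_rna"],
        n_cells_atac=cfg["n_cells_atac"],
        n_ref_cells=cfg["n_ref_cells"],
        dosage_gain=cfg["dosage_gain"],
        dosage_loss=cfg["dosage_loss"],
        single_chain_fraction=tcr_cfg["single_chain_fraction"],
        clonotype_freqs={s: _clonotype_freqs(n_ct, s) for s in sites},
        cell_type_proportions=cfg["tme"]["cell_types"],
    )

    # --- bulk CCF + heterogeneity -----------------------------------------
    site_a, site_b = sites[0], sites[1]
    var_a, seg_a = syn_mod.simulate_bulk_reads(tree, config, site_a)
    var_b, seg_b = syn_mod.simulate_bulk_reads(tree, config, site_b)
    variants = var_a.merge(
        var_b[["variant_id", f"ALT_READS_{site_b}", f"TOTAL_READS_{site_b}", f"TRUE_CCF_{site_b}"]],
        on="variant_id",
    )
    snv_classes = ccf_mod.classify_variant_table(variants, purity, site_a=site_a, site_b=site_b)
    cna_classes = ccf_mod.classify_segment_tables(
        seg_a[seg_a["OWNER"] != 0], seg_b[seg_b["OWNER"] != 0], site_a=site_a, site_b=site_b
    )
    snv_summary = ccf_mod.summarize_heterogeneity(snv_classes)
    cna_summary = ccf_mod.summarize_heterogeneity(cna_classes)

    # --- single-cell subclones --------------------------------------------
    regions = [
        sub_mod.SubclonalRegion(
            ev.event_id, ev.chrom, ev.start, ev.end, ev.direction,
            seg_ccf={s: tree.event_ccf(ev.event_id, s) for s in sites},
        )
        for ev in tree.subclonal_cnas()
    ]
    region_ids = [r.event_id for r in regions]
    candidates = [
        sub_mod.SubcloneGenotype(f"sub{sc.subclone_id}", tree.genotype(sc.subclone_id, region_ids))
        for sc in tree.subclones
    ]
    rna_parts, atac_parts = [], []
    for s in sites:
        rna_parts.append(syn_mod.simulate_sc_counts(tree, config, s, "rna"))
        if cfg["include_atac"]:
            atac_parts.append(syn_mod.simulate_sc_counts(tree, config, s, "atac"))
    import anndata as ad

    rna = ad.concat(rna_parts, index_unique=None)
    rna.var = rna_parts[0].var
    rna = sub_mod.qc_filter_cells(rna, "rna")
    rna_signal = sub_mod.region_signal_rna(rna, regions)
    tumor_mask = ~rna.obs["is_reference"].to_numpy()
    rna_asgn = sub_mod.cluster_subclones(rna_signal[tumor_mask], regions, candidates)

    atac_asgn = None
    if cfg["include_atac"]:
        atac = ad.concat(atac_parts, index_unique=None)
        atac.var = atac_parts[0].var
        atac = sub_mod.qc_filter_cells(atac, "atac")
        frags = syn_mod.fragments_from_counts(atac)
        ref_cells = set(atac.obs_names[atac.obs["is_reference"]])
        atac_signal = sub_mod.region_signal_atac(
            frags, regions, genome.chrom_lengths, ref_cells
        )
        atac_signal = atac_signal.loc[atac.obs_names]
        a_tumor = ~atac.obs["is_reference"].to_numpy()
        atac_asgn = sub_mod.cluster_subclones(
            atac_signal[a_tumor], regions, candidates, tau=sub_mod.GENOTYPE_TAU_Z
        )

    sub_mod.confirm_subclones(rna_asgn, atac_asgn, regions)
    composition = sub_mod.site_composition(
        rna_asgn, rna.obs["site"], confirmed_only=True
    )

    # --- co-accessibility ---------------------------------------------------
    co = cfg["coaccess"]
    n_co_cells = co["n_cells"]
    groups = np.array([site_a] * (n_co_cells // 2) + [site_b] * (n_co_cells - n_co_cells // 2))
    peaks = syn_mod.simulate_peak_matrix(
        n_cells=n_co_cells,
        n_peaks=co["n_peaks"],
        planted_pairs=[(2, 3), (10, 11)],
        group_specific={(10, 11): site_b},
        group_labels=groups,
        seed=seed + 11,
    )
    links_by_group = coaccess_mod.coaccess_by_group(
        peaks,
        window=co["window"],
        n_shuffles=co["n_shuffles"],
        seed=seed + 13,
        min_pct=co["min_pct"],
    )

    # --- TCR ---------------------------------------------------------------
    contigs = pd.concat(
        [syn_mod.simulate_tcr(config, s, tcr_cfg["n_cells_per_site"])[0] for s in sites],
        ignore_index=True,
    )
    clonotypes, cell_map = rep_mod.assign_clonotypes(contigs)
    site_totals = {
        s: int(contigs[contigs["site"] == s]["cell_id"].nunique()) for s in sites
    }
    clonotypes = rep_mod.classify_expansion(clonotypes, site_totals)
    clonotypes = rep_mod.compare_sites(clonotypes, site_totals, site_a=site_a, site_b=site_b)

    # --- TME annotations (cohort test happens across patients) -------------
    annotations = syn_mod.simulate_tme_annotations(
        config, patient, n_cells_per_site=cfg["tme"]["n_cells_per_site"]
    )

    return {
        "patient": patient,
        "purity": purity,
        "tree": tree,
        "variants": variants,
        "snv_classes": snv_classes,
        "cna_classes": cna_classes,
        "snv_summary": snv_summary,
        "cna_summary": cna_summary,
        "rna_assignment": rna_asgn,
        "atac_assignment": atac_asgn,
        "composition": composition,
        "links_by_group": links_by_group,
        "clonotypes": clonotypes,
        "annotations": annotations,
    }


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full synthetic-cohort pipeline and write one report per patient.

    ``config`` is a dict or a path to a JSON file following
    :func:`default_pipeline_config`. Outputs (classification TSVs, clonotype
    TSVs, composition TSV, report JSONs) land in ``out_dir``. Deterministic:
    identical config gives byte-identical reports.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    base = default_pipeline_config(config.get("seed", 7))
    merged = {**base, **config}
    for key in ("tcr", "coaccess", "tme", "genome"):
        if key in config:
            merged[key] = {**base[key], **config[key]}
    cfg = merged
    _validate_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    results = []
    for i in range(cfg["n_patients"]):
        patient = f"P{i + 1:02d}"
        seed = int(cfg["seed"]) * 10_000 + i
        site_unique = i < cfg["n_site_unique_patients"]
        logger.info("running patient %s (seed %d)", patient, seed)
        results.append(run_patient(patient, cfg, seed, site_unique))

    annotations = pd.concat([r["annotations"] for r in results], ignore_index=True)
    if cfg["n_patients"] >= 2:
        tme_table = compare_tme_composition(annotations)
        tme_table.to_csv(out_dir / "tme_composition.tsv", sep="\t", index=False)
        tme_flags = {
            r["cell_type"]: ("depleted" if r["depleted"] else "enriched")
            for _, r in tme_table.iterrows()
            if r["depleted"] or r["enriched"]
        }
    else:
        tme_flags = {}

    for r in results:
        patient = r["patient"]
        r["snv_classes"].to_csv(out_dir / f"{patient}_snv_classes.tsv", sep="\t", index=False)
        r["cna_classes"].to_csv(out_dir / f"{patient}_cna_classes.tsv", sep="\t", index=False)
        r["composition"].to_csv(out_dir / f"{patient}_subclone_composition.tsv", sep="\t", index=False)
        r["clonotypes"].to_csv(out_dir / f"{patient}_clonotypes.tsv", sep="\t", index=False)
        report = build_patient_report(
            patient,
            r["snv_summary"],
            r["cna_summary"],
            r["composition"],
            r["links_by_group"],
            r["clonotypes"],
            tme_flags,
        )
        (out_dir / f"{patient}_report.json").write_text(report.to_json() + "\n")
    logger.info("pipeline complete: %d patients -> %s", len(results), out_dir)
    return out_dir
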