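"""Synthetic paired-site myeloma cohort generator.

Every downstream stage of the pipeline (CCF estimation, single-cell subclone
detection, co-accessibility, TCR repertoire, microenvironment comparison) is
exercised on data produced here, with full ground truth retained: the clonal
tree with per-site subclone prevalences, each SNV's owner subclone and
multiplicity, each CNA event's carriers, per-cell subclone labels, clonotype
frequencies and cell-type proportions.

The bulk read model inverts the cancer-clonal-fraction equation: an SNV with
multiplicity m on a locus of total copy number n_locus, carried by a fraction
CCF of tumor cells in a sample of purity p, has expected variant allele
fraction

    VAF = m * CCF * p / (p * n_locus + 2 * (1 - p))

Alt reads are drawn binomially at that VAF (plus a symmetric substitution
error) with total depth Poisson around the configured mean coverage (85x by
default, matching typical tumor WGS depth).

SNVs are placed only on copy-number backgrounds that are clonal in every
tumor cell (diploid or truncal CNA), so n_locus is a sample-wide quantity and
the closed-form VAF above is exact. Subclonal CNA events are kept SNV-free;
they drive the single-cell dosage signal and the paired-site CNA classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .genome import GenomeModel, default_genome

__all__ = [
    "CnaEvent",
    "Snv",
    "Subclone",
    "CloneTree",
    "SimulationConfig",
    "simulate_clone_tree",
    "simulate_bulk_reads",
    "simulate_sc_counts",
    "fragments_from_counts",
    "simulate_tcr",
    "simulate_peak_matrix",
    "simulate_tme_annotations",
    "clonotype_table",
    "true_snv_classes",
    "add_artifact_subclone",
]

SITES = ("RBM", "FL")


@dataclass(frozen=True)
class CnaEvent:
    """A copy-number event: delta is the copy change relative to diploid."""

    event_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    delta: int  # +1 single-copy gain, -1 single-copy loss, etc.
    owner: int  # subclone id

    @property
    def direction(self) -> str:
        return "gain" if self.delta > 0 else "loss"

    @property
    def total_cn(self) -> int:
        return 2 + self.delta


@dataclass(frozen=True)
class Snv:
    snv_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    owner: int
    multiplicity: int


@dataclass
class Subclone:
    subclone_id: int
    parent: int | None  # None only for the root (clonal) population
    snv_ids: list[str] = field(default_factory=list)
    cna_ids: list[str] = field(default_factory=list)


@dataclass
class CloneTree:
    """Clonal tree with per-site subclone prevalences.

    ``prevalence[site][subclone_id]`` is the fraction of tumor cells whose
    most-derived clone is that subclone (clone fractions, disjoint, summing
    to 1 per site). A cell carries the events of its clone and of all its
    ancestors, so the CCF of an event is the summed prevalence of the owner
    and its descendants.
    """

    subclones: list[Subclone]
    prevalence: dict[str, dict[int, float]]
    snvs: dict[str, Snv]
    cnas: dict[str, CnaEvent]

    def __post_init__(self) -> None:
        roots = [s for s in self.subclones if s.parent is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root subclone")
        for site, prev in self.prevalence.items():
            vals = np.array(list(prev.values()), dtype=float)
            if np.any(vals < -1e-12):
                raise ValueError(f"negative prevalence at site {site}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"prevalences at site {site} do not sum to 1")

    @property
    def root(self) -> Subclone:
        return next(s for s in self.subclones if s.parent is None)

    @property
    def sites(self) -> list[str]:
        return list(self.prevalence)

    def children(self, subclone_id: int) -> list[int]:
        return [s.subclone_id for s in self.subclones if s.parent == subclone_id]

    def descendants(self, subclone_id: int) -> set[int]:
        out: set[int] = set()
        stack = [subclone_id]
        while stack:
            node = stack.pop()
            for child in self.children(node):
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    def carriers(self, event_id: str) -> set[int]:
        """Subclones (clone labels) whose cells carry the given event."""
        owner = (
            self.snvs[event_id].owner
            if event_id in self.snvs
            else self.cnas[event_id].owner
        )
        return {owner} | self.descendants(owner)

    def event_ccf(self, event_id: str, site: str) -> float:
        prev = self.prevalence[site]
        return float(sum(prev.get(c, 0.0) for c in self.carriers(event_id)))

    def carried_events(self, subclone_id: int) -> set[str]:
        """All event ids carried by cells of the given clone (own + ancestral)."""
        out: set[str] = set()
        node: int | None = subclone_id
        by_id = {s.subclone_id: s for s in self.subclones}
        while node is not None:
            sub = by_id[node]
            out.update(sub.snv_ids)
            out.update(sub.cna_ids)
            node = sub.parent
        return out

    def subclonal_cnas(self) -> list[CnaEvent]:
        """CNA events owned by non-root subclones (subclonal by construction)."""
        root_id = self.root.subclone_id
        return [c for c in self.cnas.values() if c.owner != root_id]

    def local_cn(self, subclone_id: int, chrom: str, pos: int) -> int:
        """Total copy number at a 0-based position in cells of one clone."""
        carried = self.carried_events(subclone_id)
        cn = 2
        for cna_id in carried:
            if cna_id not in self.cnas:
                continue
            ev = self.cnas[cna_id]
            if ev.chrom == chrom and ev.start <= pos < ev.end:
                cn += ev.delta
        return cn

    def genotype(self, subclone_id: int, event_ids: Sequence[str]) -> tuple[int, ...]:
        carried = self.carried_events(subclone_id)
        return tuple(1 if e in carried else 0 for e in event_ids)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic patient.

    Defaults mirror the paired-site study design: two bone-marrow sites
    (random iliac-crest aspirate RBM and focal lesion FL), ~85x mean tumor
    coverage, purity per site, a 1.5x / 0.5x expression-accessibility dosage
    effect per copy gained/lost, and a sequencing substitution error rate of
    1e-3.
    """

    seed: int = 0
    sites: tuple[str, ...] = SITES
    purity: dict[str, float] = field(default_factory=lambda: {"RBM": 0.7, "FL": 0.7})
    depth: float = 85.0
    genome: GenomeModel | None = None
    n_cells_rna: int = 400
    n_cells_atac: int = 400
    n_ref_cells: int = 150
    dosage_gain: float = 1.5
    dosage_loss: float = 0.5
    error_rate: float = 1e-3
    rna_dispersion: float = 10.0
    rna_base_mean: float = 1.0
    atac_tile_bp: int = 2_000_000
    atac_mean_frags_per_tile: float = 6.0
    qc_fail_fraction: float = 0.05
    clonotype_freqs: dict[str, np.ndarray] | np.ndarray | None = None
    single_chain_fraction: float = 0.15
    cell_type_proportions: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        for site, p in self.purity.items():
            if not (0 < p <= 1):
                raise ValueError(f"purity at {site} must be in (0, 1], got {p}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for frac in (self.error_rate, self.single_chain_fraction, self.qc_fail_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.genome is None:
            self.genome = default_genome(seed=self.seed)

    def site_freqs(self, site: str) -> np.ndarray:
        """Clonotype frequency vector for a site (shared vector if not per-site)."""
        if self.clonotype_freqs is None:
            raise ValueError("clonotype_freqs not configured")
        freqs = self.clonotype_freqs
        if isinstance(freqs, dict):
            freqs = freqs[site]
        freqs = np.asarray(freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("clonotype frequencies must sum to 1 (tolerance 1e-9)")
        return freqs


# ---------------------------------------------------------------------------
# clone tree
# ---------------------------------------------------------------------------


def simulate_clone_tree(
    n_subclones: int,
    n_sites: int = 2,
    site_unique: Sequence[bool] | None = None,
    seed: int = 0,
    *,
    sites: Sequence[str] | None = None,
    genome: GenomeModel | None = None,
    n_truncal_snvs: int = 60,
    n_snvs_per_subclone: int = 30,
    n_truncal_cnas: int = 2,
    cna_size: int = 40_000_000,
    min_prevalence: float = 0.1,
    topology: str = "random",
) -> CloneTree:
    """Sample a random clonal tree with events placed on the genome.

    The root subclone owns all truncal SNVs and truncal CNA backgrounds; each
    non-root subclone owns a private block of SNVs and one subclonal CNA
    event on a chromosome of its own. Subclones flagged ``site_unique`` get
    prevalence 0 at every site but one (chosen at random).

    ``topology`` is "random" (each subclone attaches to a uniformly chosen
    earlier non-unique subclone) or "star" (every subclone is a direct child
    of the root, i.e. sibling branches).

    Per-site prevalences are Dirichlet-distributed over subclones and sum
    to 1.
    """
    if topology not in ("random", "star"):
        raise ValueError(f"unknown topology {topology!r}")
    if n_subclones < 1:
        raise ValueError("n_subclones must be >= 1")
    if sites is None:
        sites = [SITES[i] if i < len(SITES) else f"site{i}" for i in range(n_sites)]
    sites = list(sites)
    if site_unique is None:
        site_unique = [False] * n_subclones
    if len(site_unique) != n_subclones:
        raise ValueError("site_unique must have one flag per subclone")
    if site_unique[0]:
        raise ValueError("the root (clonal) subclone cannot be site-unique")
    rng = np.random.default_rng(seed)
    genome = genome if genome is not None else default_genome(seed=seed)

    # site-unique subclones stay leaves: a descendant of a unique subclone
    # would carry its mutations at other sites and break uniqueness
    subclones = [Subclone(0, None)]
    for i in range(1, n_subclones):
        if topology == "star":
            parent = 0
        else:
            eligible = [j for j in range(i) if not site_unique[j]]
            parent = int(rng.choice(eligible))
        subclones.append(Subclone(i, parent))

    # chromosomes hosting subclonal CNAs are kept SNV-free (see module docstring)
    chroms = genome.chroms
    n_sub_cnas = n_subclones - 1
    if n_sub_cnas + n_truncal_cnas >= len(chroms):
        raise ValueError("genome too small for the requested number of CNA events")
    cna_chroms = chroms[:n_sub_cnas]
    snv_chroms = chroms[n_sub_cnas:]

    snvs: dict[str, Snv] = {}
    cnas: dict[str, CnaEvent] = {}

    # truncal CNA backgrounds: define non-diploid clonal n_locus for some SNVs
    truncal_bg: list[CnaEvent] = []
    bg_chroms = list(rng.choice(snv_chroms, size=n_truncal_cnas, replace=False))
    for j, chrom in enumerate(bg_chroms):
        length = genome.chrom_lengths[chrom]
        size = min(cna_size, length // 2)
        start = int(rng.integers(0, length - size))
        delta = int(rng.choice([1, -1]))
        ev = CnaEvent(f"cna_truncal_{j}", chrom, start, start + size, delta, owner=0)
        cnas[ev.event_id] = ev
        subclones[0].cna_ids.append(ev.event_id)
        truncal_bg.append(ev)

    # subclonal CNAs: one per non-root subclone, each on its own chromosome
    for i in range(1, n_subclones):
        chrom = cna_chroms[i - 1]
        length = genome.chrom_lengths[chrom]
        size = min(cna_size, length // 2)
        start = int(rng.integers(0, length - size))
        delta = int(rng.choice([1, -1]))
        ev = CnaEvent(f"cna_sub_{i}", chrom, start, start + size, delta, owner=i)
        cnas[ev.event_id] = ev
        subclones[i].cna_ids.append(ev.event_id)

    bases = np.array(list("ACGT"))

    def _place_snvs(owner: int, n: int, prefix: str) -> None:
        for j in range(n):
            chrom = str(rng.choice(snv_chroms))
            pos = int(rng.integers(1, genome.chrom_lengths[chrom]))
            n_locus = 2
            for ev in truncal_bg:
                if ev.chrom == chrom and ev.start <= pos - 1 < ev.end:
                    n_locus = ev.total_cn
            if n_locus == 0:
                n_locus = 1  # cannot place an SNV on a homozygous deletion
            mult = int(rng.integers(1, max(1, n_locus) + 1))
            ref, alt = rng.choice(bases, size=2, replace=False)
            snv = Snv(f"{prefix}_{j}", chrom, pos, str(ref), str(alt), owner, mult)
            snvs[snv.snv_id] = snv
            subclones[owner].snv_ids.append(snv.snv_id)

    _place_snvs(0, n_truncal_snvs, "snv_truncal")
    for i in range(1, n_subclones):
        _place_snvs(i, n_snvs_per_subclone, f"snv_sub{i}")

    # per-site clone fractions; unique subclones zeroed away from their site
    home_site = {}
    for i in range(n_subclones):
        if site_unique[i]:
            home_site[i] = sites[int(rng.integers(0, len(sites)))]
    # a site-unique subclone dominates its home site (the focal-lesion
    # pattern: the FL-dominant subclone is absent or minor in the RBM)
    dominance = {i: float(rng.uniform(0.75, 0.9)) for i in home_site}
    prevalence: dict[str, dict[int, float]] = {}
    for site in sites:
        raw = rng.dirichlet(np.full(n_subclones, 2.0))
        raw = min_prevalence + raw * (1 - n_subclones * min_prevalence)
        home_here = [i for i, home in home_site.items() if home == site]
        for i, home in home_site.items():
            raw[i] = 0.0
        raw = raw / raw.sum()
        total_dom = sum(dominance[i] for i in home_here)
        # several unique subclones at one site share a capped dominant mass
        scale = min(total_dom, 0.88) / total_dom if total_dom else 0.0
        raw = raw * (1.0 - total_dom * scale)
        for i in home_here:
            raw[i] = dominance[i] * scale
        prevalence[site] = {i: float(raw[i]) for i in range(n_subclones)}

    return CloneTree(subclones=subclones, prevalence=prevalence, snvs=snvs, cnas=cnas)


# ---------------------------------------------------------------------------
# bulk WGS reads
# ---------------------------------------------------------------------------


def expected_vaf(m: float, ccf: float, purity: float, n_locus: int) -> float:
    """Expected variant allele fraction under the CCF equation, capped at 1."""
    denom = purity * n_locus + 2.0 * (1.0 - purity)
    if denom <= 0:
        raise ValueError("degenerate denominator: purity and n_locus both ~0")
    return min(1.0, m * ccf * purity / denom)


def simulate_bulk_reads(
    tree: CloneTree, config: SimulationConfig, site: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw bulk WGS read counts for one site.

    Returns ``(variants, segments)``. Variants carry per-site alt/total read
    counts plus truth columns (owner subclone, true multiplicity, true CCF).
    Segments list every CNA event with nonzero carrier fraction at the site,
    with total CN in carrier cells and segment CCF = summed carrier clone
    prevalence.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _site_key(site), 1]))
    purity = config.purity[site]
    err = config.error_rate

    rows = []
    for snv in tree.snvs.values():
        ccf = tree.event_ccf(snv.snv_id, site)
        carrier_cns = {
            tree.local_cn(c, snv.chrom, snv.pos - 1) for c in tree.carriers(snv.snv_id)
        }
        if 0 in carrier_cns:
            raise ValueError(
                f"{snv.snv_id}: locus copy number 0 in a carrier subclone"
            )
        n_locus = tree.local_cn(tree.root.subclone_id, snv.chrom, snv.pos - 1)
        vaf = expected_vaf(snv.multiplicity, ccf, purity, n_locus)
        vaf_obs = vaf * (1 - err) + (1 - vaf) * err
        total = max(1, int(rng.poisson(config.depth)))
        alt = int(rng.binomial(total, vaf_obs))
        rows.append(
            (
                snv.snv_id,
                snv.chrom,
                snv.pos,
                snv.ref,
                snv.alt,
                alt,
                total,
                n_locus,
                snv.multiplicity,
                ccf,
                snv.owner,
            )
        )
    variants = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "CHROM",
            "POS",
            "REF",
            "ALT",
            f"ALT_READS_{site}",
            f"TOTAL_READS_{site}",
            "N_LOCUS",
            "TRUE_M",
            f"TRUE_CCF_{site}",
            "OWNER",
        ],
    )

    seg_rows = []
    for ev in tree.cnas.values():
        seg_ccf = tree.event_ccf(ev.event_id, site)
        if seg_ccf <= 0:
            continue
        seg_rows.append(
            (ev.event_id, ev.chrom, ev.start, ev.end, ev.total_cn, seg_ccf, ev.owner)
        )
    segments = pd.DataFrame(
        seg_rows,
        columns=["event_id", "CHROM", "START", "END", "TOTAL_CN", "SEG_CCF", "OWNER"],
    )
    return variants, segments


def _site_key(site: str) -> int:
    return sum(ord(c) for c in site)


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------


def _dosage_multiplier(delta: int, config: SimulationConfig) -> float:
    if delta >= 0:
        return config.dosage_gain**delta
    return config.dosage_loss ** (-delta)


def simulate_sc_counts(
    tree: CloneTree, config: SimulationConfig, site: str, modality: str
):
    """Simulate a cells-by-features count matrix for one site and modality.

    RNA counts are negative-binomial (gamma-poisson) with per-gene base
    means; ATAC counts are Poisson per fixed genomic tile. In cells carrying
    a CNA event, the mean of every feature inside the event region is scaled
    by the configured dosage effect per copy. A block of neutral normal
    plasma-cell reference cells is appended, plus per-cell QC metadata.

    Returns an :class:`anndata.AnnData` with truth labels in
    ``obs["subclone"]`` (``"normal"`` for reference cells).
    """
    import anndata as ad

    if modality not in ("rna", "atac"):
        raise ValueError(f"unknown modality {modality!r}")
    n_cells = config.n_cells_rna if modality == "rna" else config.n_cells_atac
    if n_cells < 1:
        raise ValueError("at least one cell must be requested")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _site_key(site), 2 if modality == "rna" else 3])
    )
    genome = config.genome
    prev = tree.prevalence[site]
    clone_ids = np.array(sorted(prev))
    probs = np.array([prev[i] for i in clone_ids])
    labels = rng.choice(clone_ids, size=n_cells, p=probs)
    n_ref = config.n_ref_cells
    all_labels = np.concatenate([labels.astype(object), np.array(["normal"] * n_ref, dtype=object)])
    n_total = n_cells + n_ref

    if modality == "rna":
        genes = genome.gene_table()
        n_genes = len(genes)
        base = rng.lognormal(mean=np.log(config.rna_base_mean), sigma=0.6, size=n_genes)
        cell_factor = rng.lognormal(mean=0.0, sigma=0.15, size=n_total)
        mult = np.ones((n_total, n_genes))
        for ev in tree.cnas.values():
            in_region = (
                (genes["chrom"].to_numpy() == ev.chrom)
                & (genes["pos"].to_numpy() >= ev.start)
                & (genes["pos"].to_numpy() < ev.end)
            )
            if not in_region.any():
                continue
            carrier_set = tree.carriers(ev.event_id)
            carrier_cells = np.array(
                [lbl != "normal" and lbl in carrier_set for lbl in all_labels]
            )
            mult[np.ix_(carrier_cells, in_region)] *= _dosage_multiplier(ev.delta, config)
        mean = base[None, :] * mult * cell_factor[:, None]
        theta = config.rna_dispersion
        lam = rng.gamma(shape=theta, scale=mean / theta)
        counts = rng.poisson(lam).astype(np.int32)
        var = pd.DataFrame(
            {
                "chrom": genes["chrom"].to_numpy(),
                "start": genes["pos"].to_numpy(),
                "end": genes["pos"].to_numpy() + 1,
            },
            index=genes["gene_id"],
        )
    else:
        tiles = []
        tile_bp = config.atac_tile_bp
        for chrom, length in genome.chrom_lengths.items():
            for start in range(0, length, tile_bp):
                tiles.append((chrom, start, min(start + tile_bp, length)))
        tile_df = pd.DataFrame(tiles, columns=["chrom", "start", "end"])
        n_tiles = len(tile_df)
        base = np.full(n_tiles, config.atac_mean_frags_per_tile) * (
            (tile_df["end"] - tile_df["start"]).to_numpy() / tile_bp
        )
        cell_factor = rng.lognormal(mean=0.0, sigma=0.15, size=n_total)
        mult = np.ones((n_total, n_tiles))
        mids = ((tile_df["start"] + tile_df["end"]) // 2).to_numpy()
        for ev in tree.cnas.values():
            in_region = (
                (tile_df["chrom"].to_numpy() == ev.chrom)
                & (mids >= ev.start)
                & (mids < ev.end)
            )
            if not in_region.any():
                continue
            carrier_set = tree.carriers(ev.event_id)
            carrier_cells = np.array(
                [lbl != "normal" and lbl in carrier_set for lbl in all_labels]
            )
            mult[np.ix_(carrier_cells, in_region)] *= _dosage_multiplier(ev.delta, config)
        mean = base[None, :] * mult * cell_factor[:, None]
        counts = rng.poisson(mean).astype(np.int32)
        var = tile_df.copy()
        var.index = pd.Index(
            [f"tile_{c}_{s}" for c, s in zip(tile_df["chrom"], tile_df["start"])]
        )

    barcodes = [f"{site}_{modality}_cell{i}" for i in range(n_total)]
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    obs["site"] = site
    obs["modality"] = modality
    obs["subclone"] = all_labels
    obs["is_reference"] = obs["subclone"] == "normal"

    n_fail = int(round(config.qc_fail_fraction * n_total))
    fail_idx = rng.choice(n_total, size=n_fail, replace=False) if n_fail else np.array([], int)
    fail_mask = np.zeros(n_total, dtype=bool)
    fail_mask[fail_idx] = True
    if modality == "rna":
        mito = np.clip(rng.normal(0.02, 0.008, n_total), 0.0, 0.05)
        mito[fail_mask] = rng.uniform(0.06, 0.15, fail_mask.sum())
        doublet = np.clip(rng.normal(0.1, 0.05, n_total), 0.0, 0.3)
        obs["mito_fraction"] = mito
        obs["n_detected_features"] = (counts > 0).sum(axis=1)
        obs["doublet_score"] = doublet
    else:
        tss = np.clip(rng.normal(13.0, 2.0, n_total), 8.5, None)
        tss[fail_mask] = rng.uniform(4.0, 7.5, fail_mask.sum())
        obs["tss_score"] = tss
        obs["fragment_count"] = counts.sum(axis=1)
        obs["doublet_enrichment"] = np.clip(rng.normal(1.5, 1.0, n_total), 0.0, 6.0)
        obs["predicted_doublet_score"] = np.clip(rng.normal(50, 30, n_total), 0.0, 200.0)

    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
    return adata


def fragments_from_counts(adata) -> pd.DataFrame:
    """Expand a cells-by-tiles ATAC count matrix into a BED-like fragment table.

    One row per (cell, tile) with the drawn fragment count; fragments span
    the tile interval (chrom, start, end, barcode, count).
    """
    X = sparse.coo_matrix(adata.X)
    var = adata.var
    return pd.DataFrame(
        {
            "chrom": var["chrom"].to_numpy()[X.col],
            "start": var["start"].to_numpy()[X.col],
            "end": var["end"].to_numpy()[X.col],
            "barcode": adata.obs_names.to_numpy()[X.row],
            "count": X.data.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# TCR repertoire
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def clonotype_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic clonotype catalogue (id, TRA CDR3, TRB CDR3).

    Seeded from the config seed alone so the same clonotype keeps the same
    CDR3 pair at every site.
    """
    freqs = config.clonotype_freqs
    if freqs is None:
        raise ValueError("clonotype_freqs not configured")
    n = len(next(iter(freqs.values()))) if isinstance(freqs, dict) else len(freqs)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    seen: set[tuple[str, str]] = set()
    rows = []
    for i in range(n):
        while True:
            tra = "CA" + "".join(rng.choice(_AA, size=9)) + "F"
            trb = "CASS" + "".join(rng.choice(_AA, size=8)) + "F"
            if (tra, trb) not in seen:
                seen.add((tra, trb))
                break
        rows.append((f"ct{i}", tra, trb))
    return pd.DataFrame(rows, columns=["clonotype_id", "tra_cdr3", "trb_cdr3"])


def simulate_tcr(
    config: SimulationConfig, site: str, n_cells: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate AIRR-style contig records for the T cells of one site.

    Cells are assigned clonotypes multinomially from the configured frequency
    vector; a configurable fraction of cells emit only one chain. Returns
    ``(contigs, truth)`` where truth lists per-clonotype sampled cell counts.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    freqs = config.site_freqs(site)
    catalogue = clonotype_table(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _site_key(site), 4]))
    assignments = rng.choice(len(freqs), size=n_cells, p=freqs)
    single_chain = rng.random(n_cells) < config.single_chain_fraction
    which_chain = rng.choice(["TRA", "TRB"], size=n_cells)

    rows = []
    for i in range(n_cells):
        ct = catalogue.iloc[assignments[i]]
        cell = f"{site}_t{i}"
        chains = [which_chain[i]] if single_chain[i] else ["TRA", "TRB"]
        for chain in chains:
            cdr3 = ct["tra_cdr3"] if chain == "TRA" else ct["trb_cdr3"]
            rows.append((cell, chain, cdr3, True, site))
    contigs = pd.DataFrame(
        rows, columns=["cell_id", "locus", "junction_aa", "productive", "site"]
    )
    counts = pd.Series(assignments).value_counts().reindex(range(len(freqs)), fill_value=0)
    truth = catalogue.copy()
    truth["true_freq"] = freqs
    truth["n_cells"] = counts.to_numpy()
    truth["site"] = site
    return contigs, truth


# ---------------------------------------------------------------------------
# peak matrix with planted co-accessible pairs
# ---------------------------------------------------------------------------


def simulate_peak_matrix(
    n_cells: int = 500,
    n_peaks: int = 50,
    peak_spacing: int = 20_000,
    mean_count: float = 0.5,
    planted_pairs: Sequence[tuple[int, int]] = (),
    latent_on_fraction: float = 0.5,
    group_labels: Sequence[str] | None = None,
    group_specific: dict[tuple[int, int], str] | None = None,
    seed: int = 0,
):
    """Independent Poisson peak-by-cell matrix with optional planted links.

    Peaks sit on one chromosome at fixed spacing. For each planted pair a
    shared latent on/off state across cells drives both peaks (on: Poisson
    at 4x the base mean; off: zero), producing genuine co-accessibility;
    ``group_specific`` restricts a pair's latent coupling to the cells of one
    group, with independent signal elsewhere.

    Returns an AnnData (cells x peaks) with peak coordinates in ``var`` and
    group labels in ``obs["group"]``.
    """
    import anndata as ad

    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean_count, size=(n_cells, n_peaks)).astype(np.int32)
    groups = (
        np.asarray(group_labels, dtype=object)
        if group_labels is not None
        else np.array(["all"] * n_cells, dtype=object)
    )
    group_specific = group_specific or {}
    truth = []
    for (i, j) in planted_pairs:
        target_group = group_specific.get((i, j))
        in_scope = np.ones(n_cells, bool) if target_group is None else groups == target_group
        latent = rng.random(n_cells) < latent_on_fraction
        for p in (i, j):
            on = in_scope & latent
            counts[on, p] = rng.poisson(4.0 * mean_count + 2.0, size=int(on.sum()))
            counts[in_scope & ~latent, p] = 0
            # outside the target group the two peaks stay independent
            if target_group is not None:
                out = ~in_scope
                counts[out, p] = rng.poisson(mean_count, size=int(out.sum()))
        truth.append({"peak_i": min(i, j), "peak_j": max(i, j), "group": target_group})

    var = pd.DataFrame(
        {
            "chrom": ["1"] * n_peaks,
            "start": np.arange(n_peaks) * peak_spacing,
            "end": np.arange(n_peaks) * peak_spacing + 500,
        },
        index=[f"peak{k}" for k in range(n_peaks)],
    )
    obs = pd.DataFrame(
        {"group": groups}, index=[f"cell{k}" for k in range(n_cells)]
    )
    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
    adata.uns["planted_links"] = truth
    return adata


# ---------------------------------------------------------------------------
# ground truth helpers
# ---------------------------------------------------------------------------


def true_snv_classes(
    tree: CloneTree, config: SimulationConfig, site_a: str, site_b: str
) -> pd.DataFrame:
    """Noise-free reference classification of every SNV.

    Applies the paired-site decision rule to the *expected* read counts
    (expected VAF times mean depth, rounded) instead of sampled ones, so the
    reference class is exactly what the rule yields on noiseless data;
    divergences under sampled reads measure read-noise flips only.
    """
    from .ccf import classify_snv_pair, estimate_ccf

    depth = int(round(config.depth))
    rows = []
    for snv in tree.snvs.values():
        n_locus = tree.local_cn(tree.root.subclone_id, snv.chrom, snv.pos - 1)
        ests = {}
        for site in (site_a, site_b):
            ccf = tree.event_ccf(snv.snv_id, site)
            vaf = expected_vaf(snv.multiplicity, ccf, config.purity[site], n_locus)
            vaf_obs = vaf * (1 - config.error_rate) + (1 - vaf) * config.error_rate
            alt = int(round(vaf_obs * depth))
            ests[site] = estimate_ccf(
                alt, depth, config.purity[site], n_locus, error_rate=config.error_rate
            )
        cl = classify_snv_pair(
            ests[site_a], ests[site_b], event_id=snv.snv_id, site_a=site_a, site_b=site_b
        )
        rows.append(
            {
                "variant_id": snv.snv_id,
                "true_class": cl.cls,
                "true_coarse": cl.cls.split("_")[0],
                "owner": snv.owner,
            }
        )
    return pd.DataFrame(rows)


def add_artifact_subclone(
    tree: CloneTree,
    carry_event_ids: Sequence[str],
    fraction: float,
    site: str,
) -> CloneTree:
    """Graft a leaf subclone carrying copies of the given CNA regions.

    The new leaf takes ``fraction`` of the site's tumor cells (other clones
    rescaled). Its events duplicate the coordinates of existing subclonal
    CNAs under new ids, so its dosage signal reproduces a carrier pattern
    over those regions that no genuine clone has — an artifact genotype to
    exercise the cross-modality confirmation rule.
    """
    import copy

    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    new = copy.deepcopy(tree)
    new_id = max(s.subclone_id for s in new.subclones) + 1
    leaf = Subclone(new_id, parent=new.root.subclone_id)
    for k, eid in enumerate(carry_event_ids):
        src = new.cnas[eid]
        art = CnaEvent(
            f"cna_artifact_{k}", src.chrom, src.start, src.end, src.delta, owner=new_id
        )
        new.cnas[art.event_id] = art
        leaf.cna_ids.append(art.event_id)
    new.subclones.append(leaf)
    for s, prev in new.prevalence.items():
        if s == site:
            scaled = {i: v * (1 - fraction) for i, v in prev.items()}
            scaled[new_id] = fraction
        else:
            scaled = dict(prev)
            scaled[new_id] = 0.0
        new.prevalence[s] = scaled
    return new


# ---------------------------------------------------------------------------
# microenvironment annotations
# ---------------------------------------------------------------------------


def simulate_tme_annotations(
    config: SimulationConfig, patient: str, n_cells_per_site: int = 500
) -> pd.DataFrame:
    """Sample per-cell TME cell-type annotations for both sites of a patient."""
    props = config.cell_type_proportions
    if props is None:
        raise ValueError("cell_type_proportions not configured")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    rows = []
    for site in config.sites:
        site_props = props[site]
        types = list(site_props)
        p = np.array([site_props[t] for t in types], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"cell-type proportions at {site} must sum to 1")
        draws = rng.choice(types, size=n_cells_per_site, p=p)
        for i, t in enumerate(draws):
            rows.append((patient, site, f"{patient}_{site}_tme{i}", t))
    return pd.DataFrame(rows, columns=["patient", "site", "cell_id", "cell_type"])
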