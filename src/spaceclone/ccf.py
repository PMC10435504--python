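"""Cancer-clonal-fraction estimation and paired-site heterogeneity classes.

For one SNV in one bulk sample with variant allele fraction f_s, tumor
purity p and locus total copy number n_locus, the mutation copy number is

    n_mut = f_s * (1/p) * [p * n_locus + 2 * (1 - p)]

The multiplicity n_chr (how many chromosome copies carry the mutation) is
chosen by maximum binomial likelihood over candidates C in {1..n_locus},
comparing the observed alt/total counts against the expected VAF
C*p / (p*n_locus + 2(1-p)) (capped at 1). CCF = n_mut / n_chr.

Paired-site SNVs are then classified: *filtered* when neither site reaches
CCF > 0.15; *major* when the 95% CI upper bound on CCF reaches 1 at the
dominant site, *minor* otherwise; *unshared* when the mutation is
undetectable at the partner site; *enriched* when detected at both sites,
major at the dominant one, with a >= 3-fold CCF ratio; *shared* otherwise.
CNA events use segment CCF with a 0.6 major cut-off and a > 200 kb length
filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CcfEstimate",
    "PairClassification",
    "estimate_ccf",
    "classify_snv_pair",
    "classify_cna_pair",
    "match_cna_segments",
    "classify_variant_table",
    "classify_segment_tables",
    "summarize_heterogeneity",
    "HeterogeneitySummary",
]

CCF_FILTER = 0.15  # SNVs retained only when CCF > 0.15 at >= 1 site
CNA_MAJOR_CCF = 0.6  # segment CCF cut-off separating major from minor CNAs
CNA_MIN_LENGTH = 200_000  # CNAs must exceed 200 kb
ENRICHMENT_FOLD = 3.0
DETECTION_CCF = 0.05


@dataclass(frozen=True)
class CcfEstimate:
    """CCF of one variant in one sample, with its 95% CI.

    ``n_mut`` is the mutation copy number, ``n_chr`` the maximum-likelihood
    multiplicity, ``ccf = n_mut / n_chr`` (reported uncapped). The CI is a
    Wilson score interval on the VAF mapped through the CCF equation with
    ``n_chr`` held fixed. ``detected`` is False only when the CCF is below
    the detection floor and the alt reads are compatible with sequencing
    error alone.
    """

    f_s: float
    p: float
    n_locus: int
    n_mut: float
    n_chr: int
    ccf: float
    ci_low: float
    ci_high: float
    detected: bool
    alt: int
    total: int
    homdel_conflict: bool = False


def _candidate_vafs(purity: float, n_locus: int) -> np.ndarray:
    denom = purity * n_locus + 2.0 * (1.0 - purity)
    cands = np.arange(1, max(1, n_locus) + 1)
    return np.minimum(1.0, cands * purity / denom)


def estimate_ccf(
    alt: int,
    total: int,
    purity: float,
    n_locus: int,
    *,
    error_rate: float = 1e-3,
    detection_ccf: float = DETECTION_CCF,
) -> CcfEstimate:
    """Estimate the cancer clonal fraction of one variant in one sample.

    Parameters
    ----------
    alt, total
        Variant-supporting and total read counts at the locus.
    purity
        Tumor cell fraction of the bulk sample, in (0, 1].
    n_locus
        Tumor total copy number at the locus (0 flags a homozygous-deletion
        conflict when alt reads are present).
    error_rate
        Per-base substitution error used by the detection floor.
    detection_ccf
        CCF below which a variant with error-compatible alt reads counts as
        undetected.
    """
    if total <= 0:
        raise ValueError("total read count must be positive")
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if alt < 0 or alt > total:
        raise ValueError("alt reads must satisfy 0 <= alt <= total")
    if n_locus < 0:
        raise ValueError("n_locus must be >= 0")

    f_s = alt / total
    denom = purity * n_locus + 2.0 * (1.0 - purity)
    n_mut = f_s * denom / purity
    homdel = n_locus == 0 and alt > 0

    vafs = _candidate_vafs(purity, n_locus)
    loglik = stats.binom.logpmf(alt, total, vafs)
    n_chr = int(np.argmax(loglik)) + 1  # ties resolve to the smallest C
    ccf = n_mut / n_chr

    lo, hi = proportion_confint(alt, total, alpha=0.05, method="wilson")
    scale = denom / (purity * n_chr)  # monotone map f_s -> ccf at fixed n_chr
    ci_low, ci_high = float(lo) * scale, float(hi) * scale

    err_reads = total * error_rate
    detected = not (ccf < detection_ccf and alt <= 1 + err_reads)
    return CcfEstimate(
        f_s=f_s,
        p=purity,
        n_locus=n_locus,
        n_mut=n_mut,
        n_chr=n_chr,
        ccf=ccf,
        ci_low=ci_low,
        ci_high=ci_high,
        detected=detected,
        alt=alt,
        total=total,
        homdel_conflict=homdel,
    )


# ---------------------------------------------------------------------------
# paired-site classification
# ---------------------------------------------------------------------------

SNV_CLASSES = (
    "shared_major",
    "shared_minor",
    "unshared_major",
    "unshared_minor",
    "enriched",
    "filtered",
)


@dataclass(frozen=True)
class PairClassification:
    event_id: str
    cls: str
    direction: str | None  # site label that dominates, None for filtered/tied

    def __post_init__(self) -> None:
        if self.cls not in SNV_CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")


def classify_snv_pair(
    est_a: CcfEstimate,
    est_b: CcfEstimate,
    *,
    event_id: str = "",
    site_a: str = "RBM",
    site_b: str = "FL",
) -> PairClassification:
    """Classify one SNV across the two paired sites."""
    if max(est_a.ccf, est_b.ccf) <= CCF_FILTER:
        return PairClassification(event_id, "filtered", None)
    if est_a.ccf >= est_b.ccf:
        dom, minor, dom_site = est_a, est_b, site_a
    else:
        dom, minor, dom_site = est_b, est_a, site_b
    major = dom.ci_high >= 1.0
    if not minor.detected:
        cls = "unshared_major" if major else "unshared_minor"
        return PairClassification(event_id, cls, dom_site)
    if major and minor.ccf > 0 and dom.ccf / minor.ccf >= ENRICHMENT_FOLD:
        return PairClassification(event_id, "enriched", dom_site)
    return PairClassification(
        event_id, "shared_major" if major else "shared_minor", dom_site
    )


def classify_cna_pair(
    seg_a: pd.Series | None,
    seg_b: pd.Series | None,
    *,
    event_id: str = "",
    site_a: str = "RBM",
    site_b: str = "FL",
) -> PairClassification:
    """Classify one CNA event across paired sites.

    Each side is a segment row with START/END/SEG_CCF, or None when the event
    is absent at that site. Events of <= 200 kb are filtered.
    """
    if seg_a is None and seg_b is None:
        raise ValueError("CNA event absent from both sites")
    present = seg_a if seg_a is not None else seg_b
    length = int(present["END"]) - int(present["START"])
    if length <= CNA_MIN_LENGTH:
        return PairClassification(event_id, "filtered", None)
    ccf_a = float(seg_a["SEG_CCF"]) if seg_a is not None else 0.0
    ccf_b = float(seg_b["SEG_CCF"]) if seg_b is not None else 0.0
    dom_site = site_a if ccf_a >= ccf_b else site_b
    dom, minor = max(ccf_a, ccf_b), min(ccf_a, ccf_b)
    if minor == 0.0:
        cls = "unshared_major" if dom > CNA_MAJOR_CCF else "unshared_minor"
        return PairClassification(event_id, cls, dom_site)
    if dom > CNA_MAJOR_CCF and minor <= CNA_MAJOR_CCF:
        return PairClassification(event_id, "enriched", dom_site)
    cls = "shared_major" if dom > CNA_MAJOR_CCF else "shared_minor"
    return PairClassification(event_id, cls, dom_site)


def match_cna_segments(
    segs_a: pd.DataFrame, segs_b: pd.DataFrame, min_reciprocal_overlap: float = 0.5
) -> list[tuple[pd.Series | None, pd.Series | None]]:
    """Match CNA segments across samples by reciprocal overlap.

    Two segments match when they sit on the same chromosome, change copy
    number in the same direction, and each covers at least
    ``min_reciprocal_overlap`` of the other. Unmatched segments pair with
    None.
    """
    used_b: set[int] = set()
    pairs: list[tuple[pd.Series | None, pd.Series | None]] = []
    for _, a in segs_a.iterrows():
        best, best_ov = None, 0.0
        for jb, b in segs_b.iterrows():
            if jb in used_b or a["CHROM"] != b["CHROM"]:
                continue
            if ("TOTAL_CN" in a) and ("TOTAL_CN" in b):
                if (a["TOTAL_CN"] - 2) * (b["TOTAL_CN"] - 2) <= 0:
                    continue
            ov = min(a["END"], b["END"]) - max(a["START"], b["START"])
            if ov <= 0:
                continue
            rec = min(ov / (a["END"] - a["START"]), ov / (b["END"] - b["START"]))
            if rec >= min_reciprocal_overlap and rec > best_ov:
                best, best_ov = jb, rec
        if best is not None:
            used_b.add(best)
            pairs.append((a, segs_b.loc[best]))
        else:
            pairs.append((a, None))
    for jb, b in segs_b.iterrows():
        if jb not in used_b:
            pairs.append((None, b))
    return pairs


def classify_variant_table(
    variants: pd.DataFrame,
    purity: dict[str, float],
    *,
    site_a: str = "RBM",
    site_b: str = "FL",
    n_locus_col: str = "N_LOCUS",
    error_rate: float = 1e-3,
) -> pd.DataFrame:
    """Estimate per-site CCFs and classify every SNV of a paired patient.

    ``variants`` needs ALT_READS_<site>/TOTAL_READS_<site> columns for both
    sites plus a locus copy-number column (default ``N_LOCUS``; absent values
    fall back to diploid).
    """
    rows = []
    for _, v in variants.iterrows():
        n_locus = int(v[n_locus_col]) if n_locus_col in v and pd.notna(v[n_locus_col]) else 2
        ests = {}
        for site in (site_a, site_b):
            ests[site] = estimate_ccf(
                int(v[f"ALT_READS_{site}"]),
                int(v[f"TOTAL_READS_{site}"]),
                purity[site],
                n_locus,
                error_rate=error_rate,
            )
        cl = classify_snv_pair(
            ests[site_a],
            ests[site_b],
            event_id=str(v.get("variant_id", f"{v['CHROM']}:{v['POS']}")),
            site_a=site_a,
            site_b=site_b,
        )
        rows.append(
            {
                "variant_id": cl.event_id,
                "CHROM": v["CHROM"],
                "POS": v["POS"],
                f"ccf_{site_a}": ests[site_a].ccf,
                f"ccf_{site_b}": ests[site_b].ccf,
                f"ci_high_{site_a}": ests[site_a].ci_high,
                f"ci_high_{site_b}": ests[site_b].ci_high,
                f"n_chr_{site_a}": ests[site_a].n_chr,
                f"n_chr_{site_b}": ests[site_b].n_chr,
                "class": cl.cls,
                "direction": cl.direction,
            }
        )
    return pd.DataFrame(rows)


def classify_segment_tables(
    segs_a: pd.DataFrame,
    segs_b: pd.DataFrame,
    *,
    site_a: str = "RBM",
    site_b: str = "FL",
) -> pd.DataFrame:
    """Match and classify the CNA segments of a paired patient."""
    rows = []
    for k, (a, b) in enumerate(match_cna_segments(segs_a, segs_b)):
        present = a if a is not None else b
        event_id = str(present.get("event_id", f"cna_{k}"))
        cl = classify_cna_pair(a, b, event_id=event_id, site_a=site_a, site_b=site_b)
        rows.append(
            {
                "event_id": event_id,
                "CHROM": present["CHROM"],
                "START": present["START"],
                "END": present["END"],
                f"seg_ccf_{site_a}": float(a["SEG_CCF"]) if a is not None else 0.0,
                f"seg_ccf_{site_b}": float(b["SEG_CCF"]) if b is not None else 0.0,
                "class": cl.cls,
                "direction": cl.direction,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HeterogeneitySummary:
    counts: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    heterogeneous: int = 0
    heterogeneous_fraction: float = float("nan")

    @property
    def heterogeneous_pct(self) -> float:
        return 100.0 * self.heterogeneous_fraction


def summarize_heterogeneity(classes: pd.DataFrame) -> HeterogeneitySummary:
    """Count paired-site classes and the heterogeneous (unshared + enriched) share.

    The denominator is the number of retained (non-filtered) events; an
    empty or fully-filtered input yields an NaN fraction with zero
    denominators flagged by ``retained == 0``.
    """
    counts = {c: 0 for c in SNV_CLASSES}
    if len(classes):
        for c, n in classes["class"].value_counts().items():
            counts[c] = int(n)
    retained = sum(n for c, n in counts.items() if c != "filtered")
    het = counts["unshared_major"] + counts["unshared_minor"] + counts["enriched"]
    frac = het / retained if retained else float("nan")
    return HeterogeneitySummary(
        counts=counts,
        retained=retained,
        heterogeneous=het,
        heterogeneous_fraction=frac,
    )
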