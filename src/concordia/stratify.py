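"""Stratified concordance summaries.

Strata supported: minor-allele-frequency bins (monomorphic SNPs as their
own bin, then right-closed 0.05-wide intervals), per-SNP mean quality
score bins, Axiom category groups, and a concordant-vs-discordant quality
comparison (Welch two-sample t-test).  Quality orientation matters
throughout: Illumina GC scores improve upward, Affymetrix confidence
scores improve downward, so thresholds and bin display order are
orientation-aware.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DataError, PipelineError
from .harmonize import AlignedPair
from .concordance import ConcordanceSummary, summarize
from .model import CATEGORIES, HIGHER_IS_BETTER, LOWER_IS_BETTER, MISSING, PlatformDataset

logger = logging.getLogger(__name__)

__all__ = [
    "StratifiedSummary",
    "QualityComparison",
    "plot_strata",
    "compute_maf",
    "stratify_by_maf",
    "stratify_by_quality",
    "restrict_by_quality",
    "category_summary",
    "polyhighres_pooled_concordance",
    "quality_mean_comparison",
]


@dataclass
class StratifiedSummary:
    """Per-stratum unweighted means of the per-SNP statistics."""

    stratifier: str  # "maf" | "quality" | "category"
    bin_label: str
    n_snps: int
    correlation_mean: float  # NaN when no defined correlations in the bin
    genotype_concordance_mean: float
    allele_concordance_mean: float
    allele_concordance_sd: Optional[float] = None
    n_correlation_na: int = 0
    share_pct: Optional[float] = None
    n_compared: int = 0


@dataclass
class QualityComparison:
    """Quality of concordant vs discordant genotype cells."""

    mean_quality_concordant: float
    mean_quality_discordant: float
    n_concordant: int
    n_discordant: int
    t_statistic: float
    p_value: float


def compute_maf(ds: PlatformDataset, snp_id: str) -> float:
    """Minor allele frequency at one SNP; NaN if every call is missing."""
    j = ds.snp_index(snp_id)
    return float(_maf_vector(ds)[j])


def _maf_vector(ds: PlatformDataset) -> np.ndarray:
    called = ds.calls != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(ds.calls != MISSING, ds.calls, 0).sum(axis=0) / (2.0 * n)
    f = np.where(n > 0, f, np.nan)
    return np.minimum(f, 1.0 - f)


def _group_means(
    stratifier: str,
    labels: Sequence[str],
    groups: dict[str, np.ndarray],
    per_snp: Sequence[ConcordanceSummary],
    total: int,
) -> list[StratifiedSummary]:
    corr = np.array([s.correlation for s in per_snp], dtype=float)
    gc = np.array([s.genotype_concordance for s in per_snp], dtype=float)
    ac = np.array([s.allele_concordance for s in per_snp], dtype=float)
    ncmp = np.array([s.n_compared for s in per_snp], dtype=np.int64)
    out = []
    for lab in labels:
        idx = groups.get(lab, np.array([], dtype=int))
        c = corr[idx]
        cval = c[np.isfinite(c)]
        out.append(
            StratifiedSummary(
                stratifier=stratifier,
                bin_label=lab,
                n_snps=int(idx.size),
                correlation_mean=float(cval.mean()) if cval.size else float("nan"),
                genotype_concordance_mean=float(np.nanmean(gc[idx])) if idx.size else float("nan"),
                allele_concordance_mean=float(np.nanmean(ac[idx])) if idx.size else float("nan"),
                allele_concordance_sd=float(np.nanstd(ac[idx], ddof=1)) if idx.size > 1 else float("nan"),
                n_correlation_na=int(idx.size - cval.size),
                share_pct=100.0 * idx.size / total if total else float("nan"),
                n_compared=int(ncmp[idx].sum()),
            )
        )
    return out


def maf_bin_label(maf: float, width: float = 0.05) -> str:
    """Bin label for a MAF value: ``0`` for monomorphic, else right-closed
    ``(lo,hi]`` intervals of the given width."""
    if math.isnan(maf):
        return "NA"
    if maf == 0.0:
        return "0"
    k = int(math.ceil(round(maf / width, 12))) - 1
    lo, hi = k * width, (k + 1) * width
    return f"({lo:.2f},{min(hi, 0.5):.2f}]"


def stratify_by_maf(
    pair: AlignedPair,
    per_snp: Sequence[ConcordanceSummary],
    reference: str = "left",
    width: float = 0.05,
) -> list[StratifiedSummary]:
    """Group per-SNP summaries by MAF computed on the reference platform."""
    if reference not in ("left", "right"):
        raise ConfigError(f"reference must be left or right, got {reference!r}")
    ds = pair.left if reference == "left" else pair.right
    if [s.unit_id for s in per_snp] != ds.snp_ids:
        raise DataError("per-SNP summaries do not match the pair's SNP order")
    mafs = _maf_vector(ds)
    labels = ["0"] + [
        f"({k * width:.2f},{min((k + 1) * width, 0.5):.2f}]"
        for k in range(int(round(0.5 / width)))
    ]
    assigned = np.array([maf_bin_label(m, width) for m in mafs])
    if (assigned == "NA").any():
        labels = labels + ["NA"]
    groups = {lab: np.flatnonzero(assigned == lab) for lab in labels}
    return _group_means("maf", labels, groups, per_snp, len(per_snp))


def _per_snp_mean_quality(ds: PlatformDataset) -> np.ndarray:
    if ds.quality is None:
        raise PipelineError(
            f"platform {ds.platform_name!r} carries no quality scores"
        )
    q = np.where(ds.calls != MISSING, ds.quality, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(q, axis=0)


def stratify_by_quality(
    pair: AlignedPair,
    platform: str = "left",
    bin_edges: Optional[Sequence[float]] = None,
    per_snp: Optional[Sequence[ConcordanceSummary]] = None,
) -> list[StratifiedSummary]:
    """Bin SNPs by per-SNP mean quality score on the chosen platform.

    For a lower-is-better score the bin list is returned best-first, i.e.
    reversed, so displays always run from high to low quality.
    """
    if platform not in ("left", "right"):
        raise ConfigError(f"platform must be left or right, got {platform!r}")
    ds = pair.left if platform == "left" else pair.right
    meanq = _per_snp_mean_quality(ds)
    if per_snp is None:
        per_snp = summarize(pair, "snp")
    if bin_edges is None:
        lo = float(np.floor(np.nanmin(meanq) * 20) / 20)
        hi = float(np.ceil(np.nanmax(meanq) * 20) / 20)
        if hi <= lo:
            hi = lo + 0.05
        bin_edges = np.round(np.arange(lo, hi + 1e-9, 0.05), 10)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or not (np.diff(edges) > 0).all():
        raise ConfigError("quality bin edges must be increasing, length >= 2")
    labels = [f"({edges[i]:.2f},{edges[i+1]:.2f}]" for i in range(edges.size - 1)]
    labels[0] = f"[{edges[0]:.2f},{edges[1]:.2f}]"
    # right-closed bins, lowest bin closed on the left too
    which = np.digitize(meanq, edges[1:-1], right=True)
    in_range = np.isfinite(meanq) & (meanq >= edges[0]) & (meanq <= edges[-1])
    groups = {
        lab: np.flatnonzero(in_range & (which == i))
        for i, lab in enumerate(labels)
    }
    out = _group_means("quality", labels, groups, per_snp, len(per_snp))
    if ds.quality_orientation == LOWER_IS_BETTER:
        out = out[::-1]
    return out


def restrict_by_quality(
    pair: AlignedPair, platform: str, threshold: float
) -> AlignedPair:
    """Mask genotype cells whose quality is on the bad side of ``threshold``.

    For a higher-is-better score cells with quality <= threshold are set
    missing on that platform; for lower-is-better, cells with quality >=
    threshold.  ``platform`` is ``left``, ``right`` or ``both``.
    """
    if platform not in ("left", "right", "both"):
        raise ConfigError(f"platform must be left/right/both, got {platform!r}")
    sides = ("left", "right") if platform == "both" else (platform,)
    new = {"left": pair.left.copy(), "right": pair.right.copy()}
    for side in sides:
        ds = new[side]
        if ds.quality is None:
            raise PipelineError(
                f"platform {ds.platform_name!r} carries no quality scores"
            )
        if ds.quality_orientation == HIGHER_IS_BETTER:
            bad = ds.quality <= threshold
        else:
            bad = ds.quality >= threshold
        bad &= ds.calls != MISSING
        ds.calls[bad] = MISSING
        ds.quality[bad] = np.nan
    restricted = AlignedPair(left=new["left"], right=new["right"], audit=pair.audit)
    if not restricted.both_called().any():
        raise PipelineError(
            f"quality restriction at {threshold} removed every comparable cell"
        )
    return restricted


def category_summary(
    pair: AlignedPair,
    per_snp: Sequence[ConcordanceSummary],
) -> list[StratifiedSummary]:
    """Group per-SNP summaries by the Axiom category labels carried on the
    right-platform SNP records; unlabelled SNPs form an ``Unlabelled`` row."""
    if [s.unit_id for s in per_snp] != pair.right.snp_ids:
        raise DataError("per-SNP summaries do not match the pair's SNP order")
    cats = np.array(
        [s.category if s.category is not None else "Unlabelled"
         for s in pair.right.snps]
    )
    labels = [c for c in CATEGORIES if (cats == c).any()]
    if (cats == "Unlabelled").any():
        labels.append("Unlabelled")
    groups = {lab: np.flatnonzero(cats == lab) for lab in labels}
    return _group_means("category", labels, groups, per_snp, len(per_snp))


def polyhighres_pooled_concordance(
    pair: AlignedPair, reference: str = "left"
) -> tuple[float, int]:
    """Pooled genotype concordance over segregating PolyHighResolution SNPs.

    Returns (concordance, n_cells); (NaN, 0) when no such SNPs exist.
    """
    ds = pair.left if reference == "left" else pair.right
    mafs = _maf_vector(ds)
    is_phr = np.array(
        [s.category == "PolyHighResolution" for s in pair.right.snps]
    )
    keep = is_phr & (mafs > 0)
    if not keep.any():
        return float("nan"), 0
    sub = pair.subset_snps(np.flatnonzero(keep))
    m = sub.both_called()
    n = int(m.sum())
    if n == 0:
        return float("nan"), 0
    gc = float((sub.left.calls[m] == sub.right.calls[m]).mean())
    return gc, n


def plot_strata(
    summaries: Sequence[StratifiedSummary],
    path,
    statistic: str = "allele_concordance_mean",
    title: Optional[str] = None,
) -> None:
    """Bar chart of per-bin means (+/- SD where available) with SNP counts
    overlaid as a line on a secondary axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [s for s in summaries if s.n_snps > 0]
    if not rows:
        raise PipelineError("nothing to plot: all strata empty")
    labels = [s.bin_label for s in rows]
    values = np.array([getattr(s, statistic) for s in rows], dtype=float)
    sds = np.array(
        [s.allele_concordance_sd
         if statistic == "allele_concordance_mean"
         and s.allele_concordance_sd is not None else np.nan
         for s in rows]
    )
    counts = [s.n_snps for s in rows]
    x = np.arange(len(rows))
    fig, ax = plt.subplots(figsize=(max(6, 0.7 * len(rows)), 4))
    ax.bar(x, values, color="0.6",
           yerr=np.where(np.isfinite(sds), sds, 0.0), capsize=2)
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel(statistic.replace("_", " "))
    ax.set_ylim(0, 1.05)
    ax2 = ax.twinx()
    ax2.plot(x, counts, color="black", marker="o", markersize=3)
    ax2.set_ylabel("n SNPs")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def quality_mean_comparison(
    pair: AlignedPair, platform: str = "left"
) -> QualityComparison:
    """Compare quality scores of concordant vs discordant genotype cells.

    ``platform`` selects the per-cell quality statistic: ``left`` or
    ``right`` uses that platform's score; ``both_min`` uses the worse of
    the two (the minimum for higher-is-better scores), the natural choice
    for duplicate runs on the same chemistry.  Group means are compared
    with a Welch two-sample two-sided t-test.
    """
    m = pair.both_called()
    if platform == "left":
        qsrc = [pair.left]
    elif platform == "right":
        qsrc = [pair.right]
    elif platform == "both_min":
        if pair.left.quality_orientation != pair.right.quality_orientation:
            raise ConfigError(
                "both_min quality comparison needs matching orientations"
            )
        qsrc = [pair.left, pair.right]
    else:
        raise ConfigError(f"platform must be left/right/both_min, got {platform!r}")
    for ds in qsrc:
        if ds.quality is None:
            raise PipelineError(
                f"platform {ds.platform_name!r} carries no quality scores"
            )
    if len(qsrc) == 1:
        q = qsrc[0].quality
    else:
        stack = np.stack([d.quality for d in qsrc])
        with warnings.catch_warnings():
            # all-NaN cells (missing on both sides) are filtered below
            warnings.simplefilter("ignore", RuntimeWarning)
            if qsrc[0].quality_orientation == HIGHER_IS_BETTER:
                q = np.nanmin(stack, axis=0)
            else:
                q = np.nanmax(stack, axis=0)
    use = m & np.isfinite(q)
    conc = pair.left.calls == pair.right.calls
    qc = q[use & conc]
    qd = q[use & ~conc]
    if qc.size == 0 or qd.size == 0:
        logger.warning(
            "quality comparison: empty group (concordant n=%d, discordant "
            "n=%d); statistics undefined", qc.size, qd.size,
        )
        t, p = float("nan"), float("nan")
    elif qc.size < 2 or qd.size < 2:
        t, p = float("nan"), float("nan")
    else:
        res = sps.ttest_ind(qc, qd, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(t):
            t, p = float("nan"), float("nan")
    return QualityComparison(
        mean_quality_concordant=float(qc.mean()) if qc.size else float("nan"),
        mean_quality_discordant=float(qd.mean()) if qd.size else float("nan"),
        n_concordant=int(qc.size),
        n_discordant=int(qd.size),
        t_statistic=t,
        p_value=p,
    )
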