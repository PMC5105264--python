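"""Reproducibility statistics for paired genotype call sets.

Three statistics are computed per animal, per SNP, and pooled over all
cells, always with pairwise deletion of missing calls:

* correlation between allele counts (Pearson; undefined at zero variance);
* genotype concordance: proportion of compared cells with identical calls;
* allele concordance: proportion of compared alleles shared.  A het/hom
  disagreement shares one allele; opposite homozygotes share none, so the
  shared-allele count for counts ``c1, c2`` is ``2 - |c1 - c2|`` and the
  algebraic identity ``AC = GC + p1/2`` holds, with ``p1`` the proportion
  of compared cells differing by exactly one allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DataError, PipelineError
from .harmonize import AlignedPair
from .model import MISSING, PlatformDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceSummary",
    "ContingencyTable3",
    "CallsetComparison",
    "shared_alleles",
    "genotype_concordance",
    "allele_concordance",
    "allele_count_correlation",
    "contingency_table",
    "summarize",
    "summary_stats",
    "compare_callsets",
    "filter_snps_by_concordance",
]


@dataclass
class ConcordanceSummary:
    """The three statistics for one unit (animal, SNP, or pooled)."""

    unit: str  # "animal" | "snp" | "overall"
    unit_id: str
    n_compared: int
    correlation: float  # NaN when undefined
    genotype_concordance: float
    allele_concordance: float


@dataclass
class ContingencyTable3:
    """3x3 genotype cross-tabulation (rows: left calls, columns: right)."""

    counts: np.ndarray  # (3, 3) int

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_percent(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / sums

    @property
    def genotype_concordance(self) -> float:
        return float(np.trace(self.counts) / self.n_total)

    @property
    def n_opposite_hom(self) -> int:
        return int(self.counts[0, 2] + self.counts[2, 0])

    @property
    def opposite_hom_given_left(self) -> float:
        """Opposite homozygotes / cells homozygous on the left platform."""
        denom = self.counts[0, :].sum() + self.counts[2, :].sum()
        return float(self.n_opposite_hom / denom) if denom else float("nan")

    @property
    def opposite_hom_given_right(self) -> float:
        denom = self.counts[:, 0].sum() + self.counts[:, 2].sum()
        return float(self.n_opposite_hom / denom) if denom else float("nan")


class CallsetComparison(NamedTuple):
    """Cell-level comparison of two call sets over identical axes."""

    n_called_both: int
    n_different: int
    n_opposite_hom: int

    @property
    def pct_different(self) -> float:
        return 100.0 * self.n_different / self.n_called_both


def shared_alleles(c1: int, c2: int) -> int:
    """Number of alleles two genotypes share: ``2 - |c1 - c2|``.

    Equivalent to the size of the intersection of the two allele
    multisets; a heterozygote and a homozygote share one allele, opposite
    homozygotes share none.
    """
    if c1 not in (0, 1, 2) or c2 not in (0, 1, 2):
        raise DataError(
            f"shared_alleles requires calls in {{0,1,2}}, got ({c1}, {c2}); "
            "missing calls must be filtered by the caller"
        )
    return 2 - abs(c1 - c2)


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise DataError(f"vector length mismatch: {x.shape} vs {y.shape}")
    m = (x != MISSING) & (y != MISSING)
    return x[m], y[m]


def genotype_concordance(x, y) -> float:
    """Proportion of pairwise-complete positions with identical calls."""
    xs, ys = _pairwise_complete(x, y)
    if xs.size == 0:
        logger.warning("genotype_concordance: no pairwise-complete positions")
        return float("nan")
    return float((xs == ys).mean())


def allele_concordance(x, y) -> float:
    """Proportion of compared alleles shared: mean of ``(2 - |x - y|) / 2``."""
    xs, ys = _pairwise_complete(x, y)
    if xs.size == 0:
        logger.warning("allele_concordance: no pairwise-complete positions")
        return float("nan")
    return float(1.0 - np.abs(xs.astype(np.int64) - ys).mean() / 2.0)


def allele_count_correlation(x, y) -> float:
    """Pearson correlation of allele counts over pairwise-complete positions.

    NaN when fewer than two complete pairs or either restricted vector is
    constant (zero variance).
    """
    xs, ys = _pairwise_complete(x, y)
    if xs.size < 2 or (xs == xs[0]).all() or (ys == ys[0]).all():
        return float("nan")
    return float(np.corrcoef(xs.astype(float), ys.astype(float))[0, 1])


def contingency_table(pair: AlignedPair) -> ContingencyTable3:
    """Cross-tabulate left vs right genotypes over all compared cells."""
    m = pair.both_called()
    if not m.any():
        raise PipelineError("contingency table: no pairwise-complete cells")
    l = pair.left.calls[m].astype(np.int64)
    r = pair.right.calls[m].astype(np.int64)
    counts = np.bincount(3 * l + r, minlength=9).reshape(3, 3)
    return ContingencyTable3(counts=counts)


def _masked_rowwise_stats(
    l: np.ndarray, r: np.ndarray, axis: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row (axis=1) or per-column (axis=0) statistics with
    pairwise deletion; returns (n, correlation, GC, AC) arrays."""
    m = (l != MISSING) & (r != MISSING)
    lf = np.where(m, l, 0).astype(np.float64)
    rf = np.where(m, r, 0).astype(np.float64)
    n = m.sum(axis=axis).astype(np.float64)
    sx = lf.sum(axis=axis)
    sy = rf.sum(axis=axis)
    sxx = (lf * lf).sum(axis=axis)
    syy = (rf * rf).sum(axis=axis)
    sxy = (lf * rf).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        denom = np.sqrt(varx * vary)
        corr = np.where(
            (n >= 2) & (varx > 1e-9) & (vary > 1e-9),
            (n * sxy - sx * sy) / np.where(denom > 0, denom, np.nan),
            np.nan,
        )
        eq = ((l == r) & m).sum(axis=axis)
        gc = np.where(n > 0, eq / n, np.nan)
        absdiff = (np.abs(lf - rf) * m).sum(axis=axis)
        ac = np.where(n > 0, 1.0 - absdiff / (2.0 * n), np.nan)
    return n.astype(np.int64), corr, gc, ac


def summarize(pair: AlignedPair, unit: str) -> list[ConcordanceSummary]:
    """Per-animal, per-SNP, or pooled overall concordance summaries."""
    l, r = pair.left.calls, pair.right.calls
    if unit == "animal":
        n, corr, gc, ac = _masked_rowwise_stats(l, r, axis=1)
        ids = pair.left.sample_ids
    elif unit == "snp":
        n, corr, gc, ac = _masked_rowwise_stats(l, r, axis=0)
        ids = pair.left.snp_ids
    elif unit == "overall":
        n, corr, gc, ac = _masked_rowwise_stats(l.reshape(1, -1), r.reshape(1, -1), axis=1)
        ids = ["ALL"]
    else:
        raise DataError(f"unknown summary unit {unit!r}")
    return [
        ConcordanceSummary(
            unit=unit,
            unit_id=uid,
            n_compared=int(ni),
            correlation=float(ci),
            genotype_concordance=float(gi),
            allele_concordance=float(ai),
        )
        for uid, ni, ci, gi, ai in zip(ids, n, corr, gc, ac)
    ]


def summary_stats(summaries: Sequence[ConcordanceSummary]) -> dict:
    """Mean/min/max of each statistic across units.

    NaN correlations (monomorphic units) are excluded from the correlation
    aggregate and counted separately; units with no compared cells are
    excluded throughout.
    """
    valid = [s for s in summaries if s.n_compared > 0]
    corr = np.array([s.correlation for s in valid], dtype=float)
    corr = corr[np.isfinite(corr)]
    gc = np.array([s.genotype_concordance for s in valid], dtype=float)
    ac = np.array([s.allele_concordance for s in valid], dtype=float)

    def mmm(a: np.ndarray) -> dict:
        if a.size == 0:
            return {"mean": None, "min": None, "max": None}
        return {"mean": float(a.mean()), "min": float(a.min()), "max": float(a.max())}

    return {
        "n_units": len(valid),
        "correlation": mmm(corr),
        "n_correlation_na": int(len(valid) - corr.size),
        "genotype_concordance": mmm(gc),
        "allele_concordance": mmm(ac),
    }


def compare_callsets(
    a: PlatformDataset, b: PlatformDataset
) -> CallsetComparison:
    """Count differing and opposite-homozygote cells between two call sets
    over the same samples and SNPs (e.g. original vs re-clustered calls)."""
    if a.calls.shape != b.calls.shape:
        raise DataError(
            f"call-set shapes differ: {a.calls.shape} vs {b.calls.shape}"
        )
    if a.sample_ids != b.sample_ids or a.snp_ids != b.snp_ids:
        raise DataError("call sets cover different samples or SNPs")
    m = (a.calls != MISSING) & (b.calls != MISSING)
    diff = np.abs(
        a.calls.astype(np.int16) - b.calls.astype(np.int16)
    )
    n_both = int(m.sum())
    n_diff = int(((diff > 0) & m).sum())
    n_opp = int(((diff == 2) & m).sum())
    return CallsetComparison(n_both, n_diff, n_opp)


def filter_snps_by_concordance(
    pair: AlignedPair,
    per_snp: Sequence[ConcordanceSummary],
    min_allele_concordance: float,
) -> AlignedPair:
    """Restrict the pair to SNPs with allele concordance >= the threshold.

    SNPs with no compared cells (undefined concordance) are removed too.
    """
    if [s.unit_id for s in per_snp] != pair.left.snp_ids:
        raise DataError("per-SNP summaries do not match the pair's SNP order")
    ac = np.array([s.allele_concordance for s in per_snp], dtype=float)
    keep = np.flatnonzero(np.isfinite(ac) & (ac >= min_allele_concordance))
    n_removed = pair.n_snps - keep.size
    if keep.size == 0:
        raise PipelineError(
            f"all SNPs fall below allele concordance {min_allele_concordance}"
        )
    if n_removed:
        logger.info(
            "concordance filter: removed %d of %d SNPs below AC %.2f",
            n_removed, pair.n_snps, min_allele_concordance,
        )
    return pair.subset_snps(keep)
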