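"""Matching and reconciliation of two call sets over shared samples and SNPs.

The pipeline order is: intersect SNPs, filter samples by call rate computed
on the matched SNP set, then reconcile the B-allele coding of the right
dataset against the left.  Reconciliation tests, per SNP, the four ways two
vendors can report the same variant: identical letters, A/B swap (counts
``c -> 2 - c``), opposite strand (complemented letters, counts unchanged),
and strand complement plus swap.  Strand-ambiguous SNPs (A/T, C/G), where
letters cannot distinguish a swap from a strand flip, are resolved by
allele-frequency proximity only when the left-platform MAF is below 0.4;
otherwise they are dropped as unresolvable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError, PipelineError
from .model import COMPLEMENT, MISSING, PlatformDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FilterAudit",
    "AlignedPair",
    "sample_call_rate",
    "snp_call_rate",
    "filter_samples_by_call_rate",
    "match_snps",
    "reconcile_allele_coding",
    "align",
]


@dataclass
class FilterAudit:
    """Full accounting of what matching and filtering removed, and why."""

    n_snps_initial_left: int = 0
    n_snps_initial_right: int = 0
    n_snps_common: int = 0
    n_snps_dropped_unresolvable: int = 0
    dropped_snp_ids: list[str] = field(default_factory=list)
    n_samples_initial: int = 0
    samples_failing_left: list[str] = field(default_factory=list)
    samples_failing_right: list[str] = field(default_factory=list)
    n_samples_retained: int = 0
    call_rate_threshold: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n_snps_initial_left": self.n_snps_initial_left,
            "n_snps_initial_right": self.n_snps_initial_right,
            "n_snps_common": self.n_snps_common,
            "n_snps_dropped_unresolvable": self.n_snps_dropped_unresolvable,
            "dropped_snp_ids": list(self.dropped_snp_ids),
            "n_samples_initial": self.n_samples_initial,
            "samples_failing_left": list(self.samples_failing_left),
            "samples_failing_right": list(self.samples_failing_right),
            "n_samples_retained": self.n_samples_retained,
            "call_rate_threshold": self.call_rate_threshold,
        }


@dataclass
class AlignedPair:
    """Two datasets restricted to common samples and coding-reconciled SNPs.

    Sample and SNP order is identical on both sides, and ``allele_b``
    refers to the same physical allele per SNP; this is the unit every
    concordance statistic operates on.
    """

    left: PlatformDataset
    right: PlatformDataset
    audit: FilterAudit = field(default_factory=FilterAudit)

    def __post_init__(self) -> None:
        if self.left.sample_ids != self.right.sample_ids:
            raise DataError("aligned pair: sample order differs between sides")
        if self.left.snp_ids != self.right.snp_ids:
            raise DataError("aligned pair: SNP order differs between sides")

    @property
    def n_samples(self) -> int:
        return self.left.n_samples

    @property
    def n_snps(self) -> int:
        return self.left.n_snps

    def both_called(self) -> np.ndarray:
        return self.left.called_mask() & self.right.called_mask()

    def subset_snps(self, indices) -> "AlignedPair":
        return AlignedPair(
            left=self.left.subset_snps(indices),
            right=self.right.subset_snps(indices),
            audit=self.audit,
        )


def sample_call_rate(ds: PlatformDataset, sample_id: str) -> float:
    """Fraction of SNPs called for one sample."""
    i = ds.sample_index(sample_id)
    if ds.n_snps == 0:
        raise DataError("call rate undefined on a dataset with no SNPs")
    return float((ds.calls[i, :] != MISSING).mean())


def snp_call_rate(ds: PlatformDataset, snp_id: str) -> float:
    """Fraction of samples called at one SNP."""
    j = ds.snp_index(snp_id)
    if ds.n_samples == 0:
        raise DataError("call rate undefined on a dataset with no samples")
    return float((ds.calls[:, j] != MISSING).mean())


def filter_samples_by_call_rate(
    left: PlatformDataset,
    right: PlatformDataset,
    threshold: float = 0.90,
) -> tuple[PlatformDataset, PlatformDataset, FilterAudit]:
    """Drop from BOTH datasets every shared sample whose call rate falls
    below ``threshold`` on EITHER platform.
    """
    if not (0.0 < threshold <= 1.0):
        raise ConfigError(f"call-rate threshold must be in (0, 1], got {threshold}")
    right_set = set(right.sample_ids)
    shared = [s for s in left.sample_ids if s in right_set]
    if not shared:
        raise PipelineError("no shared samples between the two datasets")
    lidx = [left.sample_index(s) for s in shared]
    ridx = [right.sample_index(s) for s in shared]
    lrate = (left.calls[lidx, :] != MISSING).mean(axis=1)
    rrate = (right.calls[ridx, :] != MISSING).mean(axis=1)
    failing_left = [s for s, r in zip(shared, lrate) if r < threshold]
    failing_right = [s for s, r in zip(shared, rrate) if r < threshold]
    failing = set(failing_left) | set(failing_right)
    kept = [s for s in shared if s not in failing]
    if not kept:
        raise PipelineError(
            f"all {len(shared)} shared samples fail the {threshold:.2f} "
            "call-rate threshold"
        )
    audit = FilterAudit(
        n_samples_initial=len(shared),
        samples_failing_left=failing_left,
        samples_failing_right=failing_right,
        n_samples_retained=len(kept),
        call_rate_threshold=threshold,
    )
    lkept = left.subset_samples([left.sample_index(s) for s in kept])
    rkept = right.subset_samples([right.sample_index(s) for s in kept])
    logger.info(
        "sample filter: %d shared, %d failing left, %d failing right, "
        "%d retained", len(shared), len(failing_left), len(failing_right),
        len(kept),
    )
    return lkept, rkept, audit


def match_snps(
    left: PlatformDataset,
    right: PlatformDataset,
    drop_ids: Sequence[str] = (),
) -> tuple[PlatformDataset, PlatformDataset, FilterAudit]:
    """Restrict both datasets, in left order, to common SNPs minus ``drop_ids``."""
    drop = set(drop_ids)
    right_ids = set(right.snp_ids)
    common = [s for s in left.snp_ids if s in right_ids and s not in drop]
    if not common:
        raise PipelineError("no common SNPs between the two datasets")
    audit = FilterAudit(
        n_snps_initial_left=left.n_snps,
        n_snps_initial_right=right.n_snps,
        n_snps_common=len(common),
    )
    lsub = left.subset_snps([left.snp_index(s) for s in common])
    rsub = right.subset_snps([right.snp_index(s) for s in common])
    logger.info(
        "SNP match: %d left, %d right, %d dropped by request, %d common",
        left.n_snps, right.n_snps, len(drop), len(common),
    )
    return lsub, rsub, audit


def _b_allele_freq(calls: np.ndarray) -> float:
    called = calls != MISSING
    if not called.any():
        return float("nan")
    return float(calls[called].mean() / 2.0)


def reconcile_allele_coding(
    left: PlatformDataset,
    right: PlatformDataset,
    ambiguous_maf_limit: float = 0.4,
) -> tuple[PlatformDataset, PlatformDataset, FilterAudit]:
    """Transform the right dataset so ``allele_b`` matches the left per SNP.

    Tries, in order: identity, A/B swap, strand complement, complement plus
    swap.  Strand-ambiguous SNPs are oriented by B-allele-frequency
    proximity when the left MAF is below ``ambiguous_maf_limit``, else
    dropped.  SNPs with letters incompatible under all four transformations
    are dropped (counted in the audit), never fatal.
    """
    if left.snp_ids != right.snp_ids:
        raise DataError("reconcile_allele_coding requires matched SNPs")
    right = right.copy()
    keep: list[int] = []
    dropped: list[str] = []
    for j, (ls, rs) in enumerate(zip(left.snps, right.snps)):
        l_pair = (ls.allele_a, ls.allele_b)
        r_pair = (rs.allele_a, rs.allele_b)
        flip = None  # None = drop, False = keep counts, True = 2 - counts
        if ls.is_strand_ambiguous:
            if {COMPLEMENT[r_pair[0]], COMPLEMENT[r_pair[1]]} != set(l_pair) \
                    and set(r_pair) != set(l_pair):
                flip = None
            else:
                f_l = _b_allele_freq(left.calls[:, j])
                maf_l = min(f_l, 1.0 - f_l) if np.isfinite(f_l) else float("nan")
                if np.isfinite(maf_l) and maf_l < ambiguous_maf_limit:
                    f_r = _b_allele_freq(right.calls[:, j])
                    if not np.isfinite(f_r):
                        flip = False  # no right calls: orientation moot
                    else:
                        flip = abs((1.0 - f_r) - f_l) < abs(f_r - f_l)
                else:
                    flip = None
        else:
            comp = (COMPLEMENT[r_pair[0]], COMPLEMENT[r_pair[1]])
            if r_pair == l_pair:
                flip = False
            elif (r_pair[1], r_pair[0]) == l_pair:
                flip = True
            elif comp == l_pair:
                flip = False
            elif (comp[1], comp[0]) == l_pair:
                flip = True
            else:
                flip = None
        if flip is None:
            dropped.append(ls.snp_id)
            continue
        if flip:
            col = right.calls[:, j]
            called = col != MISSING
            col[called] = 2 - col[called]
        rs.allele_a, rs.allele_b = ls.allele_a, ls.allele_b
        keep.append(j)

    if not keep:
        raise PipelineError("allele reconciliation dropped every SNP")
    audit = FilterAudit(
        n_snps_initial_left=left.n_snps,
        n_snps_initial_right=right.n_snps,
        n_snps_common=len(keep),
        n_snps_dropped_unresolvable=len(dropped),
        dropped_snp_ids=dropped,
    )
    if dropped:
        logger.info("reconcile: dropped %d unresolvable SNPs", len(dropped))
        left = left.subset_snps(keep)
        right = right.subset_snps(keep)
    return left, right, audit


def align(
    left: PlatformDataset,
    right: PlatformDataset,
    call_rate_threshold: float = 0.90,
    drop_ids: Sequence[str] = (),
    ambiguous_maf_limit: float = 0.4,
) -> AlignedPair:
    """Full harmonization: match SNPs, filter samples on the matched SNP
    set, reconcile allele coding; returns the aligned pair with a merged
    audit."""
    l0, r0 = left.n_snps, right.n_snps
    lm, rm, _ = match_snps(left, right, drop_ids)
    lf, rf, sample_audit = filter_samples_by_call_rate(lm, rm, call_rate_threshold)
    lr, rr, rec_audit = reconcile_allele_coding(lf, rf, ambiguous_maf_limit)
    audit = FilterAudit(
        n_snps_initial_left=l0,
        n_snps_initial_right=r0,
        n_snps_common=lr.n_snps,
        n_snps_dropped_unresolvable=rec_audit.n_snps_dropped_unresolvable,
        dropped_snp_ids=rec_audit.dropped_snp_ids,
        n_samples_initial=sample_audit.n_samples_initial,
        samples_failing_left=sample_audit.samples_failing_left,
        samples_failing_right=sample_audit.samples_failing_right,
        n_samples_retained=sample_audit.n_samples_retained,
        call_rate_threshold=call_rate_threshold,
    )
    return AlignedPair(left=lr, right=rr, audit=audit)
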