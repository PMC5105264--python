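"""Core data model: SNP records and per-platform genotype matrices.

Genotypes are stored as B-allele counts (0 = AA, 1 = AB, 2 = BB) in an
``int8`` sample x SNP matrix; ``MISSING`` (-1) marks no-calls.  Per-call
quality scores (Illumina GenCall GC score, Affymetrix confidence score)
live in an optional float matrix of the same shape, NaN where the call is
missing.  Quality orientation records whether larger scores mean better
calls (GC score) or worse calls (Affymetrix confidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import DataError

#: Sentinel for a missing genotype call, distinct from any valid allele count.
MISSING: int = -1

VALID_BASES = frozenset("ACGT")

#: The six Axiom cluster-quality categories.
CATEGORIES = (
    "PolyHighResolution",
    "NoMinorHom",
    "MonoHighResolution",
    "OffTargetVariant",
    "CallRateBelowThres",
    "Other",
)

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SnpRecord:
    """Identity, map position and allele letters of one biallelic SNP.

    ``allele_b`` is the allele whose copies the call matrix counts
    (Illumina A/B convention).  ``category`` is the optional Axiom
    cluster-quality label assigned by the Affymetrix calling software.
    """

    snp_id: str
    chrom: str = "0"
    pos: int = 0
    allele_a: str = "A"
    allele_b: str = "C"
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.allele_a not in VALID_BASES or self.allele_b not in VALID_BASES:
            raise DataError(
                f"SNP {self.snp_id}: alleles must be A/C/G/T, got "
                f"{self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise DataError(f"SNP {self.snp_id}: allele_a equals allele_b")
        if self.pos < 0:
            raise DataError(f"SNP {self.snp_id}: negative map position")
        if self.category is not None and self.category not in CATEGORIES:
            raise DataError(
                f"SNP {self.snp_id}: unknown category {self.category!r}"
            )

    @property
    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G SNPs read the same on both strands."""
        return COMPLEMENT[self.allele_a] == self.allele_b


@dataclass
class PlatformDataset:
    """Genotype calls from one platform: samples x SNPs allele-count matrix."""

    platform_name: str
    sample_ids: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray
    quality: Optional[np.ndarray] = None
    quality_orientation: str = HIGHER_IS_BETTER

    # Lazily built lookup caches; never serialized.
    _sample_index: Optional[dict] = field(default=None, repr=False, compare=False)
    _snp_index: Optional[dict] = field(default=None, repr=False, compare=False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def sample_index(self, sample_id: str) -> int:
        if self._sample_index is None or len(self._sample_index) != self.n_samples:
            self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(
                f"sample {sample_id!r} not present on platform "
                f"{self.platform_name!r}"
            ) from None

    def snp_index(self, snp_id: str) -> int:
        if self._snp_index is None or len(self._snp_index) != self.n_snps:
            self._snp_index = {s.snp_id: i for i, s in enumerate(self.snps)}
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(
                f"SNP {snp_id!r} not present on platform {self.platform_name!r}"
            ) from None

    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def validate(self) -> None:
        """Check the dataset invariants; raise :class:`DataError` on breach."""
        if self.calls.shape != (self.n_samples, self.n_snps):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.n_samples} samples x {self.n_snps} SNPs"
            )
        if len(set(self.sample_ids)) != self.n_samples:
            raise DataError("duplicate sample_ids")
        ids = self.snp_ids
        if len(set(ids)) != len(ids):
            raise DataError("duplicate snp_ids")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"invalid call {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, SNP {ids[j]!r}"
            )
        if self.quality_orientation not in (HIGHER_IS_BETTER, LOWER_IS_BETTER):
            raise DataError(
                f"unknown quality orientation {self.quality_orientation!r}"
            )
        if self.quality is not None:
            if self.quality.shape != self.calls.shape:
                raise DataError("quality matrix shape differs from calls")
            called = self.called_mask()
            if not np.isfinite(self.quality[called]).all():
                raise DataError("non-missing call without a quality value")
            if np.nanmin(self.quality, initial=0.0) < 0:
                raise DataError("negative quality score")

    def subset_samples(self, indices: Sequence[int]) -> "PlatformDataset":
        idx = np.asarray(indices, dtype=int)
        return PlatformDataset(
            platform_name=self.platform_name,
            sample_ids=[self.sample_ids[i] for i in idx],
            snps=self.snps,
            calls=self.calls[idx, :],
            quality=None if self.quality is None else self.quality[idx, :],
            quality_orientation=self.quality_orientation,
        )

    def subset_snps(self, indices: Sequence[int]) -> "PlatformDataset":
        idx = np.asarray(indices, dtype=int)
        return PlatformDataset(
            platform_name=self.platform_name,
            sample_ids=self.sample_ids,
            snps=[self.snps[i] for i in idx],
            calls=self.calls[:, idx],
            quality=None if self.quality is None else self.quality[:, idx],
            quality_orientation=self.quality_orientation,
        )

    def copy(self) -> "PlatformDataset":
        return PlatformDataset(
            platform_name=self.platform_name,
            sample_ids=list(self.sample_ids),
            snps=[replace(s) for s in self.snps],
            calls=self.calls.copy(),
            quality=None if self.quality is None else self.quality.copy(),
            quality_orientation=self.quality_orientation,
        )
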