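"""Readers and writers for genotype call sets.

Two text formats are supported:

* PLINK text PED/MAP (six leading PED columns, space-delimited allele
  pairs, ``0`` as the missing-allele code);
* a long call table: TSV with header ``sample_id  snp_id  call  quality``
  where ``call`` is the B-allele count (0/1/2) or ``NA``.

PED files carry allele letters, so the B allele is assigned per SNP as the
*minor* observed letter (ties at MAF 0.5 broken alphabetically).  Call
tables carry counts only; SNP metadata (map position, allele letters,
Axiom category) travels in an optional companion SNP table.
"""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError
from .model import (
    HIGHER_IS_BETTER,
    MISSING,
    CATEGORIES,
    PlatformDataset,
    SnpRecord,
    VALID_BASES,
)

__all__ = [
    "read_plink_text",
    "read_call_table",
    "write_call_table",
    "read_snp_table",
    "write_snp_table",
]


def _read_map(map_path: Path) -> list[tuple[str, str, int]]:
    """Parse a PLINK MAP file into (chrom, snp_id, pos) tuples."""
    out = []
    seen = set()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) == 4:
                chrom, snp_id, _cm, pos = fields
            elif len(fields) == 3:
                chrom, snp_id, pos = fields
            else:
                raise ParseError(
                    f"{map_path}: line {lineno}: expected 3 or 4 columns, "
                    f"got {len(fields)}"
                )
            try:
                pos_i = int(pos)
            except ValueError:
                raise ParseError(
                    f"{map_path}: line {lineno}: non-integer position {pos!r}"
                ) from None
            if snp_id in seen:
                raise DataError(f"{map_path}: duplicate snp_id {snp_id!r}")
            seen.add(snp_id)
            out.append((chrom, snp_id, pos_i))
    if not out:
        raise ParseError(f"{map_path}: empty MAP file")
    return out


def read_plink_text(
    ped_path, map_path, platform_name: str,
    quality_orientation: str = HIGHER_IS_BETTER,
) -> PlatformDataset:
    """Read a PLINK text PED/MAP pair into a :class:`PlatformDataset`.

    Allele letters are re-coded per SNP as the count of the minor observed
    allele (``allele_b``); ``0 0`` pairs become missing.  A SNP observed
    with more than two allele letters is a data error.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snp_meta = _read_map(map_path)
    n_snps = len(snp_meta)

    sample_ids: list[str] = []
    rows_a: list[list[str]] = []  # first allele letter per cell, "0" = missing
    rows_b: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected "
                    f"{6 + 2 * n_snps} fields for {n_snps} SNPs, got "
                    f"{len(fields)}"
                )
            sample_ids.append(fields[1])
            a = [x.upper() for x in fields[6::2]]
            b = [x.upper() for x in fields[7::2]]
            for x in a + b:
                if x != "0" and x not in VALID_BASES:
                    raise ParseError(
                        f"{ped_path}: line {lineno}: invalid allele {x!r}"
                    )
            rows_a.append(a)
            rows_b.append(b)
    if not sample_ids:
        raise ParseError(f"{ped_path}: empty PED file")
    if len(set(sample_ids)) != len(sample_ids):
        raise DataError(f"{ped_path}: duplicate sample ids")

    n_samples = len(sample_ids)
    arr_a = np.array(rows_a, dtype="U1")
    arr_b = np.array(rows_b, dtype="U1")
    missing = (arr_a == "0") | (arr_b == "0")

    snps: list[SnpRecord] = []
    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    for j, (chrom, snp_id, pos) in enumerate(snp_meta):
        col_ok = ~missing[:, j]
        letters = Counter(arr_a[col_ok, j]) + Counter(arr_b[col_ok, j])
        if len(letters) > 2:
            raise DataError(
                f"{ped_path}: SNP {snp_id!r} has >2 observed alleles: "
                f"{sorted(letters)}"
            )
        if len(letters) == 0:
            # Entirely missing column: arbitrary but deterministic letters.
            major, minor = "A", "C"
        elif len(letters) == 1:
            major = next(iter(letters))
            minor = next(b for b in "ACGT" if b != major)
        else:
            (l1, c1), (l2, c2) = sorted(letters.items())
            # major = more frequent; alphabetical letter wins ties
            major, minor = (l1, l2) if c1 >= c2 else (l2, l1)
        snps.append(
            SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                      allele_a=major, allele_b=minor)
        )
        cnt = (arr_a[:, j] == minor).astype(np.int8) + (arr_b[:, j] == minor)
        calls[col_ok, j] = cnt[col_ok]

    ds = PlatformDataset(
        platform_name=platform_name,
        sample_ids=sample_ids,
        snps=snps,
        calls=calls,
        quality=None,
        quality_orientation=quality_orientation,
    )
    ds.validate()
    return ds


def read_call_table(
    path,
    platform_name: str,
    quality_orientation: str = HIGHER_IS_BETTER,
    snps: Optional[Sequence[SnpRecord]] = None,
) -> PlatformDataset:
    """Read a long-format call table (TSV) into a :class:`PlatformDataset`.

    Cells absent from the file are missing.  When ``snps`` is given it
    fixes the SNP universe, order and metadata; otherwise SNPs appear in
    order of first occurrence with placeholder allele letters.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "snp_id": str, "call": str},
        na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    required = {"sample_id", "snp_id", "call"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: header must contain {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df.duplicated(subset=["sample_id", "snp_id"]).any():
        dup = df[df.duplicated(subset=["sample_id", "snp_id"])].iloc[0]
        raise DataError(
            f"{path}: duplicate cell ({dup['sample_id']}, {dup['snp_id']})"
        )

    call_str = df["call"]
    valid = call_str.isna() | call_str.isin(["0", "1", "2"])
    if not valid.all():
        bad = call_str[~valid].iloc[0]
        raise ParseError(f"{path}: invalid call value {bad!r}")
    call_num = call_str.map({"0": 0, "1": 1, "2": 2}).astype("float64")

    sample_ids = list(dict.fromkeys(df["sample_id"]))
    if snps is None:
        snp_list = [SnpRecord(snp_id=s) for s in dict.fromkeys(df["snp_id"])]
    else:
        snp_list = list(snps)
    snp_pos = {s.snp_id: j for j, s in enumerate(snp_list)}
    unknown = set(df["snp_id"]) - set(snp_pos)
    if unknown:
        raise DataError(f"{path}: SNPs not in the declared set: {sorted(unknown)[:5]}")

    n, m = len(sample_ids), len(snp_list)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    rows = df["sample_id"].map({s: i for i, s in enumerate(sample_ids)}).to_numpy()
    cols = df["snp_id"].map(snp_pos).to_numpy()
    called = call_num.notna().to_numpy()
    calls[rows[called], cols[called]] = call_num[called].astype(np.int8)

    quality = None
    if "quality" in df.columns:
        qvals = pd.to_numeric(df["quality"], errors="coerce").to_numpy(float)
        quality = np.full((n, m), np.nan)
        quality[rows, cols] = qvals
        quality[calls == MISSING] = np.nan
        if np.isnan(quality[calls != MISSING]).all() and called.sum() > 0:
            quality = None  # column present but entirely empty

    ds = PlatformDataset(
        platform_name=platform_name,
        sample_ids=sample_ids,
        snps=snp_list,
        calls=calls,
        quality=quality,
        quality_orientation=quality_orientation,
    )
    ds.validate()
    return ds


def write_call_table(ds: PlatformDataset, path) -> None:
    """Write a dataset as a long call table; inverse of :func:`read_call_table`.

    Every (sample, SNP) cell is written, missing calls as ``NA``, so that
    samples or SNPs with no calls remain represented and the round trip is
    exact.
    """
    if ds.n_snps == 0 or ds.n_samples == 0:
        raise DataError("refusing to write a dataset with no SNPs or samples")
    path = Path(path)
    snp_ids = ds.snp_ids
    n, m = ds.n_samples, ds.n_snps
    out = pd.DataFrame(
        {
            "sample_id": np.repeat(ds.sample_ids, m),
            "snp_id": np.tile(snp_ids, n),
            "call": ds.calls.reshape(-1).astype(object),
        }
    )
    out.loc[out["call"] == MISSING, "call"] = np.nan
    if ds.quality is not None:
        out["quality"] = ds.quality.reshape(-1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


_SNP_COLS = ["snp_id", "chrom", "pos", "allele_a", "allele_b", "category"]


def write_snp_table(snps: Sequence[SnpRecord], path) -> None:
    """Serialize SNP metadata (id, position, alleles, category) as TSV."""
    df = pd.DataFrame(
        [(s.snp_id, s.chrom, s.pos, s.allele_a, s.allele_b, s.category)
         for s in snps],
        columns=_SNP_COLS,
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_snp_table(path) -> list[SnpRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    if list(df.columns) != _SNP_COLS:
        raise ParseError(f"{path}: expected columns {_SNP_COLS}")
    snps = []
    for rec in df.itertuples(index=False):
        cat = rec.category
        if cat is None or (isinstance(cat, float) and math.isnan(cat)):
            cat = None
        if cat is not None and cat not in CATEGORIES:
            raise DataError(f"{path}: unknown category {cat!r}")
        snps.append(
            SnpRecord(snp_id=rec.snp_id, chrom=rec.chrom, pos=int(rec.pos),
                      allele_a=rec.allele_a, allele_b=rec.allele_b,
                      category=cat)
        )
    return snps
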