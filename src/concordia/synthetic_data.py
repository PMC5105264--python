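"""Dual-platform genotype simulator with known truth.

The generative model: per SNP a minor (B) allele frequency is drawn from a
configurable law, a fixed fraction of SNPs is forced monomorphic, and true
genotypes follow Hardy-Weinberg proportions at that frequency.  Each
platform observes the truth through an *allele-level* error channel: each
of the two alleles of a call flips independently with probability epsilon,
so single-allele discrepancies (het/hom) occur at order epsilon while
opposite-homozygote miscalls occur at order epsilon^2 — matching the
near-absence of opposite homozygotes seen in real replicate data.  Cells
are masked missing at a per-platform rate, and per-call quality scores are
drawn from a "concordant" Beta law for correct calls and a lower-mean
"discordant" law for erroneous calls (when coupling is enabled), emulating
the empirical gap between the GC scores of correct and incorrect calls.

Axiom-style category labels are attached to the right platform:
MonoHighResolution only on monomorphic SNPs, CallRateBelowThres SNPs get
elevated missingness, OffTargetVariant and Other get elevated error rates.

Exact enumeration oracles (:func:`error_kernel`,
:func:`expected_genotype_concordance`, :func:`expected_opposite_hom_rate`)
give closed-form expectations for validating simulation output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .harmonize import AlignedPair, FilterAudit
from .model import (
    CATEGORIES,
    HIGHER_IS_BETTER,
    LOWER_IS_BETTER,
    MISSING,
    PlatformDataset,
    SnpRecord,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_truth",
    "apply_platform_error",
    "simulate_dual_platform",
    "error_kernel",
    "expected_genotype_concordance",
    "expected_opposite_hom_rate",
    "make_fixture",
    "fixture_sample_failures",
    "fixture_snp_overlap",
    "fixture_differing_calls",
    "fixture_snp_call_rates",
]

# Category shares mirroring the composition of a typical custom Axiom
# panel: three-cluster SNPs dominate, with minorities of two-cluster,
# monomorphic, low-call-rate, off-target and unclassifiable probe sets.
DEFAULT_CATEGORY_FRACTIONS = {
    "PolyHighResolution": 0.7359,
    "NoMinorHom": 0.0418,
    "MonoHighResolution": 0.0190,
    "OffTargetVariant": 0.0091,
    "CallRateBelowThres": 0.0839,
    "Other": 0.1103,
}

#: Error-rate multiplier for the poorly clustering categories.
ELEVATED_ERROR_CATEGORIES = ("OffTargetVariant", "Other")
ELEVATED_ERROR_MULTIPLIER = 10.0
#: Extra missingness for SNPs labelled CallRateBelowThres.
EXTRA_MISSING_CALLRATE_CATEGORY = 0.15

_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("A", "T"),
    ("C", "G"), ("C", "T"), ("G", "T"),
]


@dataclass
class SimulationConfig:
    """All simulator parameters.

    Defaults emulate a dual-platform study of 84 animals on a ~51k-SNP
    ovine panel: a near-perfect reference platform (allele error 0.002,
    call rate 99.4%) against a noisier second platform (allele error 0.01,
    call rate 97.4%), uniform MAF, 2% monomorphic SNPs, and quality laws
    whose means differ between correct (~0.89) and erroneous (~0.85) calls.
    """

    n_samples: int = 84
    n_snps: int = 51121
    maf_law: tuple = ("uniform", 0.0, 0.5)
    monomorphic_fraction: float = 0.02
    error_rate_left: float = 0.002
    error_rate_right: float = 0.01
    missing_rate_left: float = 0.006
    missing_rate_right: float = 0.026
    quality_concordant_law: tuple = ("beta", 44.5, 5.5)   # mean 0.89
    quality_discordant_law: tuple = ("beta", 42.5, 7.5)   # mean 0.85
    quality_error_coupling: str = "coupled"  # or "independent"
    quality_orientation_left: str = HIGHER_IS_BETTER
    quality_orientation_right: str = LOWER_IS_BETTER
    category_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_snps <= 0:
            raise ConfigError("n_samples and n_snps must be positive")
        if not (0.0 <= self.monomorphic_fraction < 1.0):
            raise ConfigError("monomorphic_fraction must be in [0, 1)")
        for name in ("error_rate_left", "error_rate_right"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ConfigError(f"{name} must be in [0, 0.5), got {v}")
        for name in ("missing_rate_left", "missing_rate_right"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if self.quality_error_coupling not in ("coupled", "independent"):
            raise ConfigError(
                f"unknown quality_error_coupling {self.quality_error_coupling!r}"
            )
        if set(self.category_fractions) - set(CATEGORIES):
            raise ConfigError(
                f"unknown categories: {set(self.category_fractions) - set(CATEGORIES)}"
            )
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"category_fractions sum to {total}, not 1")
        if any(v < 0 for v in self.category_fractions.values()):
            raise ConfigError("category_fractions must be non-negative")
        mono_cat = self.category_fractions.get("MonoHighResolution", 0.0)
        if mono_cat > self.monomorphic_fraction + 1e-12:
            raise ConfigError(
                "MonoHighResolution fraction exceeds monomorphic_fraction: "
                f"{mono_cat} > {self.monomorphic_fraction}"
            )
        for name in ("quality_concordant_law", "quality_discordant_law"):
            law = getattr(self, name)
            if law[0] != "beta" or len(law) != 3 or law[1] <= 0 or law[2] <= 0:
                raise ConfigError(f"{name} must be ('beta', a>0, b>0)")
        kind = self.maf_law[0]
        if kind == "uniform":
            lo, hi = self.maf_law[1], self.maf_law[2]
            if not (0.0 <= lo < hi <= 0.5):
                raise ConfigError("uniform MAF law needs 0 <= lo < hi <= 0.5")
        elif kind == "beta":
            if self.maf_law[1] <= 0 or self.maf_law[2] <= 0:
                raise ConfigError("beta MAF law needs positive shapes")
        elif kind == "point_mass":
            if not (0.0 <= self.maf_law[1] <= 0.5):
                raise ConfigError("point_mass MAF must be in [0, 0.5]")
        else:
            raise ConfigError(f"unknown MAF law {kind!r}")


@dataclass
class TruthSet:
    """Ground truth behind a simulated pair: true calls, per-SNP MAF and
    category, and (after observation) per-platform error indicators."""

    sample_ids: list[str]
    snps: list[SnpRecord]
    true_calls: np.ndarray  # (n_samples, n_snps) int8, no missing
    maf: np.ndarray  # per-SNP true minor (B) allele frequency
    categories: list[str]
    errors: dict = field(default_factory=dict)  # side -> bool matrix


def _draw_maf(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size)
    if kind == "beta":
        # Beta on [0,1] folded onto [0,0.5] so that it is a MAF law.
        f = rng.beta(law[1], law[2], size)
        return np.minimum(f, 1.0 - f)
    if kind == "point_mass":
        return np.full(size, float(law[1]))
    raise ConfigError(f"unknown MAF law {kind!r}")


def simulate_truth(cfg: SimulationConfig) -> TruthSet:
    """Draw per-SNP MAFs, categories and Hardy-Weinberg true genotypes."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_snps

    maf = _draw_maf(rng, cfg.maf_law, m)
    n_mono = int(round(cfg.monomorphic_fraction * m))
    mono_idx = rng.choice(m, size=n_mono, replace=False) if n_mono else np.array([], dtype=int)
    maf[mono_idx] = 0.0
    mono_mask = np.zeros(m, dtype=bool)
    mono_mask[mono_idx] = True

    # True genotypes: B-allele count ~ Binomial(2, maf) per sample.
    true_calls = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)

    categories = _assign_categories(rng, cfg, mono_mask)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    snps = []
    width = len(str(m))
    for j in range(m):
        a, b = _ALLELE_PAIRS[pair_idx[j]]
        snps.append(
            SnpRecord(
                snp_id=f"snp{j + 1:0{width}d}",
                chrom=str(1 + j % 26),
                pos=1 + j,
                allele_a=a,
                allele_b=b,
            )
        )
    sample_ids = [f"animal{i + 1:0{len(str(n))}d}" for i in range(n)]
    return TruthSet(
        sample_ids=sample_ids,
        snps=snps,
        true_calls=true_calls,
        maf=maf,
        categories=categories,
    )


def _assign_categories(
    rng: np.random.Generator, cfg: SimulationConfig, mono_mask: np.ndarray
) -> list[str]:
    """Per-SNP category draw honouring the monomorphic constraint.

    MonoHighResolution can only label truly monomorphic SNPs: each
    monomorphic SNP gets it with probability p_mono / monomorphic_fraction,
    all other draws come from the remaining categories re-normalized, so
    expected shares equal ``cfg.category_fractions`` exactly.
    """
    m = mono_mask.size
    fr = {c: cfg.category_fractions.get(c, 0.0) for c in CATEGORIES}
    p_mono_cat = fr["MonoHighResolution"]
    others = [c for c in CATEGORIES if c != "MonoHighResolution"]
    w = np.array([fr[c] for c in others], dtype=float)
    if w.sum() <= 0:
        return ["MonoHighResolution"] * m
    w = w / w.sum()
    cats = np.array(others, dtype=object)[
        rng.choice(len(others), size=m, p=w)
    ]
    if p_mono_cat > 0 and mono_mask.any():
        p_hit = min(1.0, p_mono_cat / cfg.monomorphic_fraction)
        hit = rng.random(m) < p_hit
        cats[mono_mask & hit] = "MonoHighResolution"
    return list(cats)


def _draw_quality(rng: np.random.Generator, law: tuple, size) -> np.ndarray:
    return rng.beta(law[1], law[2], size)


def apply_platform_error(
    truth: TruthSet, side: str, cfg: SimulationConfig
) -> PlatformDataset:
    """Observe the truth through one platform's error/missingness channel."""
    if side not in ("left", "right"):
        raise ConfigError(f"side must be 'left' or 'right', got {side!r}")
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1 if side == "left" else 2])
    n, m = truth.true_calls.shape

    eps_base = cfg.error_rate_left if side == "left" else cfg.error_rate_right
    miss_base = cfg.missing_rate_left if side == "left" else cfg.missing_rate_right
    orientation = (
        cfg.quality_orientation_left if side == "left"
        else cfg.quality_orientation_right
    )

    cats = np.array(truth.categories, dtype=object)
    eps = np.full(m, eps_base)
    eps[np.isin(cats, ELEVATED_ERROR_CATEGORIES)] = min(
        0.45, eps_base * ELEVATED_ERROR_MULTIPLIER
    )
    miss = np.full(m, miss_base)
    miss[cats == "CallRateBelowThres"] += EXTRA_MISSING_CALLRATE_CATEGORY

    t = truth.true_calls.astype(np.int16)
    down = rng.binomial(t, eps[None, :])
    up = rng.binomial(2 - t, eps[None, :])
    observed = (t - down + up).astype(np.int8)
    err = observed != truth.true_calls

    quality = _draw_quality(rng, cfg.quality_concordant_law, (n, m))
    if cfg.quality_error_coupling == "coupled" and err.any():
        quality[err] = _draw_quality(
            rng, cfg.quality_discordant_law, int(err.sum())
        )
    if orientation == LOWER_IS_BETTER:
        quality = 1.0 - quality

    missing_mask = rng.random((n, m)) < miss[None, :]
    observed[missing_mask] = MISSING
    quality[missing_mask] = np.nan
    truth.errors[side] = err & ~missing_mask

    return PlatformDataset(
        platform_name=f"sim_{side}",
        sample_ids=list(truth.sample_ids),
        snps=[replace(s) for s in truth.snps],
        calls=observed,
        quality=quality,
        quality_orientation=orientation,
    )


def simulate_dual_platform(
    cfg: SimulationConfig,
) -> tuple[AlignedPair, TruthSet]:
    """Simulate one aligned dual-platform pair with its ground truth.

    Category labels are attached to the right platform's SNP records, as a
    second-vendor calling pipeline would report them.
    """
    truth = simulate_truth(cfg)
    left = apply_platform_error(truth, "left", cfg)
    right = apply_platform_error(truth, "right", cfg)
    for snp, cat in zip(right.snps, truth.categories):
        snp.category = cat
    audit = FilterAudit(
        n_snps_initial_left=cfg.n_snps,
        n_snps_initial_right=cfg.n_snps,
        n_snps_common=cfg.n_snps,
        n_samples_initial=cfg.n_samples,
        n_samples_retained=cfg.n_samples,
    )
    return AlignedPair(left=left, right=right, audit=audit), truth


# ---------------------------------------------------------------------------
# Enumeration oracles: exact expectations under the allele-flip channel.
# ---------------------------------------------------------------------------

def error_kernel(eps: float) -> np.ndarray:
    """Exact 3x3 transition matrix K[g, h] = P(observed h | true g).

    With true B-allele count g, the observed count is
    ``g - Binomial(g, eps) + Binomial(2 - g, eps)``; the kernel is the
    exact enumeration of those flips.
    """
    K = np.zeros((3, 3))
    for g in range(3):
        for d in range(g + 1):  # B->A flips
            pd = math.comb(g, d) * eps**d * (1 - eps) ** (g - d)
            for u in range(2 - g + 1):  # A->B flips
                pu = math.comb(2 - g, u) * eps**u * (1 - eps) ** (2 - g - u)
                K[g, g - d + u] += pd * pu
    return K


def _hwe(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def expected_genotype_concordance(
    mafs, eps_left: float, eps_right: float
) -> float:
    """Expected cross-platform genotype concordance given per-SNP MAFs.

    Averages, over SNPs, ``sum_g P_HWE(g) sum_h KL[g,h] KR[g,h]`` — the
    probability both platforms observe the same genotype.
    """
    KL, KR = error_kernel(eps_left), error_kernel(eps_right)
    agree = (KL * KR).sum(axis=1)  # sum_h KL[g,h] * KR[g,h]
    p = _hwe(mafs)  # (m, 3)
    return float((p @ agree).mean())


def expected_opposite_hom_rate(
    mafs, eps_left: float, eps_right: float
) -> float:
    """Expected fraction of compared cells called as opposite homozygotes."""
    KL, KR = error_kernel(eps_left), error_kernel(eps_right)
    opp = KL[:, 0] * KR[:, 2] + KL[:, 2] * KR[:, 0]
    p = _hwe(mafs)
    return float((p @ opp).mean())


# ---------------------------------------------------------------------------
# Exact-count fixtures
# ---------------------------------------------------------------------------

def _min_failing_missing(n_calls: int, threshold: float) -> int:
    """Smallest number of missing calls driving the call rate strictly
    below the threshold; exact at integer boundaries like 0.90 * 200."""
    return n_calls - int(math.ceil(threshold * n_calls - 1e-9)) + 1


def _blank_dataset(
    platform_name: str,
    n_samples: int,
    n_snps: int,
    snp_prefix: str = "snp",
    fill: int = 0,
) -> PlatformDataset:
    width = len(str(n_snps))
    snps = [
        SnpRecord(snp_id=f"{snp_prefix}{j + 1:0{width}d}", chrom="1", pos=j + 1)
        for j in range(n_snps)
    ]
    samples = [f"s{i + 1:0{len(str(n_samples))}d}" for i in range(n_samples)]
    calls = np.full((n_samples, n_snps), fill, dtype=np.int8)
    return PlatformDataset(
        platform_name=platform_name, sample_ids=samples, snps=snps, calls=calls
    )


def fixture_sample_failures(
    n_samples: int = 89,
    n_snps: int = 400,
    n_fail_left: int = 2,
    n_fail_right: int = 4,
    n_fail_both: int = 1,
    threshold: float = 0.90,
) -> tuple[PlatformDataset, PlatformDataset]:
    """Two datasets where exactly the requested samples fail the call-rate
    threshold: ``n_fail_left``/``n_fail_right`` are per-platform totals and
    ``n_fail_both`` of them overlap."""
    if n_fail_both > min(n_fail_left, n_fail_right):
        raise ConfigError("n_fail_both exceeds a per-platform total")
    n_union = n_fail_left + n_fail_right - n_fail_both
    if n_union >= n_samples:
        raise ConfigError("failing samples exceed the sample count")
    left = _blank_dataset("fixture_left", n_samples, n_snps)
    right = _blank_dataset("fixture_right", n_samples, n_snps)
    k = _min_failing_missing(n_snps, threshold)
    if k > n_snps:
        raise ConfigError("threshold infeasible at this SNP count")
    fail_both = range(0, n_fail_both)
    fail_left_only = range(n_fail_both, n_fail_left)
    fail_right_only = range(n_fail_left, n_union)
    for i in list(fail_both) + list(fail_left_only):
        left.calls[i, :k] = MISSING
    for i in list(fail_both) + list(fail_right_only):
        right.calls[i, :k] = MISSING
    return left, right


def fixture_snp_overlap(
    n_left: int = 51135,
    n_absent_right: int = 4,
    n_drop: int = 10,
    n_samples: int = 4,
) -> tuple[PlatformDataset, PlatformDataset, list[str]]:
    """A SNP-manifest fixture: the right platform lacks the last
    ``n_absent_right`` SNPs of the left manifest, and ``n_drop`` further
    common SNPs are returned as an explicit drop list."""
    if n_absent_right + n_drop >= n_left:
        raise ConfigError("nothing would remain after matching")
    left = _blank_dataset("fixture_left", n_samples, n_left)
    keep = list(range(n_left - n_absent_right))
    right = left.subset_snps(keep)
    right = PlatformDataset(
        platform_name="fixture_right",
        sample_ids=right.sample_ids,
        snps=right.snps,
        calls=right.calls.copy(),
    )
    drop_ids = [left.snps[j].snp_id for j in range(n_drop)]
    return left, right, drop_ids


def fixture_differing_calls(
    n_samples: int = 84,
    n_snps: int = 50754,
    n_called: int = 4263331,
    n_different: int = 3789,
) -> tuple[PlatformDataset, PlatformDataset]:
    """Two call sets over the same axes with exactly ``n_called`` cells
    called in both and ``n_different`` of them differing by one allele
    (never opposite homozygotes)."""
    total = n_samples * n_snps
    if n_called > total or n_different > n_called:
        raise ConfigError("requested counts infeasible for the matrix size")
    a = _blank_dataset("fixture_a", n_samples, n_snps, fill=1)
    b = a.copy()
    b.platform_name = "fixture_b"
    n_missing = total - n_called
    flat_a = a.calls.reshape(-1)
    flat_b = b.calls.reshape(-1)
    if n_missing:
        flat_a[:n_missing] = MISSING
        flat_b[:n_missing] = MISSING
    flat_b[n_missing:n_missing + n_different] = 2  # het -> hom: one allele off
    return a, b


def fixture_snp_call_rates(
    n_snps: int = 51121,
    n_low: int = 771,
    n_samples: int = 84,
    threshold: float = 0.90,
) -> PlatformDataset:
    """A dataset with exactly ``n_low`` SNPs below the call-rate threshold."""
    if n_low > n_snps:
        raise ConfigError("n_low exceeds n_snps")
    ds = _blank_dataset("fixture", n_samples, n_snps)
    k = _min_failing_missing(n_samples, threshold)
    if k > n_samples:
        raise ConfigError("threshold infeasible at this sample count")
    ds.calls[:k, :n_low] = MISSING
    return ds


_FIXTURES = {
    "sample_failures": fixture_sample_failures,
    "snp_overlap": fixture_snp_overlap,
    "differing_calls": fixture_differing_calls,
    "snp_call_rates": fixture_snp_call_rates,
}


def make_fixture(kind: str, **params):
    """Build a deterministic exact-count fixture by name.

    Kinds: ``sample_failures``, ``snp_overlap``, ``differing_calls``,
    ``snp_call_rates``; see the individual builders for parameters.
    """
    try:
        builder = _FIXTURES[kind]
    except KeyError:
        raise ConfigError(
            f"unknown fixture kind {kind!r}; known: {sorted(_FIXTURES)}"
        ) from None
    return builder(**params)
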