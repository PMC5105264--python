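"""Sample/SNP matching, call-rate filtering and allele-coding reconciliation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from concordia import (
    MISSING,
    ConfigError,
    PipelineError,
    SimulationConfig,
    SnpRecord,
    align,
    filter_samples_by_call_rate,
    genotype_concordance,
    match_snps,
    reconcile_allele_coding,
    sample_call_rate,
    snp_call_rate,
)
from concordia.model import COMPLEMENT
from concordia.synthetic_data import (
    fixture_sample_failures,
    fixture_snp_overlap,
    simulate_dual_platform,
)
from conftest import make_dataset


class TestCallRates:
    def test_sample_call_rate(self):
        calls = np.zeros((1, 100), dtype=np.int8)
        ds = make_dataset(calls)
        assert sample_call_rate(ds, "s1") == 1.0
        calls[0, :3] = MISSING
        assert sample_call_rate(make_dataset(calls), "s1") == 0.97
        calls[0, :] = MISSING
        assert sample_call_rate(make_dataset(calls), "s1") == 0.0

    def test_snp_call_rate(self):
        calls = np.ones((84, 1), dtype=np.int8)
        assert snp_call_rate(make_dataset(calls), "snp1") == 1.0
        calls[:9, 0] = MISSING
        rate = snp_call_rate(make_dataset(calls), "snp1")
        assert rate == pytest.approx(75 / 84)
        assert rate < 0.90

    def test_unknown_ids_raise(self):
        ds = make_dataset(np.zeros((2, 2)))
        with pytest.raises(KeyError):
            sample_call_rate(ds, "nope")
        with pytest.raises(KeyError):
            snp_call_rate(ds, "nope")


class TestSampleFilter:
    def test_union_removal_matches_study_accounting(self):
        """2 failures on one platform, 4 on the other, 1 shared: 89 -> 84."""
        left, right = fixture_sample_failures(
            n_samples=89, n_snps=200, n_fail_left=2, n_fail_right=4,
            n_fail_both=1,
        )
        lk, rk, audit = filter_samples_by_call_rate(left, right, 0.90)
        assert audit.n_samples_retained == 84
        assert lk.n_samples == rk.n_samples == 84
        assert len(audit.samples_failing_left) == 2
        assert len(audit.samples_failing_right) == 4
        assert len(set(audit.samples_failing_left)
                   & set(audit.samples_failing_right)) == 1

    def test_degenerate_threshold_rejected(self):
        ds = make_dataset(np.zeros((2, 4)))
        with pytest.raises(ConfigError):
            filter_samples_by_call_rate(ds, ds, 0.0)

    def test_no_failures_is_identity(self):
        ds = make_dataset(np.ones((3, 5)))
        lk, rk, audit = filter_samples_by_call_rate(ds, ds, 0.90)
        assert lk.sample_ids == ds.sample_ids
        assert audit.samples_failing_left == []
        assert audit.samples_failing_right == []

    def test_all_failing_is_pipeline_error(self):
        calls = np.full((2, 4), MISSING, dtype=np.int8)
        ds = make_dataset(calls)
        with pytest.raises(PipelineError):
            filter_samples_by_call_rate(ds, ds, 0.90)

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(2, 20),
        fail_l=st.sets(st.integers(0, 19), max_size=10),
        fail_r=st.sets(st.integers(0, 19), max_size=10),
    )
    def test_audit_arithmetic_matches_set_union(self, n, fail_l, fail_r):
        """retained = initial - |union of per-platform failing sets|."""
        fail_l = {i for i in fail_l if i < n}
        fail_r = {i for i in fail_r if i < n}
        if fail_l | fail_r == set(range(n)):
            fail_l.discard(0)
            fail_r.discard(0)
        m = 20
        lcalls = np.zeros((n, m), dtype=np.int8)
        rcalls = np.zeros((n, m), dtype=np.int8)
        k = int(m * 0.1) + 1
        for i in fail_l:
            lcalls[i, :k] = MISSING
        for i in fail_r:
            rcalls[i, :k] = MISSING
        _, _, audit = filter_samples_by_call_rate(
            make_dataset(lcalls), make_dataset(rcalls), 0.90
        )
        assert audit.n_samples_retained == n - len(fail_l | fail_r)


class TestMatchSnps:
    def test_study_manifest_accounting(self):
        """51,135 SNPs, 4 absent on the second chip, 10 dropped: 51,121."""
        left, right, drop_ids = fixture_snp_overlap(
            n_left=51135, n_absent_right=4, n_drop=10, n_samples=2,
        )
        lm, rm, audit = match_snps(left, right, drop_ids)
        assert audit.n_snps_common == 51121
        assert lm.n_snps == rm.n_snps == 51121
        assert lm.snp_ids == rm.snp_ids

    def test_identity_on_identical_manifests(self):
        ds = make_dataset(np.zeros((2, 5)))
        lm, rm, audit = match_snps(ds, ds, ())
        assert lm.snp_ids == ds.snp_ids
        assert audit.n_snps_common == 5

    def test_disjoint_manifests_error(self):
        a = make_dataset(np.zeros((2, 2)))
        b = make_dataset(np.zeros((2, 2)))
        for j, s in enumerate(b.snps):
            s.snp_id = f"other{j}"
        with pytest.raises(PipelineError):
            match_snps(a, b, ())


def _snp(sid, a, b):
    return SnpRecord(snp_id=sid, chrom="1", pos=1, allele_a=a, allele_b=b)


def oracle_transform(l_pair, r_pair):
    """Brute force over the four letter transformations; returns the flip
    decision for unambiguous SNPs, None when no transformation matches."""
    candidates = [
        (r_pair, False),
        ((r_pair[1], r_pair[0]), True),
        ((COMPLEMENT[r_pair[0]], COMPLEMENT[r_pair[1]]), False),
        ((COMPLEMENT[r_pair[1]], COMPLEMENT[r_pair[0]]), True),
    ]
    for pair, flip in candidates:
        if pair == l_pair:
            return flip
    return None


class TestReconcile:
    def test_swap_restores_concordance(self):
        calls = np.array([[0, 1], [2, 1], [1, 0]], dtype=np.int8)
        left = make_dataset(calls, snps=[_snp("snp1", "A", "G"),
                                         _snp("snp2", "A", "G")])
        right = make_dataset(2 - calls, snps=[_snp("snp1", "G", "A"),
                                              _snp("snp2", "G", "A")])
        l2, r2, audit = reconcile_allele_coding(left, right)
        assert audit.n_snps_dropped_unresolvable == 0
        assert genotype_concordance(l2.calls.ravel(), r2.calls.ravel()) == 1.0

    def test_strand_complement_keeps_counts(self):
        """T/C letters on the right are the opposite strand of A/G: the
        brute-force transformation search picks the complement, counts
        unchanged."""
        calls = np.array([[0], [1], [2]], dtype=np.int8)
        left = make_dataset(calls, snps=[_snp("snp1", "A", "G")])
        right = make_dataset(calls.copy(), snps=[_snp("snp1", "T", "C")])
        assert oracle_transform(("A", "G"), ("T", "C")) is False
        l2, r2, _ = reconcile_allele_coding(left, right)
        assert np.array_equal(r2.calls, calls)
        assert r2.snps[0].allele_b == "G"

    @settings(max_examples=60, deadline=None)
    @given(
        l=st.sampled_from([("A", "G"), ("A", "C"), ("C", "T"), ("G", "T")]),
        r=st.sampled_from([
            ("A", "G"), ("G", "A"), ("T", "C"), ("C", "T"),
            ("A", "C"), ("C", "A"), ("T", "G"), ("G", "T"),
        ]),
    )
    def test_unambiguous_agrees_with_bruteforce_oracle(self, l, r):
        calls = np.array([[0], [1], [2], [1]], dtype=np.int8)
        left = make_dataset(calls, snps=[_snp("snp1", *l)])
        right = make_dataset(calls.copy(), snps=[_snp("snp1", *r)])
        expected = oracle_transform(l, r)
        if expected is None:
            with pytest.raises(PipelineError):
                # single-SNP dataset: dropping the SNP empties the pair
                reconcile_allele_coding(left, right)
        else:
            _, r2, audit = reconcile_allele_coding(left, right)
            assert audit.n_snps_dropped_unresolvable == 0
            want = 2 - calls if expected else calls
            assert np.array_equal(r2.calls, want)

    def test_ambiguous_high_maf_dropped(self):
        # A/T SNP with left MAF 0.45: unresolvable by rule
        calls = np.array([[1]] * 9 + [[0]], dtype=np.int8)  # f = 9/20 = 0.45
        other = np.array([[0], [1]], dtype=np.int8)
        left = make_dataset(
            np.hstack([calls, np.tile(other, (5, 1))]),
            snps=[_snp("snp1", "A", "T"), _snp("snp2", "A", "G")],
        )
        right = left.copy()
        right.platform_name = "r"
        _, _, audit = reconcile_allele_coding(left, right)
        assert audit.n_snps_dropped_unresolvable == 1
        assert audit.dropped_snp_ids == ["snp1"]

    def test_ambiguous_low_maf_resolved_by_frequency(self):
        # A/T SNP, left MAF 0.1; right reports the mirrored coding
        calls = np.array([[1]] + [[0]] * 9, dtype=np.int8)
        left = make_dataset(calls, snps=[_snp("snp1", "A", "T")])
        right = make_dataset(2 - calls, snps=[_snp("snp1", "T", "A")])
        _, r2, audit = reconcile_allele_coding(left, right)
        assert audit.n_snps_dropped_unresolvable == 0
        assert np.array_equal(r2.calls, calls)


class TestAlign:
    def test_zero_error_simulation_fully_concordant(self):
        cfg = SimulationConfig(
            n_samples=20, n_snps=300, error_rate_left=0.0,
            error_rate_right=0.0, missing_rate_left=0.0,
            missing_rate_right=0.0, seed=3,
        )
        pair, _ = simulate_dual_platform(cfg)
        aligned = align(pair.left, pair.right)
        assert genotype_concordance(
            aligned.left.calls.ravel(), aligned.right.calls.ravel()
        ) == 1.0

    def test_match_and_filter_commute(self, rng):
        """Filtering on the common SNP set then matching equals matching
        then filtering."""
        n, m = 12, 40
        lcalls = rng.integers(0, 3, (n, m)).astype(np.int8)
        rcalls = rng.integers(0, 3, (n, m)).astype(np.int8)
        lcalls[2, :30] = MISSING  # sample 2 fails only on the common set
        left = make_dataset(lcalls)
        right = make_dataset(rcalls)
        right = right.subset_snps(range(30))  # right lacks the last 10 SNPs

        lm, rm, _ = match_snps(left, right)
        l1, r1, a1 = filter_samples_by_call_rate(lm, rm, 0.90)

        lf, rf, a2 = filter_samples_by_call_rate(
            left.subset_snps(range(30)), right, 0.90
        )
        l2, r2, _ = match_snps(
            left.subset_samples([left.sample_index(s) for s in lf.sample_ids]),
            rf,
        )
        assert l1.sample_ids == l2.sample_ids
        assert np.array_equal(l1.calls, l2.calls)
        assert np.array_equal(r1.calls, r2.calls)
        assert a1.samples_failing_left == a2.samples_failing_left
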