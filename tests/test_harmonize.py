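"""Instrument selection: significance filter, LD clumping, palindromes,
allele alignment, and instrument-strength F statistics."""

import numpy as np
import pandas as pd
import pytest

from mrkit import (
    AssociationTable,
    CoverageError,
    MRKitError,
    VariantRecord,
    classify_palindrome,
    f_statistic,
    harmonize,
    ld_clump,
    load_fixture,
    significance_filter,
)
from mrkit.harmonize import build_instrument_set


def rec(snp, ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01, pval=1e-9, chrom="1", pos=100):
    return VariantRecord(snp, chrom, pos, ea, oa, eaf, beta, se, pval)


def table(records, trait="exp", trait_type="continuous"):
    return AssociationTable(trait, trait_type, tuple(records))


class TestSignificanceFilter:
    def test_phosphorus_fixture_all_pass_at_genome_wide_threshold(self):
        exposure = load_fixture("phosphorus").exposure
        assert len(significance_filter(exposure, 5e-8)) == 5

    def test_threshold_one_is_identity(self):
        t = table([rec("rs1", pval=0.99), rec("rs2", pval=1e-3)])
        assert significance_filter(t, 1.0).records == t.records

    def test_boundary_p_equal_to_threshold_is_dropped(self):
        t = table([rec("rs1", pval=5e-8), rec("rs2", pval=4.99e-8)])
        kept = significance_filter(t, 5e-8)
        assert kept.snp_ids == ("rs2",)


def ld_frame(ids, r2):
    return pd.DataFrame(r2, index=ids, columns=ids)


class TestLdClump:
    def test_correlated_pair_keeps_smaller_p(self):
        t = table([rec("rs1", pval=1e-9), rec("rs2", pval=1e-10)])
        ld = ld_frame(["rs1", "rs2"], [[1.0, 0.5], [0.5, 1.0]])
        assert ld_clump(t, ld, 0.01).snp_ids == ("rs2",)

    def test_uncorrelated_snps_all_retained(self):
        t = table([rec(f"rs{i}", pval=10.0**-(9 + i)) for i in range(4)])
        ld = ld_frame(t.snp_ids, np.eye(4))
        assert ld_clump(t, ld, 0.01).snp_ids == t.snp_ids

    def test_missing_snp_in_ld_matrix_raises(self):
        t = table([rec("rs1"), rec("rs2")])
        ld = ld_frame(["rs1"], [[1.0]])
        with pytest.raises(CoverageError, match="rs2"):
            ld_clump(t, ld, 0.01)

    def test_random_instances_match_brute_force_oracle(self):
        """Exhaustive check of the greedy definition on random <=8-SNP sets:
        every retained pair is below threshold, and every dropped SNP
        conflicts with a retained SNP of smaller (p, input-order) rank."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(2, 9))
            ids = [f"rs{i}" for i in range(k)]
            pvals = rng.uniform(1e-12, 1e-8, size=k)
            a = rng.uniform(0, 1, size=(k, k))
            r2 = (a + a.T) / 2
            np.fill_diagonal(r2, 1.0)
            thr = float(rng.uniform(0.05, 0.8))
            t = table([rec(ids[i], pval=pvals[i]) for i in range(k)])
            kept = set(ld_clump(t, ld_frame(ids, r2), thr).snp_ids)
            rank = {ids[i]: (pvals[i], i) for i in range(k)}
            idx = {s: i for i, s in enumerate(ids)}
            for s in kept:
                for q in kept:
                    if s != q:
                        assert r2[idx[s], idx[q]] < thr
            for s in set(ids) - kept:
                assert any(
                    r2[idx[s], idx[q]] >= thr and rank[q] < rank[s] for q in kept
                )

    def test_row_order_invariance_with_distinct_pvalues(self):
        rng = np.random.default_rng(3)
        k = 6
        ids = [f"rs{i}" for i in range(k)]
        pvals = rng.permutation(np.logspace(-12, -8, k))
        a = rng.uniform(0, 1, size=(k, k))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = ld_frame(ids, r2)
        t1 = table([rec(ids[i], pval=pvals[i]) for i in range(k)])
        perm = rng.permutation(k)
        t2 = table([rec(ids[i], pval=pvals[i]) for i in perm])
        assert set(ld_clump(t1, ld, 0.3).snp_ids) == set(ld_clump(t2, ld, 0.3).snp_ids)


class TestClassifyPalindrome:
    @pytest.mark.parametrize(
        "ea,oa,eaf,expected",
        [
            ("A", "T", 0.44, "drop"),
            ("T", "A", 0.56, "drop"),
            ("C", "T", 0.49, "not_palindromic"),
            ("G", "C", 0.30, "alignable"),
            ("A", "T", 0.42, "alignable"),  # strict inequality: MAF == 0.42 kept
            ("C", "G", 0.95, "alignable"),
        ],
    )
    def test_rule(self, ea, oa, eaf, expected):
        assert classify_palindrome(ea, oa, eaf) == expected


class TestHarmonize:
    def test_iron_fixture_already_aligned(self):
        study = load_fixture("iron")
        ins = harmonize(study.exposure, study.outcome)
        assert ins.k == 5
        assert ins.dropped == ()
        assert all("flipped_outcome" not in p.flags for p in ins.pairs)

    def test_swapped_alleles_negate_outcome_beta(self):
        exp = table([rec("rs1", ea="A", oa="G", beta=0.1)])
        out = table([rec("rs1", ea="G", oa="A", eaf=0.7, beta=0.05)], trait="out")
        ins = harmonize(exp, out)
        pair = ins.pairs[0]
        assert pair.beta_out == -0.05
        assert pair.eaf_out == pytest.approx(0.3)
        assert "flipped_outcome" in pair.flags

    def test_unmatched_snp_recorded(self):
        exp = table([rec("rs1"), rec("rs2")])
        out = table([rec("rs1")], trait="out")
        ins = harmonize(exp, out)
        assert ("rs2", "unmatched_in_outcome") in ins.dropped

    def test_incompatible_alleles_recorded(self):
        exp = table([rec("rs1", ea="A", oa="G"), rec("rs2")])
        out = table([rec("rs1", ea="A", oa="C"), rec("rs2")], trait="out")
        ins = harmonize(exp, out)
        assert ("rs1", "allele_mismatch") in ins.dropped

    def test_high_maf_palindrome_dropped(self):
        exp = table([rec("rs1", ea="A", oa="T", eaf=0.5), rec("rs2")])
        out = table([rec("rs1", ea="A", oa="T", eaf=0.5), rec("rs2")], trait="out")
        ins = harmonize(exp, out)
        assert ("rs1", "palindromic_maf_gt_threshold") in ins.dropped

    def test_alignable_palindrome_flipped_by_frequency(self):
        exp = table([rec("rs1", ea="A", oa="T", eaf=0.2, beta=0.1)])
        out = table([rec("rs1", ea="A", oa="T", eaf=0.8, beta=0.05)], trait="out")
        pair = harmonize(exp, out).pairs[0]
        assert pair.beta_out == -0.05
        assert pair.flags == frozenset({"flipped_outcome", "palindromic_aligned"})

    def test_ambiguous_palindrome_frequency_dropped(self):
        exp = table([rec("rs1", ea="A", oa="T", eaf=0.498), rec("rs2")])
        out = table([rec("rs1", ea="A", oa="T", eaf=0.5), rec("rs2")], trait="out")
        ins = harmonize(exp, out)
        assert any(s == "rs1" and r.startswith("palindromic") for s, r in ins.dropped)

    def test_idempotent_on_aligned_tables(self):
        study = load_fixture("selenium")
        first = harmonize(study.exposure, study.outcome)
        again = harmonize(study.exposure, study.outcome)
        assert first.pairs == again.pairs

    def test_allele_coding_invariance(self):
        """Flipping EA/OA with beta negation and eaf complement in the
        outcome table yields the same harmonized effects."""
        study = load_fixture("magnesium")
        flipped = study.outcome.with_records(r.flip_alleles() for r in study.outcome.records)
        a = harmonize(study.exposure, study.outcome)
        b = harmonize(study.exposure, flipped)
        for pa, pb in zip(a.pairs, b.pairs):
            assert pa.beta_out == pytest.approx(pb.beta_out)
            assert pa.beta_exp == pb.beta_exp

    def test_build_instrument_set_merges_audit_trail(self):
        exp = table([rec("rs1", pval=1e-9), rec("rs2", pval=1e-3), rec("rs3", pval=1e-10)])
        out = table([rec("rs1"), rec("rs3")], trait="out")
        ld = ld_frame(["rs1", "rs3"], [[1.0, 0.9], [0.9, 1.0]])
        ins = build_instrument_set(exp, out, ld=ld)
        assert ("rs2", "not_significant") in ins.dropped
        assert ("rs1", "clumped") in ins.dropped
        assert ins.snp_ids == ("rs3",)


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.050, 0.005, 100.0), (0.011, 0.001, 121.0), (0.0, 0.3, 0.0)],
    )
    def test_values(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_nonpositive_se_raises(self):
        with pytest.raises(MRKitError):
            f_statistic(0.1, 0.0)

    def test_all_fixture_instruments_exceed_strength_threshold(self, fixture_instruments):
        for ins in fixture_instruments.values():
            assert all(f_statistic(p.beta_exp, p.se_exp) > 10 for p in ins.pairs)
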