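"""IO, Z-score conversion, harmonization, clumping and filter tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrkit as mk
from mrkit.exceptions import (
    ConfigurationError,
    DegenerateFrequencyError,
    SumstatsError,
    UnsupportedAlleleError,
)
from mrkit.sumstats import COMPLEMENT


def rec(snp="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, pval=1e-9,
        chrom="1", pos=None, **kw):
    return mk.SummaryStatRecord(snp_id=snp, chrom=chrom, effect_allele=ea,
                                other_allele=oa, eaf=eaf, beta=beta, se=se,
                                pval=pval, pos=pos, **kw)


class TestReadWrite:
    def test_fixture_file_reads_all_rows(self, selenium_files):
        records = mk.read_sumstats(selenium_files["exposure"])
        assert len(records) == 11
        by_id = {r.snp_id: r for r in records}
        assert by_id["rs921943"].beta == 0.294952
        assert by_id["rs921943"].se == 0.022447

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("SNP\tCHR\tA1\tA2\tEAF\tBETA\tSE\tP\n")
        assert mk.read_sumstats(path) == []

    def test_invalid_eaf_row_rejected_with_diagnostic(self, tmp_path, caplog):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "SNP\tCHR\tA1\tA2\tEAF\tBETA\tSE\tP\n"
            "rs1\t1\tA\tG\t0.3\t0.1\t0.02\t1e-9\n"
            "rs2\t1\tT\tC\t1.2\t0.1\t0.02\t1e-9\n"
        )
        with caplog.at_level("WARNING"):
            records = mk.read_sumstats(path)
        assert [r.snp_id for r in records] == ["rs1"]
        assert any("row 3" in m for m in caplog.messages)
        with pytest.raises(SumstatsError):
            mk.read_sumstats(path, strict=True)

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "nocol.tsv"
        path.write_text("SNP\tA1\tA2\tEAF\tBETA\tP\nrs1\tA\tG\t0.3\t0.1\t1e-9\n")
        with pytest.raises(ConfigurationError, match="SE"):
            mk.read_sumstats(path)

    def test_unparseable_numeric_collected_not_fatal(self, tmp_path):
        path = tmp_path / "dirty.tsv"
        path.write_text(
            "SNP\tCHR\tA1\tA2\tEAF\tBETA\tSE\tP\n"
            "rs1\t1\tA\tG\t0.3\toops\t0.02\t1e-9\n"
            "rs2\t1\tT\tC\t0.4\t0.1\t0.02\t1e-9\n"
        )
        records = mk.read_sumstats(path)
        assert [r.snp_id for r in records] == ["rs2"]

    @settings(deadline=None, max_examples=50)
    @given(
        eaf=st.floats(0.01, 0.99),
        beta=st.floats(-2, 2, allow_nan=False),
        se=st.floats(1e-6, 1.0),
        pval=st.floats(1e-300, 1.0, exclude_min=False),
        pos=st.one_of(st.none(), st.integers(1, 10**9)),
    )
    def test_write_read_round_trip_exact(self, tmp_path_factory, eaf, beta, se, pval, pos):
        """Every numeric field survives a write/read cycle bit-for-bit."""
        record = rec(eaf=eaf, beta=beta, se=se, pval=pval, pos=pos)
        path = tmp_path_factory.mktemp("rt") / "one.tsv"
        mk.write_sumstats([record], path)
        (back,) = mk.read_sumstats(path)
        assert back == record


class TestZToBeta:
    @settings(deadline=None, max_examples=200)
    @given(z=st.floats(-50, 50, allow_nan=False).filter(lambda z: abs(z) > 1e-8),
           eaf=st.floats(0.001, 0.999), n=st.floats(10, 1e7))
    def test_ratio_identity(self, z, eaf, n):
        """beta / se recovers the Z-score to machine precision."""
        beta, se = mk.z_to_beta(z, eaf, n)
        assert beta / se == pytest.approx(z, rel=1e-12)
        assert se > 0

    def test_null_effect(self):
        beta, se = mk.z_to_beta(0.0, 0.5, 1000)
        assert beta == 0.0
        assert se == pytest.approx(1 / math.sqrt(500), rel=1e-12)

    def test_degenerate_frequency(self):
        with pytest.raises(DegenerateFrequencyError):
            mk.z_to_beta(1.0, 0.0, 1000)

    def test_sample_size_recovered_by_bisection_matches_published_se(self):
        """Solving for the n that reproduces rs672413's published beta
        yields an se matching its published se — the conversion is the
        one used to derive the panel's exposure effects."""
        z, eaf, beta_target = 7.53, 0.32, 0.164418
        lo, hi = 10.0, 1e8
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            beta, _ = mk.z_to_beta(z, eaf, mid)
            # beta decreases with n
            if beta > beta_target:
                lo = mid
            else:
                hi = mid
        n_solved = 0.5 * (lo + hi)
        beta, se = mk.z_to_beta(z, eaf, n_solved)
        assert beta == pytest.approx(0.164418, abs=1e-6)
        assert se == pytest.approx(0.021835, abs=1e-4)


class TestPalindrome:
    @pytest.mark.parametrize("ea,oa,expected", [
        ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
        ("T", "C", False), ("A", "G", False), ("T", "G", False), ("G", "A", False),
    ])
    def test_definition(self, ea, oa, expected):
        assert mk.detect_palindrome(ea, oa) is expected

    def test_fixture_panel_is_entirely_non_palindromic(self):
        table = mk.selenium_table()
        assert not any(mk.detect_palindrome(r.effect_allele, r.other_allele)
                       for r in table.itertuples())

    def test_non_acgt_allele_rejected(self):
        with pytest.raises(UnsupportedAlleleError):
            mk.detect_palindrome("A", "N")


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = [rec(ea="A", oa="G", beta=0.2)]
        out = [rec(ea="G", oa="A", beta=0.001, eaf=0.7)]
        result = mk.harmonize(exp, out)
        assert len(result) == 1
        row = result.iloc[0]
        assert row.beta_out == -0.001
        assert row.flipped
        assert row.beta_exp == 0.2

    def test_strand_complement_alignment(self):
        # outcome reported on the opposite strand: A/G vs T/C is the same variant
        exp = [rec(ea="A", oa="G", beta=0.2)]
        out = [rec(ea="T", oa="C", beta=0.003)]
        result = mk.harmonize(exp, out)
        assert len(result) == 1
        assert result.iloc[0].beta_out == 0.003
        assert not result.iloc[0].flipped

    def test_fixture_already_aligned_no_flips(self, selenium_records):
        exposure, egfr, _ = selenium_records
        result = mk.harmonize(exposure, egfr)
        assert len(result) == 11
        assert not result["flipped"].any()

    def test_palindromic_dropped_under_default_policy(self):
        exp = [rec(ea="A", oa="T", beta=0.2), rec(snp="rs2", ea="T", oa="C")]
        out = [rec(ea="A", oa="T", beta=0.1), rec(snp="rs2", ea="T", oa="C")]
        result = mk.harmonize(exp, out)
        assert list(result.snp_id) == ["rs2"]

    def test_palindromic_inferred_from_frequency(self):
        # eaf 0.2 vs 0.8: opposite strands, effect must flip
        exp = [rec(ea="A", oa="T", eaf=0.2, beta=0.2)]
        out = [rec(ea="A", oa="T", eaf=0.8, beta=0.05)]
        result = mk.harmonize(exp, out, palindrome_policy="infer")
        assert result.iloc[0].beta_out == -0.05
        # ambiguous frequency: dropped even in infer mode
        out_amb = [rec(ea="A", oa="T", eaf=0.5, beta=0.05)]
        assert mk.harmonize(exp, out_amb, palindrome_policy="infer").empty

    def test_irreconcilable_alleles_dropped(self):
        exp = [rec(ea="A", oa="G")]
        out = [rec(ea="A", oa="C")]
        assert mk.harmonize(exp, out).empty

    def test_snp_absent_from_outcome_dropped(self, selenium_records):
        exposure, egfr, _ = selenium_records
        result = mk.harmonize(exposure, egfr[:-1])
        assert len(result) == 10

    def test_sign_equivariance_under_outcome_recoding(self, selenium_records):
        """Swapping every outcome allele pair and negating its betas is the
        same data in the other coding: harmonization must undo it."""
        import dataclasses

        exposure, egfr, _ = selenium_records
        recoded = [
            dataclasses.replace(r, effect_allele=r.other_allele,
                                other_allele=r.effect_allele,
                                beta=-r.beta, eaf=1.0 - r.eaf)
            for r in egfr
        ]
        direct = mk.harmonize(exposure, egfr)
        undone = mk.harmonize(exposure, recoded)
        assert np.allclose(direct.beta_out, undone.beta_out)
        assert undone["flipped"].all()


class TestLdClump:
    def _ld(self, pairs):
        table = mk.LdTable()
        for a, b, r2 in pairs:
            table.set(a, b, r2)
        return table

    def test_weaker_of_two_linked_snps_removed(self):
        records = [rec(snp="rs1", pos=1000, pval=1e-20),
                   rec(snp="rs2", pos=2000, pval=1e-9)]
        ld = self._ld([("rs1", "rs2", 0.5)])
        kept = mk.ld_clump(records, ld, r2_max=0.3)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_different_chromosomes_never_clumped(self):
        records = [rec(snp="rs1", chrom="1", pos=1000, pval=1e-20),
                   rec(snp="rs2", chrom="2", pos=1000, pval=1e-9)]
        ld = self._ld([("rs1", "rs2", 0.99)])
        assert len(mk.ld_clump(records, ld, r2_max=0.3)) == 2

    def test_outside_window_not_clumped(self):
        records = [rec(snp="rs1", pos=0, pval=1e-20),
                   rec(snp="rs2", pos=11_000_000, pval=1e-9)]
        ld = self._ld([("rs1", "rs2", 0.99)])
        assert len(mk.ld_clump(records, ld, r2_max=0.3, window=10_000_000)) == 2

    def test_missing_positions_raise_for_finite_window(self):
        with pytest.raises(ConfigurationError):
            mk.ld_clump([rec(snp="rs1")], mk.LdTable(), window=1000)

    def test_matches_independent_greedy_oracle(self):
        """Against a simple quadratic-time re-implementation on random LD
        structures: same kept set, and the kept set is always pairwise
        independent at the threshold."""
        rng = np.random.default_rng(12345)
        for trial in range(25):
            k = 6
            records = [rec(snp=f"rs{i}", pos=int(rng.integers(0, 5000)),
                           pval=float(rng.uniform(1e-30, 1e-8))) for i in range(k)]
            ld = mk.LdTable()
            r2s = {}
            for i in range(k):
                for j in range(i + 1, k):
                    r2 = float(rng.uniform(0, 1))
                    ld.set(f"rs{i}", f"rs{j}", r2)
                    r2s[(i, j)] = r2

            def linked(i, j, thr=0.3, win=2000):
                a, b = records[i], records[j]
                if abs(a.pos - b.pos) > win:
                    return False
                return r2s[(min(i, j), max(i, j))] >= thr

            oracle = []
            for i in sorted(range(k), key=lambda i: (records[i].pval, records[i].snp_id)):
                if all(not linked(i, j) for j in oracle):
                    oracle.append(i)
            expected = [records[i].snp_id for i in sorted(oracle)]

            kept = mk.ld_clump(records, ld, r2_max=0.3, window=2000)
            assert [r.snp_id for r in kept] == expected
            idx = {r.snp_id: i for i, r in enumerate(records)}
            for a in kept:
                for b in kept:
                    if a.snp_id < b.snp_id:
                        assert not linked(idx[a.snp_id], idx[b.snp_id])

    def test_ld_table_round_trip(self, tmp_path):
        ld = self._ld([("rs1", "rs2", 0.53), ("rs2", "rs3", 0.11)])
        path = tmp_path / "ld.tsv"
        ld.to_tsv(path)
        back = mk.LdTable.from_tsv(path)
        assert back.get("rs2", "rs1") == 0.53
        assert back.get("rs1", "rs1") == 1.0
        assert back.get("rs1", "rs99") == 0.0  # missing -> independent


class TestFilters:
    def test_significance_filter(self):
        records = [rec(snp="rs1", pval=1e-9), rec(snp="rs2", pval=1e-7)]
        assert [r.snp_id for r in mk.filter_significant(records)] == ["rs1"]

    def test_egfr_outcome_exclusion_removes_confounded_snp(self, egfr_all):
        kept, excluded = mk.exclude_outcome_associated(egfr_all)
        assert len(kept) == 10
        assert list(excluded.snp_id) == ["rs921943"]

    def test_bun_outcome_exclusion_removes_nothing(self, bun_all):
        kept, excluded = mk.exclude_outcome_associated(bun_all)
        assert len(kept) == 11
        assert excluded.empty

    def test_empty_instruments(self, egfr_all):
        empty = egfr_all.iloc[0:0]
        kept, excluded = mk.exclude_outcome_associated(empty)
        assert kept.empty and excluded.empty


def test_complement_table_is_involutive():
    for a, b in COMPLEMENT.items():
        assert COMPLEMENT[b] == a
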