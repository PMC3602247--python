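"""QC statistics: counts, call rate, MAF, replicates, the HWE chi-square.

The HWE oracle recomputes expected genotype counts from the allele counts
with plain arithmetic, independent of the implementation's code path, and
the p-value via the closed form erfc(sqrt(x/2)) for a 1-df chi-square.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpqc.errors import MultiAllelicError
from snpqc.genotype_core import SampleCall, SNPCallSet, WellAddress, normalize_genotype
from snpqc.genotype_core import collect_replicates
from snpqc.qc_stats import (
    GenotypeCounts,
    build_qc_report,
    call_rate,
    genotype_counts,
    hwe_chisq,
    minor_allele_freq,
    replicate_summary,
)


def hwe_oracle(n_aa, n_ab, n_bb):
    """Brute-force HWE chi-square from allele counts (independent route)."""
    n = n_aa + n_ab + n_bb
    count_a = 2 * n_aa + n_ab
    if count_a == 0 or count_a == 2 * n:
        return 0.0, None
    p = count_a / (2 * n)
    expected = [n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)]
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n_aa, n_ab, n_bb), expected))
    return chi2, math.erfc(math.sqrt(chi2 / 2))


class TestGenotypeCounts:
    def test_simple_column(self):
        counts = genotype_counts(["A/A"] * 25 + ["A/G"] * 50 + ["G/G"] * 25)
        assert counts.as_triple() == (25, 50, 25)
        assert (counts.allele1, counts.allele2) == ("A", "G")
        assert counts.n_missing == 0

    def test_all_missing_column(self):
        counts = genotype_counts(["0/0"] * 10)
        assert counts.as_triple() == (0, 0, 0) and counts.n_missing == 10

    def test_multiallelic_rejected(self):
        with pytest.raises(MultiAllelicError):
            genotype_counts(["A/A", "C/G"])

    def test_declared_alleles_orient_monomorphic_column(self):
        counts = genotype_counts(["G/G"] * 50, alleles=("A", "G"))
        assert counts.as_triple() == (0, 0, 50)


class TestCallRate:
    def test_complete_and_empty(self):
        assert call_rate(genotype_counts(["A/A"] * 4)) == 1.0
        assert call_rate(genotype_counts(["0/0"] * 10)) == 0.0
        assert call_rate(GenotypeCounts(0, 0, 0, None, None, 0)) is None

    def test_absent_sample_counts_in_denominator(self):
        """8 called of a 10-sample manifest (1 absent, 1 no-call) -> 0.8."""
        column = ["A/A"] * 4 + ["A/G"] * 4 + ["0/0", "0/0"]
        assert call_rate(genotype_counts(column)) == pytest.approx(0.8)


class TestMaf:
    def test_symmetric_column_ties_to_first_allele(self):
        maf, minor = minor_allele_freq(genotype_counts(
            ["A/A"] * 25 + ["A/G"] * 50 + ["G/G"] * 25))
        assert maf == pytest.approx(0.5) and minor == "A"

    def test_hand_counted_frequency(self):
        # 90 AA + 10 AB: 190 A alleles vs 10 G alleles of 200
        maf, minor = minor_allele_freq(genotype_counts(
            ["A/A"] * 90 + ["A/G"] * 10))
        assert maf == pytest.approx(0.05) and minor == "G"

    def test_monomorphic(self):
        maf, minor = minor_allele_freq(genotype_counts(["G/G"] * 50, alleles=("A", "G")))
        assert maf == 0.0 and minor == "A"

    def test_all_missing_undefined(self):
        assert minor_allele_freq(genotype_counts(["0/0"] * 3)) == (None, None)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(deadline=None)
    def test_maf_bounded_and_order_invariant(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        column = ["A/A"] * n_aa + ["A/G"] * n_ab + ["G/G"] * n_bb
        maf, _ = minor_allele_freq(genotype_counts(column, alleles=("A", "G")))
        assert 0.0 <= maf <= 0.5
        maf_rev, _ = minor_allele_freq(genotype_counts(column[::-1], alleles=("A", "G")))
        assert maf == maf_rev


def _groups(spec):
    """spec: list of genotype-string lists, one per sample."""
    calls = []
    for i, genos in enumerate(spec):
        for j, g in enumerate(genos):
            calls.append(SampleCall(f"S{i}", "p", WellAddress("A", len(calls) + 1),
                                    normalize_genotype(g)))
    return collect_replicates(SNPCallSet("rs1", "rs1", calls))


class TestReplicateSummary:
    def test_hand_enumerated_mixture(self):
        """Three duplicated samples: one clean pair, one pair with a missing
        call, one discordant pair -> expected 3, real 2, discordant 1."""
        groups = _groups([["A/G", "A/G"], ["A/G", "0/0"], ["A/G", "G/G"]])
        summary = replicate_summary(groups)
        assert (summary.expected, summary.real, summary.discordant) == (3, 2, 1)
        assert summary.discordance_rate == pytest.approx(0.5)

    def test_no_replicates(self):
        summary = replicate_summary(_groups([["A/G"], ["A/A"]]))
        assert (summary.expected, summary.real, summary.discordant) == (0, 0, 0)
        assert summary.discordance_rate is None

    def test_all_concordant(self):
        summary = replicate_summary(_groups([["A/G", "A/G"]] * 4))
        assert (summary.expected, summary.real, summary.discordant,
                summary.discordance_rate) == (4, 4, 0, 0.0)

    def test_discordant_bounded_by_real_bounded_by_expected(self):
        groups = _groups([["A/G", "A/G"], ["A/G", "0/0"], ["A/G", "G/G"],
                          ["A/A"], ["0/0", "0/0"]])
        s = replicate_summary(groups)
        assert s.discordant <= s.real <= s.expected


class TestHwe:
    def test_exact_equilibrium(self):
        chi2, p = hwe_chisq(GenotypeCounts(25, 50, 25, "A", "G"))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_known_deviation(self):
        """(30,40,30): expected (25,50,25) -> chi2 = 1+2+1 = 4."""
        chi2, p = hwe_chisq(GenotypeCounts(30, 40, 30, "A", "G"))
        assert chi2 == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(math.erfc(math.sqrt(2.0)), rel=1e-9)

    def test_monomorphic_undefined_p(self):
        chi2, p = hwe_chisq(GenotypeCounts(50, 0, 0, "A", "G"))
        assert chi2 == 0.0 and p is None

    def test_empty_undefined(self):
        assert hwe_chisq(GenotypeCounts(0, 0, 0, "A", "G", 5)) == (None, None)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(deadline=None, max_examples=300)
    def test_matches_bruteforce_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        chi2, p = hwe_chisq(GenotypeCounts(n_aa, n_ab, n_bb, "A", "G"))
        exp_chi2, exp_p = hwe_oracle(n_aa, n_ab, n_bb)
        assert chi2 == pytest.approx(exp_chi2, abs=1e-9)
        if exp_p is None:
            assert p is None
        else:
            assert p == pytest.approx(exp_p, abs=1e-9)


class TestQcReport:
    def test_composed_report(self):
        groups = _groups([["A/G", "A/G"], ["A/A"], ["G/G"]])
        column = ["A/G", "A/A", "G/G", "0/0"]
        report = build_qc_report("rs1", column, groups, alleles=("A", "G"),
                                 operator="op", comment="c")
        assert report.snp_id == "rs1"
        assert report.call_rate == pytest.approx(0.75)
        assert report.expected_replicates == 1
        assert report.discordant_replicates == 0
        assert report.maf is not None and report.hwe_p is not None

    def test_monomorphic_report_has_undefined_hwe_p(self):
        report = build_qc_report("rs1", ["A/A"] * 5, [], alleles=("A", "G"))
        assert report.hwe_p is None and report.maf == 0.0

    def test_no_replicates_rate_undefined(self):
        report = build_qc_report("rs1", ["A/G"] * 3, _groups([["A/G"]]))
        assert report.discordance_rate is None
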