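"""Allele summaries, Hardy-Weinberg testing, case-control contingency
tests, and inheritance-model coding."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from obesnp import refdata
from obesnp.genetics import (
    GenotypeCounts,
    allele_counts,
    case_control_allele_test,
    case_control_genotype_test,
    encode,
    encode_array,
    hwe_test,
    snp_association_table,
)
from obesnp.prevalence import pearson_chisq

genotype_counts = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
).filter(lambda t: sum(t) > 0)


class TestAlleleCounts:
    def test_case_group_effect_frequencies(self):
        _, n_c, freq_c = allele_counts(refdata.CASE_GENOTYPES["rs17782313"])
        assert n_c == 175
        assert round(100 * freq_c, 2) == 27.43
        _, n_a, freq_a = allele_counts(refdata.CASE_GENOTYPES["rs12970134"])
        assert n_a == 152
        assert round(100 * freq_a, 2) == 23.82

    def test_monomorphic_has_zero_effect_frequency(self):
        _, n_eff, freq = allele_counts(GenotypeCounts("x", 50, 0, 0))
        assert n_eff == 0 and freq == 0.0

    @given(genotype_counts)
    def test_alleles_conserved(self, counts):
        gc = GenotypeCounts("x", *counts)
        n_ref, n_eff, _ = allele_counts(gc)
        assert n_ref + n_eff == 2 * gc.total


class TestHweTest:
    @pytest.mark.parametrize(
        "snp, expected_p",
        [("rs17782313", 0.9091), ("rs1121980", 0.2614), ("rs12970134", 0.7177), ("rs17817449", 0.4469)],
    )
    def test_control_group_reference_values(self, snp, expected_p):
        _, p = hwe_test(refdata.CONTROL_GENOTYPES[snp])
        assert round(p, 4) == expected_p

    def test_exact_equilibrium(self):
        chi2, p = hwe_test(GenotypeCounts("x", 25, 50, 25))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_test(GenotypeCounts("x", 100, 0, 0))

    def test_p_uniform_under_equilibrium(self):
        """Under HWE the asymptotic p-value is ~Uniform(0,1): the empirical
        CDF over 1e4 simulated replicates stays within the DKW band (plus an
        asymptotic allowance)."""
        rng = np.random.default_rng(0)
        n, q, reps = 500, 0.3, 10_000
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        draws = rng.multinomial(n, probs, size=reps)
        ps = [
            hwe_test(GenotypeCounts("x", *row))[1]
            for row in draws
            if row[0] < n and row[2] < n
        ]
        ks = stats.kstest(ps, "uniform").statistic
        dkw = np.sqrt(np.log(2 / 0.001) / (2 * len(ps)))
        assert ks < dkw + 0.01


class TestCaseControlTests:
    def test_genotype_comparison_reference_values(self):
        _, df, p = case_control_genotype_test(
            refdata.CASE_GENOTYPES["rs17782313"], refdata.CONTROL_GENOTYPES["rs17782313"]
        )
        assert df == 2 and round(p, 4) == 0.2157
        _, _, p = case_control_genotype_test(
            refdata.CASE_GENOTYPES["rs17817449"], refdata.CONTROL_GENOTYPES["rs17817449"]
        )
        assert round(p, 4) == 0.7031

    def test_identical_distributions_give_p_one(self):
        gc = GenotypeCounts("x", 100, 60, 10)
        chi2, _, p = case_control_genotype_test(gc, gc)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
        chi2, _, p, odds = case_control_allele_test(gc, gc)
        assert p == pytest.approx(1.0) and odds == pytest.approx(1.0)

    def test_allele_comparison_reference_values(self):
        _, df, p, _ = case_control_allele_test(
            refdata.CASE_GENOTYPES["rs17782313"], refdata.CONTROL_GENOTYPES["rs17782313"]
        )
        assert df == 1 and round(p, 4) == 0.1082
        _, _, p, _ = case_control_allele_test(
            refdata.CASE_GENOTYPES["rs12970134"], refdata.CONTROL_GENOTYPES["rs12970134"]
        )
        assert round(p, 4) == 0.1202

    @given(genotype_counts, genotype_counts)
    def test_allele_test_consistent_with_explicit_table(self, c_case, c_ctrl):
        """The allele test equals the generic Pearson test applied to the
        explicitly constructed 2x2 allele table."""
        gc_case, gc_ctrl = GenotypeCounts("x", *c_case), GenotypeCounts("x", *c_ctrl)
        case_ref, case_eff, _ = allele_counts(gc_case)
        ctrl_ref, ctrl_eff, _ = allele_counts(gc_ctrl)
        table = [[case_ref, case_eff], [ctrl_ref, ctrl_eff]]
        try:
            expected = pearson_chisq(table)
        except ValueError:
            return
        chi2, _, p, _ = case_control_allele_test(gc_case, gc_ctrl)
        assert chi2 == pytest.approx(expected[0], rel=1e-9)
        assert p == pytest.approx(expected[2], rel=1e-9)

    def test_zero_cell_or_uses_haldane_correction(self):
        gc_case = GenotypeCounts("x", 50, 0, 0)
        gc_ctrl = GenotypeCounts("x", 40, 10, 0)
        _, _, _, odds = case_control_allele_test(gc_case, gc_ctrl)
        assert odds == pytest.approx((0.5 * 90.5) / (100.5 * 10.5))


class TestInheritanceCoding:
    @pytest.mark.parametrize(
        "count, model, expected",
        [
            (0, "dominant", 0), (1, "dominant", 1), (2, "dominant", 1),
            (0, "recessive", 0), (1, "recessive", 0), (2, "recessive", 1),
            (0, "additive", 0), (1, "additive", 1), (2, "additive", 2),
            (0, "codominant", (0, 0)), (1, "codominant", (1, 0)), (2, "codominant", (0, 1)),
        ],
    )
    def test_design_values(self, count, model, expected):
        assert encode(count, model) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            encode(3, "dominant")
        with pytest.raises(ValueError):
            encode(1, "overdominant")

    def test_vectorized_matches_scalar(self):
        g = [0, 1, 2, 1]
        for model in ("dominant", "recessive", "additive"):
            assert encode_array(g, model).tolist() == [encode(c, model) for c in g]
        assert encode_array(g, "codominant").tolist() == [
            list(encode(c, "codominant")) for c in g
        ]


def test_association_table_reproduces_reference_columns():
    table = snp_association_table(refdata.CASE_GENOTYPES, refdata.CONTROL_GENOTYPES)
    by_snp = table.set_index("snp")
    assert round(by_snp.loc["rs17782313", "genotype_p"], 4) == 0.2157
    assert round(by_snp.loc["rs12970134", "genotype_p"], 4) == 0.2661
    assert round(by_snp.loc["rs1121980", "allele_p"], 4) == 0.4293
    assert round(by_snp.loc["rs17817449", "allele_p"], 4) == 0.5010
    assert round(by_snp.loc["rs12970134", "hwe_p"], 4) == 0.7177
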