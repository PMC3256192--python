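import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdrkit import (DataError, GenotypeCountTable, TwoByTwo,
                    adjusted_odds_ratio, collapse, crude_odds_ratio,
                    fisher_exact_p, hwe_test, ld_pairwise, tabulate)
from mdrkit.data import MISSING
from mdrkit.simulate import simulate_genotypes_hwe

from conftest import make_dataset


def exact_fisher_two_sided(a, b, c, d):
    """Enumeration oracle in exact rational arithmetic (point-probability)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    total = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(n - r1, c1 - a), total)
    p = Fraction(0)
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        px = Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), total)
        if px <= p_obs:
            p += px
    return float(p)


class TestCollapse:
    @pytest.fixture
    def sult(self):
        return GenotypeCountTable(np.array([[132, 60], [60, 43], [2, 6]]))

    def test_dominant(self, sult):
        assert collapse(sult, "dominant") == TwoByTwo(49, 60, 62, 132)

    def test_extreme(self, sult):
        assert collapse(sult, "extreme") == TwoByTwo(6, 60, 2, 132)

    def test_heterozygous(self, sult):
        assert collapse(sult, "heterozygous") == TwoByTwo(43, 60, 60, 132)

    def test_zero_cells_preserved(self):
        t = GenotypeCountTable(np.array([[10, 5], [3, 2], [0, 0]]))
        c = collapse(t, "extreme")
        assert c.a == 0 and c.c == 0

    def test_dominant_margins_are_het_plus_extreme(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = GenotypeCountTable(rng.integers(0, 30, (3, 2)))
            dom = collapse(t, "dominant")
            het = collapse(t, "heterozygous")
            ext = collapse(t, "extreme")
            assert dom.a == het.a + ext.a
            assert dom.c == het.c + ext.c


class TestCrudeOddsRatio:
    def test_published_dominant_value(self):
        r = crude_odds_ratio(TwoByTwo(49, 60, 62, 132))
        assert round(r.or_estimate, 2) == 1.74

    def test_published_extreme_value(self):
        r = crude_odds_ratio(TwoByTwo(6, 60, 2, 132))
        assert round(r.or_estimate, 2) == 6.6

    def test_balanced_table_symmetric_ci(self):
        r = crude_odds_ratio(TwoByTwo(10, 10, 10, 10))
        assert r.or_estimate == pytest.approx(1.0)
        assert r.ci_low * r.ci_high == pytest.approx(1.0)

    def test_haldane_correction_frozen_value(self):
        # (0.5 * 132.5) / (60.5 * 2.5), hand-computed cross product
        r = crude_odds_ratio(TwoByTwo(0, 60, 2, 132), "haldane")
        assert r.or_estimate == pytest.approx(0.4380165289256198)
        assert r.zero_corrected

    def test_uncorrected_zero_reports_zero_with_finite_upper(self):
        r = crude_odds_ratio(TwoByTwo(0, 60, 2, 132))
        assert r.or_estimate == 0.0
        assert r.ci_low == 0.0
        assert 0 < r.ci_high < math.inf

    def test_double_diagonal_zero_undefined(self):
        with pytest.raises(DataError):
            crude_odds_ratio(TwoByTwo(0, 5, 7, 0))

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_exposure_relabel_inverts_or(self, cells):
        a, b, c, d = cells
        r1 = crude_odds_ratio(TwoByTwo(a, b, c, d))
        r2 = crude_odds_ratio(TwoByTwo(b, a, d, c))
        assert r1.or_estimate * r2.or_estimate == pytest.approx(1.0)


class TestFisherExact:
    def test_published_p_value(self):
        p = fisher_exact_p(TwoByTwo(6, 60, 2, 132))
        assert p == pytest.approx(0.017, abs=0.005)

    def test_no_association_gives_p_one(self):
        assert fisher_exact_p(TwoByTwo(10, 10, 10, 10)) >= 0.99

    def test_matches_rational_enumeration_small_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 6, 4)
            if (a + c == 0) or (b + d == 0) or (a + b + c + d) == 0:
                continue
            expect = exact_fisher_two_sided(int(a), int(b), int(c), int(d))
            got = fisher_exact_p(TwoByTwo(int(a), int(b), int(c), int(d)))
            assert got == pytest.approx(expect, rel=1e-9)

    def test_mid_p_is_smaller(self):
        t = TwoByTwo(6, 60, 2, 132)
        assert fisher_exact_p(t, mid_p=True) < fisher_exact_p(t)


class TestAdjustedOddsRatio:
    def test_exposure_only_logistic_equals_crude(self):
        # saturated 2x2 logistic identity
        values = np.array([[1]] * 30 + [[0]] * 20 + [[1]] * 15 + [[0]] * 35,
                          dtype=np.int16)
        status = [1] * 50 + [0] * 50
        ds = make_dataset(values, status)
        r = adjusted_odds_ratio(ds, "S1", "dominant", covariates=())
        crude = crude_odds_ratio(TwoByTwo(30, 20, 15, 35))
        assert r.or_estimate == pytest.approx(crude.or_estimate, rel=1e-5)

    def test_constant_covariate_leaves_or_unchanged(self):
        import pandas as pd
        values = np.array([[1]] * 30 + [[0]] * 20 + [[1]] * 15 + [[0]] * 35,
                          dtype=np.int16)
        status = [1] * 50 + [0] * 50
        ds = make_dataset(values, status)
        ds.covariates = pd.DataFrame({"age": [50.0] * 100})
        r0 = adjusted_odds_ratio(ds, "S1", "dominant", covariates=())
        r1 = adjusted_odds_ratio(ds, "S1", "dominant", covariates=("age",))
        assert r1.or_estimate == pytest.approx(r0.or_estimate, rel=1e-5)

    def test_recovers_known_conditional_or(self):
        # dominant carrier effect with population OR 2.0 at the logit scale
        import pandas as pd
        rng = np.random.default_rng(11)
        n = 2000
        g = simulate_genotypes_hwe(n, 0.3, rng)
        x = (g >= 1).astype(float)
        age = rng.normal(50, 10, n)
        logit = -1.2 + math.log(2.0) * x + 0.01 * (age - 50)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        ds = make_dataset(g.reshape(-1, 1), y)
        ds.covariates = pd.DataFrame({"age": age})
        r = adjusted_odds_ratio(ds, "S1", "dominant", covariates=("age",))
        assert r.converged
        assert abs(r.or_estimate - 2.0) < 0.25

    def test_separation_flagged(self):
        values = np.array([[1]] * 10 + [[0]] * 10, dtype=np.int16)
        status = [1] * 10 + [0] * 10
        ds = make_dataset(values, status)
        r = adjusted_odds_ratio(ds, "S1", "dominant", covariates=())
        assert not r.converged
        assert math.isnan(r.or_estimate)


class TestHWE:
    def test_exact_hw_proportions_give_zero(self):
        r = hwe_test((25, 50, 25))
        assert r.chi_square == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_monomorphic_rule(self):
        r = hwe_test((100, 0, 0))
        assert r.chi_square == 0.0 and r.p_value == 1.0

    def test_control_panel_matches_spreadsheet_oracle(self):
        # frozen from an independent p/q/expected-counts computation
        r = hwe_test((132, 60, 2))
        assert r.chi_square == pytest.approx(2.9200210048010975, abs=1e-6)
        assert r.p_value == pytest.approx(0.08748672509827043, abs=1e-6)
        assert r.variant_freq == pytest.approx(64 / 388)

    def test_expected_counts_sum_to_total(self):
        r = hwe_test((132, 60, 2))
        assert sum(r.expected) == pytest.approx(194)

    def test_scale_invariance(self):
        r1 = hwe_test((30, 40, 30))
        r5 = hwe_test((150, 200, 150))
        assert r5.chi_square == pytest.approx(5 * r1.chi_square)

    def test_zero_iff_exact_hw(self):
        assert hwe_test((49, 42, 9)).chi_square == pytest.approx(0, abs=1e-12)
        assert hwe_test((50, 40, 10)).chi_square > 0


class TestLD:
    def test_duplicated_snp_perfect_ld(self, rng):
        g = simulate_genotypes_hwe(300, 0.3, rng)
        ds = make_dataset(np.column_stack([g, g]),
                          rng.integers(0, 2, 300))
        r = ld_pairwise(ds, "S1", "S2")
        assert r.d_prime == pytest.approx(1.0, abs=1e-6)
        assert r.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_independent_snps_low_r2(self):
        rng = np.random.default_rng(3)
        a = simulate_genotypes_hwe(5000, 0.3, rng)
        b = simulate_genotypes_hwe(5000, 0.4, rng)
        ds = make_dataset(np.column_stack([a, b]),
                          rng.integers(0, 2, 5000))
        r = ld_pairwise(ds, "S1", "S2")
        assert r.r_squared < 0.01

    def test_em_matches_direct_count_without_double_hets(self):
        # genotypes with no (1,1) pair: phase is unambiguous
        pairs = [(0, 0)] * 30 + [(1, 0)] * 20 + [(0, 2)] * 10 + [(2, 2)] * 5
        values = np.array(pairs, dtype=np.int16)
        ds = make_dataset(values, [0] * len(pairs))
        r = ld_pairwise(ds, "S1", "S2")
        # direct haplotype counts: each subject contributes two phased haplotypes
        n_hap = 2 * len(pairs)
        counts = {(0, 0): 0.0, (0, 1): 0.0, (1, 0): 0.0, (1, 1): 0.0}
        for ga, gb in pairs:
            if ga == 1:
                counts[(0, gb // 2)] += 1
                counts[(1, gb // 2)] += 1
            elif gb == 1:
                counts[(ga // 2, 0)] += 1
                counts[(ga // 2, 1)] += 1
            else:
                counts[(ga // 2, gb // 2)] += 2
        for key in counts:
            assert r.haplotype_freqs[key] == pytest.approx(
                counts[key] / n_hap, abs=1e-7)

    def test_monomorphic_flagged_undefined(self):
        values = np.column_stack([np.zeros(50, dtype=np.int16),
                                  np.tile([0, 1, 2, 1, 0], 10)])
        ds = make_dataset(values, [0] * 50)
        r = ld_pairwise(ds, "S1", "S2")
        assert not r.defined

    def test_known_haplotype_frequencies_recovered(self):
        # two-locus haplotypes drawn at known frequencies -> known D'
        rng = np.random.default_rng(12)
        freqs = {(0, 0): 0.5, (0, 1): 0.1, (1, 0): 0.1, (1, 1): 0.3}
        haps = list(freqs)
        p = np.array(list(freqs.values()))
        n = 4000
        h1 = rng.choice(4, n, p=p)
        h2 = rng.choice(4, n, p=p)
        g = np.array([(haps[i][0] + haps[j][0], haps[i][1] + haps[j][1])
                      for i, j in zip(h1, h2)], dtype=np.int16)
        ds = make_dataset(g, [0] * n)
        r = ld_pairwise(ds, "S1", "S2")
        pa, pb = 0.4, 0.4
        d_true = 0.3 - pa * pb
        assert r.d == pytest.approx(d_true, abs=0.02)
        assert r.converged


class TestTabulate:
    def test_missing_excluded_and_order_invariant(self, rng):
        values = np.array([[0], [1], [2], [MISSING], [1]], dtype=np.int16)
        ds = make_dataset(values, [1, 1, 0, 0, 0])
        t = tabulate(ds, "S1")
        assert t.counts.sum() == 4
        perm = rng.permutation(5)
        t2 = tabulate(ds.subset(perm), "S1")
        assert np.array_equal(t.counts, t2.counts)

    def test_empty_dataset_all_zero(self):
        ds = make_dataset(np.zeros((0, 1), dtype=np.int16), [])
        assert tabulate(ds, "S1").counts.sum() == 0
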