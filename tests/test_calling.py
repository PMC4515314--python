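"""Imbalance statistics: exact binomial test, beta-binomial Z,
overdispersion estimation, het-site prediction and call filtering."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import allelign as al
from allelign.calling import (
    BetaBinomialModel,
    beta_binomial_test,
    binomial_pvalue,
    call_imbalance,
    estimate_alpha,
    predict_het_sites,
    read_calls,
    write_calls,
)
from allelign.counting import AlleleCount


def _count(n1, n2, site_class="known_het", i=0):
    return AlleleCount(("chr1", i), "A", "G", n1, n2, 0, site_class)


class TestBinomialPvalue:
    @pytest.mark.parametrize(
        "a1,n,expected",
        [
            (27, 33, "3.2e-04"),  # 27 vs 6 reads
            (30, 39, "1.1e-03"),  # 30 vs 9 reads
        ],
    )
    def test_worked_examples_two_significant_figures(self, a1, n, expected):
        assert f"{binomial_pvalue(a1, n):.1e}" == expected

    def test_balanced_site_is_one(self):
        assert binomial_pvalue(5, 10) == 1.0

    def test_extreme_tail_exact(self):
        # all ten reads one allele: 2 of the 1024 outcomes are as extreme
        assert binomial_pvalue(0, 10) == Fraction(2, 1024)
        assert binomial_pvalue(10, 10) == Fraction(2, 1024)

    def test_symmetry(self):
        for n in (7, 12, 33):
            for a1 in range(n + 1):
                assert binomial_pvalue(a1, n) == binomial_pvalue(n - a1, n)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            binomial_pvalue(0, 0)

    def test_large_n_branch_matches_exact_tail_sum(self):
        # above the big-integer cutoff the scipy tail path takes over;
        # check it against a direct exact computation
        expected = 2 * sum(math.comb(2000, k) for k in range(1130, 2001)) / 2**2000
        assert binomial_pvalue(1130, 2000) == pytest.approx(expected, rel=1e-9)


class TestBetaBinomialTest:
    def test_hand_evaluated_z(self):
        z, _ = beta_binomial_test(9, 10, BetaBinomialModel(1.0))
        assert round(z, 4) == 1.2649

    def test_null_center_is_zero(self):
        z, p = beta_binomial_test(5, 10, BetaBinomialModel(1.0))
        assert z == 0.0
        assert p == 1.0

    def test_infinite_alpha_reduces_to_binomial_z(self):
        for a1, n in [(9, 10), (30, 39), (27, 33)]:
            z, _ = beta_binomial_test(a1, n, BetaBinomialModel(math.inf))
            assert z == pytest.approx((a1 / n - 0.5) * 2 * math.sqrt(n))

    def test_overdispersion_shrinks_z(self):
        z_binom, _ = beta_binomial_test(40, 50, BetaBinomialModel(math.inf))
        z_od, _ = beta_binomial_test(40, 50, BetaBinomialModel(2.0))
        assert abs(z_od) < abs(z_binom)


class TestEstimateAlpha:
    def test_recovers_known_alpha(self):
        counts = al.simulate_overdispersed_counts(2000, 50, alpha=5.0, seed=7)
        model = estimate_alpha(counts)
        assert model.alpha == pytest.approx(5.0, rel=0.2)

    def test_pure_binomial_gives_sentinel(self):
        counts = al.simulate_overdispersed_counts(2000, 50, alpha=math.inf, seed=7)
        assert math.isinf(estimate_alpha(counts).alpha)

    def test_zero_dispersion_gives_sentinel(self):
        assert math.isinf(estimate_alpha([_count(5, 5, i=0), _count(5, 5, i=1)]).alpha)

    def test_needs_two_sites(self):
        with pytest.raises(ValueError):
            estimate_alpha([_count(5, 5)])

    def test_moment_equation_solved(self):
        """The fitted alpha reproduces the empirical second moment."""
        counts = al.simulate_overdispersed_counts(500, 40, alpha=2.0, seed=3)
        a = estimate_alpha(counts).alpha
        ns = np.array([c.total for c in counts], float)
        v = np.mean([(c.n1 / c.total - 0.5) ** 2 for c in counts])
        assert np.mean((2 * a + ns) / (4 * ns * (2 * a + 1))) == pytest.approx(v, rel=1e-6)


class TestPredictHetSites:
    def _reads_at(self, ref, n_genome, other_bases):
        g = ref.genome["chr1"]
        reads = [
            al.Read(f"g{i}", g[10:40], (40,) * 30) for i in range(n_genome)
        ]
        for i, base in enumerate(other_bases):
            seq = g[10:25] + base + g[26:40]
            reads.append(al.Read(f"o{i}", seq, (40,) * 30))
        aligner = al.AlleleAwareAligner(ref, max_mismatch=1)
        return [a for a in aligner.align_all(reads) if a.status == "unique"]

    @pytest.fixture()
    def plain_ref(self, tiny_ref):
        # same genome, empty sidecar: position 25 is NOT catalogued
        return al.CustomReference(tiny_ref.genome, {})

    def test_five_and_five_predicted(self, plain_ref):
        alns = self._reads_at(plain_ref, 5, "GGGGG")
        assert predict_het_sites(alns, plain_ref) == {("chr1", 25, "A", "G")}

    def test_six_and_four_not_predicted(self, plain_ref):
        alns = self._reads_at(plain_ref, 6, "GGGG")
        assert predict_het_sites(alns, plain_ref) == set()

    def test_split_alternate_alleles_not_predicted(self, plain_ref):
        alns = self._reads_at(plain_ref, 5, "GGGTTT")
        assert predict_het_sites(alns, plain_ref) == set()

    def test_sidecar_sites_excluded(self, tiny_ref):
        alns = self._reads_at(tiny_ref, 5, "GGGGG")
        assert predict_het_sites(alns, tiny_ref) == set()

    def test_low_quality_bases_ignored(self, plain_ref):
        g = plain_ref.genome["chr1"]
        reads = [al.Read(f"g{i}", g[10:40], (40,) * 30) for i in range(5)]
        quals = [40] * 30
        quals[15] = 30  # not > 30
        for i in range(5):
            reads.append(al.Read(f"o{i}", g[10:25] + "G" + g[26:40], tuple(quals)))
        aligner = al.AlleleAwareAligner(plain_ref)
        alns = [a for a in aligner.align_all(reads) if a.status == "unique"]
        assert predict_het_sites(alns, plain_ref) == set()


class TestCallImbalance:
    def test_worked_example_flagged(self):
        (call,) = call_imbalance([_count(27, 6)])
        assert call.imbalanced
        assert call.favored_allele == "A"
        assert call.p_value == pytest.approx(3.2e-4, rel=0.02)

    def test_min_reads_per_allele_gate(self):
        assert call_imbalance([_count(4, 100)]) == []

    def test_complete_imbalance_requires_flag(self):
        counts = [_count(0, 20)]
        assert call_imbalance(counts) == []
        (call,) = call_imbalance(counts, allow_complete=True)
        assert call.imbalanced
        assert call.favored_allele == "G"

    def test_complete_imbalance_not_at_predicted_sites(self):
        counts = [_count(0, 20, site_class="predicted_het")]
        assert call_imbalance(counts, allow_complete=True) == []

    def test_tie_never_imbalanced(self):
        (call,) = call_imbalance([_count(20, 20)], p_threshold=1.1)
        assert not call.imbalanced
        assert call.favored_allele is None

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            call_imbalance([_count(10, 10)], test="bayes")

    @given(t1=st.integers(0, 12), t2=st.integers(0, 12))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_raising_min_reads_never_adds_tested_sites(self, t1, t2):
        counts = [
            _count(n1, n2, i=i)
            for i, (n1, n2) in enumerate([(0, 30), (3, 9), (5, 5), (8, 20), (12, 2), (30, 28)])
        ]
        lo, hi = sorted([t1, t2])
        sites_hi = {c.site for c in call_imbalance(counts, min_reads_per_allele=hi)}
        sites_lo = {c.site for c in call_imbalance(counts, min_reads_per_allele=lo)}
        assert sites_hi <= sites_lo

    def test_beta_binomial_reduces_false_positives_on_overdispersed_null(self):
        counts = al.simulate_overdispersed_counts(3000, 50, alpha=2.0, seed=3)
        fp_binomial = sum(c.imbalanced for c in call_imbalance(counts, test="binomial"))
        fp_bb = sum(c.imbalanced for c in call_imbalance(counts, test="beta_binomial"))
        assert fp_bb < fp_binomial

    def test_calls_round_trip(self, tmp_path):
        calls = call_imbalance([_count(27, 6), _count(12, 9, i=1)])
        path = tmp_path / "calls.tsv"
        write_calls(calls, path)
        back = read_calls(path)
        assert [(c.site, c.n1, c.n2, c.imbalanced) for c in back] == [
            (c.site, c.n1, c.n2, c.imbalanced) for c in calls
        ]
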