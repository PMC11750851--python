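import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kaspkit as kk
from kaspkit.genotype_io import MISSING, GenotypeCall
from kaspkit.popgen_stats import (
    UndefinedStatisticError,
    matrix_locus_stats,
    minor_allele_frequency,
    round_half_up,
)

from conftest import calls_matrix


def C(s):
    return GenotypeCall.from_string(s)


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "calls, expected, n",
        [
            (["AA", "AG", "GG", "AG"], {"A": 0.5, "G": 0.5}, 4),
            (["AA", "AA", "AG"], {"A": 5 / 6, "G": 1 / 6}, 3),
            (["AA", "NN"], {"A": 1.0}, 1),
        ],
    )
    def test_hand_counts(self, calls, expected, n):
        freqs, n_called = kk.allele_frequencies([C(s) for s in calls])
        assert n_called == n
        assert freqs == pytest.approx(expected)

    def test_all_missing_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            kk.allele_frequencies([MISSING, MISSING])


class TestPic:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ({"A": 0.479, "G": 0.521}, 0.375),  # upper endpoint of a core-panel MAF span
            ({"A": 0.125, "G": 0.875}, 0.195),  # lower endpoint
            ({"A": 1.0}, 0.0),
            ({"A": 0.3, "G": 0.7}, 0.3318),  # 1 - 0.58 - 2*0.09*0.49
        ],
    )
    def test_values(self, freqs, expected):
        assert round_half_up(kk.pic(freqs), 4 if expected == 0.3318 else 3) == expected

    def test_biallelic_maximum_exact(self):
        assert kk.pic([0.5, 0.5]) == pytest.approx(0.375, abs=1e-15)
        assert kk.expected_heterozygosity([0.5, 0.5]) == pytest.approx(0.5, abs=1e-15)

    def test_strictly_increasing_in_maf(self):
        mafs = np.linspace(0.01, 0.5, 60)
        vals = [kk.pic([m, 1 - m]) for m in mafs]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=4).map(
            lambda ws: [w / sum(ws) for w in ws]
        )
    )
    def test_agrees_with_bruteforce_double_summation(self, freqs):
        """Independent double-loop evaluation of 1 - sum Pi^2 - sumsum 2Pi^2Pj^2."""
        p = list(freqs)
        brute = 1.0 - sum(x * x for x in p)
        for i in range(len(p)):
            for j in range(i + 1, len(p)):
                brute -= 2.0 * p[i] ** 2 * p[j] ** 2
        assert kk.pic(p) == pytest.approx(brute, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0.001, 0.5))
    def test_bounded_by_expected_heterozygosity(self, maf):
        freqs = [maf, 1 - maf]
        assert kk.pic(freqs) <= kk.expected_heterozygosity(freqs)
        # biallelic identity: PIC = 1-(p^2+q^2)-2p^2q^2, HE = 2pq
        p, q = freqs
        assert kk.expected_heterozygosity(freqs) == pytest.approx(2 * p * q)
        assert kk.pic(freqs) == pytest.approx(1 - p * p - q * q - 2 * p * p * q * q)


class TestHeterozygosityAndBundle:
    @pytest.mark.parametrize(
        "calls, expected",
        [(["AG", "AG"], 1.0), (["AA", "GG"], 0.0), (["AA", "AG", "NN", "AG"], 2 / 3)],
    )
    def test_observed(self, calls, expected):
        assert kk.observed_heterozygosity([C(s) for s in calls]) == pytest.approx(expected)

    def test_endpoint_he_values(self):
        assert round_half_up(kk.expected_heterozygosity([0.479, 0.521]), 3) == 0.499
        assert round_half_up(kk.expected_heterozygosity([0.125, 0.875]), 3) == 0.219

    def test_locus_stats_bundle(self):
        calls = [C(s) for s in ["AA", "AA", "AA", "AA", "AG"]]
        s = kk.locus_stats(calls)
        assert s.n_called == 5
        assert s.maf == pytest.approx(0.1)
        assert s.het_obs == pytest.approx(0.2)
        assert s.fis == pytest.approx(1 - s.het_obs / s.het_exp)
        assert s.ne == pytest.approx(1 / (1 - s.pi_site))
        assert s.pi_site == s.het_exp

    def test_equifrequent_ne_is_two(self):
        s = kk.locus_stats([C("AA"), C("AG"), C("GG"), C("AG")])
        assert s.ne == pytest.approx(2.0)

    def test_monomorphic_locus(self):
        s = kk.locus_stats([C("AA"), C("AA")])
        assert s.pic == 0 and s.het_exp == 0 and s.ne == 1 and s.fis is None
        assert not s.is_polymorphic

    def test_maf_is_second_most_common_allele(self):
        assert minor_allele_frequency({"A": 0.6, "C": 0.3, "G": 0.1}) == pytest.approx(0.3)


class TestPopulationSummary:
    def test_mean_over_loci(self):
        m = calls_matrix([["AG", "AA"], ["AG", "AG"], ["AA", "AA"], ["GG", "AA"]])
        stats = matrix_locus_stats(m)
        summary = kk.population_summary(m)
        assert summary.n_sites == 2
        assert summary.mean_pic == pytest.approx((stats[0].pic + stats[1].pic) / 2)

    def test_all_monomorphic_flagged(self):
        m = calls_matrix([["AA", "CC"], ["AA", "CC"]])
        summary = kk.population_summary(m)
        assert summary.n_polymorphic == 0 and summary.mean_fis is None

    def test_empty_matrix_errors(self):
        m = calls_matrix([[], []])
        with pytest.raises(UndefinedStatisticError):
            kk.population_summary(m)

    def test_simulated_means_match_model_expectation(self):
        """Under F=0, E[HetExp] per locus is 2*p0*q0 and E[HetObs] = (1-f)*2*p0*q0."""
        cfg = kk.SimulationConfig(
            seed=202, n_samples=200, n_loci=800, fst=0.0,
            subpop_sizes=None, inbreeding_f=0.25, missing_rate=0.05,
        )
        matrix, truth = kk.simulate_structured_genotypes(cfg)
        summary = kk.population_summary(matrix)
        p0 = truth.ancestral_freqs
        exp_he = float(np.mean(2 * p0 * (1 - p0)))
        # 3 x Monte-Carlo SE over loci
        se = float(np.std(2 * p0 * (1 - p0)) / np.sqrt(len(p0)))
        assert abs(summary.mean_het_exp - exp_he) < 3 * se + 0.01
        assert abs(summary.mean_het_obs - 0.75 * exp_he) < 3 * se + 0.01
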