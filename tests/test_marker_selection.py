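import numpy as np
import pytest

import kaspkit as kk
from kaspkit.marker_selection import ExactBudgetExceeded, log3_lower_bound

from conftest import calls_matrix


def pairs_1based(pairs):
    return {(a + 1, b + 1) for a, b in pairs}


class TestDiscriminatingPairs:
    def test_missing_never_separates(self):
        m = calls_matrix([["AA"], ["NN"], ["AG"]])
        cov = kk.discriminating_pairs(m)
        assert pairs_1based(cov.coverage[m.loci[0].id]) == {(1, 3)}

    def test_two_genotype_classes_enumerated(self):
        m = calls_matrix([["AA"], ["AA"], ["TT"], ["TT"]])
        cov = kk.discriminating_pairs(m)
        assert pairs_1based(cov.coverage[m.loci[0].id]) == {(1, 3), (1, 4), (2, 3), (2, 4)}

    def test_identical_column_covers_nothing(self):
        m = calls_matrix([["AA", "AG"], ["AA", "GG"], ["AA", "AA"]])
        cov = kk.discriminating_pairs(m)
        assert cov.coverage[m.loci[0].id] == frozenset()

    def test_universe_excludes_duplicate_pairs(self):
        m = calls_matrix([["AA", "CC"], ["AA", "CC"], ["AG", "CT"]])
        cov = kk.discriminating_pairs(m)
        assert pairs_1based(cov.universe) == {(1, 3), (2, 3)}

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            kk.discriminating_pairs(calls_matrix([["AA"]]))


class TestDuplicateGroups:
    def test_identical_profiles_grouped(self):
        m = calls_matrix([["AA", "NN"], ["AA", "NN"], ["AG", "CC"]])
        groups = kk.find_duplicate_groups(m)
        assert len(groups) == 1
        assert groups[0].members == ("S1", "S2") and groups[0].representative == "S1"

    def test_missing_does_not_match_a_call(self):
        # S1/S2 differ only where one is missing: unseparable but NOT duplicates
        m = calls_matrix([["AA", "NN"], ["AA", "CC"]])
        assert kk.find_duplicate_groups(m) == []
        cov = kk.discriminating_pairs(m)
        assert cov.universe == frozenset({(0, 1)})  # distinct profiles...
        panel = kk.greedy_min_panel(cov)
        assert panel.residual == frozenset({(0, 1)})  # ...but no locus separates them

    def test_all_distinct(self):
        m = calls_matrix([["AA"], ["AG"], ["GG"]])
        assert kk.find_duplicate_groups(m) == []


class TestGreedyAndExact:
    def test_two_locus_cover(self):
        m = calls_matrix(
            [["AA", "CC"], ["AA", "GG"], ["TT", "CC"], ["TT", "GG"]]
        )
        cov = kk.discriminating_pairs(m)
        greedy = kk.greedy_min_panel(cov)
        exact = kk.exact_min_panel(cov)
        assert set(greedy.loci) == {m.loci[0].id, m.loci[1].id}
        assert greedy.residual == frozenset() and exact.size == 2

    def test_single_triallelic_profile_locus(self):
        m = calls_matrix([["AA"], ["AG"], ["GG"]])
        cov = kk.discriminating_pairs(m)
        assert kk.greedy_min_panel(cov).size == 1
        assert kk.exact_min_panel(cov).size == 1

    def test_all_samples_identical(self):
        m = calls_matrix([["AA", "CC"], ["AA", "CC"]])
        cov = kk.discriminating_pairs(m)
        panel = kk.greedy_min_panel(cov)
        assert panel.size == 0 and panel.residual == frozenset()
        assert len(kk.find_duplicate_groups(m)) == 1

    def test_exact_budget_refused(self):
        rng = np.random.default_rng(0)
        rows = [[rng.choice(["AA", "AG", "GG"]) for _ in range(25)] for _ in range(4)]
        cov = kk.discriminating_pairs(calls_matrix(rows))
        with pytest.raises(ExactBudgetExceeded):
            kk.exact_min_panel(cov, max_loci=20)

    @pytest.mark.parametrize("seed", range(40))
    def test_greedy_feasible_and_bounded_by_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        m_loci = int(rng.integers(3, 9))
        rows = [
            [rng.choice(["AA", "AG", "GG", "NN"], p=[0.35, 0.3, 0.3, 0.05]) for _ in range(m_loci)]
            for _ in range(n)
        ]
        cov = kk.discriminating_pairs(calls_matrix(rows))
        greedy = kk.greedy_min_panel(cov)
        exact = kk.exact_min_panel(cov)
        assert greedy.covered == exact.covered  # everything coverable is covered
        assert greedy.size >= exact.size
        assert greedy.size <= exact.size + 2

    def test_union_plus_residual_equals_universe(self, sim_matrix):
        matrix, _ = sim_matrix
        cov = kk.discriminating_pairs(matrix)
        panel = kk.greedy_min_panel(cov)
        union = frozenset().union(*(cov.coverage[l] for l in panel.loci)) if panel.loci else frozenset()
        assert (union & cov.universe) | panel.residual == cov.universe

    def test_panel_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(5)
        rows = [[rng.choice(["AA", "AG", "GG"]) for _ in range(8)] for _ in range(10)]
        m1 = calls_matrix(rows)
        perm = rng.permutation(10)
        m2 = calls_matrix([rows[i] for i in perm])
        p1 = kk.greedy_min_panel(kk.discriminating_pairs(m1))
        p2 = kk.greedy_min_panel(kk.discriminating_pairs(m2))
        assert set(p1.loci) == set(p2.loci)


class TestVerifyAndCurve:
    def test_log3_bound_for_83_profiles(self):
        assert log3_lower_bound(83) == 5  # 3^4 = 81 < 83 <= 3^5
        assert log3_lower_bound(81) == 4
        assert log3_lower_bound(1) == 0

    def test_greedy_panel_verifies_clean(self, sim_matrix):
        matrix, _ = sim_matrix
        cov = kk.discriminating_pairs(matrix)
        panel = kk.greedy_min_panel(cov)
        ver = kk.verify_panel(matrix, panel)
        assert ver.collisions == []
        assert ver.panel_size >= ver.lower_bound

    def test_truncated_panel_lists_collisions(self, sim_matrix):
        matrix, _ = sim_matrix
        panel = kk.greedy_min_panel(kk.discriminating_pairs(matrix))
        truncated = kk.MarkerPanel(
            loci=panel.loci[:1], covered=frozenset(), residual=frozenset(), gains=[]
        )
        ver = kk.verify_panel(matrix, truncated)
        assert len(ver.collisions) > 0

    def test_efficiency_curve_monotone_and_complete(self, sim_matrix):
        matrix, _ = sim_matrix
        cov = kk.discriminating_pairs(matrix)
        panel = kk.greedy_min_panel(cov)
        curve = kk.efficiency_curve(matrix, panel)
        assert curve[0] == {"n_markers": 0, "distinct_profiles": 1, "pairs_covered_frac": 0.0}
        profs = [r["distinct_profiles"] for r in curve]
        fracs = [r["pairs_covered_frac"] for r in curve]
        assert profs == sorted(profs) and fracs == sorted(fracs)
        ver = kk.verify_panel(matrix, panel)
        assert curve[-1]["distinct_profiles"] == ver.n_distinct_profiles
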