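import numpy as np
import pytest

import kaspkit as kk
from kaspkit.popgen_stats import pic
from kaspkit.snp_filtering import (
    DegenerateWindowError,
    FilterConfigError,
    flank_cleanliness,
    flank_uniqueness,
    reverse_complement,
)

from conftest import calls_matrix


def _with_metadata(matrix, depth=10, qual=50.0):
    for loc in matrix.loci:
        loc.depth_per_sample = np.full(matrix.n_samples, depth)
        loc.qual = qual
    return matrix


class TestPopulationFilter:
    def test_planted_single_rule_violations_attributed_exactly(self):
        cfg = kk.SimulationConfig(
            seed=303, n_loci=60, ancestral_maf_bounds=(0.2, 0.5), fst=0.0,
            subpop_sizes=None, missing_rate=0.05, depth_mean=12.0,
        )
        matrix, truth = kk.simulate_structured_genotypes(cfg)
        rules = ("depth", "maf", "completeness", "qual", "allele_count")
        truth = kk.simulate_locus_metadata(matrix, cfg, planted_rules=rules, truth=truth)
        out, report = kk.population_filter(matrix)
        assert report.n_output == 55
        assert report.first_failed == truth.planted_violations
        assert report.failures_by_rule == {r: 1 for r in rules}
        surviving = {loc.id for loc in out.loci}
        assert surviving.isdisjoint(truth.planted_violations)

    def test_maf_boundary_inclusive(self):
        # one alt copy among 10 samples: MAF = 1/20 = 0.05 exactly -> retained
        rows = [["AG"]] + [["AA"]] * 9
        m = _with_metadata(calls_matrix(rows))
        out, report = kk.population_filter(m)
        assert out.n_loci == 1 and report.failures_by_rule["maf"] == 0

    def test_disabled_criteria_identity(self, sim_matrix):
        matrix, _ = sim_matrix
        crit = kk.FilterCriteria(
            min_mean_depth=None, min_maf=None, min_completeness=None,
            min_qual=None, required_allele_count=None,
        )
        out, report = kk.population_filter(matrix, crit)
        assert out.n_loci == matrix.n_loci and report.n_output == report.n_input

    def test_threshold_without_field_is_config_error(self):
        m = calls_matrix([["AG"], ["AA"]])  # no depth/qual metadata
        with pytest.raises(FilterConfigError):
            kk.population_filter(m)

    def test_report_counts_add_up(self, sim_matrix):
        matrix, _ = sim_matrix
        out, report = kk.population_filter(matrix)
        assert report.n_output + sum(report.failures_by_rule.values()) == report.n_input


class TestFlankCleanliness:
    def test_neighbor_at_radius_fails(self):
        a = kk.LocusRecord("c", 100, "A", ("G",))
        b = kk.LocusRecord("c", 149, "C", ("T",))
        assert not flank_cleanliness(a, [a, b], 50)
        assert not flank_cleanliness(b, [a, b], 50)

    def test_neighbor_beyond_radius_passes(self):
        a = kk.LocusRecord("c", 100, "A", ("G",))
        b = kk.LocusRecord("c", 151, "C", ("T",))
        assert flank_cleanliness(a, [a, b], 50)
        assert flank_cleanliness(b, [a, b], 50)

    def test_single_snp_and_other_chromosome(self):
        a = kk.LocusRecord("c1", 100, "A", ("G",))
        b = kk.LocusRecord("c2", 100, "C", ("T",))
        assert flank_cleanliness(a, [a], 50)
        assert flank_cleanliness(a, [a, b], 50)


def brute_force_count(reference, query):
    """Naive sliding-window occurrence count over both strands."""
    total = 0
    rc = reverse_complement(query)
    for name in reference.keys():
        contig = str(reference[name][:])
        for pat in {query, rc}:
            total += sum(
                contig[i:i + len(pat)] == pat
                for i in range(len(contig) - len(pat) + 1)
            )
    return total


class TestFlankUniqueness:
    def test_planted_duplicate_and_clean(self, planted_reference):
        ref, matrix, labels = planted_reference
        for loc in matrix.loci:
            if loc.id not in labels:
                continue
            w = kk.extract_flank_window(ref, loc, 100)
            expected = labels[loc.id] != "duplicated_window"
            assert kk.flank_uniqueness(w, ref) is expected
            assert (brute_force_count(ref, w.full_window) == 1) is expected

    def test_reverse_complement_copy_counts(self, tmp_path):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        window = seq[50:121]  # 71-mer around pos 86 (0-based 85)
        doctored = seq + "T" * 20 + reverse_complement(window) + seq[300:]
        p = tmp_path / "rc.fa"
        p.write_text(">c\n" + doctored + "\n")
        ref = kk.open_reference(str(p))
        loc = kk.LocusRecord("c", 86, ref=seq[85], alts=(next(b for b in "ACGT" if b != seq[85]),))
        w = kk.extract_flank_window(ref, loc, 35)
        assert w.full_window == window
        assert not kk.flank_uniqueness(w, ref)  # forward + reverse copy = 2 hits
        assert brute_force_count(ref, window) == 2

    def test_window_shorter_than_seed_errors(self, planted_reference):
        ref, matrix, _ = planted_reference
        w = kk.extract_flank_window(ref, matrix.loci[0], 10)
        with pytest.raises(DegenerateWindowError):
            kk.flank_uniqueness(w, ref, k=31)


class TestKaspCandidateFilter:
    def test_planted_failures_and_survivors(self, planted_reference):
        ref, matrix, labels = planted_reference
        _with_metadata(matrix)
        out, report = kk.kasp_candidate_filter(matrix, ref)
        failed = report.first_failed
        for lid, label in labels.items():
            if label == "dirty_neighbor":
                assert failed[lid] == "flank_clean"
            elif label == "duplicated_window":
                assert failed[lid] == "flank_unique"
        # the planted neighbour variant itself also fails flank cleanliness
        assert report.failures_by_rule["flank_clean"] == 2

    def test_pic_threshold_is_strict(self, planted_reference):
        ref, matrix, labels = planted_reference
        _with_metadata(matrix)
        clean = [loc.id for loc, lab in ((l, labels.get(l.id)) for l in matrix.loci) if lab == "clean"]
        j = matrix.locus_index(clean[0])
        locus_pic = pic(kk.allele_frequencies(matrix.calls_at(j))[0])
        crit = kk.FilterCriteria(min_pic=locus_pic)  # PIC == threshold must fail
        out, report = kk.kasp_candidate_filter(matrix, ref, crit)
        assert report.first_failed[clean[0]] == "pic"
        crit2 = kk.FilterCriteria(min_pic=locus_pic - 1e-9)
        out2, _ = kk.kasp_candidate_filter(matrix, ref, crit2)
        assert clean[0] in {loc.id for loc in out2.loci}

    def test_survivors_satisfy_all_predicates(self, planted_reference):
        ref, matrix, _ = planted_reference
        _with_metadata(matrix)
        out, _ = kk.kasp_candidate_filter(matrix, ref)
        for loc in out.loci:
            assert flank_cleanliness(loc, matrix.loci, 50)
            w = kk.extract_flank_window(ref, loc, 100)
            assert kk.flank_uniqueness(w, ref)
            freqs, _ = kk.allele_frequencies(out.calls_at(out.locus_index(loc.id)))
            assert len(freqs) == 2 and pic(freqs) > 0.020

    def test_output_invariant_to_locus_order(self, planted_reference):
        ref, matrix, _ = planted_reference
        _with_metadata(matrix)
        out1, _ = kk.kasp_candidate_filter(matrix, ref)
        perm = list(reversed(range(matrix.n_loci)))
        shuffled = matrix.subset_loci(perm)
        out2, _ = kk.kasp_candidate_filter(shuffled, ref)
        assert {l.id for l in out1.loci} == {l.id for l in out2.loci}

    def test_empty_candidate_set_valid(self, planted_reference):
        ref, matrix, _ = planted_reference
        _with_metadata(matrix, depth=1)  # everything fails depth_biallelic
        out, report = kk.kasp_candidate_filter(matrix, ref)
        assert out.n_loci == 0
        assert report.n_output == 0 and report.n_input == matrix.n_loci
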