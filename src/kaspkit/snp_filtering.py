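"""The two SNP filter cascades.

``population_filter`` is the population-grade screen applied before any
diversity analysis: mean sequencing depth >= 5x, minor allele frequency
>= 0.05, call completeness ("information integrity") >= 0.70, Phred site
quality Q >= 30, and exactly two observed alleles.

``kasp_candidate_filter`` is the stricter marker-engineering screen applied
to loci that will become allele-specific PCR assays: a conserved flank (no
neighbouring variant within 50 bp), depth and biallelism re-checked, a
flank window (100 bp each side) that occurs exactly once in the reference
genome on either strand, and PIC strictly greater than 0.020.

Both cascades apply their rules in a fixed order and attribute each removed
locus to the *first* rule it fails, so reports are reproducible; the
surviving set itself is order-independent (pure conjunction of predicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pyfaidx import Fasta

from .genotype_io import FlankWindow, GenotypeMatrix, LocusRecord, extract_flank_window
from .popgen_stats import (
    UndefinedStatisticError,
    allele_frequencies,
    minor_allele_frequency,
    pic,
)


class FilterConfigError(ValueError):
    """A threshold is enabled but the required evidence field is absent."""


class DegenerateWindowError(ValueError):
    """Flank window too short for the uniqueness seed scan."""


@dataclass
class FilterCriteria:
    """Thresholds for both cascades.  Set a field to None to disable it."""

    min_mean_depth: float | None = 5.0
    min_maf: float | None = 0.05
    min_completeness: float | None = 0.70
    min_qual: float | None = 30.0
    required_allele_count: int | None = 2
    flank_clean_radius: int = 50
    uniqueness_window: int = 100
    min_pic: float = 0.020

    def __post_init__(self) -> None:
        for name in ("min_mean_depth", "min_maf", "min_qual"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_completeness is not None and not (0 <= self.min_completeness <= 1):
            raise ValueError("min_completeness must be in [0, 1]")


# rule labels, in cascade order
POP_RULES = ("depth", "maf", "completeness", "qual", "allele_count")
KASP_RULES = ("flank_clean", "depth_biallelic", "flank_unique", "pic")


@dataclass
class FilterReport:
    """Counts and per-locus attribution for one cascade run."""

    n_input: int
    n_output: int
    failures_by_rule: dict[str, int]
    first_failed: dict[str, str]  # locus id -> first violated rule

    def __post_init__(self) -> None:
        if self.n_output + sum(self.failures_by_rule.values()) != self.n_input:
            raise ValueError("report counts do not add up")


# ---------------------------------------------------------------------------
# population-grade cascade
# ---------------------------------------------------------------------------

def _observed_allele_stats(matrix: GenotypeMatrix, j: int):
    """(freq map, n_called, n observed alleles) or None if all missing."""
    try:
        freqs, n_called = allele_frequencies(matrix.calls_at(j))
    except UndefinedStatisticError:
        return None
    return freqs, n_called, len(freqs)


def population_filter(
    matrix: GenotypeMatrix, criteria: FilterCriteria | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the population-grade screen; thresholds are inclusive (>=).

    Rule order for attribution: depth, maf, completeness, qual,
    allele_count.  A locus with every call missing fails "completeness"
    (call rate 0) unless that rule is disabled, in which case it fails
    "maf"/"allele_count" as undefined.
    """
    criteria = criteria or FilterCriteria()
    if criteria.min_mean_depth is not None and any(
        loc.depth_per_sample is None for loc in matrix.loci
    ):
        raise FilterConfigError("depth threshold enabled but DP absent for some loci")
    if criteria.min_qual is not None and any(loc.qual is None for loc in matrix.loci):
        raise FilterConfigError("qual threshold enabled but QUAL absent for some loci")

    keep: list[int] = []
    failures = {r: 0 for r in POP_RULES}
    first_failed: dict[str, str] = {}
    for j, loc in enumerate(matrix.loci):
        stats = _observed_allele_stats(matrix, j)
        call_rate = float((~matrix.missing_mask[:, j]).mean())
        failed = None
        if criteria.min_mean_depth is not None and loc.mean_depth < criteria.min_mean_depth:
            failed = "depth"
        elif criteria.min_maf is not None and (
            stats is None or minor_allele_frequency(stats[0]) < criteria.min_maf
        ):
            failed = "maf"
        elif criteria.min_completeness is not None and call_rate < criteria.min_completeness:
            failed = "completeness"
        elif criteria.min_qual is not None and loc.qual < criteria.min_qual:
            failed = "qual"
        elif criteria.required_allele_count is not None and (
            stats is None or stats[2] != criteria.required_allele_count
        ):
            failed = "allele_count"
        if failed is None:
            keep.append(j)
        else:
            failures[failed] += 1
            first_failed[loc.id] = failed
    report = FilterReport(matrix.n_loci, len(keep), failures, first_failed)
    return matrix.subset_loci(keep), report


# ---------------------------------------------------------------------------
# flank predicates
# ---------------------------------------------------------------------------

def flank_cleanliness(
    locus: LocusRecord, all_loci: Sequence[LocusRecord], radius: int = 50
) -> bool:
    """True iff no *other* variant lies within ``radius`` bases on either side.

    A neighbour at distance exactly ``radius`` fails (conservation must hold
    for strictly more than ``radius`` bases).
    """
    for other in all_loci:
        if other is locus or other.chrom != locus.chrom:
            continue
        if abs(other.pos - locus.pos) <= radius:
            return False
    return True


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _count_occurrences(haystack: str, needle: str, k: int) -> int:
    """Exact occurrences of ``needle`` via k-mer seeded scan with confirmation."""
    seed = needle[:k]
    count = 0
    start = 0
    while True:
        hit = haystack.find(seed, start)
        if hit < 0:
            break
        if haystack.startswith(needle, hit):
            count += 1
        start = hit + 1
    return count


def flank_uniqueness(window: FlankWindow, reference: Fasta, k: int = 31) -> bool:
    """True iff the window string occurs exactly once genome-wide, both strands.

    The query is ``upstream + ref + downstream``.  Occurrences are found by
    an exact k-mer seed scan (default k=31) with full-window confirmation;
    the reverse strand is scanned as the reverse complement of the query.  A
    palindromic query is counted once per site, not twice.
    """
    query = window.full_window
    if len(query) < k:
        raise DegenerateWindowError(f"window length {len(query)} < seed k={k}")
    rc = reverse_complement(query)
    total = 0
    for name in reference.keys():
        contig = str(reference[name][:])
        total += _count_occurrences(contig, query, k)
        if rc != query:
            total += _count_occurrences(contig, rc, k)
        if total > 1:
            return False
    return total == 1


# ---------------------------------------------------------------------------
# KASP-candidate cascade
# ---------------------------------------------------------------------------

def kasp_candidate_filter(
    matrix: GenotypeMatrix,
    reference: Fasta,
    criteria: FilterCriteria | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the marker-engineering screen on a population-grade matrix.

    Rule order: flank cleanliness (no neighbour within 50 bp) -> mean depth
    >= 5 and exactly two observed alleles -> flank-window uniqueness in the
    reference (100 bp each side, both strands) -> PIC strictly > 0.020.
    MAF/PIC are recomputed on the current matrix, never cached.
    """
    criteria = criteria or FilterCriteria()
    keep: list[int] = []
    failures = {r: 0 for r in KASP_RULES}
    first_failed: dict[str, str] = {}
    for j, loc in enumerate(matrix.loci):
        stats = _observed_allele_stats(matrix, j)
        failed = None
        if not flank_cleanliness(loc, matrix.loci, criteria.flank_clean_radius):
            failed = "flank_clean"
        elif (
            (criteria.min_mean_depth is not None
             and (loc.mean_depth is None or loc.mean_depth < criteria.min_mean_depth))
            or stats is None
            or stats[2] != 2
        ):
            failed = "depth_biallelic"
        else:
            window = extract_flank_window(reference, loc, criteria.uniqueness_window)
            if not flank_uniqueness(window, reference):
                failed = "flank_unique"
            elif not pic(stats[0]) > criteria.min_pic:  # strict: PIC == 0.020 fails
                failed = "pic"
        if failed is None:
            keep.append(j)
        else:
            failures[failed] += 1
            first_failed[loc.id] = failed
    report = FilterReport(matrix.n_loci, len(keep), failures, first_failed)
    return matrix.subset_loci(keep), report
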