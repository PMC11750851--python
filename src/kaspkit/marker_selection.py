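"""Minimum discriminating marker sets over genotype profiles.

Distinguishing every pair of cultivars with as few markers as possible is a
minimum test-cover problem: each locus "covers" the sample pairs whose calls
at that locus are both non-missing and different, and a panel is feasible
when the union of its loci's pair sets equals the universe of separable
pairs.  A no-call can never certify a difference, so missing-vs-call pairs
are simply not covered by that locus.

Samples with byte-identical profiles over every candidate locus (duplicate
groups — synonymous cultivars in practice) can never be separated; their
intra-group pairs are excluded from the universe and reported separately.

``greedy_min_panel`` is the standard greedy set-cover heuristic with
deterministic tie-breaking (higher PIC, then chrom:pos order) and a backward
pruning pass; ``exact_min_panel`` enumerates subsets in ascending size and is
the optimality oracle for small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import GenotypeMatrix

Pair = tuple[int, int]  # sample indices, i < j


@dataclass
class PairCoverage:
    """Per-locus separable sample pairs plus the coverable universe."""

    samples: list[str]
    coverage: dict[str, frozenset[Pair]]  # locus id -> pairs it separates
    universe: frozenset[Pair]  # all pairs of samples with distinct profiles
    locus_order: list[str]  # candidate loci in chrom:pos order


@dataclass
class DuplicateGroup:
    """Samples with identical genotype profiles (incl. missing pattern)."""

    members: tuple[str, ...]
    representative: str


@dataclass
class MarkerPanel:
    """An ordered marker subset with its coverage bookkeeping."""

    loci: list[str]
    covered: frozenset[Pair]
    residual: frozenset[Pair]
    gains: list[int]
    proven_minimal: bool = False

    @property
    def size(self) -> int:
        return len(self.loci)


@dataclass
class PanelVerification:
    n_distinct_profiles: int
    collisions: list[tuple[str, str]]  # colliding sample-id pairs (outside dup groups)
    lower_bound: int
    panel_size: int

    @property
    def ok(self) -> bool:
        return not self.collisions and self.panel_size >= self.lower_bound


def _profiles(matrix: GenotypeMatrix, loci_idx: Sequence[int] | None = None):
    return [matrix.profile(i, loci_idx) for i in range(matrix.n_samples)]


def find_duplicate_groups(matrix: GenotypeMatrix) -> list[DuplicateGroup]:
    """Maximal groups of samples with identical full profiles.

    Missing matches only missing: samples differing only where one has a
    no-call are *not* grouped (they are unseparable but not identical; such
    pairs surface in the residual of any panel).  Singletons are omitted.
    The representative is the lexicographically first member.
    """
    buckets: dict[tuple[str, ...], list[str]] = {}
    for i, prof in enumerate(_profiles(matrix)):
        buckets.setdefault(prof, []).append(matrix.samples[i])
    groups = [
        DuplicateGroup(members=tuple(sorted(v)), representative=min(v))
        for v in buckets.values()
        if len(v) > 1
    ]
    groups.sort(key=lambda g: g.representative)
    return groups


def discriminating_pairs(matrix: GenotypeMatrix) -> PairCoverage:
    """Per-locus separable pairs and the universe of distinct-profile pairs.

    A pair enters a locus's set only when both calls are non-missing and
    unequal.  The universe is every pair of samples whose *full* profiles
    differ — pairs inside duplicate groups are unseparable by construction
    and excluded.
    """
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    profs = _profiles(matrix)
    universe = frozenset(
        (i, j) for i, j in combinations(range(n), 2) if profs[i] != profs[j]
    )
    iu, ju = np.triu_indices(n, k=1)
    coverage: dict[str, frozenset[Pair]] = {}
    for jcol, loc in enumerate(matrix.loci):
        a1 = matrix.a1[:, jcol]
        a2 = matrix.a2[:, jcol]
        called = a1 >= 0
        # unordered pair equality on allele-index pairs (a1<=? not guaranteed;
        # compare as sorted tuples via min/max)
        lo = np.minimum(a1, a2)
        hi = np.maximum(a1, a2)
        differ = (
            called[iu]
            & called[ju]
            & ((lo[iu] != lo[ju]) | (hi[iu] != hi[ju]))
        )
        coverage[loc.id] = frozenset(
            (int(a), int(b)) for a, b in zip(iu[differ], ju[differ])
        )
    order = sorted(
        (loc.id for loc in matrix.loci),
        key=lambda lid: _chrom_pos_key(matrix, lid),
    )
    return PairCoverage(
        samples=list(matrix.samples),
        coverage=coverage,
        universe=universe,
        locus_order=order,
    )


def _chrom_pos_key(matrix: GenotypeMatrix, locus_id: str):
    j = matrix.locus_index(locus_id)
    return (matrix.loci[j].chrom, matrix.loci[j].pos)


def greedy_min_panel(
    coverage: PairCoverage, tie_break: Mapping[str, float] | None = None
) -> MarkerPanel:
    """Greedy set cover with PIC tie-break and backward pruning.

    At each step the locus covering the most still-uncovered pairs is taken;
    ties go to the higher PIC (``tie_break``), then to chrom:pos order.  The
    loop stops when the universe is covered or no locus adds coverage; a
    final backward pass drops any marker whose removal leaves the covered
    set intact, so the panel is inclusion-minimal.
    """
    tie_break = tie_break or {}
    uncovered = set(coverage.universe)
    selected: list[str] = []
    gains: list[int] = []
    rank = {lid: r for r, lid in enumerate(coverage.locus_order)}
    candidates = list(coverage.locus_order)
    while uncovered:
        best = None
        best_key = None
        for lid in candidates:
            if lid in selected:
                continue
            gain = len(coverage.coverage[lid] & uncovered)
            if gain == 0:
                continue
            key = (-gain, -tie_break.get(lid, 0.0), rank[lid])
            if best_key is None or key < best_key:
                best, best_key = lid, key
        if best is None:
            break  # residual pairs uncoverable by any candidate
        selected.append(best)
        gains.append(-best_key[0])
        uncovered -= coverage.coverage[best]

    # backward pruning: drop markers that became redundant
    target = coverage.universe - frozenset(uncovered)
    changed = True
    while changed:
        changed = False
        for lid in list(selected):
            others = [x for x in selected if x != lid]
            if _union(coverage, others) >= target:
                k = selected.index(lid)
                selected.pop(k)
                gains.pop(k)
                changed = True
                break
    covered = frozenset(_union(coverage, selected))
    return MarkerPanel(
        loci=selected,
        covered=covered,
        residual=coverage.universe - covered,
        gains=gains,
    )


def _union(coverage: PairCoverage, loci: Sequence[str]) -> set[Pair]:
    out: set[Pair] = set()
    for lid in loci:
        out |= coverage.coverage[lid]
    return out


class ExactBudgetExceeded(ValueError):
    """Too many candidate loci for exhaustive minimum-cover search."""


def exact_min_panel(coverage: PairCoverage, max_loci: int = 20) -> MarkerPanel:
    """Provably minimum-cardinality cover by ascending-size enumeration.

    Only the pairs coverable by the full candidate set are required (pairs
    no locus can separate are residual for every panel).  Refuses instances
    with more than ``max_loci`` candidates.
    """
    lids = coverage.locus_order
    if len(lids) > max_loci:
        raise ExactBudgetExceeded(
            f"{len(lids)} candidate loci exceed the exhaustive budget {max_loci}"
        )
    coverable = frozenset(_union(coverage, lids))
    if not coverable:
        return MarkerPanel([], frozenset(), coverage.universe, [], proven_minimal=True)
    for size in range(1, len(lids) + 1):
        for combo in combinations(lids, size):
            if _union(coverage, combo) >= coverable:
                sel = list(combo)
                return MarkerPanel(
                    loci=sel,
                    covered=coverable,
                    residual=coverage.universe - coverable,
                    gains=[],
                    proven_minimal=True,
                )
    raise AssertionError("unreachable: full set covers coverable")


def verify_panel(matrix: GenotypeMatrix, panel: MarkerPanel) -> PanelVerification:
    """Recheck pairwise distinctness restricted to the panel loci.

    Reports colliding pairs that the full candidate set *could* separate
    (collisions inside duplicate groups or otherwise unseparable pairs are
    expected and not counted), the number of distinct restricted profiles,
    and the information-theoretic lower bound ceil(log3 m) for m distinct
    profiles of biallelic co-dominant markers (3 genotype classes/locus).
    """
    idx = [matrix.locus_index(lid) for lid in panel.loci]
    profs = _profiles(matrix, idx)
    full = _profiles(matrix)
    cov = discriminating_pairs(matrix)
    separable = _union(cov, [loc.id for loc in matrix.loci])
    collisions = []
    for i, j in combinations(range(matrix.n_samples), 2):
        if profs[i] == profs[j] and full[i] != full[j] and (i, j) in separable:
            collisions.append((matrix.samples[i], matrix.samples[j]))
    m = len(set(full))
    bound = 0 if m <= 1 else math.ceil(math.log(m, 3) - 1e-12)
    return PanelVerification(
        n_distinct_profiles=len(set(profs)),
        collisions=collisions,
        lower_bound=bound,
        panel_size=panel.size,
    )


def log3_lower_bound(n_distinct_profiles: int) -> int:
    """ceil(log3 m): fewest biallelic co-dominant markers for m profiles."""
    if n_distinct_profiles <= 1:
        return 0
    return math.ceil(math.log(n_distinct_profiles, 3) - 1e-12)


def efficiency_curve(matrix: GenotypeMatrix, panel: MarkerPanel) -> list[dict]:
    """Identification efficiency after each marker added, in panel order.

    Each row: markers used so far, number of distinct profiles, and fraction
    of universe pairs covered.  Both quantities are monotone non-decreasing.
    """
    cov = discriminating_pairs(matrix)
    rows = [
        {
            "n_markers": 0,
            "distinct_profiles": 1 if matrix.n_samples else 0,
            "pairs_covered_frac": 0.0 if cov.universe else 1.0,
        }
    ]
    seen: set[Pair] = set()
    idx: list[int] = []
    for k, lid in enumerate(panel.loci, start=1):
        idx.append(matrix.locus_index(lid))
        seen |= cov.coverage[lid]
        frac = (len(seen & cov.universe) / len(cov.universe)) if cov.universe else 1.0
        rows.append(
            {
                "n_markers": k,
                "distinct_profiles": len(set(_profiles(matrix, idx))),
                "pairs_covered_frac": frac,
            }
        )
    return rows
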