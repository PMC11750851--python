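"""Per-locus and population-level genetic diversity indices.

The index suite covers the quantities routinely reported for SNP panels in
cultivar-fingerprinting studies: observed/expected heterozygosity, per-site
nucleotide diversity, inbreeding coefficient, polymorphic information
content (PIC), effective number of alleles, and minor allele frequency.

PIC is evaluated over the *distinct alleles* of a locus:

    PIC = 1 - sum_i Pi^2 - sum_{i<j} 2 Pi^2 Pj^2

which for a biallelic locus reduces to ``1 - (p^2 + q^2) - 2 p^2 q^2`` and
is bounded above by 0.375 (at p = q = 0.5).  Expected heterozygosity is the
uncorrected ``HE = 1 - sum_i Pi^2`` (no small-sample n/(n-1) factor), and
per-site nucleotide diversity is reported equal to HE (per-site
heterozygosity without a pairwise-sample correction).  The inbreeding
coefficient per locus is ``Fis = 1 - HetObs/HetExp``, undefined at
monomorphic loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeCall, GenotypeMatrix, LocusRecord


class UndefinedStatisticError(ValueError):
    """Raised when a statistic has no defined value (e.g. all calls missing)."""


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (report display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# per-locus building blocks
# ---------------------------------------------------------------------------

def allele_frequencies(calls: Iterable[GenotypeCall]) -> tuple[dict[str, float], int]:
    """Allele frequency map and number of called samples for one locus.

    Each non-missing call contributes two allele copies; missing calls are
    excluded from the denominator entirely.
    """
    counts: dict[str, int] = {}
    n_called = 0
    for c in calls:
        if c.is_missing:
            continue
        n_called += 1
        counts[c.allele_a] = counts.get(c.allele_a, 0) + 1
        counts[c.allele_b] = counts.get(c.allele_b, 0) + 1
    if n_called == 0:
        raise UndefinedStatisticError("all calls missing: allele frequencies undefined")
    total = 2 * n_called
    return {al: n / total for al, n in sorted(counts.items())}, n_called


def pic(freqs: Mapping[str, float] | Sequence[float]) -> float:
    """Polymorphic information content over distinct-allele frequencies.

    PIC = 1 - sum_i Pi^2 - sum_{i<j} 2 Pi^2 Pj^2.  Monomorphic input gives 0.
    """
    p = _freq_vector(freqs)
    sq = p ** 2
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * sq[i] * sq[j]
    return float(1.0 - sq.sum() - cross)


def expected_heterozygosity(freqs: Mapping[str, float] | Sequence[float]) -> float:
    """HE = 1 - sum_i Pi^2 (no small-sample correction)."""
    p = _freq_vector(freqs)
    return float(1.0 - (p ** 2).sum())


def observed_heterozygosity(calls: Iterable[GenotypeCall]) -> float:
    """Fraction of called samples whose two alleles differ."""
    n_called = 0
    n_het = 0
    for c in calls:
        if c.is_missing:
            continue
        n_called += 1
        n_het += c.is_het
    if n_called == 0:
        raise UndefinedStatisticError("all calls missing: HetObs undefined")
    return n_het / n_called


def minor_allele_frequency(freqs: Mapping[str, float] | Sequence[float]) -> float:
    """Frequency of the second most common allele (0 for monomorphic loci)."""
    p = sorted(_freq_vector(freqs), reverse=True)
    return float(p[1]) if len(p) > 1 else 0.0


def _freq_vector(freqs: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    vals = list(freqs.values()) if isinstance(freqs, Mapping) else list(freqs)
    p = np.asarray(vals, dtype=float)
    if p.size == 0:
        raise UndefinedStatisticError("empty frequency vector")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {p.sum()}")
    return p


# ---------------------------------------------------------------------------
# bundled per-locus statistics
# ---------------------------------------------------------------------------

@dataclass
class LocusStats:
    """Index bundle for one locus.  ``fis`` is None at monomorphic loci."""

    n_called: int
    freqs: dict[str, float]
    maf: float
    het_obs: float
    het_exp: float
    pic: float
    ne: float
    pi_site: float
    fis: float | None

    @property
    def is_polymorphic(self) -> bool:
        return len(self.freqs) > 1


def locus_stats(calls: Sequence[GenotypeCall], locus: LocusRecord | None = None) -> LocusStats:
    """Compute the full index bundle for one locus column.

    ``ne`` is the effective number of alleles 1/sum(Pi^2) (= 1/(1-pi_site));
    ``fis`` is 1 - HetObs/HetExp where HetExp > 0, else undefined (None).
    """
    freqs, n_called = allele_frequencies(calls)
    he = expected_heterozygosity(freqs)
    ho = observed_heterozygosity(calls)
    sum_sq = 1.0 - he
    return LocusStats(
        n_called=n_called,
        freqs=freqs,
        maf=minor_allele_frequency(freqs),
        het_obs=ho,
        het_exp=he,
        pic=pic(freqs),
        ne=1.0 / sum_sq,
        pi_site=he,
        fis=(1.0 - ho / he) if he > 0 else None,
    )


@dataclass
class PopulationSummary:
    """Arithmetic means of the per-locus indices across a matrix.

    ``mean_fis`` averages only loci where Fis is defined (HetExp > 0) and is
    None when no locus is polymorphic.
    """

    n_sites: int
    n_polymorphic: int
    mean_het_obs: float
    mean_het_exp: float
    mean_pi: float
    mean_fis: float | None
    mean_pic: float
    mean_ne: float
    mean_maf: float


def matrix_locus_stats(matrix: GenotypeMatrix) -> list[LocusStats | None]:
    """Per-locus stats for every column; None where all calls are missing."""
    out: list[LocusStats | None] = []
    for j in range(matrix.n_loci):
        try:
            out.append(locus_stats(matrix.calls_at(j), matrix.loci[j]))
        except UndefinedStatisticError:
            out.append(None)
    return out


def population_summary(matrix: GenotypeMatrix) -> PopulationSummary:
    """Mean of each index over loci where it is defined."""
    if matrix.n_loci == 0:
        raise UndefinedStatisticError("empty matrix")
    stats = [s for s in matrix_locus_stats(matrix) if s is not None]
    if not stats:
        raise UndefinedStatisticError("no locus has any non-missing call")
    fis_vals = [s.fis for s in stats if s.fis is not None]
    return PopulationSummary(
        n_sites=len(stats),
        n_polymorphic=sum(s.is_polymorphic for s in stats),
        mean_het_obs=float(np.mean([s.het_obs for s in stats])),
        mean_het_exp=float(np.mean([s.het_exp for s in stats])),
        mean_pi=float(np.mean([s.pi_site for s in stats])),
        mean_fis=float(np.mean(fis_vals)) if fis_vals else None,
        mean_pic=float(np.mean([s.pic for s in stats])),
        mean_ne=float(np.mean([s.ne for s in stats])),
        mean_maf=float(np.mean([s.maf for s in stats])),
    )


def per_locus_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """One row per locus with the full index suite (NaN where undefined)."""
    rows = []
    for loc, s in zip(matrix.loci, matrix_locus_stats(matrix)):
        if s is None:
            rows.append({"locus": loc.id, "chrom": loc.chrom, "pos": loc.pos})
            continue
        rows.append(
            {
                "locus": loc.id,
                "chrom": loc.chrom,
                "pos": loc.pos,
                "n_called": s.n_called,
                "maf": s.maf,
                "het_obs": s.het_obs,
                "het_exp": s.het_exp,
                "pi": s.pi_site,
                "fis": math.nan if s.fis is None else s.fis,
                "pic": s.pic,
                "ne": s.ne,
            }
        )
    return pd.DataFrame(rows)


def summary_table(summary: PopulationSummary) -> pd.DataFrame:
    """Single-row frame in conventional column order."""
    return pd.DataFrame(
        [
            {
                "Sites": summary.n_sites,
                "Polymorphic": summary.n_polymorphic,
                "HetObs": summary.mean_het_obs,
                "HetExp": summary.mean_het_exp,
                "Pi": summary.mean_pi,
                "Fis": math.nan if summary.mean_fis is None else summary.mean_fis,
                "PIC": summary.mean_pic,
                "Ne": summary.mean_ne,
                "MAF": summary.mean_maf,
            }
        ]
    )
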