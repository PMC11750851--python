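"""Structured-population genotype and reference simulators.

The generator emulates the statistical shape of a ddRAD-derived SNP
genotype matrix for a panel of clonally propagated cultivars: K
subpopulations under the Balding-Nichols model (subpopulation allele
frequencies Beta-distributed around an ancestral frequency with
differentiation parameter Fst), a heterozygote deficit controlled by an
inbreeding coefficient f, i.i.d. missing calls, per-sample negative
binomial read depths, Phred-like site qualities, and optional groups of
byte-identical duplicate samples (synonymous cultivars).

Defaults mirror the study system this toolkit was built around: 50
cultivars in K=4 groups of 14/5/23/8, f = 0.25 (matching the observed
heterozygote deficit), 10% missing calls, mean depth 6.6x.  All simulators
are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import GenotypeMatrix, LocusRecord

NUC = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the genotype simulator; ``seed`` is mandatory."""

    seed: int
    n_samples: int = 50
    n_loci: int = 1000
    n_subpops: int = 4
    subpop_sizes: tuple[int, ...] | None = (14, 5, 23, 8)  # None = equal split
    fst: float | Sequence[float] = 0.10
    ancestral_maf_bounds: tuple[float, float] = (0.05, 0.5)
    inbreeding_f: float = 0.25
    missing_rate: float = 0.10
    duplicate_group_sizes: tuple[int, ...] = ()
    depth_mean: float = 6.6
    depth_dispersion: float = 3.0  # negative binomial size parameter
    qual_mean: float = 60.0
    qual_shape: float = 4.0  # gamma shape; scale = qual_mean / shape

    def __post_init__(self) -> None:
        fsts = self.fst_per_subpop
        if any(not (0 <= F < 1) for F in fsts):
            raise ValueError("fst must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.inbreeding_f <= 1):
            raise ValueError("inbreeding_f must be in [0, 1]")
        lo, hi = self.ancestral_maf_bounds
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral MAF bounds must satisfy 0 < lo <= hi <= 0.5")
        if self.subpop_sizes is not None:
            if len(self.subpop_sizes) != self.n_subpops:
                raise ValueError("subpop_sizes length must equal n_subpops")
            if sum(self.subpop_sizes) != self.n_samples:
                raise ValueError("subpop_sizes must sum to n_samples")
        if sum(self.duplicate_group_sizes) > self.n_samples:
            raise ValueError("duplicate groups exceed sample count")

    @property
    def fst_per_subpop(self) -> tuple[float, ...]:
        if isinstance(self.fst, (int, float)):
            return (float(self.fst),) * self.n_subpops
        if len(self.fst) != self.n_subpops:
            raise ValueError("per-subpop fst length must equal n_subpops")
        return tuple(float(F) for F in self.fst)


def preset(name: str, seed: int) -> SimulationConfig:
    """Named scenario configurations.

    ``ensifolium50``: the 50-cultivar discovery panel (K=4, groups 14/5/23/8).
    ``ensifolium83``: the 83-cultivar genotyping panel, including one
    duplicate group of four and one of two samples.
    """
    if name == "ensifolium50":
        return SimulationConfig(seed=seed)
    if name == "ensifolium83":
        return SimulationConfig(
            seed=seed,
            n_samples=83,
            subpop_sizes=(23, 8, 38, 14),
            duplicate_group_sizes=(4, 2),
        )
    raise KeyError(f"unknown preset {name!r}")


@dataclass
class TruthTable:
    """Ground truth recorded alongside a simulated matrix."""

    ancestral_freqs: np.ndarray  # (n_loci,) frequency of the ref allele
    subpop_freqs: np.ndarray  # (K, n_loci)
    subpop_labels: np.ndarray  # (n_samples,) int
    duplicate_groups: list[tuple[str, ...]] = field(default_factory=list)
    planted_violations: dict[str, str] = field(default_factory=dict)  # locus id -> rule


def _sample_names(n: int) -> list[str]:
    return [f"CES{i:03d}" for i in range(1, n + 1)]


def simulate_structured_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw a Balding-Nichols genotype matrix with inbreeding and missingness.

    Per locus, the ancestral ref-allele frequency p0 is Uniform over
    ``1 - maf_bounds`` (ref is the major allele); subpopulation k's
    frequency is Beta(p0(1-F)/F, (1-p0)(1-F)/F) (exactly p0 when F=0).
    Genotypes: P(ref/ref) = p^2 + f p q, P(het) = 2pq(1-f),
    P(alt/alt) = q^2 + f p q.  Missing calls are i.i.d.  Duplicate groups,
    if configured, are injected afterwards (see
    :func:`inject_duplicate_groups`).
    """
    rng = np.random.default_rng(config.seed)
    n, m, K = config.n_samples, config.n_loci, config.n_subpops
    lo, hi = config.ancestral_maf_bounds
    maf0 = rng.uniform(lo, hi, size=m)
    p0 = 1.0 - maf0  # ref allele is the ancestral major allele

    fsts = config.fst_per_subpop
    subpop_freqs = np.empty((K, m))
    for k in range(K):
        F = fsts[k]
        if F == 0:
            subpop_freqs[k] = p0
        else:
            a = p0 * (1 - F) / F
            b = (1 - p0) * (1 - F) / F
            subpop_freqs[k] = rng.beta(a, b)

    if config.subpop_sizes is not None:
        sizes = config.subpop_sizes
    else:
        base = n // K
        sizes = tuple(base + (1 if k < n % K else 0) for k in range(K))
    labels = np.repeat(np.arange(K), sizes)

    p = subpop_freqs[labels]  # (n, m)
    q = 1.0 - p
    f = config.inbreeding_f
    probs = np.stack(
        [p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q], axis=-1
    )
    u = rng.uniform(size=(n, m))
    cum = probs.cumsum(axis=-1)
    gt = (u[..., None] > cum).sum(axis=-1)  # 0 hom-ref, 1 het, 2 hom-alt

    a1 = np.where(gt == 2, 1, 0).astype(np.int8)
    a2 = np.where(gt >= 1, 1, 0).astype(np.int8)
    miss = rng.uniform(size=(n, m)) < config.missing_rate
    a1[miss] = -1
    a2[miss] = -1

    # locus identities: spread across 20 chromosomes, random ref/alt pairs
    chroms = rng.integers(1, 21, size=m)
    positions: dict[int, int] = {}
    loci = []
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    for j in range(m):
        c = int(chroms[j])
        positions[c] = positions.get(c, 0) + int(rng.integers(500, 5000))
        ref = str(NUC[ref_idx[j]])
        alt = str(NUC[(ref_idx[j] + alt_shift[j]) % 4])
        loci.append(LocusRecord(chrom=f"Chr{c}", pos=positions[c], ref=ref, alts=(alt,)))

    matrix = GenotypeMatrix(_sample_names(n), loci, a1, a2)
    truth = TruthTable(
        ancestral_freqs=p0, subpop_freqs=subpop_freqs, subpop_labels=labels
    )
    if config.duplicate_group_sizes:
        matrix, truth = inject_duplicate_groups(
            matrix, config.duplicate_group_sizes, truth=truth, seed=config.seed + 1
        )
    return matrix, truth


def inject_duplicate_groups(
    matrix: GenotypeMatrix,
    group_sizes: Sequence[int],
    truth: TruthTable | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Overwrite designated samples with their group seed's calls.

    Groups are taken from disjoint random sample indices; every member copies
    the first member's calls including the missing pattern, making the group
    byte-identical (and hence unseparable by any marker).
    """
    rng = np.random.default_rng(seed)
    total = sum(group_sizes)
    if total > matrix.n_samples:
        raise ValueError("duplicate groups exceed sample count")
    chosen = rng.choice(matrix.n_samples, size=total, replace=False)
    a1, a2 = matrix.a1.copy(), matrix.a2.copy()
    groups: list[tuple[str, ...]] = []
    k = 0
    for size in group_sizes:
        idx = sorted(int(i) for i in chosen[k:k + size])
        k += size
        if size < 2:
            continue
        seed_i = idx[0]
        for i in idx[1:]:
            a1[i] = a1[seed_i]
            a2[i] = a2[seed_i]
        groups.append(tuple(sorted(matrix.samples[i] for i in idx)))
    out = GenotypeMatrix(matrix.samples, matrix.loci, a1, a2)
    if truth is None:
        truth = TruthTable(
            ancestral_freqs=np.array([]),
            subpop_freqs=np.empty((0, 0)),
            subpop_labels=np.array([]),
        )
    truth.duplicate_groups = groups
    return out, truth


# rules that can be planted as single violations, and how
PLANTABLE_RULES = ("depth", "maf", "completeness", "qual", "allele_count")


def simulate_locus_metadata(
    matrix: GenotypeMatrix,
    config: SimulationConfig,
    planted_rules: Sequence[str] = (),
    truth: TruthTable | None = None,
) -> TruthTable:
    """Fill per-locus depth and quality in place; optionally plant violations.

    Depth per sample ~ NegativeBinomial(mean, dispersion); quality ~
    Gamma(shape, mean/shape), floored at 30.5 for clean loci so only planted
    loci can fail the quality rule.  ``planted_rules`` forces one otherwise
    clean locus per named rule below its threshold (recorded in the truth
    table):

    * depth: all depths drawn with mean 2
    * qual: site quality set to 10
    * maf: genotypes overwritten nearly monomorphic (one het)
    * completeness: 40% of calls set missing
    * allele_count: locus made strictly monomorphic
    """
    rng = np.random.default_rng(config.seed + 2)
    n, m = matrix.n_samples, matrix.n_loci
    size = config.depth_dispersion
    p_nb = size / (size + config.depth_mean)
    for loc in matrix.loci:
        loc.depth_per_sample = rng.negative_binomial(size, p_nb, size=n)
        loc.qual = max(30.5, float(rng.gamma(config.qual_shape, config.qual_mean / config.qual_shape)))
    if truth is None:
        truth = TruthTable(
            ancestral_freqs=np.array([]),
            subpop_freqs=np.empty((0, 0)),
            subpop_labels=np.array([]),
        )
    if planted_rules:
        if m < len(planted_rules):
            raise ValueError("not enough loci to plant violations")
        targets = rng.choice(m, size=len(planted_rules), replace=False)
        for rule, j in zip(planted_rules, (int(t) for t in targets)):
            loc = matrix.loci[j]
            if rule == "depth":
                low_p = size / (size + 2.0)
                loc.depth_per_sample = rng.negative_binomial(size, low_p, size=n)
                if loc.mean_depth >= 5:  # guard against unlucky draws
                    loc.depth_per_sample = np.minimum(loc.depth_per_sample, 4)
            elif rule == "qual":
                loc.qual = 10.0
            elif rule == "maf":
                matrix.a1[:, j] = 0
                matrix.a2[:, j] = 0
                matrix.a2[0, j] = 1  # single alt copy: MAF = 1/(2n) < 0.05
            elif rule == "completeness":
                n_miss = int(np.ceil(0.4 * n))
                miss_idx = rng.choice(n, size=n_miss, replace=False)
                matrix.a1[miss_idx, j] = -1
                matrix.a2[miss_idx, j] = -1
            elif rule == "allele_count":
                # triallelic with balanced frequencies, so only the
                # allele-count rule (exactly 2) fails — MAF stays >= 0.05
                third = next(b for b in "ACGT" if b not in loc.alleles)
                loc.alts = loc.alts + (third,)
                cyc = np.arange(n) % 3
                matrix.a1[:, j] = cyc
                matrix.a2[:, j] = cyc
            else:
                raise ValueError(f"unknown plantable rule {rule!r}")
            truth.planted_violations[loc.id] = rule
    return truth


@dataclass
class ReferenceSimConfig:
    """Reference-with-planted-SNPs scenario."""

    seed: int
    n_snps: int = 10
    window: int = 100  # uniqueness window each side
    spacing: int = 400  # between planted SNPs (> 2*flank radius)
    n_samples: int = 8
    gc_content: float = 0.5
    n_dirty_neighbor: int = 0  # SNPs given a neighbour variant at distance 49
    n_duplicated_window: int = 0  # SNPs whose 201-bp window is copied elsewhere


def simulate_reference_with_snps(
    config: ReferenceSimConfig, fasta_path: str | Path
) -> tuple[Path, GenotypeMatrix, dict[str, str]]:
    """Write a random contig with planted SNPs; return matrix and truth labels.

    The contig is i.i.d. random bases at the configured GC content.  The
    first ``n_dirty_neighbor`` SNPs get a second variant 49 bp away (flank
    cleanliness must fail at radius 50); the next ``n_duplicated_window``
    SNPs have their (2*window+1)-mer copied into a spacer region (flank
    uniqueness must fail).  Remaining SNPs are clean.  Truth labels map
    locus id -> "dirty_neighbor" | "duplicated_window" | "clean".
    """
    rng = np.random.default_rng(config.seed)
    w = config.window
    spacing = max(config.spacing, 2 * w + 50)
    n_extra = config.n_duplicated_window * (2 * w + 1 + 100)
    length = (config.n_snps + 1) * spacing + n_extra + 2 * w
    p_gc = config.gc_content / 2
    p_at = (1 - config.gc_content) / 2
    seq = rng.choice(NUC, size=length, p=[p_at, p_gc, p_gc, p_at])

    snp_pos0 = [(i + 1) * spacing for i in range(config.n_snps)]  # 0-based
    labels: dict[str, str] = {}
    loci: list[LocusRecord] = []
    neighbor_loci: list[LocusRecord] = []
    paste_at = config.n_snps * spacing + spacing // 2  # start of spacer region

    for i, p0 in enumerate(snp_pos0):
        ref = str(seq[p0])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        loc = LocusRecord(chrom="Contig1", pos=p0 + 1, ref=ref, alts=(alt,))
        if i < config.n_dirty_neighbor:
            labels[loc.id] = "dirty_neighbor"
            nb = p0 + 49
            nref = str(seq[nb])
            nalt = str(rng.choice([b for b in "ACGT" if b != nref]))
            neighbor_loci.append(
                LocusRecord(chrom="Contig1", pos=nb + 1, ref=nref, alts=(nalt,))
            )
        elif i < config.n_dirty_neighbor + config.n_duplicated_window:
            labels[loc.id] = "duplicated_window"
            window_mer = seq[p0 - w:p0 + w + 1].copy()
            seq[paste_at:paste_at + 2 * w + 1] = window_mer
            paste_at += 2 * w + 1 + 100
        else:
            labels[loc.id] = "clean"
        loci.append(loc)

    all_loci = loci + neighbor_loci
    all_loci.sort(key=lambda l: l.pos)
    n = config.n_samples
    a1 = np.zeros((n, len(all_loci)), dtype=np.int8)
    a2 = np.zeros((n, len(all_loci)), dtype=np.int8)
    for j in range(len(all_loci)):
        gt = rng.integers(0, 3, size=n)  # uniform genotype classes
        a1[:, j] = np.where(gt == 2, 1, 0)
        a2[:, j] = np.where(gt >= 1, 1, 0)
    matrix = GenotypeMatrix(_sample_names(n), all_loci, a1, a2)

    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        fh.write(">Contig1\n")
        s = "".join(seq)
        for k in range(0, len(s), 80):
            fh.write(s[k:k + 80] + "\n")
    return fasta_path, matrix, labels


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def estimate_fst_hudson(matrix: GenotypeMatrix, labels: np.ndarray) -> float:
    """Hudson-style Fst from true subpopulation labels (ratio of sums).

    For each subpopulation pair and biallelic locus: numerator
    (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) with n the allele count,
    denominator p1(1-p2) + p2(1-p1); Fst is the sum of numerators over the
    sum of denominators, averaged over subpopulation pairs.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if len(pops) < 2:
        raise ValueError("need >= 2 subpopulations")
    called = matrix.a1 >= 0
    alt_copies = (matrix.a1 == 1).astype(np.int32) + (matrix.a2 == 1).astype(np.int32)
    ests = []
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            ia, ib = labels == pops[a], labels == pops[b]
            n1 = 2 * called[ia].sum(axis=0)
            n2 = 2 * called[ib].sum(axis=0)
            ok = (n1 > 2) & (n2 > 2)
            p1 = alt_copies[ia].sum(axis=0)[ok] / n1[ok]
            p2 = alt_copies[ib].sum(axis=0)[ok] / n2[ok]
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / (n1[ok] - 1)
                - p2 * (1 - p2) / (n2[ok] - 1)
            )
            den = p1 * (1 - p2) + p2 * (1 - p1)
            ests.append(num.sum() / den.sum())
    return float(np.mean(ests))
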