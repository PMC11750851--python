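"""Genotype containers and file I/O.

The pipeline's central object is a :class:`GenotypeMatrix`: an ordered set of
samples by an ordered set of SNP loci, holding unordered diploid allele-pair
calls with explicit missing-call support.  Everything downstream (index
computation, filter cascades, panel selection, fingerprinting) consumes this
one container.

Conventions
-----------
* External coordinates (VCF, FASTA) are 1-based inclusive; internal offsets
  are 0-based half-open.
* Calls are unordered pairs stored canonically in alphabetical nucleotide
  order, so ``(G, A)`` and ``(A, G)`` are the same call, printed ``"AG"``.
* Only single-nucleotide substitutions enter the matrix; indel rows are
  skipped at parse time (counted and logged).  Multiallelic SNP rows are
  loaded but flagged — the filter cascades remove them explicitly.
* All sequence handling is on the reference forward strand; primer design is
  the only place a reverse complement appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
MISSING_STRING = "NN"


class VcfFormatError(ValueError):
    """Malformed VCF header or body."""


class RecordError(ValueError):
    """A specific VCF record is invalid; the message names chrom:pos."""


class GenotypeParseError(ValueError):
    """A genotype-table cell could not be parsed; names row/column."""


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid allele pair, or a missing call.

    Alleles are canonicalised alphabetically at construction, so
    ``GenotypeCall("G", "A")`` equals ``GenotypeCall("A", "G")``.  Either
    both alleles are present or both are ``None`` (missing).
    """

    allele_a: str | None
    allele_b: str | None

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        if (a is None) != (b is None):
            raise ValueError("half-missing call: both alleles or neither")
        if a is not None:
            for x in (a, b):
                if x not in NUCLEOTIDES:
                    raise ValueError(f"invalid allele {x!r}")
            if b < a:  # canonical alphabetical order
                object.__setattr__(self, "allele_a", b)
                object.__setattr__(self, "allele_b", a)

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_het(self) -> bool:
        return (not self.is_missing) and self.allele_a != self.allele_b

    def to_string(self) -> str:
        if self.is_missing:
            return MISSING_STRING
        return f"{self.allele_a}{self.allele_b}"

    @classmethod
    def from_string(cls, s: str) -> "GenotypeCall":
        if s == MISSING_STRING:
            return MISSING
        if len(s) != 2:
            raise ValueError(f"genotype string must have 2 letters: {s!r}")
        return cls(s[0], s[1])


MISSING = GenotypeCall(None, None)


@dataclass
class LocusRecord:
    """One SNP's identity and evidence.

    ``qual`` is the Phred-scaled site quality; ``depth_per_sample`` holds
    non-negative read depths aligned with the matrix sample order;
    ``region_class`` is an optional annotation label (e.g. ``"exonic"``).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    depth_per_sample: np.ndarray | None = None
    region_class: str | None = None

    def __post_init__(self) -> None:
        self.alts = tuple(self.alts)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES:
            raise ValueError(f"ref must be a single nucleotide, got {self.ref!r}")
        for a in self.alts:
            if a not in NUCLEOTIDES:
                raise ValueError(f"alt must be a single nucleotide, got {a!r}")
        if self.ref in self.alts:
            raise ValueError(f"ref {self.ref} repeated in alts {self.alts}")
        if self.depth_per_sample is not None:
            self.depth_per_sample = np.asarray(self.depth_per_sample)
            if (self.depth_per_sample < 0).any():
                raise ValueError("depths must be non-negative")

    @property
    def id(self) -> str:
        """Locus identifier in ``chrom-pos`` form (e.g. ``Chr1-55623523``)."""
        return f"{self.chrom}-{self.pos}"

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def mean_depth(self) -> float | None:
        if self.depth_per_sample is None:
            return None
        return float(np.mean(self.depth_per_sample))


class GenotypeMatrix:
    """samples x loci grid of :class:`GenotypeCall`.

    Internally stored as two ``(n_samples, n_loci)`` int8 arrays of allele
    indices into each locus's ``(ref,) + alts`` tuple, with ``-1`` marking a
    missing call.  This keeps per-locus statistics vectorisable while the
    public API speaks in calls and nucleotide strings.
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[LocusRecord],
        a1: np.ndarray,
        a2: np.ndarray,
        skipped_indels: int = 0,
    ) -> None:
        self.samples = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        self.loci = list(loci)
        self.a1 = np.asarray(a1, dtype=np.int8)
        self.a2 = np.asarray(a2, dtype=np.int8)
        self.skipped_indels = skipped_indels
        shape = (len(self.samples), len(self.loci))
        if self.a1.shape != shape or self.a2.shape != shape:
            raise ValueError(
                f"call grid {self.a1.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if ((self.a1 < 0) != (self.a2 < 0)).any():
            raise ValueError("half-missing calls in grid")
        for j, loc in enumerate(self.loci):
            top = len(loc.alleles) - 1
            col_max = max(self.a1[:, j].max(initial=-1), self.a2[:, j].max(initial=-1))
            if col_max > top:
                raise ValueError(f"allele index out of range at {loc.id}")

    # -- basic shape ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): True where the call is missing."""
        return self.a1 < 0

    def locus_index(self, locus_id: str) -> int:
        for j, loc in enumerate(self.loci):
            if loc.id == locus_id:
                return j
        raise KeyError(locus_id)

    # -- call access ------------------------------------------------------

    def call(self, i: int, j: int) -> GenotypeCall:
        ai, bi = int(self.a1[i, j]), int(self.a2[i, j])
        if ai < 0:
            return MISSING
        alleles = self.loci[j].alleles
        return GenotypeCall(alleles[ai], alleles[bi])

    def calls_at(self, j: int) -> list[GenotypeCall]:
        """All samples' calls at locus column ``j``."""
        return [self.call(i, j) for i in range(self.n_samples)]

    def genotype_string(self, i: int, j: int) -> str:
        return self.call(i, j).to_string()

    def profile(self, i: int, loci_idx: Sequence[int] | None = None) -> tuple[str, ...]:
        """Sample ``i``'s genotype-string profile over the given loci."""
        idx = range(self.n_loci) if loci_idx is None else loci_idx
        return tuple(self.genotype_string(i, j) for j in idx)

    # -- subsetting -------------------------------------------------------

    def subset_loci(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            self.samples,
            [self.loci[j] for j in keep],
            self.a1[:, keep],
            self.a2[:, keep],
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci)"


def matrix_from_calls(
    samples: Sequence[str],
    loci: Sequence[LocusRecord],
    calls: Sequence[Sequence[GenotypeCall]],
) -> GenotypeMatrix:
    """Build a matrix from a samples-major nested list of calls."""
    n, m = len(samples), len(loci)
    a1 = np.full((n, m), -1, dtype=np.int8)
    a2 = np.full((n, m), -1, dtype=np.int8)
    for j, loc in enumerate(loci):
        lookup = {al: k for k, al in enumerate(loc.alleles)}
        for i in range(n):
            c = calls[i][j]
            if c.is_missing:
                continue
            try:
                a1[i, j] = lookup[c.allele_a]
                a2[i, j] = lookup[c.allele_b]
            except KeyError as e:
                raise ValueError(
                    f"call {c.to_string()} at {loc.id} uses allele outside "
                    f"{loc.alleles}"
                ) from e
    return GenotypeMatrix(samples, loci, a1, a2)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    region_classes: Mapping[tuple[str, int], str] | None = None,
) -> GenotypeMatrix:
    """Load SNP rows of a VCF 4.x into a :class:`GenotypeMatrix`.

    Indel rows (any allele longer than one base, or symbolic) are skipped and
    counted in ``matrix.skipped_indels``.  Missing genotypes (``./.``) become
    missing calls.  ``region_classes`` optionally maps ``(chrom, pos)`` to a
    region label (e.g. from an annotation table).
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as e:
        raise VcfFormatError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vf.header.samples)
    loci: list[LocusRecord] = []
    cols_a1: list[np.ndarray] = []
    cols_a2: list[np.ndarray] = []
    skipped = 0
    for rec in vf:
        alts = tuple(a for a in (rec.alts or ()))
        alleles = (rec.ref,) + alts
        if any(a is None or len(a) != 1 or a not in NUCLEOTIDES for a in alleles):
            skipped += 1
            continue
        n_alleles = len(alleles)
        c1 = np.full(len(samples), -1, dtype=np.int8)
        c2 = np.full(len(samples), -1, dtype=np.int8)
        depths = np.zeros(len(samples), dtype=np.int64)
        have_dp = False
        for i, s in enumerate(samples):
            sd = rec.samples[s]
            gt = sd.get("GT", (None, None))
            if gt is None or len(gt) < 2 or gt[0] is None or gt[1] is None:
                pass
            else:
                if gt[0] >= n_alleles or gt[1] >= n_alleles:
                    raise RecordError(
                        f"GT allele index out of range at {rec.chrom}:{rec.pos}"
                    )
                c1[i], c2[i] = gt[0], gt[1]
            dp = sd.get("DP")
            if dp is not None:
                have_dp = True
                depths[i] = int(dp)
        loci.append(
            LocusRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=alts,
                qual=None if rec.qual is None else float(rec.qual),
                depth_per_sample=depths if have_dp else None,
                region_class=(region_classes or {}).get((rec.chrom, rec.pos)),
            )
        )
        cols_a1.append(c1)
        cols_a2.append(c2)
    vf.close()
    if skipped:
        logger.info("read_vcf: skipped %d non-SNP row(s)", skipped)
    n, m = len(samples), len(loci)
    a1 = np.stack(cols_a1, axis=1) if m else np.empty((n, 0), dtype=np.int8)
    a2 = np.stack(cols_a2, axis=1) if m else np.empty((n, 0), dtype=np.int8)
    return GenotypeMatrix(samples, loci, a1, a2, skipped_indels=skipped)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix as an uncompressed VCF 4.2 with GT (and DP if present).

    Loci are emitted sorted by chromosome then position.
    """
    header = pysam.VariantHeader()
    header.formats.add("GT", 1, "String", "Genotype")
    any_depth = any(loc.depth_per_sample is not None for loc in matrix.loci)
    if any_depth:
        header.formats.add("DP", 1, "Integer", "Read depth")
    for chrom in sorted({loc.chrom for loc in matrix.loci}):
        header.contigs.add(chrom)
    for s in matrix.samples:
        header.add_sample(s)
    order = sorted(range(matrix.n_loci), key=lambda j: (matrix.loci[j].chrom, matrix.loci[j].pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            loc = matrix.loci[j]
            rec = out.new_record(
                contig=loc.chrom,
                start=loc.pos - 1,
                stop=loc.pos,
                alleles=loc.alleles,
                qual=loc.qual,
            )
            for i, s in enumerate(matrix.samples):
                ai, bi = int(matrix.a1[i, j]), int(matrix.a2[i, j])
                rec.samples[s]["GT"] = (None, None) if ai < 0 else (ai, bi)
                if loc.depth_per_sample is not None:
                    rec.samples[s]["DP"] = int(loc.depth_per_sample[i])
            out.write(rec)


# ---------------------------------------------------------------------------
# TSV genotype tables
# ---------------------------------------------------------------------------

def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a samples-rows x loci-columns TSV of two-letter genotype strings."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(loc.id for loc in matrix.loci) + "\n")
        for i, s in enumerate(matrix.samples):
            row = [matrix.genotype_string(i, j) for j in range(matrix.n_loci)]
            fh.write(s + "\t" + "\t".join(row) + "\n")


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read a samples x loci TSV of two-letter genotype strings ("NN" missing).

    Locus records are reconstructed from the observed alleles: the
    alphabetically first observed allele becomes the reference.  Column
    headers of ``chrom-pos`` form are split back into coordinates.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    locus_ids = header[1:]
    samples: list[str] = []
    cells: list[list[str]] = []
    for r, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise GenotypeParseError(f"row {r}: expected {len(header)} fields")
        samples.append(parts[0])
        cells.append(parts[1:])
    calls_grid: list[list[GenotypeCall]] = []
    for r, row in enumerate(cells, start=2):
        calls_row = []
        for c, cell in enumerate(row):
            try:
                calls_row.append(GenotypeCall.from_string(cell))
            except ValueError as e:
                raise GenotypeParseError(
                    f"row {r}, column {locus_ids[c]!r}: {e}"
                ) from e
        calls_grid.append(calls_row)
    loci = []
    for c, lid in enumerate(locus_ids):
        observed = sorted(
            {al for row in calls_grid for al in
             ((row[c].allele_a, row[c].allele_b) if not row[c].is_missing else ())}
        )
        chrom, _, pos_s = lid.rpartition("-")
        try:
            pos = int(pos_s)
            if not chrom:
                raise ValueError
        except ValueError:
            chrom, pos = lid, c + 1  # fall back: opaque id, synthetic position
        if not observed:
            observed = ["A"]  # all-missing column: placeholder ref
        loci.append(LocusRecord(chrom=chrom, pos=pos, ref=observed[0], alts=tuple(observed[1:])))
    return matrix_from_calls(samples, loci, calls_grid)


# ---------------------------------------------------------------------------
# Reference FASTA flanks
# ---------------------------------------------------------------------------

class ReferenceMismatchError(ValueError):
    """Reference base at the locus does not equal the locus ref allele."""


@dataclass
class FlankWindow:
    """Sequence context around one SNP, excluding the SNP base itself.

    ``upstream_seq`` are the bases immediately 5' of the SNP on the forward
    strand, ``downstream_seq`` the bases immediately 3'.  Windows shorter
    than ``window_len_each_side`` (contig edge) carry a truncation flag.
    """

    locus: LocusRecord
    upstream_seq: str
    downstream_seq: str
    window_len_each_side: int = 100
    truncated_upstream: bool = False
    truncated_downstream: bool = False

    def __post_init__(self) -> None:
        for seq in (self.upstream_seq, self.downstream_seq):
            if any(b not in "ACGTN" for b in seq):
                raise ValueError("flank sequences must be A/C/G/T/N")
        if len(self.upstream_seq) > self.window_len_each_side:
            raise ValueError("upstream flank longer than window")
        if len(self.downstream_seq) > self.window_len_each_side:
            raise ValueError("downstream flank longer than window")

    @property
    def full_window(self) -> str:
        """upstream + ref + downstream: the reference substring spanning the window."""
        return self.upstream_seq + self.locus.ref + self.downstream_seq

    @property
    def snp_offset(self) -> int:
        """0-based index of the SNP base inside :attr:`full_window`."""
        return len(self.upstream_seq)


def open_reference(path: str | Path) -> Fasta:
    """Open a FASTA with .fai-style random access (index built on demand)."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def extract_flank_window(
    reference: Fasta,
    locus: LocusRecord,
    each_side: int = 100,
    strict: bool = False,
) -> FlankWindow:
    """Extract ``each_side`` bases up- and downstream of a SNP.

    The SNP base itself is excluded from both flank strings.  In strict mode
    a reference/ref-allele mismatch raises; otherwise it warns.
    """
    if locus.chrom not in reference:
        raise KeyError(f"chromosome {locus.chrom!r} not in reference")
    contig = reference[locus.chrom]
    clen = len(contig)
    p0 = locus.pos - 1  # 0-based SNP offset
    if p0 >= clen:
        raise KeyError(f"position {locus.pos} beyond {locus.chrom} length {clen}")
    base = str(contig[p0:p0 + 1])
    if base != locus.ref:
        msg = f"reference base {base} != ref allele {locus.ref} at {locus.id}"
        if strict:
            raise ReferenceMismatchError(msg)
        logger.warning(msg)
    up_start = max(0, p0 - each_side)
    upstream = str(contig[up_start:p0])
    downstream = str(contig[p0 + 1:min(clen, p0 + 1 + each_side)])
    return FlankWindow(
        locus=locus,
        upstream_seq=upstream,
        downstream_seq=downstream,
        window_len_each_side=each_side,
        truncated_upstream=len(upstream) < each_side,
        truncated_downstream=len(downstream) < each_side,
    )
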