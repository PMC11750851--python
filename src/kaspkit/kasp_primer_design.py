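"""Tailed allele-specific (KASP) primer candidate construction.

A KASP assay genotypes one biallelic SNP with three oligos: two
allele-specific primers that end 3' exactly on the SNP base (one per
allele, identical otherwise) carrying the universal FAM and VIC tail
sequences, plus one common (universal) reverse primer on the opposite
strand.  Competitive extension of whichever allele-specific primer matches
the template, followed by tail-mediated fluorophore release, reads out the
genotype as a FAM/VIC signal ratio — no sequencing or gels.

Design constraints used here: body GC content strictly below 60%, body
melting temperature between 57 and 63 degrees C inclusive, amplicon not
exceeding 120 bp (5' body end to 5' body end, tails excluded).  Tm is the
nearest-neighbour thermodynamic model (50 mM monovalent salt, 200 nM
oligo) with the Wallace 2(A+T)+4(G+C) rule as a fast fallback.  Tails are
excluded from Tm/GC: they are universal and non-templated in early cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from Bio.SeqUtils import MeltingTemp as _mt

from .genotype_io import FlankWindow, LocusRecord
from .snp_filtering import reverse_complement

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
VIC_TAIL = "GAAGGTCGGAGTCAACGGATT"


@dataclass
class DesignConstraints:
    """Assay acceptance thresholds; GC is strict (<), Tm and product inclusive."""

    gc_max: float = 0.60
    tm_min: float = 57.0
    tm_max: float = 63.0
    product_max: int = 120
    body_len_min: int = 16
    body_len_max: int = 32
    tm_method: str = "nearest_neighbor"
    na_mM: float = 50.0
    oligo_nM: float = 200.0

    def __post_init__(self) -> None:
        if not self.tm_min < self.tm_max:
            raise ValueError("tm_min must be < tm_max")


def melting_temperature(
    seq: str,
    method: Literal["nearest_neighbor", "wallace"] = "nearest_neighbor",
    na_mM: float = 50.0,
    oligo_nM: float = 200.0,
) -> float:
    """Oligo melting temperature in degrees C.

    ``nearest_neighbor`` uses unified duplex thermodynamics at the given
    monovalent-salt and oligo concentrations; ``wallace`` is the
    2(A+T)+4(G+C) rule.  Ambiguity codes are rejected.
    """
    if len(seq) < 8:
        raise ValueError("sequence too short for a meaningful Tm (< 8 nt)")
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"ambiguity codes not supported: {seq!r}")
    if method == "wallace":
        return float(_mt.Tm_Wallace(seq))
    if method == "nearest_neighbor":
        return float(_mt.Tm_NN(seq, Na=na_mM, dnac1=oligo_nM, dnac2=0))
    raise ValueError(f"unknown Tm method {method!r}")


def gc_fraction(seq: str) -> float:
    return sum(b in "GC" for b in seq) / len(seq)


@dataclass
class PrimerOligo:
    """One oligo: body (5'->3'), optional universal tail, body Tm/GC.

    ``tail_seq`` is stored explicitly (defaulting to the published FAM/VIC
    sequence for the given tail) so synthesis-order errors can be detected
    by validation rather than silently normalised away.
    """

    body_seq: str
    tail: Literal["none", "FAM", "VIC"]
    tm_body: float
    gc_body: float
    strand: Literal["forward", "reverse"]
    tail_seq: str = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tail_seq is None:
            self.tail_seq = {"none": "", "FAM": FAM_TAIL, "VIC": VIC_TAIL}[self.tail]

    @property
    def full_seq(self) -> str:
        return self.tail_seq + self.body_seq


@dataclass
class KaspAssay:
    """Two tailed allele-specific primers + one common primer for one SNP."""

    locus: LocusRecord
    allele_specific_a: PrimerOligo  # FAM, alphabetically first allele
    allele_specific_b: PrimerOligo  # VIC, alphabetically second allele
    common: PrimerOligo
    product_len: int
    allele_a: str
    allele_b: str
    pass_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class DesignFailure:
    """Why no assay could be built; every failure names >=1 constraint."""

    locus: LocusRecord
    reasons: dict[str, str]


def _tm_gc_ok(seq: str, c: DesignConstraints) -> tuple[float, float, bool]:
    gc = gc_fraction(seq)
    tm = melting_temperature(seq, c.tm_method, c.na_mM, c.oligo_nM)  # type: ignore[arg-type]
    ok = (gc < c.gc_max) and (c.tm_min <= tm <= c.tm_max)
    return tm, gc, ok


def design_kasp_assay(
    window: FlankWindow,
    constraints: DesignConstraints | None = None,
    common_side: Literal["downstream", "upstream"] = "downstream",
) -> KaspAssay | DesignFailure:
    """Build a KASP assay from a SNP's flank window, or explain why not.

    The allele-specific primers sit on the forward strand ending 3' on the
    SNP base; their shared body is grown 5'-ward until Tm enters the target
    range (both allele variants must pass).  The common primer is scanned on
    the opposite strand ``common_side`` of the SNP within the amplicon
    budget; the best candidate minimises |Tm - 60| then product length.
    The FAM tail goes on the alphabetically first allele, VIC on the second.
    """
    c = constraints or DesignConstraints()
    locus = window.locus
    if len(locus.alts) != 1:
        return DesignFailure(locus, {"biallelic": f"{len(locus.alleles)} alleles"})
    alleles = sorted((locus.ref, locus.alts[0]))

    if common_side == "upstream":
        # mirror the problem: design on the reverse-complemented window with
        # complemented alleles, then swap strand labels back
        flipped = FlankWindow(
            locus=LocusRecord(
                chrom=locus.chrom, pos=locus.pos,
                ref=reverse_complement(locus.ref),
                alts=(reverse_complement(locus.alts[0]),),
                qual=locus.qual,
            ),
            upstream_seq=reverse_complement(window.downstream_seq),
            downstream_seq=reverse_complement(window.upstream_seq),
            window_len_each_side=window.window_len_each_side,
        )
        res = design_kasp_assay(flipped, c, "downstream")
        if isinstance(res, DesignFailure):
            return DesignFailure(locus, res.reasons)
        # report on the original locus; strands flip
        for p in (res.allele_specific_a, res.allele_specific_b):
            p.strand = "reverse"
        res.common.strand = "forward"
        res.locus = locus
        return res

    upstream = window.upstream_seq
    downstream = window.downstream_seq

    # --- allele-specific bodies: grow 5'-ward from the SNP ---------------
    best_as = None  # (score, length, tmA, tmB, gcA, gcB)
    reason_as = "no body length in range"
    for L in range(c.body_len_min, c.body_len_max + 1):
        if L - 1 > len(upstream):
            reason_as = "upstream flank exhausted before Tm reached range"
            break
        stem = upstream[len(upstream) - (L - 1):]
        tms, gcs, oks = [], [], []
        for al in alleles:
            tm, gc, ok = _tm_gc_ok(stem + al, c)
            tms.append(tm)
            gcs.append(gc)
            oks.append(ok)
        if all(oks):
            score = max(abs(tms[0] - 60.0), abs(tms[1] - 60.0))
            if best_as is None or score < best_as[0]:
                best_as = (score, L, tms, gcs)
        elif best_as is None:
            reason_as = (
                f"at length {L}: Tm=({tms[0]:.1f},{tms[1]:.1f}) "
                f"GC=({gcs[0]:.2f},{gcs[1]:.2f}) outside constraints"
            )
    if best_as is None:
        return DesignFailure(locus, {"allele_specific": reason_as})
    _, La, tms, gcs = best_as
    stem = upstream[len(upstream) - (La - 1):]

    # --- common primer: reverse strand, downstream of the SNP ------------
    # spans window offsets [s, e] (0-based, relative to downstream string);
    # its 5' end is at e; product = La + e + 1 (SNP..e inclusive plus body)
    best_common = None  # (|tm-60|, product, e, length, tm, gc)
    reason_common = "downstream flank too short"
    for e in range(c.body_len_min - 1, len(downstream)):
        product = La + e + 1
        if product > c.product_max:
            break
        for Lc in range(c.body_len_min, min(c.body_len_max, e + 1) + 1):
            s = e - Lc + 1
            body = reverse_complement(downstream[s:e + 1])
            tm, gc, ok = _tm_gc_ok(body, c)
            if not ok:
                reason_common = (
                    f"best rejected candidate: Tm={tm:.1f} GC={gc:.2f} "
                    f"(need {c.tm_min}<=Tm<={c.tm_max}, GC<{c.gc_max})"
                )
                continue
            key = (abs(tm - 60.0), product, Lc)
            if best_common is None or key < best_common[0]:
                best_common = (key, e, Lc, body, tm, gc)
        if best_common is not None and best_common[0][0] <= 0.25:
            break  # near-ideal Tm found; shorter products were tried first
    if best_common is None:
        return DesignFailure(locus, {"common": reason_common})
    _, e, Lc, common_body, tm_c, gc_c = best_common

    assay = KaspAssay(
        locus=locus,
        allele_specific_a=PrimerOligo(stem + alleles[0], "FAM", tms[0], gcs[0], "forward"),
        allele_specific_b=PrimerOligo(stem + alleles[1], "VIC", tms[1], gcs[1], "forward"),
        common=PrimerOligo(common_body, "none", tm_c, gc_c, "reverse"),
        product_len=La + e + 1,
        allele_a=alleles[0],
        allele_b=alleles[1],
    )
    assay.pass_flags = validate_assay(assay, c)
    return assay


def validate_assay(assay: KaspAssay, constraints: DesignConstraints | None = None) -> dict[str, bool]:
    """Re-check every constraint on a finished assay; True means pass.

    Rules: body GC < gc_max (strict) on all three bodies; body Tm within
    [tm_min, tm_max] inclusive; product length <= product_max inclusive;
    allele-specific 3'-terminal bases equal their alleles and the two bodies
    differ nowhere else; tail sequences byte-identical to the published
    FAM/VIC tails.
    """
    c = constraints or DesignConstraints()
    a, b, common = assay.allele_specific_a, assay.allele_specific_b, assay.common
    bodies = (a.body_seq, b.body_seq, common.body_seq)
    flags = {
        "gc": all(gc_fraction(s) < c.gc_max for s in bodies),
        "tm": all(
            c.tm_min <= melting_temperature(s, c.tm_method, c.na_mM, c.oligo_nM) <= c.tm_max  # type: ignore[arg-type]
            for s in bodies
        ),
        "product": assay.product_len <= c.product_max,
        "allele_terminal": (
            a.body_seq[-1] == assay.allele_a and b.body_seq[-1] == assay.allele_b
        ),
        "bodies_differ_only_3prime": (
            len(a.body_seq) == len(b.body_seq)
            and a.body_seq[:-1] == b.body_seq[:-1]
            and a.body_seq[-1] != b.body_seq[-1]
        ),
        "tails": a.tail_seq == FAM_TAIL and b.tail_seq == VIC_TAIL,
    }
    return flags
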