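import textwrap
from dataclasses import replace

import pytest

import kaspkit as kk

VCF_3SAMPLE = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
    chr1\t100\t.\tA\tG\t35\t.\t.\tGT:DP\t0/0:8\t0/1:6\t1/1:9
    chr1\t250\t.\tC\tT\t50\t.\t.\tGT:DP\t0/0:7\t./.:0\t0/1:5
    chr1\t400\t.\tAT\tA\t60\t.\t.\tGT:DP\t0/0:7\t0/0:8\t0/1:6
    """)


@pytest.fixture
def three_sample_vcf(tmp_path):
    """Two SNP rows plus one 2-bp deletion row over samples S1-S3."""
    p = tmp_path / "three.vcf"
    p.write_text(VCF_3SAMPLE)
    return p


@pytest.fixture
def sim_matrix():
    """50-cultivar structured matrix with depth/qual metadata, seeded."""
    cfg = kk.SimulationConfig(seed=101, n_loci=120)
    matrix, truth = kk.simulate_structured_genotypes(cfg)
    kk.simulate_locus_metadata(matrix, cfg, truth=truth)
    return matrix, truth


@pytest.fixture
def planted_reference(tmp_path):
    """Synthetic contig with 6 planted SNPs: 1 dirty-flank, 1 duplicated-window."""
    cfg = kk.ReferenceSimConfig(
        seed=7, n_snps=6, n_dirty_neighbor=1, n_duplicated_window=1
    )
    fasta, matrix, labels = kk.simulate_reference_with_snps(cfg, tmp_path / "ref.fa")
    return kk.open_reference(str(fasta)), matrix, labels


def calls_matrix(genotype_rows, chrom="chr1", start_pos=100, spacing=1000):
    """Build a GenotypeMatrix from rows of genotype strings (samples x loci)."""
    n_loci = len(genotype_rows[0])
    samples = [f"S{i+1}" for i in range(len(genotype_rows))]
    grids = [[kk.GenotypeCall.from_string(g) for g in row] for row in genotype_rows]
    loci = []
    for j in range(n_loci):
        observed = sorted(
            {al for row in grids for al in
             ((row[j].allele_a, row[j].allele_b) if not row[j].is_missing else ())}
        ) or ["A"]
        loci.append(
            kk.LocusRecord(
                chrom=chrom, pos=start_pos + j * spacing,
                ref=observed[0], alts=tuple(observed[1:]),
            )
        )
    return kk.matrix_from_calls(samples, loci, grids)
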