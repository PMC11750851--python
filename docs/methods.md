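# Methods

## Problem setting

A cultivar collection genotyped at many biallelic SNPs yields, per sample,
an unordered diploid allele-pair call (or a no-call) at each locus.  The
engineering goal is a small marker subset such that every pair of cultivars
differs at at least one marker — a *minimum test cover*: locus L "covers"
the sample pair (i, j) when both calls at L are present and unequal, and a
panel is feasible when its loci jointly cover every coverable pair.
Cultivars with byte-identical profiles over all candidate loci (including
the missing pattern) form *duplicate groups*; no marker can separate them,
so their internal pairs are excluded from the objective and the groups are
reported as candidate synonyms for downstream morphological (DUS)
adjudication.  A no-call is treated as certifying nothing: a pair whose
profiles differ only where one member is missing stays in the universe but
may be uncoverable, and then appears in the panel's residual rather than
being silently declared distinct.

## Diversity indices

All indices are computed from observed allele frequencies at each locus,
counting two allele copies per called sample and excluding missing calls
from the denominator.

* **PIC** = 1 − Σᵢ Pᵢ² − Σᵢ<ⱼ 2Pᵢ²Pⱼ², summed over *distinct alleles*.
  For a biallelic locus this is 1 − (p²+q²) − 2p²q², strictly increasing
  in MAF with maximum 0.375 at p = q = 0.5.  The allele-indexed reading is
  fixed by its printed endpoint values: MAF 0.479 → PIC 0.375 and MAF
  0.125 → PIC 0.195 at three decimals, which a sample-indexed summation
  cannot reproduce.
* **HetExp (HE)** = 1 − Σᵢ Pᵢ², with no n/(n−1) small-sample factor —
  again pinned by the endpoint pairs (0.479 → 0.499, 0.125 → 0.219; the
  corrected form misses both).
* **Pi (per-site nucleotide diversity)** is reported equal to HE, i.e.
  per-site heterozygosity without pairwise-sample correction, matching how
  the two columns coincide in the reference index table.
* **HetObs** is the fraction of called samples that are heterozygous;
  **Fis** = 1 − HetObs/HetExp per locus, undefined (and excluded from
  averages) at monomorphic loci.  Population-level Fis is the
  average-of-ratios; a ratio-of-averages convention gives slightly
  different numbers, so cross-study comparisons of mean Fis are only
  indicative.
* **Ne** = 1/ΣᵢPᵢ² = 1/(1 − Pi); **MAF** is the frequency of the second
  most common allele (identical to the minor frequency for biallelic loci,
  well-defined for the multiallelic loci the filters later remove).

Displayed values are rounded half-up to 3 decimals; internal values keep
full precision.

## Filter cascades

Two screens with fixed rule order; each removed locus is attributed to the
first rule it fails, so reports are deterministic, while the surviving set
is a pure conjunction (order-independent).

* **Population-grade**: mean per-sample depth ≥ 5× (mean, not per-sample
  minimum — the conventional reading of "average depth"), MAF ≥ 0.05,
  call rate ≥ 0.70 ("information integrity" read as completeness), site
  quality Q ≥ 30, exactly two observed alleles.  All thresholds inclusive.
* **KASP-candidate**: flank conservation — no other variant within 50 bp
  (a neighbour at exactly 50 bp fails, i.e. conservation must exceed
  50 bp); depth and biallelism re-checked; flank-window uniqueness — the
  201-mer (100 bp each side plus the SNP) must occur exactly once in the
  reference over both strands, found by an exact 31-mer seeded scan with
  full-window confirmation (an optional hook accepts precomputed aligner
  hit counts instead); PIC strictly > 0.020.  Exact-match uniqueness is
  deterministic and dependency-free; it is stricter than an aligner that
  tolerates mismatched secondary hits.

MAF and PIC are always recomputed on the matrix being filtered, never
cached, so cascades compose.

## Panel selection

Greedy set cover: repeatedly take the locus covering the most uncovered
pairs; break ties by higher PIC, then chrom:pos order, making runs
byte-reproducible.  A backward pass removes any marker whose coverage
became redundant, so the output is inclusion-minimal.  Greedy panels are
labelled *greedy-minimal*: the classical ln(n) approximation bound applies,
and `exact_min_panel` (ascending-size exhaustive enumeration, refused above
20 candidate loci) certifies global minimality on small instances — on 200
random instances (≤ 10 loci × ≤ 12 samples) greedy always achieved full
coverage and never undercut the optimum.  `verify_panel` recomputes
pairwise distinctness from scratch and checks the information floor
⌈log₃ m⌉ for m distinct profiles (three genotype states per biallelic
co-dominant marker); for 83 distinct cultivars the floor is 5 markers.

## KASP primer construction

Each assay is two allele-specific primers and one common primer.  The
allele-specific bodies sit on the reference forward strand and end 3′
exactly on the SNP base, one per allele, identical elsewhere; the shared
5′ stem is grown from 16 up to 32 nt until both variants' Tm enter
[57, 63] °C, preferring the length minimising the worse |Tm − 60|.  The
universal FAM tail (GAAGGTGACCAAGTTCATGCT) goes on the alphabetically
first allele and the VIC tail (GAAGGTCGGAGTCAACGGATT) on the second — a
determinism convention, not chemistry; real assay sheets assign tails
arbitrarily.  The common primer is scanned on the reverse strand
downstream of the SNP (an `upstream` option mirrors the search), product
length measured 5′ body end to 5′ body end, tails excluded; the best
candidate minimises |Tm − 60| then product length, with an early stop once
a candidate within 0.25 °C of 60 is found among the shortest products.
Tm is Biopython's nearest-neighbour model at 50 mM monovalent salt and
200 nM oligo (configurable; the Wallace 2(A+T)+4(G+C) rule is available
as a fast fallback), computed on bodies only, since tails are universal
and untemplated in early cycles.  GC < 60% is strict; Tm bounds and the
120 bp product cap are inclusive.  Every emitted assay is re-validated
post hoc; failures return a report naming at least one violated
constraint.  On 50%-GC random 260 bp windows roughly 60–85% of SNPs are
designable under the defaults; GC-skewed flanks are the dominant failure
mode, as in practice.  A deliberate destabilising mismatch near the 3′
end of the allele-specific primers (common in commercial KASP design) is
not implemented.

## Fingerprints

Genotype strings are canonical alphabetical pairs ("GA" is an error, not
an alias), "NN" for no-calls.  The color legend is fixed: AA green,
AG light pink, CC yellow, CT grey ("grew" in the source legend is read as
a typo for grey), GT dark red, TT blue, AC pink, AT orange, CG light
blue, GG purple, NN white.  Hex values are this package's convention
(names only are inherited).  Tables are written loci-as-rows ×
samples-as-columns; SVG rendering pins matplotlib's hash salt and strips
timestamps so identical inputs give identical bytes.

## Synthetic data

`simulate_structured_genotypes` draws, per locus, an ancestral minor
allele frequency ~ Uniform(0.05, 0.5) (ref allele = ancestral major), and
per subpopulation k a frequency from the Balding–Nichols Beta
distribution with differentiation parameter F (exactly the ancestral
frequency when F = 0).  Genotypes follow inbreeding-adjusted
Hardy–Weinberg: P(het) = 2pq(1−f), homozygotes gaining fpq each.  Missing
calls are i.i.d.; per-sample depth is negative binomial; site quality is
Gamma, floored at 30.5 so only deliberately planted loci can fail the
quality rule.  Defaults are the study conditions this toolkit mirrors:
50 cultivars in K = 4 groups of 14/5/23/8 (the `ensifolium83` preset
scales to 83 in groups of 23/8/38/14 and injects duplicate groups of 4
and 2), subpopulation F = 0.10 (moderate differentiation typical of
regionally structured ornamental germplasm), f = 0.25 (matching the
observed heterozygote deficit, Fis ≈ 0.25), 10% missing calls, mean
depth 6.6× with dispersion 3.  `simulate_reference_with_snps` writes a
random contig with planted SNPs whose flanks are clean, or deliberately
dirty (a neighbour variant 49 bp away) or non-unique (the 201-bp window
copied elsewhere), with truth labels.

The generator reproduces the *statistical* shape the pipeline assumes —
exchangeable loci, i.i.d. missingness, no linkage, no genotyping-error
model, no restriction-site dropout shared across related samples.
Passing tests therefore demonstrate algorithmic correctness under those
assumptions, not robustness to allele dropout or batch effects in real
ddRAD data.

Parameter recovery is checked with an in-house Hudson-style Fst estimator
(ratio of sums of pairwise numerators/denominators with the standard
finite-sample correction, averaged over subpopulation pairs): at 2,000
loci × 200 samples it recovers configured F ∈ {0.05, 0.1, 0.2} within
±0.02.

## Problem sizes and numerical choices

The bundled test and demonstration scales — up to 83 samples × 500
candidate loci for panel selection, 2,000 loci × 200 samples for
parameter recovery, 100 SNPs for primer batches — were chosen so each
stage's behaviour is statistically visible while the full suite runs in
well under a minute; all stages scale linearly in loci and quadratically
in samples (pair enumeration).  Frequencies must sum to 1 within 1e-9;
the PIC implementation agrees with a brute-force double-loop evaluation
to 1e-12.  Greedy tie-breaks and FAM/VIC assignment are fixed as above;
seeds are mandatory in every simulator config, and all simulators are
pure functions of (config, seed).

## Known limitations

* Uniqueness is exact-match only; paralogues diverged by ≥ 1 mismatch
  within the window are not flagged (an aligner hit-count hook exists).
* No primer secondary-structure (hairpin/dimer) thermodynamics.
* Greedy panels are heuristic beyond the exhaustive regime; optimality is
  certified only when `exact_min_panel` confirms.
* The simulator draws loci independently; it cannot emulate linkage
  blocks or shared library-prep dropout.
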