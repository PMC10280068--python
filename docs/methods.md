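# Methods

## Problem setting and model

`ighap` treats a deep amplicon sequencing run of one nuclear locus from one
individual as a sample from a finite mixture of sequence variants. In a
genetically mosaic organism, different cells carry different versions of
the locus; PCR and sequencing sample those versions in proportion to their
cellular abundance, corrupted by per-base sequencing error and PCR chimera
formation. The analysis goal is to recover the set of true variants — the
*haplotypes*, in the operational sense of clusters of identical reads — and
to characterise how they differ.

The package's working assumptions:

- reads are already merged into one record per molecule (paired-end overlap
  merging is upstream and out of scope);
- a true haplotype is sampled often enough to clear an abundance threshold,
  while error-derived variants stay individually rare — the rationale behind
  the 1 % proportion rule;
- the locus is short enough (a few hundred bp) that exact string identity,
  not clustering with mismatch tolerance, defines a variant;
- the rank-1 (most abundant) sequence is a faithful copy of the locus
  reference, so gene-model coordinates can be anchored to it.

## Pipeline rules

**Quality trimming** removes bases from the 3′ end inward while their Phred
quality is below `q_min` (default 20), stopping at the first base at or
above the threshold; internal low-quality bases are retained. Trimming from
both ends is available behind `trim_both_ends` (default off, matching the
standard 3′-decay reading of Illumina quality profiles). The operation is
idempotent, and an empty result is valid (the read is then discarded).

**Primer matching** is end-anchored and exact: a read is kept iff it begins
with the forward primer and ends with the reverse complement of the reverse
primer, testing the read's reverse complement as well and returning the
insert in forward orientation. Any mismatch in a primer region — including
an N — rejects the read. This is the strictest reading of "perfect match"
and deliberately trades yield for specificity.

**Dereplication** groups identical inserts; ranks are assigned by count
descending with lexicographic tie-break for determinism. Proportions are
count/total rounded half-up to 4 decimal places; the rounded value is what
all thresholds see, so 0.0100 is "not over 1 %" while 0.0101 is.

**Chimera flagging** marks a unique sequence as chimeric iff two *distinct*
parents exist, each at least `chimera_factor` (default 2×) its count and of
equal length, such that the candidate equals parent A on `[0, b)` and
parent B on `[b, L)` for some breakpoint `1 ≤ b ≤ L−1`. Sequences of
unequal length and the most abundant sequence are never flagged. This is a
uchime-style de-novo rule restricted to ungapped, equal-length comparison;
on deep runs it also absorbs a share of error-derived singleton reads that
happen to be explainable as splices of two abundant variants — harmless
here, since flagged sequences are all far below the haplotype threshold.
The scan is vectorised (byte-matrix longest-common-prefix/suffix against
each candidate) so tens of thousands of uniques are processed in seconds.

**Haplotype calling.** Tissue mode keeps unique sequences with rounded
proportion strictly greater than `min_prop` (default 0.01). Single-cell
mode keeps the `top_n` (default 10) by count for alignment and reporting,
and marks an entry valid only if it clears `min_prop` *and* is not a
private-singleton artifact: an entry is error-flagged when every alignment
column where it differs from the rank-1 entry is private to it (no other
entry differs from rank 1 there). A variant supported by no second
observation at any of its sites is indistinguishable from amplification or
sequencing error, which is exactly the failure mode of whole-genome
amplified single cells.

**Alignment** is a reference-anchored star alignment: each entry is
globally aligned to the rank-1 entry by Needleman–Wunsch with affine gaps
(match +1, mismatch −1, gap open −4 for the first gap base, −1 per
extension), then pairwise gaps are projected into shared columns (a gap
opened against the reference at offset *o* by any entry creates a block of
the maximal insertion length seen at *o*; shorter insertions are
left-aligned and padded). Traceback ties prefer substitutions over gaps and
deletions over insertions, which places gaps at their leftmost equivalent
position — indels inside homopolymer runs are therefore reported at the
run's first base. For same-locus amplicons differing by SNPs the projection
is exact; with rare short indels it is deterministic and reproducible,
which is what the downstream site-calling rules require. A full progressive
MSA would add nothing for this input class.

**NJ trees** use p-distance (fraction of differing bases over columns where
both rows are ungapped) and scikit-bio's neighbor-joining; sets of one or
two entries return trivial trees directly. Entries at distance zero (e.g.
differing only by an indel) appear as zero-length cherries; branch lengths
are exactly zero only for additive inputs.

**SNP sites.** Every alignment column with ≥ 2 distinct bases among valid
rows is one site: a transition or transversion when biallelic, multiallelic
otherwise (one site, with each observed unordered base pair contributing to
the substitution spectrum). Maximal runs of consecutive gap columns carried
by the same haplotype subset collapse to a single indel event — an extended
deletion counts once — and runs split wherever the carrier subset changes.
Coordinates are 0-based half-open internally and 1-based in reports.
Density is sites per kb of *ungapped reference* length (not alignment
length); insertion events take the region of the flanking reference base to
the left. The total SNP count is transitions + transversions + indel
events.

**Codon impact.** Exon columns are lifted onto spliced coding coordinates
(reverse-complemented for − strand models, reading frame from the model's
`frame` field). Each variable exon site yields one codon change per
observed alternate base, classified synonymous/nonsynonymous by translating
reference and alternate codons under the standard genetic code (NCBI
table 1). Haplotypes whose deletions remove a splice boundary (first or
last base of an exon) or shift the frame are excluded from the exon and
protein collapse and counted separately; with intron-confined single-base
deletions (the default generative model) this path is exercised only by
synthetic edge cases. The three-level collapse — distinct genomic
sequences, distinct spliced CDSs, distinct proteins — is monotonically
non-increasing by construction.

## The simulator

`SimulationConfig` defaults define the reference study conditions used
throughout the tests:

| parameter | default | meaning |
| --- | --- | --- |
| `locus_length` | 300 bp | insert length, matching a ~300 bp merged amplicon |
| `exon_intervals` | [0,100) and [200,300) | two exons flanking one intron |
| `n_haplotypes`, `haplotype_freqs` | 5 at 0.40/0.30/0.15/0.10/0.05 | mosaic mixture |
| `snp_rate_exon` / `snp_rate_intron` | 0.005 / 0.02 per base | intron density 4× exon |
| `tstv_kappa` | 2.0 | transition:transversion odds per substitution |
| `indel_rate_intron` | 0.001 per intron base | rare single-base deletions, introns only |
| `read_depth` | 20,000 | reads per run |
| `per_base_error` | 0.002 | i.i.d. substitution error, uniform over alternatives |
| `chimera_rate` | 0.01 | probability a read is a two-parent splice |

Haplotype 1 is the unmutated reference; every other haplotype draws
Poisson(rate × region length) substitutions per region, each a transition
with probability κ/(κ+1) (the transition partner is deterministic; the two
transversion partners are equiprobable), plus intron-only single-base
deletions. Event sets that would leave a haplotype identical to an existing
one are redrawn: the model is a population of K *distinct* haplotypes, and
an undistinguishable "variant" is not a variant. Reads attach both primers,
apply errors i.i.d. per base, and carry a flat quality string encoding the
error rate's Phred value. Chimeras splice two distinct parents at a uniform
breakpoint. Given a seed, the FASTQ output is byte-identical across runs.

What the simulator does **not** emulate — and hence what passing recovery
tests do not establish about real data: position-dependent quality decay,
polymerase-specific error spectra, PCR-cycle error accumulation and
abundance skew, insertions, multi-base deletions (representable but off by
default), and any relationship between haplotype frequency and cell
lineage. The defaults are calibration knobs for exercising the pipeline,
not claims about the mutational process of any organism.

## Numerical and design choices

- **Threshold boundary**: ">1 %" is strict inequality on the *rounded*
  proportion; exactly 0.0100 is excluded.
- **Rounding**: half-up (not banker's) to 4 decimals, implemented with
  decimal arithmetic to avoid binary-float artifacts.
- **Tie-breaks**: dereplication ranks break count ties lexicographically;
  alignment traceback prefers substitution > deletion > insertion. Both
  exist purely for determinism.
- **Degenerate inputs**: empty trimmed reads are dropped, not errors; no
  unique sequence above threshold yields an empty haplotype set with a
  warning; fewer than two valid haplotypes yields zero SNP sites with a
  warning; a Ts/Tv ratio with zero transversions is reported infinite with
  an explicit flag rather than raising.
- **Region convention**: half-open intervals; a feature's start coordinate
  belongs to that feature.
- **Indel normalisation**: within a homopolymer run, all deletion positions
  are equivalent; the reported coordinate is the leftmost.
- **Genetic code**: standard table 1 throughout. One published codon table
  this package was checked against prints an amino-acid pair inconsistent
  with its own codons (AGA/AAA printed as A/K); the implementation follows
  the genetic code (R/K) rather than reproducing the typo.
- **Determinism**: all randomness is confined to the simulator and driven
  by a single integer seed; analysis stages are pure functions of their
  inputs, so re-running a pipeline reproduces the bundle byte for byte.

## Test problem sizes

The recovery acceptance test runs 20 independent seeds at depth 20,000 and
0.2 % error on the 300 bp default locus — deep enough that a 5 % haplotype
is sampled ~500× after error thinning, and small enough that the whole
suite completes in about a minute. Ts/Tv calibration pools short
intron-only simulations until ≥ 500 substitutions are planted, keeping
per-site collision bias small relative to the 3-SD acceptance band.
Alignment correctness is checked against exhaustive enumeration of all
global alignments on strings of ≤ 5 bases and against an independent
affine-gap aligner on strings of ≤ 20 bases.

## Known limitations

- Gene-model coordinates are anchored to the rank-1 haplotype; if the most
  abundant variant itself carried an indel relative to the true locus
  reference, region assignments downstream of it would shift.
- Exact-string dereplication means a haplotype is only recovered if some
  reads are entirely error-free over the insert; at error rates or lengths
  where that probability collapses, abundance thresholds on exact strings
  are the wrong tool (denoising would be required upstream).
- The chimera rule inspects equal-length sequences only; a chimera whose
  parents differ in length is invisible to it.
- Multiallelic sites count once toward density but contribute several pairs
  to the substitution spectrum; at high planted densities, coinciding
  mutations bias the site-level Ts/Tv estimate slightly toward low values.
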