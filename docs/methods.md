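# Methods

## Junction windows and candidate geometry

A circRNA record follows BED12 conventions: 0-based half-open genomic
coordinates with exon blocks relative to the record start. The mature
sequence is the concatenation of exon-block sequences in genomic order,
reverse-complemented as a whole for minus-strand records, because reagents
are designed against the RNA sense strand. Canonical identifiers print the
raw annotation coordinates (`chrom|start|end|gene|`), with no coordinate
shifting.

The BSJ window joins the last `arm_left` bases of the mature sequence to its
first `arm_right` bases (defaults 20/20, giving the 40-nt design window with
the junction centred). The window is computed by indexing into the
circularly tiled mature string, so circles shorter than the combined arms
wrap around the origin rather than failing; such windows carry a `wrapped`
flag because their candidates can re-read the same bases twice, which
matters for off-target interpretation. The windows are built from the mature
(spliced) sequence, not genomic flanks of the back-spliced exon boundaries:
the reagent binds the transcript, and only the spliced sequence represents
what the transcript contains around the joint.

Candidate enumeration slides a fixed-length frame over the window; a
candidate's junction geometry is summarized as `left+right` (bases 5' and 3'
of the junction; they always sum to the length). `min_overhang` (default 1)
sets the minimal overlap required on both sides; `min_overhang=5` with 24-nt
spacers reproduces the filtered library in which the `20+4`/`4+20` extremes
are absent, and `remove_linear_overlap_designs` (max arm 19 for 24-nt
spacers) applies the same removal to an existing library. Candidates
containing N are dropped with a warning.

shRNA→gRNA conversion extends the 21-nt target to 24 nt at its 3' end in
window coordinates, shifting 5' only at the window boundary (and a flag
mirrors the rule); this keeps the original 5'-proximal sequence intact and
guarantees the gRNA target contains the shRNA target and still spans the
junction. Spacer-length series (default 21–30 nt) anchor the target's 5' end
by default so members nest as prefixes; 3'-end anchoring is available.
Mismatch variants substitute the Watson-Crick complement (A↔T, G↔C — a
transversion at every position) at explicit 1-based positions, singly or as
consecutive pairs; variant positions are caller-supplied rather than
hard-coded because the informative positions vary by spacer.

## Off-target scan

The exclusion rule is: a candidate whose target sequence lies within 3
mismatches of any window of any transcriptome sequence is an off-target and
is excluded. The scan is an exact full-length Hamming comparison over every
transcript offset, vectorized with a byte-encoded sliding window; it
considers the forward strand only (target-sense candidate vs transcript
sense sequence) and does not model indels. An exact scan is strictly more
sensitive than a seeded heuristic aligner and — unlike heuristic misses — is
reproducible, which is why the test suite can hold it to an independent
brute-force oracle. `exempt_transcripts` lets linear-gene positive controls
match their own intended target; circRNA candidates should never exempt
anything, and the circRNA's own junction pseudo-sequence is not added to the
transcriptome.

Geometric consequences asserted on synthetic hosts: an arm-contained
(non-spanning) candidate is a verbatim host-mRNA substring (0 mismatches,
always excluded), while a centred junction-spanning candidate places ≥ 4
bases of one arm against non-matching host sequence at every offset, so
`12+12` designs cannot be excluded by the host transcript alone.

## Oligo assembly

Fixed synthesis templates: the gRNA oligo is a 35-nt 5' flank + spacer +
35-nt 3' flank (94-mer at the 24-nt design length; other lengths permitted
with a warning), and the shRNA oligo is a 19-nt prefix + 21-nt sense target
+ `ctcgag` loop + 21-nt antisense (reverse complement) + 25-nt suffix
(92-mer). Flanks are stored once as lowercase constants and byte-compared in
tests; inserts are uppercase, making round-trip extraction unambiguous. The
gRNA oligo embeds the spacer (protospacer complement) by default; a flag
embeds the target-sense sequence instead, since synthesis-table orientation
conventions differ. Pool-amplification primer pairs for both templates are
included; staggered NGS forward primers are batch-specific and configurable.

Non-targeting controls (default 150 windows of 24 nt) are sampled uniformly
without start replacement from the intergenic complement of a gene
annotation, rejecting windows with N; sampling is deterministic given the
seed and errors out when the intergenic space cannot host the requested
count.

## Screen scoring

Normalization is DESeq-style median-of-ratios computed over guides with
positive counts in all samples, falling back to total-count scaling (with a
warning) when no such guide exists. The per-guide statistic is
`log2((mean treatment + c)/(mean control + c))` of normalized counts with
pseudocount c = 1; guides are ranked ascending for negative selection and
descending for positive, ties broken by guide id for determinism. The
ranking statistic is deliberately the displayed screen quantity (normalized
LFC) rather than a count-model p-value; it is pluggable in the sense that
`score_genes` consumes any table of normalized ranks.

α-RRA (default α = 0.25): with sorted normalized ranks r(k), the gene score
is the minimum over eligible guides (r(k) ≤ α) of the Beta(k, n−k+1) CDF at
r(k), equivalently the binomial tail P(Bin(n, r(k)) ≥ k) — the identity is
cross-checked to 1e−12 in tests. Permutation p-values draw null genes of the
same size with ranks sampled uniformly without replacement from 1..N
(default 10⁴ permutations, `p = (1 + #{null ≤ obs})/(1 + N_perm)`, so p is
never 0); null draws are derived from one seeded random matrix and shared
across genes of equal size, which preserves marginal correctness and keeps
the run deterministic and fast. BH step-up adjustment (via statsmodels) maps
p to FDR per direction. With an α cutoff the null p-value distribution has a
point mass at 1 (genes with no guide in the top fraction), so p-values are
sub-uniform rather than uniform; the tests check exact uniformity at α = 1
and validity (sub-uniformity) at α = 0.25. Correlation reporting uses
Pearson on log2(normalized + 1); a dedicated variance-stabilizing transform
is out of scope.

## Synthetic data

The toy reference lays out 4–7-exon genes (exons 90–220 nt, introns
150–400 nt, intergenic gaps 400–900 nt) on alternating strands across two
chromosomes of random sequence, splices each gene into its mRNA, and chooses
each circRNA as a contiguous run of 2–3 host exons. Because the circle's
exons are exact host sub-blocks, the mature circle is a substring of the
host mRNA, giving the arm-substring property above by construction; the
centred spacer's ≥ 4-mismatch margin is verified at generation (for random
sequence the failure probability is ~1e−10 per circle) and the exon run is
re-drawn on the rare failure, keeping the guarantee constructive and the
output deterministic per seed.

The screen simulator draws per-guide baseline abundances log-normal(0, 1),
control-arm counts NB(depth·abundance, φ) and treatment-arm counts
NB(depth·abundance·2^(−effect+ε), φ), with variance μ + φμ², per-guide
efficacy noise ε ~ N(0, 0.3²) applied only to guides of affected genes, and
duplicate samples per arm. The count model is declared, not inferred from
data: real screens were scored from sequencing counts whose generative
process is unobserved, so the simulator states its assumptions (log-normal
abundance, NB overdispersion, log-additive guide effects) and the recovery
results must be read under them. In particular the simulation does not model
PCR amplification bias, infection dynamics, guide-specific off-target
toxicity, or correlated guide failures — passing recovery tests demonstrates
the statistics are implemented correctly, not that real screens of this
design would reach the same sensitivity.

Default benchmark conditions: 100 target genes × 5 guides, 150
non-targeting controls (one "NT" gene), 10 essential genes with effect 3
(8-fold depletion), depth 5×10⁵, dispersion 0.1, two replicates. The "drug"
design applies effects only in the drug arm of a vehicle/drug day-14
contrast. Benchmarking reports precision/recall per FDR threshold against
the truth table.

## Problem sizes in tests

The test suite runs everything at desk scale: the off-target oracle
comparison uses 1000 random instances with transcripts of 60–2000 nt plus
five 50 kb instances; the null-uniformity check uses 2000 two-guide genes
over N = 4000 with 2000 permutations (the sub-uniformity tolerance includes
the shared-null Monte-Carlo term, since null draws are reused across genes);
the end-to-end recovery check runs the default benchmark with 10⁴
permutations. These sizes were chosen as the smallest at which each
statistical property is sharply testable.

## Known limitations

- Off-target scanning is transcriptome-only (no intronic/intergenic search)
  and mismatch-only (no indels, no RNA-structure accessibility).
- shRNA efficacy scoring against external web services is out of scope; an
  `external_score` column can be carried through library tables untouched.
- Conservation filtering across species is accepted as a precomputed boolean
  input column, not recomputed.
- α-RRA here follows the rank-fraction formulation stated above; numerical
  identity with other rank-aggregation implementations that select guides by
  per-guide p-value is not claimed.
- The wrapped-window path supports circles shorter than the window but its
  off-target semantics (repeated bases) are only flagged, not modeled.
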