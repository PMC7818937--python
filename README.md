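# circscreen

Toolkit for designing circRNA-silencing reagent libraries and scoring the
pooled screens that use them.

Circular RNAs (circRNAs) arise from back-splicing and overlap their host
linear mRNA everywhere except the back-splice junction (BSJ) — the covalent
joint between the 3' end and 5' start of the circularized exons. The BSJ is
therefore the only sequence a knockdown reagent (an shRNA or an RNA-targeting
CRISPR/Cas13d guide) can use to hit the circle without hitting the host
mRNA. `circscreen` implements that design problem end to end, plus the
statistics needed to call hits from a pooled depletion screen built with the
resulting library.

## What it does

**Library design** (`circ_model`, `guide_design`, `offtarget`,
`oligo_assembly`):

- parse BED12-style circRNA annotations (CIRCexplorer2-compatible),
  reconstruct mature spliced sequences from a genome FASTA, and linearize a
  junction-centred window (default 40 nt: 20 nt on each side of the BSJ);
- tile all 21-nt shRNA targets and 24-nt Cas13d spacers across the window,
  labelling each candidate's junction geometry `a+b` (a bases 5' of the
  junction, b bases 3'; `20+4` and `4+20` are the host-mRNA-like extremes,
  removable with one call);
- exclude off-target candidates by an exact Hamming scan against a
  transcriptome FASTA (a candidate within 3 mismatches of any linear
  transcript is dropped);
- emit synthesis-ready oligos: 94-mer gRNA templates and 92-mer
  sense–loop–antisense shRNA hairpins with fixed cloning flanks, plus
  non-targeting controls sampled from intergenic sequence of an unrelated
  genome;
- expression-based candidate filters (RPM ≥ 0.1 in all samples;
  mean paired tumor/normal fold change ≥ 1.5).

**Screen scoring** (`screen_analysis`): median-of-ratios normalization,
per-guide log2 fold change (treatment vs control), and gene-level
aggregation by α-RRA. For a gene with n guides at normalized ranks
r(1) ≤ … ≤ r(n) in the ranked guide list,

    ρ = min { P(Beta(k, n−k+1) ≤ r(k)) : r(k) ≤ α }

— the probability that the k-th best of n uniformly placed guides would rank
that high; ρ = 1 if no guide sits in the top-α fraction. Significance comes
from permuting gene labels (p = (1 + #null ρ ≤ observed)/(1 + N_perm)) with
Benjamini–Hochberg FDR control, separately for negative (depletion) and
positive (enrichment) selection.

**Synthetic data** (`synthetic_data`): deterministic toy genomes whose
circRNAs are exon sub-runs of host genes (so all junction/off-target
geometry is checkable by construction) and negative-binomial screen
simulations (var = μ + φμ²) with known essential genes, for end-to-end
validation without downloads.

## Worked example

```
circscreen simulate-reference --seed 3 --outdir ref
circscreen design --genome ref/genome.fa --circ-bed ref/circs.bed \
    --transcriptome ref/transcriptome.fa --out lib --drop-terminal-overlaps
```

prints the per-stage candidate counts for 6 toy circRNAs:

```
shrna_enumerated        120
grna_enumerated         102
shrna_kept_offtarget    82
grna_kept_offtarget     91
grna_final              85
shrna_final             82
```

120 = 6 windows × 20 shRNA tilings and 102 = 6 × 17 spacer tilings; the
off-target scan removes candidates lying too close to the host mRNA (long
one-sided overlaps), and `--drop-terminal-overlaps` removes the remaining
`20+4`/`4+20` designs. `lib.tsv` lists each kept candidate with its overlap
label, target/spacer sequence and 94-mer or 92-mer oligo; `lib.fa` holds the
oligos as FASTA.

```
circscreen simulate-screen --seed 5 --out counts.tsv --truth truth.tsv
circscreen analyze --counts counts.tsv --control D0_r1 --control D0_r2 \
    --treatment D14_r1 --treatment D14_r2 --out genes.tsv --permutations 2000
head -4 genes.tsv
```

```
gene  n_guides  rra_score_neg            rra_score_pos  p_neg                  ...
G003  5         2.891898915411818e-07    1.0            0.0004997501249375312
G010  5         3.3728957346354493e-07   1.0            0.0004997501249375312
G007  5         5.211295747563246e-07    1.0            0.0004997501249375312
```

The simulated essential genes (G001–G010, 8-fold depleted) top the
negative-selection ranking with ρ ≈ 10⁻⁷ and p at the permutation floor;
`fdr_neg < 0.25` calls them as hits.

The same workflow is available as library calls (`design_circrna_library`,
`analyze_screen`, `simulate_screen_counts`, …) for use from Python.

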