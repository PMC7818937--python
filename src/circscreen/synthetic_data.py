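"""Synthetic references and simulated screens for end-to-end pipeline testing.

Two generators:

* :func:`make_toy_reference` builds a small random genome with multi-exon
  genes on both strands, spliced host mRNAs (the transcriptome), and
  circRNAs whose exons are contiguous sub-runs of host exons. By
  construction every circRNA's mature sequence is a substring of its host
  mRNA, so non-junction-spanning candidates match the host with 0
  mismatches, while the back-splice joint itself is absent from the linear
  transcript; centred junction-spanning spacers are verified to sit >= 4
  mismatches from the host mRNA.

* :func:`simulate_screen_counts` draws a two-condition pooled screen:
  guide abundances are log-normal, counts are negative-binomial with
  var = mu + dispersion * mu^2, and essential (or drug-sensitizing) genes
  deplete their guides by 2^-effect in the treatment arm, with per-guide
  log2-normal efficacy noise. A truth table records each gene's effect so
  hit-calling can be benchmarked.

The screen defaults mirror the pooled-screen design point the pipeline is
meant for: 5 guides per target, ~10 true essentials with 16x-to-8x
depletion among a larger null background, non-targeting controls, two
replicates per arm, and sequencing depth of several hundred counts per
guide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from ._seq import revcomp
from .circ_model import CircRNARecord, build_bsj_window, write_circ_annotation
from .guide_design import enumerate_bsj_spacers
from .offtarget import min_mismatch_scan
from .screen_analysis import ScreenCountMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class GeneModel:
    """One toy gene: genomic span, strand, and exon intervals (genomic coords)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]  # (start, end), genomic, sorted


@dataclass
class ToyReference:
    """In-memory toy genome + annotation bundle, writable as standard files."""

    genome: dict[str, str]
    genes: list[GeneModel]
    circs: list[CircRNARecord]
    transcriptome: dict[str, str]

    @property
    def gene_intervals(self) -> list[tuple[str, int, int]]:
        return [(g.chrom, g.start, g.end) for g in self.genes]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome.fa, genes.bed, circs.bed (BED12), transcriptome.fa."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.bed",
            "circs": outdir / "circs.bed",
            "transcriptome": outdir / "transcriptome.fa",
        }
        _write_fasta(self.genome, paths["genome"])
        with open(paths["genes"], "w") as out:
            for g in self.genes:
                out.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
        write_circ_annotation(self.circs, paths["circs"])
        _write_fasta(self.transcriptome, paths["transcriptome"])
        return paths


def _write_fasta(seqs: Mapping[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for name in seqs:
            out.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_toy_reference(
    seed: int = 0,
    n_chroms: int = 2,
    n_genes: int = 8,
    n_circ: int = 6,
) -> ToyReference:
    """Generate a deterministic toy genome with genes, mRNAs, and circRNAs.

    Genes (4-7 exons of 90-220 nt separated by 150-400 nt introns) are laid
    out with 400-900 nt intergenic gaps, alternating strands, spread over
    ``n_chroms`` chromosomes. Each circRNA back-splices a contiguous run of
    2-3 exons of a host gene. The returned bundle is byte-identical across
    runs with the same arguments.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(400, 900))
        parts: list[tuple[int, int]] = []
        for _ in range(per_chrom[ci]):
            gi += 1
            n_ex = int(rng.integers(4, 8))
            exons = []
            cursor = pos
            for e in range(n_ex):
                elen = int(rng.integers(90, 221))
                exons.append((cursor, cursor + elen))
                cursor += elen
                if e < n_ex - 1:
                    cursor += int(rng.integers(150, 401))
            strand = "+" if gi % 2 else "-"
            genes.append(
                GeneModel(
                    name=f"GENE{gi}",
                    chrom=chrom,
                    start=pos,
                    end=cursor,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            pos = cursor + int(rng.integers(400, 901))
        genome[chrom] = _random_seq(rng, pos)

    transcriptome = {}
    for g in genes:
        spliced = "".join(genome[g.chrom][s:e] for s, e in g.exons)
        transcriptome[g.name] = revcomp(spliced) if g.strand == "-" else spliced

    circs: list[CircRNARecord] = []
    hosts = [genes[i % len(genes)] for i in range(n_circ)]
    for host in hosts:
        for _attempt in range(20):
            first = int(rng.integers(0, len(host.exons) - 1))
            run = int(rng.integers(2, min(4, len(host.exons) - first + 1)))
            chosen = host.exons[first : first + run]
            start, end = chosen[0][0], chosen[-1][1]
            blocks = tuple((s - start, e - s) for s, e in chosen)
            rec = CircRNARecord(
                chrom=host.chrom,
                start=start,
                end=end,
                strand=host.strand,
                gene=host.name,
                blocks=blocks,
            )
            # guarantee the junction-spanning centred spacer is far from the
            # host mRNA (astronomically likely for random sequence; re-draw
            # the exon run on the rare failure)
            window = build_bsj_window(rec, genome)
            centred = [c for c in enumerate_bsj_spacers(window, 24) if c.overlap_label == "12+12"]
            min_mismatch_scan(centred[0], {host.name: transcriptome[host.name]})
            if centred[0].offtarget_min_mm >= 4:
                circs.append(rec)
                break
        else:
            raise RuntimeError("could not place a circRNA with a clean junction")
    return ToyReference(genome=genome, genes=genes, circs=circs, transcriptome=transcriptome)


@dataclass
class SimulationConfig:
    """Generative parameters for a simulated two-condition pooled screen.

    Defaults define the standard benchmark: 100 target genes x 5 guides,
    150 non-targeting controls, 10 essentials depleting 2^3 = 8-fold, depth
    5x10^5 reads per sample, negative-binomial dispersion 0.1
    (var = mu + 0.1 mu^2), per-guide efficacy noise sd 0.3 (log2 units),
    duplicate screens.
    """

    n_genes: int = 100
    guides_per_gene: int = 5
    n_nontargeting: int = 150
    depth: float = 5e5
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    n_essential: int = 10
    essential_effect: float = 3.0
    effects: dict[str, float] | None = None  # overrides n_essential/essential_effect
    guide_noise_sd: float = 0.3
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def gene_effects(self) -> dict[str, float]:
        if self.effects is not None:
            return dict(self.effects)
        eff = {f"G{i + 1:03d}": 0.0 for i in range(self.n_genes)}
        for i in range(self.n_essential):
            eff[f"G{i + 1:03d}"] = self.essential_effect
        return eff


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_screen_counts(
    cfg: SimulationConfig,
    design: Literal["growth", "drug"] = "growth",
) -> tuple[ScreenCountMatrix, pd.DataFrame]:
    """Simulate guide counts for a growth (D0/D14) or drug (vehicle/drug) screen.

    Baseline guide abundances are log-normal; control-arm counts are
    NB(depth * abundance, dispersion) and treatment-arm counts are
    NB(depth * abundance * 2^(-effect + noise), dispersion), where the
    per-gene effect (log2 units) is positive for essential/drug-sensitizing
    genes and 0 otherwise, and noise is per-guide Gaussian efficacy jitter.
    In the growth design the control arm is D0 and treatment D14; in the
    drug design both arms are day-14 (vehicle vs drug) and only the drug arm
    carries effects. Returns the count matrix and a gene-level truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    effects = cfg.gene_effects()
    genes = list(effects)
    guide_ids, guide_genes = [], []
    for g in genes:
        for j in range(cfg.guides_per_gene):
            guide_ids.append(f"{g}_sg{j + 1}")
            guide_genes.append(g)
    for j in range(cfg.n_nontargeting):
        guide_ids.append(f"NT_sg{j + 1}")
        guide_genes.append("NT")
    n_guides = len(guide_ids)

    abundance = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_guides)
    abundance /= abundance.sum()
    effect_per_guide = np.array([effects.get(g, 0.0) for g in guide_genes])
    noise = rng.normal(0.0, cfg.guide_noise_sd, size=n_guides)
    noise[effect_per_guide == 0.0] = 0.0  # efficacy noise only where there is an effect
    depleted = abundance * 2.0 ** (-effect_per_guide + noise)

    if design == "growth":
        arm_names = ("D0", "D14")
    elif design == "drug":
        arm_names = ("vehicle", "drug")
    else:
        raise ValueError("design must be 'growth' or 'drug'")
    columns: dict[str, np.ndarray] = {}
    conditions: dict[str, str] = {}
    for rep in range(1, cfg.n_replicates + 1):
        columns[f"{arm_names[0]}_r{rep}"] = _nb_draw(
            rng, cfg.depth * abundance, cfg.nb_dispersion
        )
        conditions[f"{arm_names[0]}_r{rep}"] = "control"
    for rep in range(1, cfg.n_replicates + 1):
        columns[f"{arm_names[1]}_r{rep}"] = _nb_draw(
            rng, cfg.depth * depleted, cfg.nb_dispersion
        )
        conditions[f"{arm_names[1]}_r{rep}"] = "treatment"

    counts = pd.DataFrame(columns, index=pd.Index(guide_ids, name="sgRNA"))
    matrix = ScreenCountMatrix(
        counts=counts,
        guide_gene=pd.Series(guide_genes, index=counts.index, name="gene"),
        conditions=conditions,
    )
    truth = pd.DataFrame(
        {"gene": genes, "true_effect": [effects[g] for g in genes]}
    ).set_index("gene")
    return matrix, truth


def benchmark_recovery(
    truth: pd.DataFrame,
    gene_results: pd.DataFrame,
    fdr_thresholds=(0.25, 0.1),
    direction: str = "negative",
) -> pd.DataFrame:
    """Precision/recall of hit calling against the simulation truth table.

    ``truth`` must carry a ``true_effect`` column indexed by gene; every
    truth gene must appear in ``gene_results``. Returns one row per FDR
    threshold with hit counts, true/false positives, precision and recall.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    missing = truth.index.difference(gene_results.index)
    if len(missing):
        raise ValueError(f"truth genes absent from results: {list(missing)[:5]}")
    from .screen_analysis import call_hits

    true_set = set(truth.index[truth["true_effect"] > 0])
    rows = []
    for thr in fdr_thresholds:
        hits = set(call_hits(gene_results, thr, direction).index) & set(truth.index)
        tp = len(hits & true_set)
        fp = len(hits - true_set)
        rows.append(
            {
                "fdr_threshold": thr,
                "n_hits": len(hits),
                "tp": tp,
                "fp": fp,
                "fn": len(true_set - hits),
                "precision": tp / len(hits) if hits else float("nan"),
                "recall": tp / len(true_set) if true_set else float("nan"),
            }
        )
    return pd.DataFrame(rows)
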