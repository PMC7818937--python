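"""Synthesis-oligo assembly for Cas13d gRNA and shRNA libraries.

Two array-synthesis templates are supported. The gRNA template embeds a
24-nt spacer between fixed 35-nt cloning flanks, giving a 94-mer; the shRNA
template builds a pLKO-style hairpin — 19-nt prefix, 21-nt sense target,
``ctcgag`` loop, 21-nt antisense (reverse complement of sense), 25-nt
suffix — giving a 92-mer. Flanks are emitted lowercase and inserts uppercase
so oligos can be audited visually and parsed back unambiguously. Pool
amplification primer pairs for both templates are included. Non-targeting
negative controls are sampled from intergenic sequence of an unrelated
genome so they have no complement in the screened transcriptome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .guide_design import GuideCandidate

# gRNA 94-mer template: 35-nt 5' flank + 24-nt spacer + 35-nt 3' flank.
GRNA_FLANK_5 = "caccgaacccctaccaactggtcggggtttgaaac"
GRNA_FLANK_3 = "ttttttaagcttggcgtaactagatcttgagacaa"
GRNA_POOL_FWD = "tatatatcttgtggaaaggacgaaacaccgaacccctaccaactggtcggggtttgaaac"
GRNA_POOL_REV = "cttttaaaattgtggatgaatactgccatttgtctcaagatctagttacgccaagc"

# shRNA 92-mer template: 19-nt prefix + sense(21) + loop(6) + antisense(21) + 25-nt suffix.
SHRNA_PREFIX = "ggaaaggacgaaacaccgg"
SHRNA_LOOP = "ctcgag"
SHRNA_SUFFIX = "tttttgaattctcgacctcgagaca"
SHRNA_POOL_FWD = "taacttgaaagtatttcgatttcttggctttatatatcttgtggaaaggacgaaacaccgg"
SHRNA_POOL_REV = "cccccttttcttttaaaattgtggatgaatactgccatttgtctcgaggtcgagaattc"

# Staggered NGS forward primers are synthesis-batch-specific; placeholders
# here, overridable per OligoRecord via the primer arguments.
DEFAULT_NGS_PRIMERS = {"grna": (GRNA_POOL_FWD, GRNA_POOL_REV),
                       "shrna": (SHRNA_POOL_FWD, SHRNA_POOL_REV)}

_VALID = set("ACGT")


@dataclass(frozen=True)
class OligoRecord:
    """One synthesis-ready oligo with its pool-amplification primers."""

    candidate_id: str
    template: str  # {"grna_94", "shrna_92"}
    oligo_seq: str
    fwd_primer: str
    rev_primer: str


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def assemble_grna_oligo(
    spacer: str, candidate_id: str = "", spacer_orientation: str = "spacer"
) -> OligoRecord:
    """Embed a spacer in the 94-mer gRNA synthesis template.

    ``spacer`` should already be the protospacer complement (the sequence the
    guide carries); pass ``spacer_orientation="target"`` to supply the
    target-sense sequence instead, in which case it is reverse-complemented
    before embedding. 24-nt spacers give the canonical 94-mer; other lengths
    are allowed with a warning and change the oligo length accordingly.
    """
    seq = _check_dna(spacer, "spacer")
    if spacer_orientation == "target":
        seq = revcomp(seq)
    elif spacer_orientation != "spacer":
        raise ValueError("spacer_orientation must be 'spacer' or 'target'")
    if len(seq) != 24:
        warnings.warn(
            f"spacer length {len(seq)} != 24; oligo will be {70 + len(seq)} nt",
            stacklevel=2,
        )
    oligo = GRNA_FLANK_5 + seq + GRNA_FLANK_3
    return OligoRecord(candidate_id or seq, "grna_94", oligo, GRNA_POOL_FWD, GRNA_POOL_REV)


def assemble_shrna_oligo(sense_target: str, candidate_id: str = "") -> OligoRecord:
    """Build the 92-mer hairpin oligo from a 21-nt sense target sequence."""
    seq = _check_dna(sense_target, "sense target")
    if len(seq) != 21:
        raise ValueError(f"shRNA sense target must be 21 nt, got {len(seq)}")
    oligo = SHRNA_PREFIX + seq + SHRNA_LOOP + revcomp(seq) + SHRNA_SUFFIX
    return OligoRecord(
        candidate_id or seq, "shrna_92", oligo, SHRNA_POOL_FWD, SHRNA_POOL_REV
    )


def extract_grna_spacer(oligo: str, spacer_len: int | None = None) -> str:
    """Recover the (uppercase) spacer from a gRNA template oligo."""
    if spacer_len is None:
        spacer_len = len(oligo) - len(GRNA_FLANK_5) - len(GRNA_FLANK_3)
    if (
        oligo[: len(GRNA_FLANK_5)] != GRNA_FLANK_5
        or oligo[len(GRNA_FLANK_5) + spacer_len :] != GRNA_FLANK_3
    ):
        raise ValueError("oligo flanks do not match the gRNA template")
    return oligo[len(GRNA_FLANK_5) : len(GRNA_FLANK_5) + spacer_len]


def extract_shrna_sense(oligo: str) -> str:
    """Recover the 21-nt sense target from a hairpin oligo, validating structure."""
    p, l = len(SHRNA_PREFIX), len(SHRNA_LOOP)
    sense = oligo[p : p + 21]
    expected = SHRNA_PREFIX + sense + SHRNA_LOOP + revcomp(sense) + SHRNA_SUFFIX
    if oligo != expected:
        raise ValueError("oligo does not match the shRNA hairpin template")
    return sense


@dataclass(frozen=True)
class ControlSpacer:
    """A non-targeting control sampled from intergenic sequence."""

    control_id: str
    chrom: str
    start: int
    sequence: str


def _parse_intervals(gene_annotation) -> list[tuple[str, int, int]]:
    if isinstance(gene_annotation, (str, Path)):
        out = []
        with open(gene_annotation) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                out.append((cols[0], int(cols[1]), int(cols[2])))
        return out
    return [(c, int(s), int(e)) for c, s, e in gene_annotation]


def sample_intergenic_controls(
    genome,
    gene_annotation,
    n: int = 150,
    length: int = 24,
    seed: int = 0,
) -> list[ControlSpacer]:
    """Sample ``n`` random intergenic windows as non-targeting controls.

    ``gene_annotation`` is an iterable of (chrom, start, end) intervals or a
    BED-style path. Windows are drawn uniformly (without start replacement)
    from the intergenic complement, never overlap a gene interval, contain no
    N bases, and are deterministic given ``seed``. The default of 150 controls
    of 24 nt matches the library's negative-control arm.
    """
    if isinstance(genome, Mapping):
        chrom_lens = {k: len(str(v)) for k, v in genome.items()}
    else:
        chrom_lens = {rec.name: len(rec) for rec in genome}
    intervals = _parse_intervals(gene_annotation)
    genic: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lens}
    for chrom, s, e in intervals:
        if chrom in genic:
            genic[chrom].append((s, e))
    # valid window starts: fully inside an intergenic gap
    gaps: list[tuple[str, int, int]] = []  # (chrom, gap_start, n_valid_starts)
    for chrom, clen in sorted(chrom_lens.items()):
        merged: list[list[int]] = []
        for s, e in sorted(genic[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        edges = [0] + [x for se in merged for x in se] + [clen]
        for gs, ge in zip(edges[::2], edges[1::2]):
            if ge - gs >= length:
                gaps.append((chrom, gs, ge - gs - length + 1))
    total = sum(g[2] for g in gaps)
    if total < n:
        raise ValueError(
            f"intergenic space holds only {total} windows of {length} nt; need {n}"
        )
    rng = np.random.default_rng(seed)
    from .circ_model import _fetch

    chosen = rng.choice(total, size=total, replace=False)  # random order over all starts
    controls: list[ControlSpacer] = []
    offsets = np.cumsum([0] + [g[2] for g in gaps])
    for flat in chosen:
        gi = int(np.searchsorted(offsets, flat, side="right")) - 1
        chrom, gap_start, _ = gaps[gi]
        pos = gap_start + int(flat - offsets[gi])
        seq = _fetch(genome, chrom, pos, pos + length)
        if "N" in seq:
            continue
        controls.append(ControlSpacer(f"NT_{len(controls) + 1:04d}", chrom, pos, seq))
        if len(controls) == n:
            break
    if len(controls) < n:
        raise ValueError("too few N-free intergenic windows to sample controls")
    return controls


LIBRARY_COLUMNS = [
    "candidate_id",
    "circ_id",
    "kind",
    "window_start",
    "length",
    "overlap_label",
    "target_seq",
    "spacer_seq",
    "status",
    "oligo_seq",
]


def emit_library(
    candidates: Sequence[GuideCandidate],
    oligos: Mapping[str, OligoRecord],
    path: str | Path,
) -> tuple[Path, Path]:
    """Write the library as a TSV table plus an oligo FASTA.

    ``path`` is a basename; ``<path>.tsv`` and ``<path>.fa`` are produced.
    FASTA ids equal candidate ids. An empty library yields a header-only
    table and an empty FASTA.
    """
    path = Path(path)
    tsv = path.with_suffix(".tsv")
    fasta = path.with_suffix(".fa")
    rows = []
    with open(fasta, "w") as fa:
        for cand in candidates:
            oligo = oligos.get(cand.candidate_id)
            rows.append(
                {
                    "candidate_id": cand.candidate_id,
                    "circ_id": cand.circ_id,
                    "kind": cand.kind,
                    "window_start": cand.window_start,
                    "length": cand.length,
                    "overlap_label": cand.overlap_label,
                    "target_seq": cand.target_seq,
                    "spacer_seq": cand.spacer_seq,
                    "status": cand.status,
                    "oligo_seq": oligo.oligo_seq if oligo else "",
                }
            )
            if oligo:
                fa.write(f">{cand.candidate_id}\n{oligo.oligo_seq}\n")
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(tsv, sep="\t", index=False)
    return tsv, fasta


def read_library(path: str | Path) -> pd.DataFrame:
    """Read back a library TSV written by :func:`emit_library`."""
    return pd.read_csv(Path(path).with_suffix(".tsv"), sep="\t", dtype={"oligo_seq": str})
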