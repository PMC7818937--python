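"""circRNA annotation records, mature sequences, and back-splice junction windows.

A circRNA is a covalently closed transcript produced by back-splicing: the 3'
end of a downstream exon is joined to the 5' start of an upstream exon of the
same gene. Its sequence is identical to the host linear mRNA everywhere except
across that back-splice junction (BSJ), so the BSJ is the only
circRNA-specific stretch a knockdown reagent can address. This module parses
BED12-style circRNA annotations (CIRCexplorer2-compatible; extra columns
ignored), reconstructs the mature (spliced, transcript-sense) circular
sequence from a genome, linearizes a junction-centred window for guide
design, and applies expression-based candidate filters (RPM floor and
tumor/normal fold change).

Coordinates follow the BED convention: 0-based, half-open. Canonical circRNA
identifiers are printed as ``chrom|start|end|gene|`` with the raw annotation
coordinates, e.g. ``chr10|32197099|32199491|ARHGAP12|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import circular_slice, revcomp


class AnnotationError(ValueError):
    """Raised for malformed circRNA annotation rows (carries the line number)."""


class CoordinateError(ValueError):
    """Raised when a record refers to sequence absent from the genome."""


def format_circ_id(chrom: str, start: int, end: int, gene: str) -> str:
    return f"{chrom}|{start}|{end}|{gene}|"


def parse_circ_id(circ_id: str) -> tuple[str, int, int, str]:
    """Invert :func:`format_circ_id`; raises ``ValueError`` on malformed ids."""
    parts = circ_id.split("|")
    if len(parts) != 5 or parts[4] != "":
        raise ValueError(f"malformed circRNA id: {circ_id!r}")
    chrom, start, end, gene = parts[:4]
    return chrom, int(start), int(end), gene


@dataclass
class CircRNARecord:
    """One circRNA: genomic span, strand, host gene, and exon block structure.

    ``blocks`` are (start, size) pairs relative to ``start``, sorted,
    non-overlapping; the first block starts at 0 and the last ends at
    ``end - start`` (BED12 semantics).
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene: str
    blocks: tuple[tuple[int, int], ...]
    circ_id: str = field(default="")

    def __post_init__(self) -> None:
        if not self.circ_id:
            self.circ_id = format_circ_id(self.chrom, self.start, self.end, self.gene)
        self.blocks = tuple((int(s), int(z)) for s, z in self.blocks)
        self.validate()

    def validate(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"{self.circ_id}: end must exceed start")
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.circ_id}: strand must be + or -")
        if not self.blocks:
            raise AnnotationError(f"{self.circ_id}: at least one exon block required")
        span = self.end - self.start
        if self.blocks[0][0] != 0:
            raise AnnotationError(f"{self.circ_id}: first block must start at 0")
        prev_end = -1
        for bs, bz in self.blocks:
            if bz <= 0:
                raise AnnotationError(f"{self.circ_id}: non-positive block size")
            if bs <= prev_end and prev_end >= 0:
                raise AnnotationError(f"{self.circ_id}: blocks overlap or are unsorted")
            prev_end = bs + bz - 1
        if self.blocks[-1][0] + self.blocks[-1][1] != span:
            raise AnnotationError(
                f"{self.circ_id}: last block must end at end-start ({span})"
            )

    @property
    def mature_length(self) -> int:
        return sum(bz for _, bz in self.blocks)


@dataclass
class BsjWindow:
    """Linearized junction-centred sequence for one circRNA.

    ``sequence`` is on the transcript (sense) strand; reading left to right,
    the first ``arm_left`` bases are the mature sequence's 3' tail and the
    remaining ``arm_right`` bases are its 5' head, so the back-splice joint
    sits between indices ``junction_offset - 1`` and ``junction_offset``.
    ``wrapped`` marks circles shorter than the combined arms, whose window
    traverses the origin more than once.
    """

    circ_id: str
    sequence: str
    junction_offset: int
    arm_left: int
    arm_right: int
    wrapped: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.arm_left + self.arm_right:
            raise ValueError("window length must equal arm_left + arm_right")
        if self.junction_offset != self.arm_left:
            raise ValueError("junction_offset must equal arm_left")

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_int(token: str, line_no: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise AnnotationError(f"line {line_no}: non-integer {what}: {token!r}") from None


def parse_circ_annotation(path: str | Path, gene_column: int | None = None) -> list[CircRNARecord]:
    """Parse a BED12-style circRNA annotation file into records.

    Accepts plain BED12 and CIRCexplorer2 ``annotate`` output (18 columns).
    Columns beyond the 12 BED fields are ignored, except that the host gene
    symbol is taken from column 15 (CIRCexplorer2 ``geneName``) when present,
    or from the BED ``name`` field otherwise. ``gene_column`` (0-based)
    overrides the auto-detection. Rows with inconsistent block arithmetic
    raise :class:`AnnotationError` naming the line. An empty file yields an
    empty list; input order is preserved.
    """
    records: list[CircRNARecord] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise AnnotationError(
                    f"line {line_no}: expected >=12 tab-separated columns, got {len(cols)}"
                )
            chrom = cols[0]
            start = _parse_int(cols[1], line_no, "start")
            end = _parse_int(cols[2], line_no, "end")
            strand = cols[5]
            n_blocks = _parse_int(cols[9], line_no, "blockCount")
            sizes = [
                _parse_int(t, line_no, "blockSize")
                for t in cols[10].rstrip(",").split(",")
            ]
            starts = [
                _parse_int(t, line_no, "blockStart")
                for t in cols[11].rstrip(",").split(",")
            ]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(
                    f"line {line_no}: blockCount={n_blocks} disagrees with block lists"
                )
            if gene_column is not None:
                gene = cols[gene_column]
            elif len(cols) >= 15:
                gene = cols[14]
            else:
                gene = cols[3]
            try:
                rec = CircRNARecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    gene=gene,
                    blocks=tuple(zip(starts, sizes)),
                )
            except AnnotationError as exc:
                raise AnnotationError(f"line {line_no}: {exc}") from None
            records.append(rec)
    return records


def write_circ_annotation(records: Iterable[CircRNARecord], path: str | Path) -> None:
    """Write records as 12-column BED (name = host gene symbol)."""
    with open(path, "w") as out:
        for rec in records:
            sizes = ",".join(str(bz) for _, bz in rec.blocks)
            starts = ",".join(str(bs) for bs, _ in rec.blocks)
            out.write(
                "\t".join(
                    [
                        rec.chrom,
                        str(rec.start),
                        str(rec.end),
                        rec.gene,
                        "0",
                        rec.strand,
                        str(rec.start),
                        str(rec.end),
                        "0",
                        str(len(rec.blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] from pyfaidx.Fasta or any str mapping."""
    try:
        seq_obj = genome[chrom]
    except KeyError:
        raise CoordinateError(f"chromosome {chrom!r} absent from genome") from None
    piece = str(seq_obj[start:end]).upper()
    if len(piece) != end - start:
        raise CoordinateError(
            f"{chrom}:{start}-{end} out of range (got {len(piece)} bases)"
        )
    return piece


def mature_sequence(rec: CircRNARecord, genome) -> str:
    """Mature spliced circRNA sequence, transcript-sense, uppercase.

    Exon blocks are concatenated in genomic order and the whole concatenation
    is reverse-complemented for minus-strand records, because guides must be
    designed against the RNA sense sequence. Length equals the block-size sum.
    """
    pieces = [
        _fetch(genome, rec.chrom, rec.start + bs, rec.start + bs + bz)
        for bs, bz in rec.blocks
    ]
    seq = "".join(pieces)
    return revcomp(seq) if rec.strand == "-" else seq


def build_bsj_window(
    rec: CircRNARecord, genome, arm_left: int = 20, arm_right: int = 20
) -> BsjWindow:
    """Linearize the back-splice junction of one circRNA.

    Defaults give the 40-nt window used for library design: the last 20 bases
    of the mature sequence joined to its first 20 bases, junction centred.
    Circles shorter than ``arm_left + arm_right`` wrap around the origin
    (preserving circular topology) and are flagged ``wrapped``.
    """
    mature = mature_sequence(rec, genome)
    if not mature:
        raise ValueError(f"{rec.circ_id}: zero-length mature sequence")
    n = len(mature)
    window = circular_slice(mature, (n - arm_left) % n, arm_left + arm_right)
    return BsjWindow(
        circ_id=rec.circ_id,
        sequence=window,
        junction_offset=arm_left,
        arm_left=arm_left,
        arm_right=arm_right,
        wrapped=n < arm_left + arm_right,
    )


@dataclass
class ExpressionMatrix:
    """circRNA expression in reads-per-million (RPM), circRNAs x samples.

    ``pairs`` optionally lists (tumor_sample, normal_sample) column pairs for
    paired differential ranking.
    """

    rpm: pd.DataFrame
    pairs: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if (self.rpm.values < 0).any():
            raise ValueError("RPM values must be non-negative")
        if self.pairs:
            for t, n in self.pairs:
                if t not in self.rpm.columns or n not in self.rpm.columns:
                    raise ValueError(f"pair ({t}, {n}) not in sample columns")

    @property
    def circ_ids(self) -> list[str]:
        return list(self.rpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rpm.columns)

    @classmethod
    def from_tsv(
        cls, path: str | Path, pairs: Sequence[tuple[str, str]] | None = None
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(rpm=df, pairs=tuple(pairs) if pairs else None)


def filter_expressed(
    expr: ExpressionMatrix, rpm_min: float = 0.1, require_all_samples: bool = True
) -> list[str]:
    """circRNAs expressed at >= ``rpm_min`` RPM in every sample (default).

    With ``require_all_samples=False`` a single qualifying sample suffices.
    The default floor of 0.1 RPM in all samples is the candidate-selection
    rule used for highly expressed circRNAs.
    """
    if expr.rpm.empty:
        raise ValueError("expression matrix is empty")
    ok = (expr.rpm >= rpm_min).all(axis=1) if require_all_samples else (
        expr.rpm >= rpm_min
    ).any(axis=1)
    return list(expr.rpm.index[ok])


def rank_differential(
    expr: ExpressionMatrix, fc_min: float = 1.5, pseudocount: float = 0.01
) -> list[tuple[str, float]]:
    """Rank circRNAs by mean per-pair tumor/normal fold change.

    For each (tumor, normal) sample pair the ratio
    ``(tumor + pseudocount) / (normal + pseudocount)`` is computed; circRNAs
    whose mean ratio over pairs is >= ``fc_min`` are returned sorted by
    descending fold change. The pseudocount (0.01 RPM) guards against
    division by zero in lowly expressed normals.
    """
    if not expr.pairs:
        raise ValueError("paired tumor/normal grouping required for differential ranking")
    ratios = pd.DataFrame(
        {
            f"{t}/{n}": (expr.rpm[t] + pseudocount) / (expr.rpm[n] + pseudocount)
            for t, n in expr.pairs
        }
    )
    mean_fc = ratios.mean(axis=1)
    kept = mean_fc[mean_fc >= fc_min].sort_values(ascending=False)
    return list(kept.items())
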