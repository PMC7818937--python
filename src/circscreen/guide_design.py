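"""Enumerate shRNA targets and Cas13d spacers over back-splice junction windows.

The library-design rules implemented here: every possible 21-nt shRNA target
is tiled across the 40-nt BSJ window; Cas13d gRNAs use 24-nt spacers, either
tiled directly or produced by extending a position-matched 21-nt shRNA target
to 24 nt. Each candidate carries its junction-overlap geometry as an
``a+b`` label (a bases 5' of the junction, b bases 3'), e.g. ``20+4`` for the
most linear-mRNA-like extreme. Spacer-length series (21..30 nt) and
Watson-Crick mismatch-variant series (single or consecutive-double
complement substitutions) support reagent-optimization experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._seq import complement, revcomp
from .circ_model import BsjWindow

KEPT = "kept"
EXCLUDED_OFFTARGET = "excluded_offtarget"
EXCLUDED_OVERLAP = "excluded_overlap"


@dataclass
class GuideCandidate:
    """One spacer/shRNA target site within a BSJ window.

    ``target_seq`` is the sense-strand (transcript) subsequence; for gRNAs
    ``spacer_seq`` is its reverse complement (the sequence loaded into the
    guide). ``left_overlap``/``right_overlap`` count target bases 5' and 3'
    of the back-splice junction and always sum to ``length``.
    """

    circ_id: str
    kind: str  # {"grna", "shrna"}
    window_start: int
    target_seq: str
    spacer_seq: str
    length: int
    left_overlap: int
    right_overlap: int
    offtarget_min_mm: int | None = None
    status: str = KEPT

    def __post_init__(self) -> None:
        if self.left_overlap + self.right_overlap != self.length:
            raise ValueError("overlaps must sum to spacer length")
        if min(self.left_overlap, self.right_overlap) < 0:
            raise ValueError("overlaps must be non-negative")
        if len(self.target_seq) != self.length:
            raise ValueError("target_seq length mismatch")
        if self.spacer_seq != revcomp(self.target_seq):
            raise ValueError("spacer_seq must be the reverse complement of target_seq")

    @property
    def overlap_label(self) -> str:
        return f"{self.left_overlap}+{self.right_overlap}"

    @property
    def spans_junction(self) -> bool:
        return self.left_overlap > 0 and self.right_overlap > 0

    @property
    def candidate_id(self) -> str:
        return f"{self.circ_id}{self.kind}:{self.window_start}:{self.length}"


@dataclass
class MismatchVariant:
    """A spacer with Watson-Crick complement substitutions at fixed positions."""

    parent_seq: str
    positions: tuple[int, ...]  # 1-based along the spacer
    mode: str  # {"single", "double_consecutive"}
    variant_seq: str = field(default="")

    def __post_init__(self) -> None:
        if not self.variant_seq:
            seq = list(self.parent_seq)
            for p in self.positions:
                seq[p - 1] = complement(self.parent_seq[p - 1])
            self.variant_seq = "".join(seq)


def _make_candidate(
    window: BsjWindow, start: int, length: int, kind: str
) -> GuideCandidate | None:
    target = window.sequence[start : start + length]
    if "N" in target.upper():
        warnings.warn(
            f"{window.circ_id}: candidate at {start} contains N, dropped", stacklevel=3
        )
        return None
    left = max(0, min(length, window.junction_offset - start))
    return GuideCandidate(
        circ_id=window.circ_id,
        kind=kind,
        window_start=start,
        target_seq=target,
        spacer_seq=revcomp(target),
        length=length,
        left_overlap=left,
        right_overlap=length - left,
    )


def _enumerate(
    window: BsjWindow, length: int, min_overhang: int, kind: str
) -> list[GuideCandidate]:
    if length > len(window):
        warnings.warn(
            f"{window.circ_id}: spacer length {length} exceeds window length "
            f"{len(window)}; no candidates",
            stacklevel=3,
        )
        return []
    out: list[GuideCandidate] = []
    for start in range(len(window) - length + 1):
        left = max(0, min(length, window.junction_offset - start))
        right = length - left
        if left < min_overhang or right < min_overhang:
            continue
        cand = _make_candidate(window, start, length, kind)
        if cand is not None:
            out.append(cand)
    return out


def enumerate_shrna_targets(
    window: BsjWindow, length: int = 21, min_overhang: int = 1
) -> list[GuideCandidate]:
    """All possible ``length``-nt shRNA target sites crossing the junction.

    Every substring of the window whose junction overlap is at least
    ``min_overhang`` on both sides, in ascending window_start order. On the
    default 40-nt window with 21-nt targets this yields 20 candidates.
    """
    return _enumerate(window, length, min_overhang, "shrna")


def enumerate_bsj_spacers(
    window: BsjWindow, length: int = 24, min_overhang: int = 1
) -> list[GuideCandidate]:
    """Tile ``length``-nt Cas13d spacers across the junction in 1-nt steps.

    On the default 40-nt window with 24-nt spacers this yields 17 candidates
    with overlap labels running from ``20+4`` to ``4+20``.
    """
    return _enumerate(window, length, min_overhang, "grna")


def classify_junction_overlap(candidate: GuideCandidate) -> str:
    """Return the ``a+b`` junction-overlap label (``20+4`` etc.).

    Non-spanning candidates (one overlap zero) still receive a label; use
    :attr:`GuideCandidate.spans_junction` to flag them.
    """
    return candidate.overlap_label


def extend_shrna_to_grna(
    shrna: GuideCandidate,
    window: BsjWindow,
    target_len: int = 24,
    extend_5prime: bool = False,
) -> GuideCandidate:
    """Convert a 21-nt shRNA target into a position-matched 24-nt gRNA.

    The target is extended at its 3' end (rightward in window coordinates, the
    sense strand reading direction), shifting 5' only when the window boundary
    is hit; ``extend_5prime=True`` mirrors the rule. The returned gRNA target
    always contains the shRNA target as a substring and still spans the
    junction.
    """
    if target_len < shrna.length:
        raise ValueError("target_len must be at least the shRNA length")
    if target_len > len(window):
        raise ValueError(
            f"window of length {len(window)} cannot host a {target_len}-nt target"
        )
    if target_len == shrna.length:
        start = shrna.window_start
    elif extend_5prime:
        start = max(0, shrna.window_start - (target_len - shrna.length))
    else:
        start = shrna.window_start
        if start + target_len > len(window):
            start = len(window) - target_len
    cand = _make_candidate(window, start, target_len, "grna")
    if cand is None:
        raise ValueError(f"{window.circ_id}: extension produced an N-containing target")
    assert shrna.target_seq in cand.target_seq
    return cand


def spacer_length_series(
    window: BsjWindow,
    anchor_start: int,
    lengths=range(21, 31),
    anchor: str = "5prime",
) -> list[GuideCandidate]:
    """Nested spacer series of varying length sharing one anchored end.

    With ``anchor="5prime"`` every candidate's target starts at
    ``anchor_start`` so shorter members are prefixes of longer ones; with
    ``anchor="3prime"``, ``anchor_start`` is the fixed exclusive end offset
    and members nest as suffixes. Lengths overflowing the window are skipped
    with a warning. The default 21..30 nt range covers the spacer-length
    optimization series.
    """
    out: list[GuideCandidate] = []
    for length in lengths:
        if anchor == "5prime":
            start, stop = anchor_start, anchor_start + length
        elif anchor == "3prime":
            start, stop = anchor_start - length, anchor_start
        else:
            raise ValueError("anchor must be '5prime' or '3prime'")
        if start < 0 or stop > len(window):
            warnings.warn(
                f"{window.circ_id}: length {length} overflows window, skipped",
                stacklevel=2,
            )
            continue
        cand = _make_candidate(window, start, length, "grna")
        if cand is not None:
            out.append(cand)
    return out


def mismatch_variants(
    spacer: str, positions, mode: str = "single"
) -> list[MismatchVariant]:
    """Watson-Crick complement-substitution variants of a spacer.

    ``mode="single"`` mutates one position per variant; ``"double_consecutive"``
    mutates each listed position ``p`` together with ``p + 1``. Positions are
    1-based. The substituted base is the complement of the original (A<->T,
    G<->C), i.e. a transversion at every site.
    """
    if mode not in {"single", "double_consecutive"}:
        raise ValueError("mode must be 'single' or 'double_consecutive'")
    length = len(spacer)
    out: list[MismatchVariant] = []
    for p in positions:
        if not 1 <= p <= length:
            raise ValueError(f"position {p} outside 1..{length}")
        if mode == "double_consecutive":
            if p + 1 > length:
                raise ValueError(f"double mismatch at {p} overflows spacer of length {length}")
            muts = (p, p + 1)
        else:
            muts = (p,)
        out.append(MismatchVariant(parent_seq=spacer, positions=muts, mode=mode))
    return out
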