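"""End-to-end library design: windows -> candidates -> off-target filter -> oligos."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .circ_model import CircRNARecord, build_bsj_window
from .guide_design import (
    GuideCandidate,
    enumerate_bsj_spacers,
    enumerate_shrna_targets,
    extend_shrna_to_grna,
)
from .offtarget import apply_offtarget_filter, remove_linear_overlap_designs
from .oligo_assembly import OligoRecord, assemble_grna_oligo, assemble_shrna_oligo


@dataclass
class DesignResult:
    """Kept candidates plus per-stage bookkeeping for one library design run."""

    grnas: list[GuideCandidate]
    shrnas: list[GuideCandidate]
    excluded: list[GuideCandidate]
    oligos: dict[str, OligoRecord] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)


def design_circrna_library(
    genome,
    circ_records: Sequence[CircRNARecord],
    transcriptome,
    spacer_len: int = 24,
    shrna_len: int = 21,
    min_overhang: int = 1,
    offtarget_threshold: int = 3,
    drop_terminal_overlaps: bool = False,
    position_matched: bool = False,
    arm_left: int = 20,
    arm_right: int = 20,
) -> DesignResult:
    """Design junction-targeting shRNA and Cas13d gRNA candidates.

    For each circRNA, a 40-nt BSJ window is extracted, all shRNA targets and
    gRNA spacers are tiled across the junction, and candidates within
    ``offtarget_threshold`` mismatches of any transcriptome sequence are
    excluded. With ``position_matched=True`` gRNAs are derived by extending
    each kept shRNA target to ``spacer_len`` rather than tiled independently.
    ``drop_terminal_overlaps`` additionally removes ``20+4``/``4+20``-style
    designs whose long arm matches the host linear mRNA.
    """
    all_shrnas: list[GuideCandidate] = []
    all_grnas: list[GuideCandidate] = []
    windows = {}
    for rec in circ_records:
        window = build_bsj_window(rec, genome, arm_left, arm_right)
        windows[rec.circ_id] = window
        all_shrnas.extend(enumerate_shrna_targets(window, shrna_len, min_overhang))
        if not position_matched:
            all_grnas.extend(enumerate_bsj_spacers(window, spacer_len, min_overhang))
    stage = {"shrna_enumerated": len(all_shrnas)}

    shrna_kept, shrna_excl = apply_offtarget_filter(
        all_shrnas, transcriptome, offtarget_threshold
    )
    if position_matched:
        all_grnas = [
            extend_shrna_to_grna(s, windows[s.circ_id], spacer_len) for s in shrna_kept
        ]
    stage["grna_enumerated"] = len(all_grnas)
    grna_kept, grna_excl = apply_offtarget_filter(
        all_grnas, transcriptome, offtarget_threshold
    )
    stage["shrna_kept_offtarget"] = len(shrna_kept)
    stage["grna_kept_offtarget"] = len(grna_kept)
    if drop_terminal_overlaps:
        before = set(id(c) for c in grna_kept)
        grna_kept = remove_linear_overlap_designs(grna_kept, spacer_len)
        grna_excl.extend(c for c in all_grnas if id(c) in before and c.status == "excluded_overlap")
    stage["grna_final"] = len(grna_kept)
    stage["shrna_final"] = len(shrna_kept)

    oligos: dict[str, OligoRecord] = {}
    for cand in grna_kept:
        oligos[cand.candidate_id] = assemble_grna_oligo(
            cand.spacer_seq, cand.candidate_id
        )
    for cand in shrna_kept:
        oligos[cand.candidate_id] = assemble_shrna_oligo(
            cand.target_seq, cand.candidate_id
        )
    return DesignResult(
        grnas=grna_kept,
        shrnas=shrna_kept,
        excluded=shrna_excl + grna_excl,
        oligos=oligos,
        stage_counts=stage,
    )


def audit_library(candidates: Sequence[GuideCandidate]) -> pd.DataFrame:
    """Overlap-class composition of a candidate library.

    One row per junction-overlap label with candidate counts and the
    fraction of the library (percent), e.g. to quantify how many designs are
    the near-terminal ``20+4``/``4+20`` class.
    """
    if not candidates:
        return pd.DataFrame(columns=["overlap_label", "n", "fraction_pct"])
    labels = pd.Series([c.overlap_label for c in candidates], name="overlap_label")
    counts = labels.value_counts().rename("n").rename_axis("overlap_label").reset_index()
    counts["fraction_pct"] = 100.0 * counts["n"] / counts["n"].sum()
    return counts
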