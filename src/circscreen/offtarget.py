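"""Transcriptome off-target screening for junction-targeting candidates.

A candidate is an off-target risk when its target sequence aligns to some
linear transcript with few mismatches: the exclusion rule drops every
candidate whose best transcriptome alignment has <= 3 mismatches. The scan
here is an exact full-length Hamming comparison of the candidate target
against every same-length window of every transcript, forward strand only
(candidates are compared in target-sense orientation against transcript
sense sequences); indels are not modeled. Exactness makes the scan strictly
more sensitive than a seeded heuristic aligner and reproducible in tests.

Junction geometry interacts with this rule: a candidate lying entirely
within one arm of the BSJ window is a verbatim substring of the host linear
mRNA (0 mismatches -> excluded), while a centred junction-spanning candidate
keeps one whole arm mismatched against any host placement, so overlaps >= 4
on both sides can never be excluded by the host transcript alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode
from .guide_design import EXCLUDED_OFFTARGET, EXCLUDED_OVERLAP, KEPT, GuideCandidate


@dataclass(frozen=True)
class OffTargetHit:
    """One near-match of a candidate inside a transcript."""

    query_id: str
    transcript_id: str
    offset: int  # 0-based position of the aligned window in the transcript
    mismatches: int


def _as_seq_dict(transcriptome) -> dict[str, str]:
    """Normalize a transcriptome (mapping or pyfaidx.Fasta) to {id: str}."""
    if isinstance(transcriptome, Mapping):
        return {k: str(v).upper() for k, v in transcriptome.items()}
    # pyfaidx.Fasta and similar: iterable of records with .name
    return {rec.name: str(rec).upper() for rec in transcriptome}


def min_mismatch_scan(
    candidate: GuideCandidate | str,
    transcriptome,
    report_max: int = 3,
    query_id: str | None = None,
) -> list[OffTargetHit]:
    """Scan every transcript window for near-matches of one candidate.

    Returns all hits with Hamming distance <= ``report_max`` and records the
    global minimum distance on the candidate (``offtarget_min_mm``). When no
    transcript window is comparable the minimum saturates at the candidate
    length.
    """
    seqs = _as_seq_dict(transcriptome)
    if not seqs:
        raise ValueError("empty transcriptome")
    if isinstance(candidate, GuideCandidate):
        qseq = candidate.target_seq.upper()
        qid = query_id or candidate.candidate_id
    else:
        qseq = str(candidate).upper()
        qid = query_id or qseq
    L = len(qseq)
    qarr = encode(qseq)
    best = L
    hits: list[OffTargetHit] = []
    for tid, tseq in seqs.items():
        if len(tseq) < L:
            continue
        windows = sliding_window_view(encode(tseq), L)
        mm = (windows != qarr).sum(axis=1)
        best = min(best, int(mm.min()))
        for off in np.flatnonzero(mm <= report_max):
            hits.append(OffTargetHit(qid, tid, int(off), int(mm[off])))
    if isinstance(candidate, GuideCandidate):
        candidate.offtarget_min_mm = best
    return hits


def apply_offtarget_filter(
    candidates: Sequence[GuideCandidate],
    transcriptome,
    threshold: int = 3,
    exempt_transcripts: Iterable[str] = (),
) -> tuple[list[GuideCandidate], list[GuideCandidate]]:
    """Partition candidates into (kept, excluded) by the mismatch rule.

    A candidate is excluded iff its minimum Hamming distance over all
    non-exempt transcripts is <= ``threshold`` (default 3). ``exempt_transcripts``
    lets positive-control guides match their own intended target without
    being dropped; circRNA candidates should never exempt anything. Statuses
    are updated in place, order is preserved, and the operation is idempotent.
    """
    seqs = _as_seq_dict(transcriptome)
    exempt = set(exempt_transcripts)
    scan_set = {k: v for k, v in seqs.items() if k not in exempt}
    kept: list[GuideCandidate] = []
    excluded: list[GuideCandidate] = []
    for cand in candidates:
        if scan_set:
            min_mismatch_scan(cand, scan_set, report_max=threshold)
            min_mm = cand.offtarget_min_mm
        else:
            min_mm = cand.length
            cand.offtarget_min_mm = min_mm
        if min_mm is not None and min_mm <= threshold:
            cand.status = EXCLUDED_OFFTARGET
            excluded.append(cand)
        else:
            cand.status = KEPT
            kept.append(cand)
    return kept, excluded


def remove_linear_overlap_designs(
    library: Sequence[GuideCandidate], spacer_len: int = 24, max_arm: int = 19
) -> list[GuideCandidate]:
    """Drop near-terminal junction designs (``20+4``/``4+20`` for 24-nt spacers).

    Candidates of length ``spacer_len`` whose larger junction arm exceeds
    ``max_arm`` contain a long contiguous match to the host linear mRNA and
    are removed; for the defaults this drops exactly the two extreme tilings
    of a 40-nt window. Other lengths pass through untouched; ``max_arm`` equal
    to the spacer length makes the filter the identity.
    """
    out: list[GuideCandidate] = []
    for cand in library:
        if cand.length == spacer_len and (
            cand.left_overlap > max_arm or cand.right_overlap > max_arm
        ):
            cand.status = EXCLUDED_OVERLAP
            continue
        out.append(cand)
    return out


def write_hit_report(hits: Iterable[OffTargetHit], path) -> None:
    """Tab-separated per-candidate hit report (query, transcript, offset, mismatches)."""
    with open(path, "w") as out:
        out.write("query\ttranscript\toffset\tmismatches\n")
        for h in hits:
            out.write(f"{h.query_id}\t{h.transcript_id}\t{h.offset}\t{h.mismatches}\n")
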