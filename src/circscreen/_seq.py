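"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Base-wise Watson-Crick complement, no reversal."""
    return seq.translate(_COMPLEMENT)


def circular_slice(seq: str, start: int, length: int) -> str:
    """Slice `length` bases from a circular sequence starting at `start`.

    Indices wrap modulo ``len(seq)``; the result may traverse the origin
    multiple times when ``length > len(seq)``.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("cannot slice an empty circular sequence")
    start %= n
    tiled = seq * ((start + length) // n + 1)
    return tiled[start : start + length]


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorized Hamming comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
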