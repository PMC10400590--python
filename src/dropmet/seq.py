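"""Small DNA sequence helpers shared by the simulator and the aligner.

Sequences are plain upper-case strings in the public API; hot paths use
``numpy`` uint8 arrays of ASCII codes (see :func:`to_array`).
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

A, C, G, T = (np.uint8(ord(b)) for b in "ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_array(seq: str) -> np.ndarray:
    """ASCII codes of ``seq`` as a uint8 array (zero-copy friendly)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def from_array(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def bisulfite_ct(seq: str) -> str:
    """Full C->T conversion (three-letter top-strand space)."""
    return seq.replace("C", "T")


def bisulfite_ga(seq: str) -> str:
    """Full G->A conversion (three-letter bottom-strand space)."""
    return seq.replace("G", "A")
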