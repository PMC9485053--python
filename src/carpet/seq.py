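"""Small DNA-sequence utilities used by the scanners and the simulator."""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: allowed characters after upper-casing
DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a plus-strand sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str) -> str:
    """Upper-case ``seq`` and reject characters outside A/C/G/T/N."""
    up = seq.upper()
    bad = set(up) - DNA_ALPHABET
    if bad:
        raise InvalidInputError(f"non-DNA characters in sequence: {sorted(bad)!r}")
    return up


def seq_to_bytes(seq: str) -> np.ndarray:
    """View a sequence as a uint8 array for vectorized matching."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def motif_positions(seq_bytes: np.ndarray, motif: str) -> np.ndarray:
    """0-based start positions of every (overlapping) occurrence of ``motif``."""
    m = seq_to_bytes(motif)
    k = len(m)
    n = seq_bytes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    hit = seq_bytes[: n - k + 1] == m[0]
    for j in range(1, k):
        hit &= seq_bytes[j : n - k + 1 + j] == m[j]
    return np.nonzero(hit)[0].astype(np.int64)
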