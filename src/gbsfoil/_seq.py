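"""Nucleotide encoding shared across the package.

Sequences are held as ``uint8`` arrays with A,C,G,T -> 0..3, N -> 4 and
the alignment gap -> 5.  Codes >= 4 count as missing everywhere.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN-"
A, C, G, T = 0, 1, 2, 3
N_CODE = 4
GAP_CODE = 5

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string; unknown characters become N."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def encode_many(seqs) -> np.ndarray:
    """Encode equal-length strings into a 2-D array (n, L)."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    return np.stack([encode(s) for s in seqs])


def identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of matching sites between two equal-length coded sequences."""
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(np.mean(a == b))
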