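"""Small shared sequence helpers (byte-level, numpy-backed)."""

from __future__ import annotations

import gzip
from typing import IO

import numpy as np

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of ASCII codes (no copy of semantics)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(seq_to_u8(a) != seq_to_u8(b)))


def sliding_mismatches(seq: str, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` against every window of ``seq``.

    Returns an integer array of length ``len(seq) - len(pattern) + 1``
    (empty if the pattern does not fit).
    """
    m, n = len(pattern), len(seq)
    if m > n or m == 0:
        return np.zeros(0, dtype=np.int64)
    s = seq_to_u8(seq)
    p = seq_to_u8(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    return (windows != p).sum(axis=1)


def mean_quality(qual: str, offset: int = 33) -> float:
    if not qual:
        return 0.0
    return float((seq_to_u8(qual) - offset).mean())


def open_maybe_gzip(path, mode: str = "rt") -> IO:
    """Open plain or gzip-compressed text transparently (sniffs magic bytes)."""
    path = str(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))
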