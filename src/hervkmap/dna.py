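"""Small nucleotide-sequence helpers shared across the pipeline.

Sequences are plain upper-case ``str`` at module boundaries; hot loops work
on ``numpy`` ``uint8`` code arrays (A,C,G,T -> 0..3, anything else -> 4).
"""
from __future__ import annotations

import numpy as np

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

#: base -> small-integer code; N and every non-ACGT byte map to 4 so that
#: an N position can never silently count as a match.
CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    CODE[_b] = _i
    CODE[_b + 32] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complements)."""
    return seq.encode("ascii").translate(_COMP)[::-1].decode("ascii")


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 code array."""
    return CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return bytes(_DECODE[codes]).decode("ascii")


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform i.i.d. ACGT sequence of length *n*."""
    return bytes(_BASE_LUT[rng.integers(0, 4, n, dtype=np.uint8)]).decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. point substitutions at the given per-site rate.

    Each mutated site is replaced by one of the three other bases chosen
    uniformly; non-ACGT sites are left untouched.
    """
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = CODE[arr]
    hit = rng.random(len(seq)) < rate
    hit &= codes < 4
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return seq
    shift = rng.integers(1, 4, idx.size, dtype=np.uint8)
    arr[idx] = _BASE_LUT[(codes[idx] + shift) % 4]
    return arr.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length sequences; N mismatches everything."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal lengths")
    ca, cb = encode(a), encode(b)
    return int(np.count_nonzero((ca != cb) | (ca == 4) | (cb == 4)))
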