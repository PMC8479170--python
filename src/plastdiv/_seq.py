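"""Low-level sequence helpers shared across modules.

Sequences are plain ``str`` at the API surface; internally alignments are
numpy ``uint8`` arrays of ASCII codes so column-wise operations vectorize.
"""

from __future__ import annotations

import numpy as np

GAP = ord("-")
A, C, G, T, N = ord("A"), ord("C"), ord("G"), ord("T"), ord("N")

BASES = "ACGT"

# 256-entry lookup: A,C,G,T -> 0..3, N -> 4, '-' -> 5, anything else -> 6
CODE = np.full(256, 6, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    CODE[ord(_b)] = _i
CODE[N] = 4
CODE[GAP] = 5

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}
_COMP_ARR = np.arange(256, dtype=np.uint8)
for _k, _v in _COMPLEMENT.items():
    _COMP_ARR[ord(_k)] = ord(_v)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def complement(seq: str) -> str:
    return seq.translate(str.maketrans(_COMPLEMENT))


def revcomp(seq: str) -> str:
    return complement(seq)[::-1]


def comp_array(arr: np.ndarray) -> np.ndarray:
    """Complement an ASCII uint8 array."""
    return _COMP_ARR[arr]


def to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.38) -> np.ndarray:
    """Random sequence as an ASCII array with the given GC fraction."""
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    codes = rng.choice(
        np.array([A, C, G, T], dtype=np.uint8),
        size=length,
        p=[p_at, p_gc, p_gc, p_at],
    )
    return codes.astype(np.uint8)
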