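"""Low-level DNA sequence utilities shared across the package.

Sequences are plain Python strings over {A,C,G,T,N}; the numeric 2-bit
encoding is used only inside the exact aligner and the motif profiler.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 codes: A=0 C=1 G=2 T=3, anything else (N) = 4
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe, case-preserving complement table)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 (A=0 C=1 G=2 T=3, N/other=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def random_sequence(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    """Random sequence with the given expected GC content, AT/GC symmetric."""
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return decode(codes.astype(np.uint8))


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    arr = encode(seq)
    return float(np.mean((arr == 1) | (arr == 2)))


def mutate(rng: np.random.Generator, seq: str, rate: float,
           protected: list[tuple[int, int]] | None = None) -> str:
    """Substitute bases at the given per-base rate.

    ``protected`` intervals (half-open, local coordinates) are left intact —
    used to keep a motif untouched inside a duplicated segment.
    """
    arr = encode(seq).copy()
    hit = rng.random(len(arr)) < rate
    if protected:
        for s, e in protected:
            hit[s:e] = False
    idx = np.nonzero(hit & (arr < 4))[0]
    if len(idx):
        # shift by 1..3 mod 4 guarantees a different base
        arr[idx] = (arr[idx] + rng.integers(1, 4, size=len(idx))) % 4
    return decode(arr)
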