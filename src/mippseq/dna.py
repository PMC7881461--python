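"""Small nucleotide-sequence helpers shared across the package.

Sequences are plain uppercase Python strings over {A,C,G,T,N}; numpy
integer encodings (A=0,C=1,G=2,T=3) are used internally where scanning
speed matters.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 (A=0,C=1,G=2,T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in arr)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_reference(length: int, seed: int, gc: float = 0.5) -> str:
    """Seed-fixed random reference sequence with the given GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p))


def homopolymer_lengths(seq: str) -> np.ndarray:
    """Per-position length of the homopolymer run containing that base.

    Used to scale indel error rates: platform chemistry produces excess
    indels inside long runs of a single base.
    """
    arr = encode(seq)
    n = len(arr)
    out = np.empty(n, dtype=np.int32)
    i = 0
    while i < n:
        j = i
        while j < n and arr[j] == arr[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out


def apply_snv(seq: str, offset: int, alt: str) -> str:
    """Return seq with a single-base substitution at 0-based offset."""
    return seq[:offset] + alt + seq[offset + 1 :]
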