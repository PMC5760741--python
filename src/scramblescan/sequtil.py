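"""Small nucleotide-string utilities shared across modules.

Sequences are plain upper-case strings throughout the package; coordinates
are 0-based half-open unless a file dialect says otherwise.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

#: byte codes used by the vectorised helpers: A=0, C=1, G=2, T=3, other=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases; 0.0 for an empty sequence."""
    if not seq:
        return 0.0
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    return gc / denom if denom else 0.0


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random i.i.d. sequence with expected GC content ``gc``."""
    if length <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def union_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
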