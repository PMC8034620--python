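"""Small DNA-string utilities shared across the package.

Sequences are plain Python strings over the alphabet ACGT, always written
5'->3'. Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, *, allow_n: bool = False) -> bool:
    allowed = set(DNA_ALPHABET + ("N" if allow_n else ""))
    return bool(seq) and set(seq) <= allowed


def validate_dna(seq: str, name: str = "sequence") -> str:
    if not is_dna(seq):
        raise ValueError(f"{name} contains non-ACGT characters: {seq!r:.60}")
    return seq


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA with the requested expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(DNA_ALPHABET))[rng.choice(4, size=length, p=p)])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def scan_approx(haystack: str, needle: str, max_mismatches: int = 0) -> list[int]:
    """All start offsets where ``needle`` matches ``haystack`` with at most
    ``max_mismatches`` substitutions. Simple Hamming scan at every offset;
    amplicon payloads are short so the quadratic cost is irrelevant."""
    n, m = len(haystack), len(needle)
    if m == 0 or m > n:
        return []
    if max_mismatches == 0:
        hits, start = [], haystack.find(needle)
        while start != -1:
            hits.append(start)
            start = haystack.find(needle, start + 1)
        return hits
    hay = np.frombuffer(haystack.encode(), dtype=np.uint8)
    ndl = np.frombuffer(needle.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(hay, m)
    mism = (windows != ndl).sum(axis=1)
    return [int(i) for i in np.nonzero(mism <= max_mismatches)[0]]


def mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    """Apply i.i.d. per-base substitutions at the given rate."""
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        arr[i] = rng.choice([b for b in DNA_ALPHABET if b != arr[i]])
    return "".join(arr)
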