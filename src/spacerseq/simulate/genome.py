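"""Phage-genome stand-in and PAM-adjacent protospacer sampling.

The lytic phage whose genome donates new spacers is represented by a
random sequence of configurable length and GC content; spacers acquired
by the type II-A system derive from protospacers flanked 3' by an NGG
PAM (SpyCas9), so the sampler can be restricted to PAM-adjacent sites.
"""

from __future__ import annotations

import numpy as np

from ..dna import random_dna, revcomp
from ..models import Genome


class NoSiteError(ValueError):
    """No protospacer of the requested geometry exists in the genome."""


def make_phage_genome(length: int, gc: float = 0.5, seed: int = 0,
                      id: str = "phage") -> Genome:
    """Random phage genome of exactly ``length`` bp with expected GC
    fraction ``gc``. Reproducible for a fixed seed."""
    if length < 100:
        raise ValueError("genome length must be >= 100")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    return Genome(id=id, sequence=random_dna(rng, length, gc))


def enumerate_pam_sites(genome: Genome, length: int) -> list[tuple[int, int, str]]:
    """All (start, end, strand) protospacer intervals of ``length`` whose
    3' flank on the match strand is NGG. Coordinates are forward-strand,
    0-based half-open, for both strands."""
    seq = genome.sequence
    n = len(seq)
    sites: list[tuple[int, int, str]] = []
    for i in range(0, n - length - 2):
        # + strand: PAM at [i+length, i+length+3)
        if seq[i + length + 1] == "G" and seq[i + length + 2] == "G":
            sites.append((i, i + length, "+"))
    for i in range(3, n - length + 1):
        # - strand: protospacer is revcomp(seq[i:i+length]); its 3' flank on
        # the minus strand is revcomp(seq[i-3:i]), NGG iff seq[i-3:i-1] == CC
        if seq[i - 3] == "C" and seq[i - 2] == "C":
            sites.append((i, i + length, "-"))
    return sites


def sample_protospacer(genome: Genome, length: int, require_pam: bool = True,
                       seed: int = 0) -> tuple[str, tuple[int, int], str]:
    """Draw one protospacer uniformly from the genome.

    Returns ``(sequence, (start, end), strand)`` where the sequence is the
    spacer as acquired (i.e. the match-strand sequence) and the interval is
    on the forward genome coordinate. With ``require_pam`` only sites whose
    3' flank fits NGG are eligible.
    """
    rng = np.random.default_rng(seed)
    n = len(genome)
    if length > n:
        raise NoSiteError(f"requested length {length} exceeds genome length {n}")
    if require_pam:
        sites = enumerate_pam_sites(genome, length)
        if not sites:
            raise NoSiteError(f"no NGG-adjacent site of length {length}")
        start, end, strand = sites[rng.integers(len(sites))]
    else:
        start = int(rng.integers(0, n - length + 1))
        end, strand = start + length, "+" if rng.random() < 0.5 else "-"
    sub = genome.sequence[start:end]
    return (sub if strand == "+" else revcomp(sub)), (start, end), strand
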