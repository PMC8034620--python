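"""Simulator for barcoded amplicon reads of expanded CRISPR arrays.

Each acquisition event draws a PAM-adjacent protospacer from the phage
genome, inserts it with a duplicated repeat at the leader-proximal edge
of the parent array, and emits the amplicon read that a sample-tracking
primer would produce:

    [5-nt random tag][3-5 bp sample barcode][20-nt constant anchor][locus]

PCR duplication bias is modelled as k duplicate reads per event sharing
one random tag, with k drawn from a configurable discrete distribution
(default geometric with mean 3). The returned truth table records, per
event, the sample, tag, spacer sequence/length, protospacer interval,
strand and PAM, so downstream calls can be scored exactly.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from ..dna import mutate, random_dna
from ..io import Read
from ..models import BarcodeSpec, CrisprArrayModel, Genome, check_prefix_free
from .genome import enumerate_pam_sites, NoSiteError

DEFAULT_ANCHOR = "ACGTTGCAACGTGACTGGAC"  # constant primer-anchor stand-in


def default_parent_model(seed: int = 0, n_spacers: int = 0,
                         repeat_length: int = 36, leader_length: int = 60,
                         spacer_length: int = 30) -> CrisprArrayModel:
    """A synthetic single-repeat parent plasmid model (optionally with
    ``n_spacers`` pre-existing spacers for recombination scenarios)."""
    rng = np.random.default_rng(seed)
    return CrisprArrayModel(
        leader=random_dna(rng, leader_length),
        repeat=random_dna(rng, repeat_length),
        spacers=tuple(random_dna(rng, spacer_length) for _ in range(n_spacers)),
        upstream_flank=random_dna(rng, 40),
        downstream_flank=random_dna(rng, 80),
    )


def geometric_duplication(mean: float = 3.0) -> Callable[[np.random.Generator], int]:
    """PCR duplication factor k >= 1 ~ geometric with the given mean."""
    if mean < 1:
        raise ValueError("mean duplication factor must be >= 1")
    p = 1.0 / mean
    return lambda rng: int(rng.geometric(p))


def simulate_acquisition_reads(
    model: CrisprArrayModel,
    genome: Genome,
    barcodes: list[BarcodeSpec],
    n_events: int,
    length_weights: dict[int, float],
    pcr_bias: Callable[[np.random.Generator], int] | int | None = None,
    error_rate: float = 0.0,
    require_pam: bool = True,
    anchor: str = DEFAULT_ANCHOR,
    seed: int = 0,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate ``n_events`` independent acquisition events.

    Returns ``(reads, truth)`` where ``truth`` has one row per event with
    columns: event_id, sample_id, umi, spacer, length, start, end, strand,
    pam, n_reads, umi_collision.
    """
    check_prefix_free(barcodes)
    if abs(sum(length_weights.values()) - 1.0) > 1e-9:
        raise ValueError("length_weights must sum to 1")
    if pcr_bias is None:
        pcr_bias = geometric_duplication(3.0)
    elif isinstance(pcr_bias, int):
        k = pcr_bias
        if k < 1:
            raise ValueError("duplication factor must be >= 1")
        pcr_bias = lambda rng: k  # noqa: E731

    rng = np.random.default_rng(seed)
    lengths = sorted(length_weights)
    probs = np.array([length_weights[l] for l in lengths])

    # pre-enumerate PAM-adjacent sites once per requested length
    sites_by_len: dict[int, list[tuple[int, int, str]]] = {}
    for l in lengths:
        sites = enumerate_pam_sites(genome, l) if require_pam else None
        if require_pam and not sites:
            raise NoSiteError(f"no NGG-adjacent site of length {l} in genome")
        sites_by_len[l] = sites

    from ..dna import revcomp

    reads: list[Read] = []
    rows = []
    seen_umis: dict[str, set[str]] = {b.sample_id: set() for b in barcodes}
    for ev in range(n_events):
        bc = barcodes[rng.integers(len(barcodes))]
        length = int(lengths[rng.choice(len(lengths), p=probs)])
        if require_pam:
            start, end, strand = sites_by_len[length][
                rng.integers(len(sites_by_len[length]))]
        else:
            start = int(rng.integers(0, len(genome) - length + 1))
            end, strand = start + length, "+" if rng.random() < 0.5 else "-"
        sub = genome.sequence[start:end]
        spacer = sub if strand == "+" else revcomp(sub)
        if strand == "+":
            pam = genome.sequence[end:end + 3]
        else:
            pam = revcomp(genome.sequence[start - 3:start])
        umi = random_dna(rng, bc.umi_length)
        collision = umi in seen_umis[bc.sample_id]
        seen_umis[bc.sample_id].add(umi)

        locus = model.expanded_locus(spacer, edge_index=1)
        template = umi + bc.barcode + anchor + locus
        k = pcr_bias(rng)
        for dup in range(k):
            seq = mutate(rng, template, error_rate)
            reads.append(Read(id=f"ev{ev}_d{dup}", sequence=seq))
        rows.append(dict(event_id=f"ev{ev}", sample_id=bc.sample_id, umi=umi,
                         spacer=spacer, length=length, start=start, end=end,
                         strand=strand, pam=pam, n_reads=k,
                         umi_collision=collision))
    return reads, pd.DataFrame(rows)
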