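"""Prespacer substrate designer and stochastic trimming simulator.

Substrate geometry mirrors the integration-selection design: a duplex of
configurable length with 3' single-stranded overhangs on each side and,
optionally, two abutted inverted BbsI (GAAGAC) recognition+cleavage sites
occupying the central 24 bp of the duplex. BbsI is a Type IIS enzyme that
cuts 2 nt (top) / 6 nt (bottom) downstream of its site, leaving 4-nt
overhangs, so each outward-facing half-site occupies 4 + 2 + 6 = 12 bp
and the inverted pair spans 24 bp with both cleavage overhangs inside it.

Trimming models the supercomplex's HNH-dependent 3'->5' exonucleolytic
processing: each molecule is processed with a probability set by its
longest 3' overhang, and processed molecules end up near the canonical
~30 bp product length.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from ..dna import random_dna, revcomp
from ..models import (
    BBSI_CASSETTE_BP,
    BBSI_HALF_BP,
    BBSI_SITE,
    PrespacerSubstrate,
    TrimProductSet,
)

CANONICAL_PRODUCT_BP = 30  # physiological type II-A spacer length


def bbsi_cassette_top(rng: np.random.Generator) -> str:
    """Top strand of the 24-bp inverted-BbsI cassette:
    [4-nt overhang][2-nt spacer][GTCTTC][GAAGAC][2-nt spacer][4-nt overhang]
    i.e. two recognition sites abutted at the centre on opposite strands,
    each cutting outward so its 4-nt overhang lies inside the 24 bp."""
    left = random_dna(rng, 4) + random_dna(rng, 2) + revcomp(BBSI_SITE)
    right = BBSI_SITE + random_dna(rng, 2) + random_dna(rng, 4)
    assert len(left) == len(right) == BBSI_HALF_BP
    return left + right


def design_prespacer(duplex_length: int, overhang_left: int = 0,
                     overhang_right: int = 0, with_pam: bool = False,
                     with_bbsi: bool = False, seed: int = 0) -> PrespacerSubstrate:
    """Design one prespacer substrate.

    ``overhang_left``/``overhang_right`` are 3' single-stranded extensions
    (left = bottom strand's 3' end, right = top strand's 3' end). With
    ``with_bbsi`` the central 24 bp of the duplex carry the inverted BbsI
    cassette; with ``with_pam`` the last 3 duplex bases of the top strand
    are an NGG motif.
    """
    if overhang_left < 0 or overhang_right < 0:
        raise ValueError("overhangs must be >= 0")
    if with_bbsi and duplex_length < BBSI_CASSETTE_BP:
        raise ValueError(f"BbsI cassette needs duplex_length >= {BBSI_CASSETTE_BP}")
    if duplex_length < 1:
        raise ValueError("duplex_length must be >= 1")
    rng = np.random.default_rng(seed)
    duplex = list(random_dna(rng, duplex_length))
    interval = None
    if with_bbsi:
        start = (duplex_length - BBSI_CASSETTE_BP) // 2
        interval = (start, start + BBSI_CASSETTE_BP)
        if with_pam and interval[1] > duplex_length - 3:
            raise ValueError("duplex too short to fit both BbsI cassette and PAM")
        duplex[start:start + BBSI_CASSETTE_BP] = bbsi_cassette_top(rng)
    if with_pam:
        duplex[-3:] = ["A", "G", "G"]
    duplex_top = "".join(duplex)
    top = duplex_top + random_dna(rng, overhang_right)
    bottom = revcomp(duplex_top) + random_dna(rng, overhang_left)
    return PrespacerSubstrate(
        top_strand=top, bottom_strand=bottom, duplex_length=duplex_length,
        overhang_3p_left=overhang_left, overhang_3p_right=overhang_right,
        has_pam=with_pam, bbsi_cassette_interval=interval)


def default_efficiency_by_overhang(overhang: int) -> float:
    """Processing probability as a function of the longest 3' overhang.

    Shaped after the observed substrate preference: overhangs of 6-12 nt
    are fully processed; efficiency falls off on both sides (0.6 at 3 nt,
    declining to 0.2 at 25 nt, ~0 for blunt duplexes). Piecewise linear;
    a free model knob, not a measured curve.
    """
    o = float(overhang)
    if o <= 0:
        return 0.0
    if o < 6:
        return min(1.0, 0.2 * o)  # 0.6 at 3 nt, 1.0 at 5-6
    if o <= 12:
        return 1.0
    if o <= 25:
        return 1.0 - 0.8 * (o - 12) / 13.0  # 1.0 at 12 -> 0.2 at 25
    return 0.2


def simulate_trimming(
    substrate: PrespacerSubstrate,
    target_length: int = CANONICAL_PRODUCT_BP,
    efficiency_by_overhang: Callable[[int], float] | Mapping[int, float] | None = None,
    noise_sd: float = 1.0,
    n_molecules: int = 1,
    seed: int = 0,
) -> TrimProductSet:
    """Stochastically trim ``n_molecules`` copies of ``substrate``.

    Each molecule is processed with probability
    ``efficiency_by_overhang(max overhang)``; processed molecules get a
    product duplex length drawn from round(Normal(target_length, noise_sd)),
    truncated to [1, total input length]; unprocessed molecules keep their
    input length. ``fraction_processed`` is the realised processed fraction.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    eff = efficiency_by_overhang
    if eff is None:
        eff = default_efficiency_by_overhang
    elif isinstance(eff, Mapping):
        table = dict(eff)
        eff = lambda o: table[o]  # noqa: E731
    p = float(eff(max(substrate.overhang_3p_left, substrate.overhang_3p_right)))
    if not 0.0 <= p <= 1.0:
        raise ValueError("efficiency must be a probability")

    rng = np.random.default_rng(seed)
    total = substrate.total_span
    processed = rng.random(n_molecules) < p
    lengths = np.full(n_molecules, total, dtype=int)
    n_proc = int(processed.sum())
    if n_proc:
        drawn = np.rint(rng.normal(target_length, noise_sd, size=n_proc))
        lengths[processed] = np.clip(drawn, 1, total).astype(int)
    return TrimProductSet(substrate=substrate,
                          product_lengths=[int(l) for l in lengths],
                          fraction_processed=n_proc / n_molecules)
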