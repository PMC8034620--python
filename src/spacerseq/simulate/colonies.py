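"""Simulator for colonies carrying full-site integration products.

The selection screen works like this: a prespacer substrate with a
central inverted-BbsI cassette is integrated into the parent plasmid in
vitro; BbsI digestion then swaps the central 24 bp for a chloramphenicol
selection cassette, so only plasmids with both prespacer ends joined
(full-site products) yield resistant colonies. Each colony is Sanger
sequenced with two primers inside the selection cassette pointing
outward toward the flanking array.

The simulator builds one plasmid per colony according to its event
class and emits the two outward reads:

* ``full_site_repeat_edge`` — repeat duplicated, spacer (optionally
  trimmed) inserted at the leader-side edge of a repeat; orientation
  uniform by default.
* ``ectopic_site`` — spacer inserted in the plasmid backbone, away from
  any repeat edge.
* ``nonconsecutive_flank`` — full-site insertion accompanied by loss of
  an adjacent original spacer (recombination between repeats), so the
  new spacer is flanked by nonconsecutive original spacers.
* ``prespacer_end_indel`` — full-site insertion whose prespacer end
  carries a synthesis-type defect (terminal substitution or an inserted
  base at the end junction).
* ``low_quality_trace`` — a normal full-site plasmid whose traces are
  degraded below the interpretability threshold.

Reads and qualities are sequence+score only (no chromatograms). The
truth table carries the event class, orientation, site and length for
scoring; the annotator never reads it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..dna import mutate, random_dna, revcomp
from ..models import ColonyReadPair, CrisprArrayModel, PrespacerSubstrate

COLONY_CLASSES = (
    "full_site_repeat_edge",
    "ectopic_site",
    "nonconsecutive_flank",
    "prespacer_end_indel",
    "low_quality_trace",
)

PRIMER_ANCHOR_NT = 20  # bases of cassette sequence at the start of each read


def default_cassette(seed: int = 7, length: int = 160) -> str:
    """Synthetic stand-in for the chloramphenicol selection cassette."""
    return random_dna(np.random.default_rng(seed), length)


def _spacer_arms(substrate: PrespacerSubstrate,
                 trimmed_length: int | None) -> tuple[str, str]:
    """Gap-filled prespacer arms flanking the BbsI region, optionally
    after symmetric trimming of the molecule to ``trimmed_length`` bp."""
    ft = substrate.filled_top()
    cs, ce = substrate.filled_cassette_interval()
    left, right = ft[:cs], ft[ce:]
    if trimmed_length is not None:
        excess = substrate.total_span - trimmed_length
        if excess < 0:
            raise ValueError("trimmed_length exceeds the substrate span")
        tl = excess // 2
        tr = excess - tl
        if tl > len(left) or tr > len(right):
            raise ValueError("trimmed_length cuts into the BbsI region")
        left = left[tl:]
        right = right[:len(right) - tr] if tr else right
    return left, right


def _quality_profile(rng: np.random.Generator, n: int, low: bool) -> tuple[int, ...]:
    # Sanger-like: high with a degradation tail, or globally poor traces
    if low:
        q = rng.normal(10, 3, size=n)
    else:
        q = np.linspace(50, 30, n) + rng.normal(0, 2, size=n)
    return tuple(int(x) for x in np.clip(q, 2, 60))


def simulate_integration_colonies(
    model: CrisprArrayModel,
    substrate: PrespacerSubstrate,
    class_probs: dict[str, float],
    n_colonies: int,
    read_len: int = 500,
    error_rate: float = 0.0,
    cassette: str | None = None,
    trimmed_length: int | None = None,
    seed: int = 0,
) -> tuple[list[ColonyReadPair], pd.DataFrame]:
    """Simulate ``n_colonies`` sequenced colonies.

    ``class_probs`` assigns a probability to each event class in
    :data:`COLONY_CLASSES` (missing classes get 0). ``trimmed_length``
    models supercomplex-processed prespacers: the integrated spacer is
    symmetrically trimmed to that many bp (None = unprocessed, full
    substrate span). Returns the read pairs plus a truth table.
    """
    if substrate.bbsi_cassette_interval is None:
        raise ValueError("substrate must carry a BbsI cassette for selection")
    unknown = set(class_probs) - set(COLONY_CLASSES)
    if unknown:
        raise ValueError(f"unknown colony classes: {sorted(unknown)}")
    probs = np.array([class_probs.get(c, 0.0) for c in COLONY_CLASSES], float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must sum to 1")
    if cassette is None:
        cassette = default_cassette()
    if len(cassette) < 2 * PRIMER_ANCHOR_NT:
        raise ValueError("cassette too short for two primer anchors")

    rng = np.random.default_rng(seed)
    n_spk = len(model.spacers)
    pairs: list[ColonyReadPair] = []
    rows = []
    for c in range(n_colonies):
        cls = COLONY_CLASSES[rng.choice(len(COLONY_CLASSES), p=probs)]
        forward = bool(rng.random() < 0.5)
        left, right = _spacer_arms(substrate, trimmed_length)
        spacer_len = len(left) + (substrate.bbsi_cassette_interval[1]
                                  - substrate.bbsi_cassette_interval[0]) + len(right)
        edge = None
        defect = None
        if cls == "prespacer_end_indel":
            defect = ("sub" if rng.random() < 0.5 else "ins",
                      "left" if rng.random() < 0.5 else "right")
            kind, side = defect
            if kind == "sub":
                if side == "left" and left:
                    b = left[0]
                    left = rng.choice([x for x in "ACGT" if x != b]) + left[1:]
                elif right:
                    b = right[-1]
                    right = right[:-1] + rng.choice([x for x in "ACGT" if x != b])
            else:
                extra = random_dna(rng, 1)
                if side == "left":
                    left = extra + left
                else:
                    right = right + extra

        # assemble the plasmid and locate the selection cassette within it
        if forward:
            block = left + cassette + right
            cass_off = len(left)
        else:
            block = revcomp(left + cassette + right)
            cass_off = len(right)
        cass_len = len(cassette)

        if cls == "ectopic_site":
            flank = model.downstream_flank
            if len(flank) < 20:
                raise ValueError("downstream flank too short for ectopic events")
            cut = len(flank) // 2
            pre = (model.upstream_flank + model.array_sequence() + flank[:cut])
            plasmid = pre + block + flank[cut:]
            a = len(pre) + cass_off
        elif cls == "nonconsecutive_flank":
            if n_spk < 1:
                raise ValueError("nonconsecutive_flank needs >= 1 original spacer")
            k = int(rng.integers(1, n_spk + 1))  # original spacer lost
            parts = [model.upstream_flank, model.leader]
            for i in range(1, k):
                parts += [model.repeat, model.spacers[i - 1]]
            parts += [model.repeat, block, model.repeat]
            for i in range(k + 1, n_spk + 1):
                parts += [model.spacers[i - 1], model.repeat]
            parts.append(model.downstream_flank)
            pre_len = sum(len(p) for p in parts[:2 + 2 * (k - 1) + 1])
            plasmid = "".join(parts)
            a = pre_len + cass_off
            edge = k
        else:  # full-site at a repeat edge (also the end-indel/low-quality base)
            edge = int(rng.integers(1, model.n_repeats + 1))
            plasmid = model.expanded_locus(block, edge_index=edge)
            pre_len = plasmid.index(block)  # block is unique: contains cassette
            a = pre_len + cass_off
        b = a + cass_len

        # outward reads from the two cassette-internal primer sites
        off = PRIMER_ANCHOR_NT
        if forward:
            fwd = revcomp(plasmid[max(0, a + off - read_len):a + off])
            rev = plasmid[b - off:min(len(plasmid), b - off + read_len)]
        else:
            fwd = plasmid[b - off:min(len(plasmid), b - off + read_len)]
            rev = revcomp(plasmid[max(0, a + off - read_len):a + off])
        fwd = mutate(rng, fwd, error_rate)
        rev = mutate(rng, rev, error_rate)
        low = cls == "low_quality_trace"
        pair = ColonyReadPair(
            colony_id=f"col{c}",
            fwd_read=fwd, rev_read=rev,
            fwd_quality=_quality_profile(rng, len(fwd), low),
            rev_quality=_quality_profile(rng, len(rev), low),
            truth_label=dict(event_class=cls,
                             orientation="forward" if forward else "reverse",
                             repeat_index=edge,
                             leader_proximal=(edge == 1 and cls in (
                                 "full_site_repeat_edge", "low_quality_trace")),
                             spacer_length=spacer_len,
                             defect=defect),
        )
        pairs.append(pair)
        rows.append(dict(colony_id=pair.colony_id, event_class=cls,
                         orientation=pair.truth_label["orientation"],
                         repeat_index=edge if edge is not None else -1,
                         leader_proximal=pair.truth_label["leader_proximal"],
                         spacer_length=spacer_len))
    return pairs, pd.DataFrame(rows)
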