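"""Annotation of full-site integration products from colony Sanger reads.

Each colony yields two outward-facing reads primed inside the selection
cassette. The merger reverse-complements the reverse read, concatenates
the pair around a gap sentinel, anchors each read to its
cassette-internal primer site and derives the two junction contexts in
the cassette-forward frame: ``left_context`` ends at the cassette's 5'
junction and ``right_context`` starts at its 3' junction.

The annotator then reconstructs the integrated spacer — the prespacer
arms flanking the cassette plus the 24 bp the cassette replaced — and
classifies the event. A colony is excluded if its traces are low
quality or uninterpretable; if the spacer sits anywhere other than the
edge of a direct repeat; if it is flanked by nonconsecutive spacers of
the original array (repeat-mediated recombination); or if the prespacer
ends carry mutations or indels. When defects co-occur a single primary
reason is reported, in that priority order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .dna import hamming, revcomp
from .models import (
    BBSI_CASSETTE_BP,
    ColonyReadPair,
    CrisprArrayModel,
    PrespacerSubstrate,
)
from .simulate.colonies import PRIMER_ANCHOR_NT

GAP_SENTINEL = "-" * 10
LOW_QUALITY_MEAN_PHRED = 20.0
EDGE_WINDOW_NT = 8      # repeat bases that must abut the spacer exactly
JUNCTION_SLACK_NT = 4   # stray bases tolerated (flagged as end defects)
ARM_GIVEBACK_NT = 6     # chance suffix overmatch into the repeat, reclaimable

EXCLUSION_PRIORITY = ("low_quality", "non_repeat_edge",
                      "nonconsecutive_flank", "end_mutation_indel")


@dataclass(frozen=True)
class PlasmidFeatureDb:
    """Reference features of the parent pCRISPR-like plasmid plus the
    selection cassette swapped into integrated spacers."""

    model: CrisprArrayModel
    cassette: str
    primer_anchor_nt: int = PRIMER_ANCHOR_NT

    def features(self) -> pd.DataFrame:
        """Interval table (0-based half-open) of the parent plasmid."""
        rows, pos = [], 0

        def add(label: str, seq: str) -> None:
            nonlocal pos
            if seq:
                rows.append(dict(label=label, start=pos, end=pos + len(seq)))
                pos += len(seq)

        add("upstream_flank", self.model.upstream_flank)
        add("leader", self.model.leader)
        add("repeat_1", self.model.repeat)
        for i, s in enumerate(self.model.spacers, 1):
            add(f"spacer_{i}", s)
            add(f"repeat_{i + 1}", self.model.repeat)
        add("downstream_flank", self.model.downstream_flank)
        return pd.DataFrame(rows)


@dataclass
class CompositeRead:
    """Merged, anchored read pair for one colony."""

    colony_id: str
    sequence: str            # fwd + sentinel + revcomp(rev)
    fwd_anchor_found: bool
    rev_anchor_found: bool
    left_context: str        # cassette-forward frame, ends at 5' junction
    right_context: str       # cassette-forward frame, starts at 3' junction
    mean_quality_fwd: float
    mean_quality_rev: float

    @property
    def low_quality(self) -> bool:
        return (self.mean_quality_fwd < LOW_QUALITY_MEAN_PHRED
                or self.mean_quality_rev < LOW_QUALITY_MEAN_PHRED)

    @property
    def interpretable(self) -> bool:
        return self.fwd_anchor_found and self.rev_anchor_found


@dataclass
class IntegrationEvent:
    colony_id: str
    site_class: str | None = None            # repeat_edge | ectopic
    repeat_index_from_leader: int | None = None
    leader_proximal: bool = False
    orientation: str | None = None           # forward | reverse
    spacer_length: int = 0
    flanking_spacers_consecutive: bool = True
    prespacer_ends_intact: bool = True
    excluded: bool = False
    exclusion_reason: str | None = None
    notes: list[str] = field(default_factory=list)


def merge_colony_reads(pair: ColonyReadPair, db: PlasmidFeatureDb,
                       anchor_max_mismatches: int = 2) -> CompositeRead:
    """Merge one colony's outward reads and anchor them to the cassette.

    The forward read begins with the reverse complement of the
    cassette's first ``primer_anchor_nt`` bases, the reverse read with
    its last; anchors are matched with a small mismatch budget.
    """
    off = db.primer_anchor_nt
    fa = revcomp(db.cassette[:off])
    ra = db.cassette[-off:]

    def anchored(read: str, anchor: str) -> bool:
        return (len(read) >= len(anchor)
                and hamming(read[:len(anchor)], anchor) <= anchor_max_mismatches)

    fwd_ok = anchored(pair.fwd_read, fa)
    rev_ok = anchored(pair.rev_read, ra)
    mq_f = sum(pair.fwd_quality) / max(1, len(pair.fwd_quality))
    mq_r = sum(pair.rev_quality) / max(1, len(pair.rev_quality))
    return CompositeRead(
        colony_id=pair.colony_id,
        sequence=pair.fwd_read + GAP_SENTINEL + revcomp(pair.rev_read),
        fwd_anchor_found=fwd_ok, rev_anchor_found=rev_ok,
        left_context=revcomp(pair.fwd_read[off:]) if fwd_ok else "",
        right_context=pair.rev_read[off:] if rev_ok else "",
        mean_quality_fwd=mq_f, mean_quality_rev=mq_r)


def _suffix_match_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y:
            break
        n += 1
    return n


def _prefix_match_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _best_junction(context: str, arm_match: int, edge: str, side: str,
                   slack: int = JUNCTION_SLACK_NT,
                   giveback: int = ARM_GIVEBACK_NT) -> tuple[int, int] | None:
    """Jointly refine the arm length and locate the repeat edge.

    ``arm_match`` is the greedy arm match length, which can chance-extend
    into the repeat; candidate arm lengths L' from arm_match down to
    arm_match-giveback are tried and the candidate whose repeat edge sits
    at the smallest junction offset wins (ties favour the longer arm).
    Returns ``(arm_length, offset)`` or None if no repeat edge is found
    within ``slack`` stray bases on this side.
    """
    best: tuple[int, int] | None = None
    for arm in range(arm_match, max(-1, arm_match - giveback - 1), -1):
        if side == "left":
            beyond = context[:len(context) - arm]
            for o in range(slack + 1):
                lo = len(beyond) - o - len(edge)
                if lo < 0:
                    break
                if beyond[lo:lo + len(edge)] == edge:
                    if best is None or o < best[1]:
                        best = (arm, o)
                    break
        else:
            beyond = context[arm:]
            for o in range(slack + 1):
                if len(beyond) < o + len(edge):
                    break
                if beyond[o:o + len(edge)] == edge:
                    if best is None or o < best[1]:
                        best = (arm, o)
                    break
        if best is not None and best[1] == 0:
            break
    return best


def _identify_neighbor_left(region: str, model: CrisprArrayModel,
                            min_match: int = 12) -> int | None:
    """Which array element precedes the left repeat: 0 for leader,
    i for original spacer i; None if undecidable."""
    for idx, cand in [(0, model.leader)] + [
            (i, s) for i, s in enumerate(model.spacers, 1)]:
        k = min(len(region), len(cand))
        if k >= min_match and region[-k:] == cand[-k:]:
            return idx
    return None


def _identify_neighbor_right(region: str, model: CrisprArrayModel,
                             min_match: int = 12) -> int | None:
    """Which element follows the right repeat: i for original spacer i,
    n+1 for the downstream flank; None if undecidable."""
    cands = [(i, s) for i, s in enumerate(model.spacers, 1)]
    cands.append((len(model.spacers) + 1, model.downstream_flank))
    for idx, cand in cands:
        k = min(len(region), len(cand))
        if k >= min_match and region[:k] == cand[:k]:
            return idx
    return None


def annotate_event(composite: CompositeRead, db: PlasmidFeatureDb,
                   substrate: PrespacerSubstrate,
                   repeat_max_mismatches: int = 2) -> IntegrationEvent:
    """Classify one colony's integration event.

    Works in the cassette-forward frame: the prespacer arms always read
    as the gap-filled top strand there (the cassette travels with the
    prespacer), while the array direction in that frame gives the spacer
    orientation. Exclusion reasons follow the fixed priority
    low_quality > non_repeat_edge > nonconsecutive_flank >
    end_mutation_indel.
    """
    ev = IntegrationEvent(colony_id=composite.colony_id)
    model, repeat = db.model, db.model.repeat

    def exclude(reason: str) -> IntegrationEvent:
        ev.excluded, ev.exclusion_reason = True, reason
        return ev

    if not composite.interpretable:
        ev.notes.append("cassette anchor not found")
        return exclude("low_quality")

    ft = substrate.filled_top()
    cs, ce = substrate.filled_cassette_interval()
    exp_left, exp_right = ft[:cs], ft[ce:]
    j1, j2 = composite.left_context, composite.right_context
    l_greedy = _suffix_match_len(j1, exp_left)
    r_greedy = _prefix_match_len(j2, exp_right)

    # array direction in the cassette-forward frame decides orientation
    candidates = {}
    for direction in ("forward", "reverse"):
        if direction == "forward":
            l_edge, r_edge = repeat[-EDGE_WINDOW_NT:], repeat[:EDGE_WINDOW_NT]
        else:
            l_edge = revcomp(repeat[:EDGE_WINDOW_NT])
            r_edge = revcomp(repeat[-EDGE_WINDOW_NT:])
        lt = _best_junction(j1, l_greedy, l_edge, "left")
        rt = _best_junction(j2, r_greedy, r_edge, "right")
        if lt is not None and rt is not None:
            candidates[direction] = (lt, rt)
    if not candidates:
        ev.site_class = "ectopic"
        low = composite.low_quality
        return exclude("low_quality" if low else "non_repeat_edge")
    direction = min(candidates, key=lambda d: candidates[d][0][1]
                    + candidates[d][1][1])
    (arm_l, off_l), (arm_r, off_r) = candidates[direction]

    ev.site_class = "repeat_edge"
    ev.orientation = direction
    ev.spacer_length = arm_l + BBSI_CASSETTE_BP + arm_r
    ev.prespacer_ends_intact = (off_l == 0 and off_r == 0
                                and arm_l <= len(exp_left)
                                and arm_r <= len(exp_right))

    # normalise to the plasmid-forward frame for neighbour identification
    if direction == "forward":
        p_left, p_right = j1, j2
        a_l, o_l, a_r, o_r = arm_l, off_l, arm_r, off_r
    else:
        p_left, p_right = revcomp(j2), revcomp(j1)
        a_l, o_l, a_r, o_r = arm_r, off_r, arm_l, off_l

    rlen = len(repeat)
    lrep_end = len(p_left) - a_l - o_l
    rrep_start = a_r + o_r
    left_idx = right_idx = None
    if lrep_end - rlen >= 0:
        if hamming(p_left[lrep_end - rlen:lrep_end], repeat) <= repeat_max_mismatches:
            left_idx = _identify_neighbor_left(p_left[:lrep_end - rlen], model)
        else:
            ev.notes.append("left repeat copy degenerate")
    if len(p_right) >= rrep_start + rlen:
        if hamming(p_right[rrep_start:rrep_start + rlen],
                   repeat) <= repeat_max_mismatches:
            right_idx = _identify_neighbor_right(p_right[rrep_start + rlen:], model)
        else:
            ev.notes.append("right repeat copy degenerate")

    if left_idx is not None:
        ev.repeat_index_from_leader = left_idx + 1
        ev.leader_proximal = left_idx == 0
    if left_idx is not None and right_idx is not None:
        ev.flanking_spacers_consecutive = (right_idx == left_idx + 1)

    if composite.low_quality:
        return exclude("low_quality")
    if not ev.flanking_spacers_consecutive:
        return exclude("nonconsecutive_flank")
    if not ev.prespacer_ends_intact:
        return exclude("end_mutation_indel")
    return ev


def annotate_colonies(pairs: list[ColonyReadPair], db: PlasmidFeatureDb,
                      substrate: PrespacerSubstrate,
                      **kwargs) -> list[IntegrationEvent]:
    return [annotate_event(merge_colony_reads(p, db), db, substrate, **kwargs)
            for p in pairs]


def events_table(events: list[IntegrationEvent]) -> pd.DataFrame:
    rows = [dict(colony_id=e.colony_id, site_class=e.site_class or ".",
                 repeat_index=e.repeat_index_from_leader
                 if e.repeat_index_from_leader is not None else -1,
                 leader_proximal=e.leader_proximal,
                 orientation=e.orientation or ".",
                 spacer_length=e.spacer_length,
                 flank_consecutive=e.flanking_spacers_consecutive,
                 ends_intact=e.prespacer_ends_intact,
                 excluded=e.excluded,
                 exclusion_reason=e.exclusion_reason or ".")
            for e in events]
    return pd.DataFrame(rows)


def summarize_events(events: list[IntegrationEvent]) -> dict:
    """Cohort summary over kept events plus the exclusion tally."""
    if not events:
        raise ValueError("no events to summarise")
    kept = [e for e in events if not e.excluded]
    hist = Counter(e.spacer_length for e in kept)
    n_kept = len(kept)
    return dict(
        n_events=len(events),
        n_kept=n_kept,
        spacer_length_histogram={int(k): int(v) for k, v in sorted(hist.items())},
        percent_forward=(100.0 * sum(e.orientation == "forward" for e in kept)
                         / n_kept) if n_kept else 0.0,
        percent_leader_proximal=(100.0 * sum(e.leader_proximal for e in kept)
                                 / n_kept) if n_kept else 0.0,
        exclusions={r: sum(e.exclusion_reason == r for e in events)
                    for r in EXCLUSION_PRIORITY},
    )
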