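"""Demultiplexing and spacer extraction from barcoded amplicon reads.

Reads carry [5-nt random tag][3-5 bp sample barcode][constant anchor +
locus]. Demultiplexing is exact-prefix assignment against a prefix-free
barcode table; the random tag is recorded for PCR-duplicate collapsing
later. Spacer calling scans the locus portion for repeat copies (with a
configurable per-repeat mismatch budget) and, when the array is
expanded, reports the sequence between the leader-proximal repeat and
the next repeat as the newly acquired spacer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dna import scan_approx
from .io import Read
from .models import BarcodeSpec, CrisprArrayModel, check_prefix_free

MIN_CALLABLE_LENGTH = 15  # shortest spacer worth calling, bp


@dataclass(frozen=True)
class DemuxedRead:
    sample_id: str
    umi: str
    payload: str  # anchor + locus portion (everything after the barcode)
    read_id: str


@dataclass(frozen=True)
class SpacerCall:
    sample_id: str
    spacer_sequence: str
    length: int
    umi: str
    source_read_id: str
    multi_acquisition: bool = False  # more than one new spacer in the array


def demultiplex(reads: list[Read], barcodes: list[BarcodeSpec],
                min_locus_nt: int = 56,
                ) -> tuple[list[DemuxedRead], pd.DataFrame]:
    """Assign reads to samples by exact barcode match at positions 5..5+len.

    ``min_locus_nt`` is the shortest payload considered analysable
    (roughly repeat + 20 nt); shorter reads are rejected as too_short.
    Returns ``(assigned, rejected_log)`` where the log has columns
    read_id, reason.
    """
    check_prefix_free(barcodes)
    umi_len = barcodes[0].umi_length
    by_prefix = {b.barcode: b for b in barcodes}
    lengths = sorted({len(b.barcode) for b in barcodes})
    assigned: list[DemuxedRead] = []
    rejected = []
    for r in reads:
        if len(r.sequence) < umi_len + lengths[0] + min_locus_nt:
            rejected.append((r.id, "too_short"))
            continue
        umi = r.sequence[:umi_len]
        hit = None
        for L in lengths:  # prefix-free: at most one length can match
            hit = by_prefix.get(r.sequence[umi_len:umi_len + L])
            if hit is not None:
                break
        if hit is None:
            rejected.append((r.id, "unknown_barcode"))
            continue
        payload = r.sequence[umi_len + len(hit.barcode):]
        assigned.append(DemuxedRead(hit.sample_id, umi, payload, r.id))
    return assigned, pd.DataFrame(rejected, columns=["read_id", "reason"])


def find_repeats(payload: str, repeat: str, max_mismatches: int = 2) -> list[int]:
    """Start offsets of non-overlapping repeat copies in the payload,
    left to right, each within ``max_mismatches`` of the model repeat."""
    hits = scan_approx(payload, repeat, max_mismatches)
    chosen: list[int] = []
    for h in hits:
        if not chosen or h >= chosen[-1] + len(repeat):
            chosen.append(h)
    return chosen


def call_expanded_array(read: DemuxedRead, model: CrisprArrayModel,
                        max_repeat_mismatches: int = 2,
                        min_length: int = MIN_CALLABLE_LENGTH,
                        ) -> SpacerCall | None:
    """Extract the newly acquired spacer from one demultiplexed read.

    Returns a :class:`SpacerCall`, ``None`` for an unexpanded parent
    array, and raises :class:`MalformedReadError` when no repeat copy is
    found at all.
    """
    starts = find_repeats(read.payload, model.repeat, max_repeat_mismatches)
    if not starts:
        raise MalformedReadError(read.read_id)
    if len(starts) < 2:
        return None  # parent single-repeat array, no expansion
    rlen = len(model.repeat)
    spacer = read.payload[starts[0] + rlen:starts[1]]
    if model.spacers and spacer == model.spacers[0]:
        return None  # the original array, not an expansion
    if len(spacer) < min_length:
        return None
    # expanded array: at error-free baseline it holds one extra repeat;
    # >= 3 repeats with pre-existing spacers may mean double acquisition
    expected = model.n_repeats + 1
    multi = len(starts) > expected or (not model.spacers and len(starts) > 2)
    return SpacerCall(sample_id=read.sample_id, spacer_sequence=spacer,
                      length=len(spacer), umi=read.umi,
                      source_read_id=read.read_id, multi_acquisition=multi)


class MalformedReadError(ValueError):
    """Payload contains no recognisable repeat copy."""


def call_all(reads: list[DemuxedRead], model: CrisprArrayModel,
             max_repeat_mismatches: int = 2,
             min_length: int = MIN_CALLABLE_LENGTH,
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`call_expanded_array` over a read set.

    Returns ``(calls, log)``: calls as a table (sample_id, umi, sequence,
    length, read_id, multi_acquisition); log of reads yielding no call
    (read_id, reason in {no_repeat, no_expansion}).
    """
    rows, log = [], []
    for r in reads:
        try:
            call = call_expanded_array(r, model, max_repeat_mismatches, min_length)
        except MalformedReadError:
            log.append((r.read_id, "no_repeat"))
            continue
        if call is None:
            log.append((r.read_id, "no_expansion"))
        else:
            rows.append(dict(sample_id=call.sample_id, umi=call.umi,
                             sequence=call.spacer_sequence, length=call.length,
                             read_id=call.source_read_id,
                             multi_acquisition=call.multi_acquisition))
    return (pd.DataFrame(rows, columns=["sample_id", "umi", "sequence", "length",
                                        "read_id", "multi_acquisition"]),
            pd.DataFrame(log, columns=["read_id", "reason"]))
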