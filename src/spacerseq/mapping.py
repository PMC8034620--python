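"""Perfect-match protospacer mapping and PAM classification.

Spacers are mapped by exact substring search against both strands of
the phage genome — mismatch-tolerant alignment is deliberately absent,
since only perfectly matching spacers count as phage-derived. A unique
hit yields a forward-coordinate interval, a strand, and the PAM: the
three nucleotides immediately 3' of the protospacer on the match
strand, valid when they fit NGG (SpyCas9).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dna import revcomp, validate_dna
from .models import Genome

MIN_MAPPABLE_LENGTH = 15  # below this, random 50-kb genomes start multi-hitting


@dataclass(frozen=True)
class MappingResult:
    spacer: str
    hit_count: int
    interval: tuple[int, int] | None  # forward-coordinate, 0-based half-open
    strand: str | None                # '+' or '-'
    pam: str | None                   # 3 nt, 3' of the match on the match strand
    pam_valid: bool
    ambiguous: bool                   # >1 perfect hit; no unique interval

    @property
    def mapped(self) -> bool:
        return self.hit_count == 1


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_spacer(spacer: str, genome: Genome, circular: bool = False) -> MappingResult:
    """Map one spacer against both strands of the genome.

    With ``circular`` the genome is treated as circularly permuted and
    matches may wrap the origin (reported start is still < genome length).
    """
    validate_dna(spacer, "spacer")
    if len(spacer) < MIN_MAPPABLE_LENGTH:
        raise ValueError(f"spacer shorter than {MIN_MAPPABLE_LENGTH} nt")
    seq = genome.sequence
    n = len(seq)
    search = seq + seq[:len(spacer) - 1] if circular else seq
    rc = revcomp(spacer)
    hits = [(i % n, "+") for i in _find_all(search, spacer)]
    hits += [(i % n, "-") for i in _find_all(search, rc)]
    hits = sorted(set(hits))
    if len(hits) != 1:
        return MappingResult(spacer, len(hits), None, None, None, False,
                             ambiguous=len(hits) > 1)
    start, strand = hits[0]
    end = start + len(spacer)
    pam, valid = classify_pam((start, end), strand, genome, circular)
    return MappingResult(spacer, 1, (start, end), strand, pam, valid, False)


def classify_pam(interval: tuple[int, int], strand: str, genome: Genome,
                 circular: bool = False) -> tuple[str | None, bool]:
    """PAM for a unique hit: the 3 nt immediately 3' of the protospacer on
    the match strand. Returns ``(pam, pam_valid)``; a match abutting the
    genome end with <3 nt of flank gives ``(None, False)``."""
    seq = genome.sequence
    n = len(seq)
    start, end = interval
    if strand == "+":
        if circular:
            pam = (seq + seq[:3])[end % n:end % n + 3]
        else:
            if end + 3 > n:
                return None, False
            pam = seq[end:end + 3]
    else:
        if circular:
            ext = seq[-3:] + seq
            pam = revcomp(ext[start:start + 3])
        else:
            if start - 3 < 0:
                return None, False
            pam = revcomp(seq[start - 3:start])
    return pam, pam[1:3] == "GG"


def map_all(spacers: list[str], genome: Genome,
            circular: bool = False) -> pd.DataFrame:
    """Map each unique spacer once and tabulate the results."""
    rows = []
    cache: dict[str, MappingResult] = {}
    for s in spacers:
        res = cache.get(s)
        if res is None:
            res = cache[s] = map_spacer(s, genome, circular)
        rows.append(dict(
            spacer=s, hit_count=res.hit_count,
            start=res.interval[0] if res.interval else -1,
            end=res.interval[1] if res.interval else -1,
            strand=res.strand or ".", pam=res.pam or ".",
            pam_valid=res.pam_valid, ambiguous=res.ambiguous))
    return pd.DataFrame(rows, columns=["spacer", "hit_count", "start", "end",
                                       "strand", "pam", "pam_valid", "ambiguous"])
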