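"""Domain types for type II-A CRISPR spacer-acquisition sequencing.

The central objects are:

* :class:`Genome` — the phage genome spacers are mapped against.
* :class:`CrisprArrayModel` — leader / repeat / spacer architecture of the
  parent plasmid; the reference both for detecting expanded arrays in
  amplicon reads and for annotating integration products.
* :class:`BarcodeSpec` — per-sample 3–5 bp barcode plus the 5-nt random tag
  (UMI) used to collapse PCR duplicates.
* :class:`PrespacerSubstrate` — a duplex with 3' single-stranded overhangs,
  optionally carrying the central inverted-BbsI cassette used to select
  full-site integration products.

All types are plain dataclasses with JSON round-trip helpers so pipeline
stages can exchange them as files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .dna import revcomp, validate_dna

BBSI_SITE = "GAAGAC"  # BbsI recognition sequence, 5'->3'
BBSI_SPACER_NT = 2    # nt between recognition site and top-strand cut
BBSI_OVERHANG_NT = 4  # BbsI leaves 4-nt overhangs
# one outward-facing half-site: 4 (overhang) + 2 (spacer) + 6 (recognition)
BBSI_HALF_BP = BBSI_OVERHANG_NT + BBSI_SPACER_NT + len(BBSI_SITE)
BBSI_CASSETTE_BP = 2 * BBSI_HALF_BP  # the printed central 24 bp


@dataclass(frozen=True)
class Genome:
    """A linear (optionally circularly permuted) DNA reference."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        validate_dna(self.sequence, "genome sequence")
        if len(self.sequence) < 100:
            raise ValueError("genome length must be >= 100")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CrisprArrayModel:
    """Leader/repeat/spacer architecture of the parent CRISPR plasmid.

    The array reads, from the leader: leader, then repeat, then
    (spacer_i, repeat) for each pre-existing spacer. A "single repeat"
    parent has ``spacers = []``. Spacers are indexed 1..n from the leader.
    """

    leader: str
    repeat: str
    spacers: tuple[str, ...] = ()
    upstream_flank: str = ""
    downstream_flank: str = ""

    def __post_init__(self) -> None:
        validate_dna(self.leader, "leader")
        validate_dna(self.repeat, "repeat")
        for i, s in enumerate(self.spacers, 1):
            validate_dna(s, f"spacer {i}")
        if len(set(self.spacers)) != len(self.spacers):
            raise ValueError("pre-existing spacers must be pairwise distinct")

    @property
    def n_repeats(self) -> int:
        return len(self.spacers) + 1

    def array_sequence(self) -> str:
        """leader + R + (S_i + R)* — no flanks."""
        parts = [self.leader, self.repeat]
        for s in self.spacers:
            parts += [s, self.repeat]
        return "".join(parts)

    def locus_sequence(self) -> str:
        return self.upstream_flank + self.array_sequence() + self.downstream_flank

    def expanded_locus(self, new_spacer: str, edge_index: int = 1) -> str:
        """Locus after full-site integration of ``new_spacer`` at the
        leader-side edge of repeat ``edge_index`` (1 = leader-proximal).
        Integration duplicates the repeat: ... R new R S_k ..."""
        if not 1 <= edge_index <= self.n_repeats:
            raise ValueError(f"edge_index must be in 1..{self.n_repeats}")
        parts = [self.upstream_flank, self.leader]
        for k in range(1, self.n_repeats + 1):
            if k == edge_index:
                parts += [self.repeat, new_spacer]
            parts.append(self.repeat)
            if k <= len(self.spacers):
                parts.append(self.spacers[k - 1])
        parts.append(self.downstream_flank)
        return "".join(parts)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CrisprArrayModel":
        d = json.loads(Path(path).read_text())
        d["spacers"] = tuple(d.get("spacers", ()))
        return cls(**d)


@dataclass(frozen=True)
class BarcodeSpec:
    """One sample's demultiplexing barcode. The read layout is
    [5-nt random tag][barcode][constant anchor][locus]."""

    sample_id: str
    barcode: str
    umi_length: int = 5

    def __post_init__(self) -> None:
        validate_dna(self.barcode, "barcode")
        if not 3 <= len(self.barcode) <= 5:
            raise ValueError("barcode length must be 3-5 bp")
        if self.umi_length != 5:
            raise ValueError("the random tag is 5 nt by design")


def check_prefix_free(barcodes: list[BarcodeSpec]) -> None:
    """Barcodes of different lengths are legal only if no barcode is a
    prefix of another; otherwise assignment would be ambiguous."""
    seqs = [b.barcode for b in barcodes]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate barcodes in table")
    for a in seqs:
        for b in seqs:
            if a != b and b.startswith(a):
                raise ValueError(f"barcode table not prefix-free: {a!r} prefixes {b!r}")


@dataclass(frozen=True)
class PrespacerSubstrate:
    """A prespacer duplex with 3' single-stranded overhangs.

    ``top_strand`` and ``bottom_strand`` are both written 5'->3'. The
    first ``duplex_length`` bases of the bottom strand reverse-complement
    the last ``duplex_length`` bases of... more precisely: the duplex
    region of the top strand is ``top_strand[:duplex_length]`` and
    ``bottom_strand[:duplex_length] == revcomp(top_strand[:duplex_length])``.
    A 3' overhang on the top strand protrudes on the right of the duplex;
    a 3' overhang on the bottom strand protrudes on the left.
    """

    top_strand: str
    bottom_strand: str
    duplex_length: int
    overhang_3p_left: int
    overhang_3p_right: int
    has_pam: bool = False
    bbsi_cassette_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        validate_dna(self.top_strand, "top strand")
        validate_dna(self.bottom_strand, "bottom strand")
        d = self.duplex_length
        if len(self.top_strand) != d + self.overhang_3p_right:
            raise ValueError("top strand length != duplex + right overhang")
        if len(self.bottom_strand) != d + self.overhang_3p_left:
            raise ValueError("bottom strand length != duplex + left overhang")
        if self.bottom_strand[:d] != revcomp(self.top_strand[:d]):
            raise ValueError("strands do not anneal over the duplex region")
        if self.bbsi_cassette_interval is not None:
            s, e = self.bbsi_cassette_interval
            if e - s != BBSI_CASSETTE_BP or s < 0 or e > d:
                raise ValueError("BbsI cassette must span 24 bp inside the duplex")

    @property
    def total_span(self) -> int:
        """End-to-end length in bp: left overhang + duplex + right overhang."""
        return self.overhang_3p_left + self.duplex_length + self.overhang_3p_right

    def filled_top(self) -> str:
        """Top-strand sequence after gap-filling: the left 3' overhang of the
        bottom strand is copied into the top strand, so the filled molecule
        is fully double-stranded over total_span."""
        left = revcomp(self.bottom_strand[self.duplex_length:])
        return left + self.top_strand

    def filled_cassette_interval(self) -> tuple[int, int]:
        """BbsI cassette interval on the gap-filled top strand."""
        if self.bbsi_cassette_interval is None:
            raise ValueError("substrate has no BbsI cassette")
        s, e = self.bbsi_cassette_interval
        return s + self.overhang_3p_left, e + self.overhang_3p_left

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrespacerSubstrate":
        d = json.loads(Path(path).read_text())
        if d.get("bbsi_cassette_interval") is not None:
            d["bbsi_cassette_interval"] = tuple(d["bbsi_cassette_interval"])
        return cls(**d)


@dataclass
class TrimProductSet:
    """Output of the stochastic trimming simulator."""

    substrate: PrespacerSubstrate
    product_lengths: list[int]
    fraction_processed: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_processed <= 1.0:
            raise ValueError("fraction_processed must be in [0, 1]")
        if any(l > self.substrate.total_span for l in self.product_lengths):
            raise ValueError("product length exceeds input length")

    def modal_length(self) -> int:
        from collections import Counter
        return Counter(self.product_lengths).most_common(1)[0][0]


@dataclass(frozen=True)
class ColonyReadPair:
    """Paired outward-facing Sanger-like reads from one colony.

    Both reads start at primer sites inside the selection cassette and
    extend outward toward the flanking CRISPR array. ``truth_label``
    carries the simulator's ground truth and is never read by the
    annotator.
    """

    colony_id: str
    fwd_read: str
    rev_read: str
    fwd_quality: tuple[int, ...]
    rev_quality: tuple[int, ...]
    truth_label: dict | None = None
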