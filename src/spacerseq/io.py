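"""FASTQ/FASTA/TSV plumbing, via Biopython and pandas."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Genome


@dataclass
class Read:
    """One sequencing read: id, bases, per-base Phred qualities."""

    id: str
    sequence: str
    quality: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.quality:
            self.quality = (40,) * len(self.sequence)
        if len(self.quality) != len(self.sequence):
            raise ValueError("quality length != sequence length")

    @property
    def mean_quality(self) -> float:
        return sum(self.quality) / len(self.quality) if self.quality else 0.0


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(rec.id, str(rec.seq),
                   tuple(rec.letter_annotations["phred_quality"]))


def write_fasta(genome: Genome, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta")


def read_fasta(path: str | Path) -> Genome:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return Genome(id=rec.id, sequence=str(rec.seq).upper())


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
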