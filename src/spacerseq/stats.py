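"""PCR-bias normalization, spacer-length distributions and kinetics fits.

Normalization uses the 5-nt random tag as a unique molecular identifier:
reads sharing (sample, spacer, tag) are PCR duplicates of one acquisition
event, so the normalized abundance of a spacer is its number of distinct
tags. Length distributions follow the unique-sequence convention: every
unique spacer sequence contributes once, regardless of abundance, and
counts are expressed as percentages of all unique spacers in the sample.

Processing kinetics (fraction processed vs time, one series per
replicate) are summarised by ordinary least-squares slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def normalize_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse spacer calls to one row per (sample_id, sequence).

    Input columns: sample_id, umi, sequence, length (as produced by the
    caller). Output: sample_id, sequence, length, raw_reads,
    distinct_umis — ``distinct_umis`` is the PCR-bias-normalized
    abundance.
    """
    if calls.empty:
        return pd.DataFrame(columns=["sample_id", "sequence", "length",
                                     "raw_reads", "distinct_umis"])
    g = calls.groupby(["sample_id", "sequence"], sort=True)
    out = g.agg(length=("length", "first"),
                raw_reads=("umi", "size"),
                distinct_umis=("umi", "nunique")).reset_index()
    return out


def expected_umi_collisions(n_events: int, umi_length: int = 5) -> float:
    """Birthday-bound expectation of tag collisions among ``n_events``
    events sharing one spacer: n - M(1 - (1-1/M)^n), M = 4^umi_length."""
    m = 4 ** umi_length
    return n_events - m * (1.0 - (1.0 - 1.0 / m) ** n_events)


@dataclass(frozen=True)
class LengthDistribution:
    sample_id: str
    percent_by_length: dict[int, float]  # length (bp) -> % of unique spacers
    n_unique: int

    def __post_init__(self) -> None:
        if self.percent_by_length:
            total = sum(self.percent_by_length.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"percents sum to {total}, not 100")


def length_distribution(table: pd.DataFrame, sample_id: str | None = None,
                        abundance_weighted: bool = False) -> LengthDistribution:
    """Spacer-length distribution as percent of unique spacer sequences.

    ``table`` is the normalize_counts output (optionally pre-filtered to
    mapped spacers). With ``abundance_weighted`` each sequence is weighted
    by its distinct-tag count instead of counting once.
    """
    t = table if sample_id is None else table[table["sample_id"] == sample_id]
    if t.empty:
        return LengthDistribution(sample_id or "all", {}, 0)
    w = t["distinct_umis"] if abundance_weighted else pd.Series(1.0, index=t.index)
    totals = w.groupby(t["length"]).sum()
    denom = float(totals.sum())
    pct = {int(l): 100.0 * v / denom for l, v in totals.items()}
    return LengthDistribution(sample_id or "all", pct, int(len(t)))


def summarize_mapping(mapping: pd.DataFrame) -> dict:
    """Aggregate a mapping table: unique-mapping rate, PAM validity and
    strand balance (ambiguous multi-hit spacers are excluded from the
    PAM/strand figures)."""
    if mapping.empty:
        return dict(n_spacers=0, percent_unique=0.0, percent_pam_valid=0.0,
                    percent_forward_strand=0.0, n_ambiguous=0, n_unmapped=0)
    uniq = mapping[mapping["hit_count"] == 1]
    n = len(mapping)
    n_uniq = len(uniq)
    return dict(
        n_spacers=int(n),
        percent_unique=100.0 * n_uniq / n,
        percent_pam_valid=(100.0 * uniq["pam_valid"].mean()) if n_uniq else 0.0,
        percent_forward_strand=(100.0 * (uniq["strand"] == "+").mean())
        if n_uniq else 0.0,
        n_ambiguous=int(mapping["ambiguous"].sum()),
        n_unmapped=int((mapping["hit_count"] == 0).sum()),
    )


@dataclass(frozen=True)
class KineticsSeries:
    """Fraction processed over time, replicate-wise."""

    timepoints: tuple[float, ...]                  # minutes
    fractions: tuple[tuple[float, ...], ...]       # one tuple per replicate

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        for rep in self.fractions:
            if len(rep) != len(self.timepoints):
                raise ValueError("replicate length != number of timepoints")
            if any(not 0.0 <= f <= 1.0 for f in rep):
                raise ValueError("fractions must lie in [0, 1]")


def fit_processing_rate(series: KineticsSeries) -> dict:
    """Per-replicate OLS of fraction processed vs time (min^-1 slope).

    Returns slope mean +/- SD across replicates plus per-replicate fits,
    mirroring the rate = linear-regression-slope convention.
    """
    if len(series.timepoints) < 2:
        raise ValueError("need at least two timepoints for a rate fit")
    t = np.asarray(series.timepoints, float)
    fits = []
    for rep in series.fractions:
        res = sps.linregress(t, np.asarray(rep, float))
        fits.append(dict(slope=float(res.slope), intercept=float(res.intercept),
                         r_value=float(res.rvalue) if not math.isnan(res.rvalue)
                         else 0.0))
    slopes = np.array([f["slope"] for f in fits])
    return dict(slope_mean=float(slopes.mean()),
                slope_sd=float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0,
                intercept_mean=float(np.mean([f["intercept"] for f in fits])),
                replicates=fits)


def plot_length_distribution(dist: LengthDistribution, path) -> None:
    """Bar plot of the length distribution (percent of unique spacers)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lengths = sorted(dist.percent_by_length)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(lengths, [dist.percent_by_length[l] for l in lengths], color="0.3")
    ax.set_xlabel("spacer length (bp)")
    ax.set_ylabel("% of unique spacers")
    ax.set_title(f"{dist.sample_id} (n={dist.n_unique})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
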