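"""Per-genome summaries and repeat-class statistics.

Bacterial tandem repeats fall into a small number of length classes:
units of 20-21 nt, units of 51-53 nt (the constant-length "52 nt" class),
and units whose length is a multiple of three (potentially coding for
amino-acid repeats).  This module bins detected repeats into the classes
{10-19, 20-21, 22-50, 51-53, >53}, builds the standard histograms (repeat
length with all periods over 60 pooled at 61; genomes per total-repeat
count in bins of 10) and assigns each genome a coarse repeat-profile
label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import pandas as pd

from .detect import TandemRepeat
from .io_formats import Genome, gc_percent

__all__ = [
    "BINS",
    "SummaryRow",
    "classify_period",
    "genome_summary",
    "period_histogram",
    "genome_count_histogram",
    "repeat_profile",
    "summary_table",
]

BINS = ("10-19", "20-21", "22-50", "51-53", ">53")

PROFILE_LABELS = ("rich_52", "rich_21", "intermediate", "cereus_coding", "poor")


@dataclass
class SummaryRow:
    genome_id: str
    genome_size_mb: float
    gc_percent: float
    total: int
    class_counts: Dict[str, int]
    mod3_count: int


def classify_period(period_nt: int) -> tuple:
    """Length-class bin and multiple-of-three flag for a repeat period."""
    if period_nt < 10:
        raise ValueError("period_nt must be >= 10")
    if period_nt <= 19:
        b = "10-19"
    elif period_nt <= 21:
        b = "20-21"
    elif period_nt <= 50:
        b = "22-50"
    elif period_nt <= 53:
        b = "51-53"
    else:
        b = ">53"
    return b, period_nt % 3 == 0


def genome_summary(genome: Genome, trs: Sequence[TandemRepeat]) -> SummaryRow:
    """One summary row per genome: size, GC%, total and per-class counts."""
    counts = {b: 0 for b in BINS}
    mod3 = 0
    for tr in trs:
        b, m3 = classify_period(tr.period_nt)
        counts[b] += 1
        if m3:
            mod3 += 1
    return SummaryRow(
        genome_id=genome.id,
        genome_size_mb=round(genome.length_nt / 1e6, 2),
        gc_percent=gc_percent(genome),
        total=len(trs),
        class_counts=counts,
        mod3_count=mod3,
    )


def period_histogram(trs: Sequence[TandemRepeat]) -> Dict[int, int]:
    """Counts per repeat period, with all periods over 60 pooled at 61."""
    hist: Dict[int, int] = {}
    for tr in trs:
        p = tr.period_nt if tr.period_nt <= 60 else 61
        hist[p] = hist.get(p, 0) + 1
    return dict(sorted(hist.items()))


def genome_count_histogram(
    summaries: Sequence[SummaryRow], bin_width: int = 10
) -> Dict[int, int]:
    """Number of genomes per total-repeat-count bin.

    Bin edges are half-open: [0, bin_width), [bin_width, 2*bin_width), ...
    Keys are the bin lower edges.
    """
    hist: Dict[int, int] = {}
    for row in summaries:
        lo = (row.total // bin_width) * bin_width
        hist[lo] = hist.get(lo, 0) + 1
    return dict(sorted(hist.items()))


def repeat_profile(row: SummaryRow) -> str:
    """Coarse repeat-profile label for one genome.

    Rules (deterministic, total): ``poor`` if total <= 8; ``rich_52`` if
    at least half the repeats sit in the 51-53 bin and the 20-21 bin is
    nearly empty (< 10%); ``rich_21`` symmetrically; ``cereus_coding``
    when the 22-50 bin holds >= 40% of the repeats and a majority of all
    repeats are multiples of three; otherwise ``intermediate``.  The
    richness labels require the opposite class to be nearly absent because
    genomes carrying substantial numbers of both 20-21 and 51-53 repeats
    form their own intermediate profile.
    """
    if row.total <= 8:
        return "poor"
    f52 = row.class_counts["51-53"] / row.total
    f21 = row.class_counts["20-21"] / row.total
    f_mid = row.class_counts["22-50"] / row.total
    if f52 >= 0.5 and f21 < 0.1:
        return "rich_52"
    if f21 >= 0.5 and f52 < 0.1:
        return "rich_21"
    if f_mid >= 0.4 and row.mod3_count > row.total / 2:
        return "cereus_coding"
    return "intermediate"


def summary_table(
    genomes: Sequence[Genome], per_genome_repeats: Sequence[Sequence[TandemRepeat]]
) -> pd.DataFrame:
    """Summary rows for many genomes as a DataFrame (with profile labels)."""
    rows = []
    for g, trs in zip(genomes, per_genome_repeats):
        s = genome_summary(g, trs)
        rows.append(
            {
                "genome_id": s.genome_id,
                "genome_size_mb": s.genome_size_mb,
                "gc_percent": round(s.gc_percent, 1),
                "total": s.total,
                **{b: s.class_counts[b] for b in BINS},
                "mod3": s.mod3_count,
                "profile": repeat_profile(s),
            }
        )
    return pd.DataFrame(rows)
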