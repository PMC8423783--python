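"""Assembly size, contiguity (Nx/Lx) and completeness statistics.

Nx is defined on the filtered sequence set's own cumulative length, not on
an external genome-size estimate (no NG50 here): sequences are sorted by
decreasing length and Nx is the length at which the running sum first
reaches x% of the total; Lx is the number of sequences needed to get there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import Assembly

logger = logging.getLogger(__name__)


@dataclass
class ContiguityStats:
    n_sequences: int = 0
    cumulative_size: int = 0
    acgt_only_size: int = 0
    pct_n: float = 0.0
    longest: int = 0
    nx: dict[float, int] = field(default_factory=dict)
    lx: dict[float, int] = field(default_factory=dict)
    pct_of_estimated: float | None = None
    pct_of_estimated_acgt: float | None = None

    def as_row(self, label: str = "") -> dict:
        row = {
            "assembly": label,
            "n_sequences": self.n_sequences,
            "cumulative_size": self.cumulative_size,
            "acgt_only_size": self.acgt_only_size,
            "pct_n": self.pct_n,
            "longest": self.longest,
        }
        for frac in sorted(self.nx):
            pct = int(round(frac * 100))
            row[f"N{pct}"] = self.nx[frac]
            row[f"L{pct}"] = self.lx[frac]
        row["pct_of_estimated"] = self.pct_of_estimated
        row["pct_of_estimated_acgt"] = self.pct_of_estimated_acgt
        return row


def nx_lx(lengths: Sequence[int], fraction: float) -> tuple[int, int]:
    """(Nx, Lx) for one fraction: length at which the descending cumulative
    sum first reaches ``fraction * total``, and the sequence count used.

    Ties between equal lengths are interchangeable (the sorted order is
    used as-is).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    lengths = [int(x) for x in lengths]
    if not lengths or min(lengths) <= 0:
        raise ValueError("lengths must be a non-empty list of positive sizes")
    ordered = sorted(lengths, reverse=True)
    target = fraction * sum(ordered)
    running = 0
    for i, length in enumerate(ordered, 1):
        running += length
        if running >= target:
            return length, i
    raise AssertionError("unreachable: running sum reaches total")


def pct_n(cumulative_size: int, acgt_only_size: int) -> float:
    """% of N residues, 100*(cumulative - acgt_only)/cumulative, rounded to
    two decimals (round-half-even)."""
    if cumulative_size <= 0:
        raise ValueError("cumulative_size must be positive")
    return round(100.0 * (cumulative_size - acgt_only_size) / cumulative_size, 2)


def pct_of_estimate(size: int, estimated_genome_size: int) -> float:
    """% of the (e.g. flow-cytometry) genome-size estimate, one decimal."""
    if estimated_genome_size <= 0:
        raise ValueError("estimated_genome_size must be positive")
    return round(100.0 * size / estimated_genome_size, 1)


def size_stats(assembly: Assembly, min_length: int = 0,
               fractions: Iterable[float] = (0.5, 0.9)) -> ContiguityStats:
    """Per-assembly contiguity statistics.

    Sequences shorter than ``min_length`` are excluded before every
    statistic (assemblies are often reported on contigs above a size
    cutoff, e.g. 50 kbp).  Percent-of-estimate fields are populated only
    when the assembly carries an estimated genome size.
    """
    kept = [rec for rec in assembly if rec.length >= min_length]
    if not kept:
        logger.warning("size_stats: no sequences >= %d bp; all-zero stats", min_length)
        return ContiguityStats()
    lengths = [rec.length for rec in kept]
    cumulative = sum(lengths)
    acgt_only = cumulative - sum(rec.residues.count("N") for rec in kept)
    stats = ContiguityStats(
        n_sequences=len(kept),
        cumulative_size=cumulative,
        acgt_only_size=acgt_only,
        pct_n=pct_n(cumulative, acgt_only),
        longest=max(lengths),
    )
    for frac in fractions:
        stats.nx[frac], stats.lx[frac] = nx_lx(lengths, frac)
    if assembly.estimated_genome_size:
        stats.pct_of_estimated = pct_of_estimate(
            cumulative, assembly.estimated_genome_size)
        stats.pct_of_estimated_acgt = pct_of_estimate(
            acgt_only, assembly.estimated_genome_size)
    return stats


def fold_coverage(total_read_bases: float, genome_size: float) -> float:
    """Sequencing depth: total read bases / genome size (caller rounds)."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if total_read_bases < 0:
        raise ValueError("total_read_bases must be non-negative")
    return total_read_bases / genome_size
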