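"""Windowed repeat-density tracks and density-based centromere calls.

Repeat coverage is computed per feature class on fixed, non-overlapping
windows anchored at position 0 (100 kbp by default, the usual scale for
chromosome-level repeat landscapes).  Centromeres of monocentric plant
chromosomes are delineated operationally as the run of windows where the
combined coverage of designated centromeric families (Nanica LINE, CRM
chromovirus Gypsy, centromeric satellites, rDNA ITS classes) exceeds a
threshold, with nearby runs merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import clip, merge, union_length, window_coverage
from .model import Assembly, GenomeInterval

logger = logging.getLogger(__name__)

#: Families whose density delineates centromeric boundaries.
DEFAULT_CENTROMERE_FAMILIES = (
    "daterra-Maximus", "ITS-5S", "ITS-18S", "ITS-26S",
    "Nanica", "maca-Angela", "caturra-Reina",
)


@dataclass
class DensityTrack:
    seq_name: str
    seq_length: int
    window_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    # merged source intervals per class, kept so families can be re-combined
    # by union rather than by summing per-class fractions
    source: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return -(-self.seq_length // self.window_size)

    def window_bounds(self, w: int) -> tuple[int, int]:
        return (w * self.window_size,
                min((w + 1) * self.window_size, self.seq_length))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, vals in sorted(self.values.items()):
            for w, frac in enumerate(vals):
                rows.append({"seq": self.seq_name,
                             "window_start": w * self.window_size,
                             "class": cls, "fraction": float(frac)})
        return pd.DataFrame(rows, columns=["seq", "window_start", "class", "fraction"])


@dataclass(frozen=True)
class CentromereCall:
    seq_name: str
    interval: GenomeInterval
    mean_density: float
    families_used: tuple[str, ...]


def windowed_density(intervals: Sequence[GenomeInterval],
                     seq_lengths: Mapping[str, int],
                     window_size: int = 100_000) -> dict[str, DensityTrack]:
    """Per-sequence, per-class covered fraction on fixed windows.

    Overlapping intervals of one class are unioned before coverage; the
    last window is normalised by its true width.  Intervals exceeding the
    sequence length are clipped with a warning.
    """
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for iv in intervals:
        if iv.seq_name not in seq_lengths:
            logger.warning("windowed_density: unknown sequence %s, skipped", iv.seq_name)
            continue
        if iv.end > seq_lengths[iv.seq_name]:
            logger.warning("windowed_density: %s:%d-%d exceeds length %d, clipped",
                           iv.seq_name, iv.start, iv.end, seq_lengths[iv.seq_name])
        grouped.setdefault((iv.seq_name, iv.feature_class), []).append(iv.as_pair())
    tracks = {
        name: DensityTrack(name, length, window_size)
        for name, length in seq_lengths.items()
    }
    for (name, cls), pairs in grouped.items():
        track = tracks[name]
        merged = merge(clip(pairs, 0, track.seq_length))
        track.source[cls] = merged
        track.values[cls] = window_coverage(merged, track.seq_length, window_size)
    return tracks


def combined_density(track: DensityTrack, families: Sequence[str],
                     combine: str = "union") -> np.ndarray:
    """Per-window density of several families combined.

    ``union`` unions the families' intervals before coverage (overlap
    counted once); ``sum`` adds per-class fractions (may exceed 1).
    """
    present = [f for f in families if f in track.values]
    if combine == "union":
        pairs = [p for f in present for p in track.source.get(f, [])]
        return window_coverage(merge(pairs), track.seq_length, track.window_size)
    if combine == "sum":
        total = np.zeros(track.n_windows)
        for f in present:
            total += track.values[f]
        return total
    raise ValueError(f"combine must be 'union' or 'sum', got {combine!r}")


def call_centromeres(track: DensityTrack,
                     families: Sequence[str] = DEFAULT_CENTROMERE_FAMILIES,
                     threshold: float = 0.2,
                     merge_gap: int = 500_000,
                     pick: str = "longest",
                     combine: str = "union") -> CentromereCall | None:
    """One centromere-candidate interval per sequence, or None.

    Windows with combined family density >= threshold are kept; runs of
    kept windows separated by <= merge_gap bp are merged; the final call is
    the longest (or densest) merged run, reported as a window-aligned
    interval.  mean_density averages the above-threshold windows of the
    chosen run.
    """
    if pick not in ("longest", "densest"):
        raise ValueError(f"pick must be 'longest' or 'densest', got {pick!r}")
    present = [f for f in families if f in track.values]
    if not present:
        return None
    density = combined_density(track, families, combine=combine)
    kept = np.flatnonzero(density >= threshold)
    if kept.size == 0:
        return None
    # contiguous runs of kept windows
    runs: list[tuple[int, int]] = []
    run_start = prev = int(kept[0])
    for w in kept[1:]:
        w = int(w)
        if w == prev + 1:
            prev = w
            continue
        runs.append((run_start, prev))
        run_start = prev = w
    runs.append((run_start, prev))
    # merge runs separated by <= merge_gap bp of below-threshold windows
    merged_runs = [runs[0]]
    for start, end in runs[1:]:
        gap_bp = (start - merged_runs[-1][1] - 1) * track.window_size
        if gap_bp <= merge_gap:
            merged_runs[-1] = (merged_runs[-1][0], end)
        else:
            merged_runs.append((start, end))

    def run_mean(run: tuple[int, int]) -> float:
        idx = [w for w in range(run[0], run[1] + 1) if density[w] >= threshold]
        return float(np.mean(density[idx]))

    if pick == "longest":
        key = lambda r: (r[1] - r[0], run_mean(r), -r[0])
    else:
        key = lambda r: (run_mean(r), r[1] - r[0], -r[0])
    best = max(merged_runs, key=key)
    start_bp = best[0] * track.window_size
    end_bp = min((best[1] + 1) * track.window_size, track.seq_length)
    return CentromereCall(
        seq_name=track.seq_name,
        interval=GenomeInterval(track.seq_name, start_bp, end_bp, ".", "centromere"),
        mean_density=run_mean(best),
        families_used=tuple(present))


def call_centromeres_all(tracks: Mapping[str, DensityTrack],
                         **kwargs) -> dict[str, CentromereCall]:
    calls = {}
    for name, track in tracks.items():
        call = call_centromeres(track, **kwargs)
        if call is not None:
            calls[name] = call
    return calls


def te_class_summary(intervals: Sequence[GenomeInterval], assembly: Assembly,
                     classification: Mapping[str, str]) -> pd.DataFrame:
    """Unioned bp and % of assembly per TE class.

    ``classification`` maps repeat family -> class (e.g. a Wicker-style
    grouping); families without a mapping are tallied as "unclassified"
    with a warning.  Percentages are on the cumulative assembly size.
    """
    lengths = assembly.lengths
    by_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    unmapped: set[str] = set()
    for iv in intervals:
        cls = classification.get(iv.feature_class)
        if cls is None:
            unmapped.add(iv.feature_class)
            cls = "unclassified"
        if iv.seq_name not in lengths:
            continue
        by_class.setdefault(cls, {}).setdefault(iv.seq_name, []).append(iv.as_pair())
    if unmapped:
        logger.warning("te_class_summary: unmapped families -> unclassified: %s",
                       sorted(unmapped))
    total = assembly.cumulative_size
    rows = []
    for cls in sorted(by_class):
        bp = sum(union_length(clip(pairs, 0, lengths[name]))
                 for name, pairs in by_class[cls].items())
        rows.append({"class": cls, "bp": bp,
                     "pct_of_assembly": round(100.0 * bp / total, 1)})
    return pd.DataFrame(rows, columns=["class", "bp", "pct_of_assembly"])
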