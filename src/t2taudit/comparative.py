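"""Assembly-vs-assembly comparison: new regions and new genes.

Regions of the newer assembly larger than a size floor (100 kbp by
default) with no alignment at all to the older assembly are "new";
genes of the newer assembly overlapping no lifted old-gene alignment by
even 1 bp are "new" (bedtools-intersect ``-v`` semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .intervals import clip, merge, overlap_bp, subtract, union_length
from .model import AlignmentBlock, GenomeInterval

logger = logging.getLogger(__name__)

__all__ = ["AlignmentBlock", "NewRegion", "uncovered_regions", "region_fraction",
           "new_genes", "region_repeat_fraction"]


@dataclass(frozen=True)
class NewRegion:
    interval: GenomeInterval
    repeat_fraction: float | None = None


def uncovered_regions(seq_lengths: Mapping[str, int],
                      blocks: Sequence[AlignmentBlock],
                      min_length: int = 100_000,
                      min_identity: float | None = None) -> list[NewRegion]:
    """Complement of the alignment union, kept when >= min_length.

    "Without any alignment" is strict zero overlap with the union of all
    blocks; ``min_identity`` optionally pre-drops low-identity blocks
    before the subtraction (off by default).
    """
    covered: dict[str, list[tuple[int, int]]] = {name: [] for name in seq_lengths}
    for block in blocks:
        if min_identity is not None and block.identity is not None \
                and block.identity < min_identity:
            continue
        name = block.query.seq_name
        if name not in covered:
            logger.warning("uncovered_regions: unknown sequence %s, skipped", name)
            continue
        covered[name].append(block.query.as_pair())
    regions = []
    for name in seq_lengths:
        for start, end in subtract(seq_lengths[name],
                                   clip(covered[name], 0, seq_lengths[name])):
            if end - start >= min_length:
                regions.append(NewRegion(
                    GenomeInterval(name, start, end, ".", "new_region")))
    return regions


def region_fraction(total_new_bp: float, assembly_size: float) -> float:
    """Percent of the assembly covered by new regions."""
    if assembly_size <= 0:
        raise ValueError("assembly_size must be positive")
    return 100.0 * total_new_bp / assembly_size


def new_genes(genes: Sequence[tuple[str, GenomeInterval]],
              lifted_old_gene_alignments: Sequence[GenomeInterval]) -> list[str]:
    """Gene ids with zero overlap to any lifted old-gene alignment."""
    lifted_by_seq: dict[str, list[tuple[int, int]]] = {}
    for iv in lifted_old_gene_alignments:
        lifted_by_seq.setdefault(iv.seq_name, []).append(iv.as_pair())
    lifted_by_seq = {k: merge(v) for k, v in lifted_by_seq.items()}
    out = []
    for gene_id, iv in genes:
        pairs = lifted_by_seq.get(iv.seq_name, ())
        if not any(overlap_bp(iv.as_pair(), p) for p in pairs):
            out.append(gene_id)
    return out


def region_repeat_fraction(regions: Sequence[NewRegion],
                           repeat_annotations: Sequence[GenomeInterval]
                           ) -> list[NewRegion]:
    """Set each region's repeat_fraction = unioned repeat bp / width."""
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for iv in repeat_annotations:
        by_seq.setdefault(iv.seq_name, []).append(iv.as_pair())
    out = []
    for region in regions:
        iv = region.interval
        pairs = clip(by_seq.get(iv.seq_name, ()), iv.start, iv.end)
        out.append(replace(region, repeat_fraction=union_length(pairs) / iv.width))
    return out
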