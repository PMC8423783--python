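"""Marker-based contig anchoring: assignment, ordering, orientation, AGP.

A deliberately simple desk-scale anchoring scheme: each contig is assigned
to the chromosome holding the majority of its markers (subject to a vote
fraction and marker-count floor), ordered along the chromosome by the mean
genetic position of its supporting markers, and oriented by the sign of
the Spearman rank correlation between physical and genetic positions.
Full-scale genetic-map scaffolders implement considerably more (marker
binning, conflict resolution, iterative refinement); this module is the
pipeline's auditable stand-in for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter
from typing import Mapping, Sequence

from scipy.stats import spearmanr

from .chromosome import revcomp
from .model import Assembly, MarkerObservation, SequenceRecord

logger = logging.getLogger(__name__)

UNANCHORED = "unanchored"


@dataclass(frozen=True)
class AnchorPlacement:
    contig: str
    chromosome: str              # chromosome name or "unanchored"
    order_key: float | None      # mean genetic position of supporting markers
    orientation: str             # "+", "-" or "?"
    n_markers: int
    vote_fraction: float


@dataclass(frozen=True)
class AgpRow:
    object: str
    object_beg: int              # 1-based inclusive, AGP convention
    object_end: int
    part_number: int
    component_type: str          # "W" contig or "U" gap of unknown size
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    gap_length: int | None = None

    def as_line(self) -> str:
        if self.component_type == "W":
            tail = [self.component_id, str(self.component_beg),
                    str(self.component_end), self.orientation]
        else:
            tail = [str(self.gap_length), "scaffold", "yes", "map"]
        return "\t".join([self.object, str(self.object_beg), str(self.object_end),
                          str(self.part_number), self.component_type, *tail])


def assign_contigs(markers: Sequence[MarkerObservation],
                   min_vote: float = 0.6,
                   min_markers: int = 2) -> dict[str, AnchorPlacement]:
    """Majority-vote chromosome assignment per contig.

    A contig is anchored iff it has >= min_markers markers, a unique
    majority chromosome, and that majority's vote fraction >= min_vote;
    ties are logged as ambiguous and left unanchored.  order_key and
    orientation are filled by :func:`order_and_orient`.
    """
    by_contig: dict[str, list[MarkerObservation]] = {}
    for m in markers:
        by_contig.setdefault(m.contig, []).append(m)
    placements = {}
    for contig in sorted(by_contig):
        obs = by_contig[contig]
        votes = Counter(m.map_chromosome for m in obs)
        (top, top_n), = votes.most_common(1)
        tied = [c for c, n in votes.items() if n == top_n]
        vote_fraction = top_n / len(obs)
        if len(obs) < min_markers or vote_fraction < min_vote or len(tied) > 1:
            if len(tied) > 1 and len(obs) >= min_markers:
                logger.info("assign_contigs: %s ambiguous between %s",
                            contig, sorted(tied))
            placements[contig] = AnchorPlacement(
                contig, UNANCHORED, None, "?", len(obs), vote_fraction)
            continue
        placements[contig] = AnchorPlacement(
            contig, top, None, "?", len(obs), vote_fraction)
    return placements


def _supporting(markers: Sequence[MarkerObservation],
                placement: AnchorPlacement) -> list[MarkerObservation]:
    return [m for m in markers
            if m.contig == placement.contig
            and m.map_chromosome == placement.chromosome]


def order_and_orient(placements: Mapping[str, AnchorPlacement],
                     markers: Sequence[MarkerObservation],
                     min_orient_markers: int = 3
                     ) -> dict[str, list[AnchorPlacement]]:
    """Ordered, oriented contig lists per chromosome.

    Contigs are ordered by mean genetic position of their supporting
    markers (ties broken by contig name); orientation is the sign of the
    Spearman correlation between physical and genetic position, "?" with
    fewer than min_orient_markers markers or a zero/undefined correlation.
    """
    per_chrom: dict[str, list[AnchorPlacement]] = {}
    for placement in placements.values():
        if placement.chromosome == UNANCHORED:
            continue
        sup = _supporting(markers, placement)
        order_key = sum(m.genetic_position for m in sup) / len(sup)
        orientation = "?"
        if len(sup) >= min_orient_markers:
            phys = [m.physical_position for m in sup]
            gen = [m.genetic_position for m in sup]
            rho = spearmanr(phys, gen).statistic
            if rho == rho and rho != 0:       # not NaN, not zero
                orientation = "+" if rho > 0 else "-"
        per_chrom.setdefault(placement.chromosome, []).append(
            AnchorPlacement(placement.contig, placement.chromosome, order_key,
                            orientation, placement.n_markers,
                            placement.vote_fraction))
    for chrom in per_chrom:
        per_chrom[chrom].sort(key=lambda p: (p.order_key, p.contig))
    return dict(sorted(per_chrom.items()))


def build_agp(ordered: Mapping[str, Sequence[AnchorPlacement]],
              contig_lengths: Mapping[str, int],
              gap_size: int = 100) -> list[AgpRow]:
    """AGP v2.1 rows for ordered contigs, with unknown-length scaffold
    gaps of ``gap_size`` N between consecutive contigs."""
    rows: list[AgpRow] = []
    seen: set[str] = set()
    for chrom, contigs in ordered.items():
        pos = 0
        part = 0
        for i, placement in enumerate(contigs):
            contig = placement.contig
            if contig in seen:
                raise ValueError(f"contig {contig} appears twice in AGP")
            seen.add(contig)
            if i > 0:
                part += 1
                rows.append(AgpRow(chrom, pos + 1, pos + gap_size, part, "U",
                                   gap_length=gap_size))
                pos += gap_size
            length = contig_lengths[contig]
            part += 1
            orientation = placement.orientation if placement.orientation in "+-" else "?"
            rows.append(AgpRow(chrom, pos + 1, pos + length, part, "W",
                               component_id=contig, component_beg=1,
                               component_end=length, orientation=orientation))
            pos += length
    return rows


def write_agp(rows: Sequence[AgpRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            fh.write(row.as_line() + "\n")


def agp_to_assembly(rows: Sequence[AgpRow], contigs: Assembly,
                    label: str = "scaffolds") -> Assembly:
    """Materialise scaffold sequences from AGP rows plus component contigs.

    Unknown-orientation contigs are placed forward; U gaps become N runs.
    """
    pieces: dict[str, list[str]] = {}
    for row in rows:
        if row.component_type == "U":
            pieces.setdefault(row.object, []).append("N" * row.gap_length)
            continue
        seq = contigs[row.component_id].residues[
            row.component_beg - 1:row.component_end]
        if row.orientation == "-":
            seq = revcomp(seq)
        pieces.setdefault(row.object, []).append(seq)
    records = [SequenceRecord(name, "".join(parts))
               for name, parts in pieces.items()]
    return Assembly(records, label=label)
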