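"""Tandemly duplicated gene (TDG) clustering and contig redundancy filtering.

Gene pairs are retained from all-vs-all protein similarity when the best
e-value is below 1e-20 and the pooled aligned coverage of the *smaller*
protein exceeds 80%.  Retained pairs on the same sequence whose gene ranks
differ by at most 10 become edges; TDG clusters are the connected
components (single-linkage, so long clusters can form by chaining).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import union_length
from .model import AlignmentBlock, GenomeInterval, SimilarityHit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomeInterval
    rank: int            # start-order index of the gene on its sequence


@dataclass(frozen=True)
class TDGCluster:
    cluster_id: str
    seq_name: str
    members: tuple[str, ...]      # gene ids, sorted by rank
    span: GenomeInterval

    @property
    def n_genes(self) -> int:
        return len(self.members)


def rank_genes(genes: Iterable[tuple[str, GenomeInterval]]) -> list[GeneRecord]:
    """Assign per-sequence start-order ranks (consecutive from 0)."""
    by_seq: dict[str, list[tuple[str, GenomeInterval]]] = {}
    for gene_id, iv in genes:
        by_seq.setdefault(iv.seq_name, []).append((gene_id, iv))
    out = []
    for seq_name in sorted(by_seq):
        ordered = sorted(by_seq[seq_name], key=lambda g: (g[1].start, g[1].end, g[0]))
        out.extend(GeneRecord(gid, iv, rank) for rank, (gid, iv) in enumerate(ordered))
    return out


def filter_hits(hits: Sequence[SimilarityHit],
                protein_lengths: Mapping[str, int],
                max_evalue: float = 1e-20,
                min_small_coverage: float = 0.8,
                pool_hsps: bool = True) -> list[tuple[str, str]]:
    """Deduplicated unordered gene pairs passing the similarity filters.

    Per pair, coverage is the unioned aligned span on the shorter protein
    divided by its length, pooling every HSP of the pair (or, with
    ``pool_hsps=False``, the best single HSP); the best e-value over the
    pair's HSPs is used.  Kept iff evalue < max_evalue and coverage >
    min_small_coverage.  Self-hits and hits to unknown proteins are
    dropped (the latter with a log line).
    """
    per_pair: dict[tuple[str, str], list[SimilarityHit]] = {}
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        if hit.query_id not in protein_lengths or hit.subject_id not in protein_lengths:
            logger.warning("filter_hits: unknown protein in %s-%s, row rejected",
                           hit.query_id, hit.subject_id)
            continue
        key = (min(hit.query_id, hit.subject_id), max(hit.query_id, hit.subject_id))
        per_pair.setdefault(key, []).append(hit)
    kept = []
    for (a, b), pair_hits in per_pair.items():
        best_e = min(h.evalue for h in pair_hits)
        if not best_e < max_evalue:
            continue
        small = a if protein_lengths[a] <= protein_lengths[b] else b
        spans = []
        for h in pair_hits:
            on_query = h.query_id == small
            spans.append((h.q_start, h.q_end) if on_query else (h.s_start, h.s_end))
        if pool_hsps:
            covered = union_length(spans)
        else:
            covered = max(e - s for s, e in spans)
        if covered / protein_lengths[small] > min_small_coverage:
            kept.append((a, b))
    return sorted(kept)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def tdg_clusters(pairs: Iterable[tuple[str, str]],
                 genes: Sequence[GeneRecord],
                 max_gene_distance: int = 10,
                 strict_less: bool = False) -> list[TDGCluster]:
    """Single-linkage clusters of co-localised similar genes.

    An edge joins a retained pair iff both genes sit on the same sequence
    and their rank difference is <= max_gene_distance (or < with
    ``strict_less``).  Components with >= 2 genes become clusters;
    cluster ids are deterministic, ordered by (sequence, leftmost rank).
    """
    by_id = {g.gene_id: g for g in genes}
    uf = _UnionFind()
    for a, b in pairs:
        ga, gb = by_id.get(a), by_id.get(b)
        if ga is None or gb is None:
            logger.warning("tdg_clusters: pair (%s, %s) references unknown gene", a, b)
            continue
        if ga.interval.seq_name != gb.interval.seq_name:
            continue
        dist = abs(ga.rank - gb.rank)
        if (dist < max_gene_distance) if strict_less else (dist <= max_gene_distance):
            uf.union(a, b)
    components: dict[str, list[GeneRecord]] = {}
    for gene_id in uf.parent:
        components.setdefault(uf.find(gene_id), []).append(by_id[gene_id])
    clusters = []
    for members in components.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda g: g.rank)
        seq_name = members[0].interval.seq_name
        clusters.append((seq_name, members))
    clusters.sort(key=lambda c: (c[0], c[1][0].rank))
    out = []
    for i, (seq_name, members) in enumerate(clusters, 1):
        span = GenomeInterval(seq_name,
                              min(g.interval.start for g in members),
                              max(g.interval.end for g in members),
                              ".", "tdg_cluster")
        out.append(TDGCluster(f"TDG{i:04d}", seq_name,
                              tuple(g.gene_id for g in members), span))
    return out


def cluster_delta(count_old: int, count_new: int) -> float:
    """Percent change in cluster count between two assemblies."""
    if count_old <= 0:
        raise ValueError("count_old must be positive")
    return 100.0 * (count_new - count_old) / count_old


def containment_filter(contig_alignments: Sequence[AlignmentBlock],
                       lengths: Mapping[str, int],
                       min_contained_fraction: float = 0.95
                       ) -> tuple[list[str], dict[str, float]]:
    """Flag contigs almost entirely contained in strictly longer sequences.

    Containment is the unioned aligned bp on the contig (query side,
    counting only alignments whose target is strictly longer) divided by
    contig length.  Returns (kept contig ids, flagged id -> fraction).
    Contigs with no alignments are kept.
    """
    spans: dict[str, list[tuple[int, int]]] = {name: [] for name in lengths}
    for block in contig_alignments:
        contig = block.query.seq_name
        target = block.target.seq_name
        if contig not in lengths:
            logger.warning("containment_filter: unknown contig %s", contig)
            continue
        target_len = lengths.get(target)
        if target_len is not None and target_len <= lengths[contig]:
            continue
        spans[contig].append(block.query.as_pair())
    kept, flagged = [], {}
    for contig in lengths:
        fraction = union_length(spans[contig]) / lengths[contig]
        if fraction >= min_contained_fraction:
            flagged[contig] = fraction
        else:
            kept.append(contig)
    return kept, flagged
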