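"""Deterministic synthetic genomes with truth tables for every audit stage.

Each simulated chromosome follows the architecture of a repeat-rich plant
chromosome: a 5' telomere array (CCCTAAA orientation), a gene- and TE-
bearing arm, a centromeric block of tandem satellite arrays (optionally
including an rDNA gene/spacer cluster), a second arm, and a 3' telomere
array (TTTAGGG).  N-gaps, tandemly-duplicated-gene clusters, interspersed
TE annotations and background genes are planted at recorded positions, so
every downstream module can be tested against generator truth.

A degraded "sister" assembly (fragmented contigs with collapsed repeat
regions) plus exact truth alignments emulates comparing a long-read
assembly against an older short-read one; a simulated genetic map supports
the anchoring stage.  All outputs are byte-identical for a fixed
(config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chromosome import TELOMERE_MONOMER, revcomp, _occurrences
from .intervals import subtract
from .model import (AlignmentBlock, Assembly, GenomeInterval, MarkerObservation,
                    SequenceRecord, SimilarityHit, write_bed, write_fasta,
                    write_markers, write_similarity_hits)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationError(ValueError):
    """Raised when a configuration cannot fit its features."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TelomereSim:
    copies_range: tuple[int, int] = (30, 120)
    mutation_rate: float = 0.02          # per-copy chance of one point mutation


@dataclass
class CentromereSim:
    length_range: tuple[int, int] = (240_000, 480_000)
    monomer_lengths: dict = field(default_factory=lambda: {
        "Nanica": 190, "daterra-Maximus": 350, "maca-Angela": 280})
    chunk_range: tuple[int, int] = (20_000, 60_000)
    rdna_family: str = "ITS-5S"
    rdna_unit: int = 120                  # rDNA gene length
    rdna_spacer: int = 200
    rdna_copies: int = 150
    rdna_chromosomes: tuple[int, ...] = (0, 2)   # chromosome indices with rDNA


@dataclass
class TESim:
    families: tuple[str, ...] = ("Gypsy-Tekay", "Copia-Tnt1", "hAT-Ac", "LINE-L1")
    density: float = 0.25                 # target fraction of arm bp annotated
    length_range: tuple[int, int] = (800, 6_000)


@dataclass
class TDGSim:
    n_clusters: int = 8
    size_range: tuple[int, int] = (2, 12)
    sizes: tuple[int, ...] | None = None  # explicit sizes override the range
    gene_length: int = 1_200
    intergenic: int = 300


@dataclass
class GapSim:
    count: int = 8
    length_range: tuple[int, int] = (200, 5_000)
    sentinel_fraction: float = 0.4        # emitted as 100-N unknown-length gaps
    sentinel_length: int = 100
    in_repeat_fraction: float = 0.5       # gaps embedded inside a TE annotation


@dataclass
class DegradeSim:
    fragment_n50: int = 300_000
    collapse_fraction: float = 0.5        # of each centromere block deleted
    min_collapse_len: int = 120_000
    n_gene_region_deletions: int = 1      # TDG-cluster regions deleted entirely
    gene_region_pad: int = 150_000


@dataclass
class SimConfig:
    n_chromosomes: int = 5
    chromosome_length_range: tuple[int, int] = (1_000_000, 2_000_000)
    n_background_genes: int = 150
    telomere: TelomereSim = field(default_factory=TelomereSim)
    centromere: CentromereSim = field(default_factory=CentromereSim)
    te: TESim = field(default_factory=TESim)
    tdg: TDGSim = field(default_factory=TDGSim)
    gaps: GapSim = field(default_factory=GapSim)
    degrade: DegradeSim = field(default_factory=DegradeSim)
    seed: int = 1


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelomereTruth:
    seq_name: str
    terminus: str
    start: int
    end: int
    copies: int          # copies planted
    exact_copies: int    # exact monomer matches in the realised array


@dataclass(frozen=True)
class GapTruth:
    seq_name: str
    start: int
    end: int
    length_known: bool


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    seq_name: str
    start: int
    end: int
    strand: str
    cluster_id: str | None


@dataclass
class TruthTables:
    telomeres: list[TelomereTruth] = field(default_factory=list)
    gaps: list[GapTruth] = field(default_factory=list)
    centromeres: list[GenomeInterval] = field(default_factory=list)
    repeats: list[GenomeInterval] = field(default_factory=list)
    genes: list[GeneTruth] = field(default_factory=list)
    protein_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g in self.genes:
            if g.cluster_id is not None:
                out.setdefault(g.cluster_id, []).append(g.gene_id)
        return out


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


_SCRUB = (TELOMERE_MONOMER, revcomp(TELOMERE_MONOMER))


def _background(rng: np.random.Generator, n: int) -> str:
    """Uniform ACGT background scrubbed of accidental telomere monomers."""
    seq = _random_dna(rng, n)
    for motif in _SCRUB:
        while motif in seq:
            i = seq.index(motif)
            base = seq[i + 3]
            repl = "A" if base != "A" else "C"
            seq = seq[:i + 3] + repl + seq[i + 4:]
    return seq


def _mutate_one(rng: np.random.Generator, unit: str) -> str:
    i = int(rng.integers(0, len(unit)))
    alt = [b for b in "ACGT" if b != unit[i]]
    return unit[:i] + alt[int(rng.integers(0, 3))] + unit[i + 1:]


def _telomere_array(rng: np.random.Generator, monomer: str, copies: int,
                    mutation_rate: float) -> str:
    """Tandem monomer array with point-mutated copies.

    Mutated copies are kept >= 10 copies apart so a planted array always
    retains a detectable run (generator self-consistency: planted features
    must be recoverable by the audit at default thresholds).
    """
    parts = []
    last_mutated = -10
    for i in range(copies):
        unit = monomer
        if rng.random() < mutation_rate and i - last_mutated >= 10:
            unit = _mutate_one(rng, unit)
            last_mutated = i
        parts.append(unit)
    return "".join(parts)


def _tandem_array(monomer: str, length: int) -> str:
    reps = -(-length // len(monomer))
    return (monomer * reps)[:length]


# ---------------------------------------------------------------------------
# assembly simulation
# ---------------------------------------------------------------------------

def simulate_assembly(config: SimConfig) -> tuple[Assembly, TruthTables]:
    """Build the synthetic genome and its truth tables.

    Raises :class:`SimulationError` when the configured features cannot
    fit inside the configured chromosome lengths.
    """
    rng = np.random.default_rng(config.seed)
    cen = config.centromere
    monomers = {fam: _random_dna(rng, mlen)
                for fam, mlen in sorted(cen.monomer_lengths.items())}
    rdna_gene = _random_dna(rng, cen.rdna_unit)
    truth = TruthTables()

    # --- chromosome scaffolding: lengths, telomeres, centromere spans -----
    lo, hi = config.chromosome_length_range
    plans = []
    for i in range(config.n_chromosomes):
        name = f"chr{i + 1:02d}"
        length = int(rng.integers(lo, hi + 1))
        n5 = int(rng.integers(*config.telomere.copies_range, endpoint=True))
        n3 = int(rng.integers(*config.telomere.copies_range, endpoint=True))
        telo_bp = 7 * (n5 + n3)
        c_hi = min(cen.length_range[1], length - telo_bp - 300_000)
        if c_hi < cen.length_range[0]:
            raise SimulationError(
                f"{name}: centromere of {cen.length_range[0]} bp plus arms "
                f"will not fit in {length} bp")
        c_len = int(rng.integers(cen.length_range[0], c_hi + 1))
        arms_total = length - telo_bp - c_len
        arm1 = int(round(arms_total * rng.uniform(0.35, 0.65)))
        plans.append({"name": name, "length": length, "n5": n5, "n3": n3,
                      "c_len": c_len, "arm_lens": (arm1, arms_total - arm1),
                      "rdna": i in cen.rdna_chromosomes})

    # --- genome-wide item allocation to arms ------------------------------
    arm_keys = [(ci, ai) for ci in range(len(plans)) for ai in (0, 1)]
    arm_lens = np.array([plans[ci]["arm_lens"][ai] for ci, ai in arm_keys], float)
    arm_p = arm_lens / arm_lens.sum()
    arm_items: dict[tuple[int, int], list[dict]] = {k: [] for k in arm_keys}

    def _place(item: dict) -> None:
        k = arm_keys[int(rng.choice(len(arm_keys), p=arm_p))]
        arm_items[k].append(item)

    sizes = (list(config.tdg.sizes) if config.tdg.sizes is not None else
             [int(rng.integers(*config.tdg.size_range, endpoint=True))
              for _ in range(config.tdg.n_clusters)])
    gene_counter = 0
    for ci_cluster, size in enumerate(sizes, 1):
        cluster_id = f"SIMC{ci_cluster:03d}"
        gene_ids = []
        for _ in range(size):
            gene_counter += 1
            gene_ids.append(f"g{gene_counter:05d}")
        _place({"kind": "cluster", "cluster_id": cluster_id, "genes": gene_ids})
    for _ in range(config.n_background_genes):
        gene_counter += 1
        _place({"kind": "gene", "gene_id": f"g{gene_counter:05d}"})
    for _ in range(config.gaps.count):
        if rng.random() < config.gaps.sentinel_fraction:
            glen, known = config.gaps.sentinel_length, False
        else:
            glen = int(rng.integers(*config.gaps.length_range, endpoint=True))
            while glen == config.gaps.sentinel_length:
                glen = int(rng.integers(*config.gaps.length_range, endpoint=True))
            known = True
        embedded = rng.random() < config.gaps.in_repeat_fraction
        _place({"kind": "gap", "length": glen, "known": known,
                "embedded": embedded})

    # --- materialise chromosomes ------------------------------------------
    records = []
    for ci, plan in enumerate(plans):
        name = plan["name"]
        pieces: list[str] = []
        pos = 0

        def _emit(seq: str) -> tuple[int, int]:
            nonlocal pos
            pieces.append(seq)
            start, pos_end = pos, pos + len(seq)
            pos = pos_end
            return start, pos_end

        # 5' telomere (reverse-complement monomer orientation)
        arr = _telomere_array(rng, revcomp(TELOMERE_MONOMER), plan["n5"],
                              config.telomere.mutation_rate)
        s, e = _emit(arr)
        truth.telomeres.append(TelomereTruth(
            name, "five_prime", s, e, plan["n5"],
            len(_occurrences(arr, revcomp(TELOMERE_MONOMER)))))

        for ai in (0, 1):
            if ai == 1:
                _emit_centromere(rng, config, plan, name, monomers, rdna_gene,
                                 truth, _emit)
            _emit_arm(rng, config, arm_items[(ci, ai)],
                      plan["arm_lens"][ai], name, truth, _emit)

        arr = _telomere_array(rng, TELOMERE_MONOMER, plan["n3"],
                              config.telomere.mutation_rate)
        s, e = _emit(arr)
        truth.telomeres.append(TelomereTruth(
            name, "three_prime", s, e, plan["n3"],
            len(_occurrences(arr, TELOMERE_MONOMER))))

        residues = "".join(pieces)
        assert len(residues) == plan["length"], (name, len(residues), plan["length"])
        records.append(SequenceRecord(name, residues))

    for g in truth.genes:
        truth.protein_lengths[g.gene_id] = (g.end - g.start) // 3
    truth.telomeres.sort(key=lambda t: (t.seq_name, t.start))
    truth.gaps.sort(key=lambda t: (t.seq_name, t.start))
    truth.repeats.sort(key=lambda iv: (iv.seq_name, iv.start))
    truth.genes.sort(key=lambda g: (g.seq_name, g.start))
    return Assembly(records, label="sim"), truth


def _emit_centromere(rng, config, plan, name, monomers, rdna_gene, truth, _emit):
    """Tile the centromeric block with satellite/rDNA chunks (no background)."""
    cen = config.centromere
    c_len = plan["c_len"]
    cen_start = None
    remaining = c_len
    families = list(monomers)
    want_rdna = plan["rdna"]
    rdna_len = cen.rdna_copies * (cen.rdna_unit + cen.rdna_spacer)
    while remaining > 0:
        if want_rdna and remaining >= rdna_len:
            unit = rdna_gene + _background(rng, cen.rdna_spacer)
            seq = (unit * cen.rdna_copies)[:rdna_len]
            fam = cen.rdna_family
            want_rdna = False
        else:
            chunk = int(rng.integers(*cen.chunk_range, endpoint=True))
            chunk = min(chunk, remaining)
            fam = families[int(rng.integers(0, len(families)))]
            seq = _tandem_array(monomers[fam], chunk)
        s, e = _emit(seq)
        if cen_start is None:
            cen_start = s
        truth.repeats.append(GenomeInterval(name, s, e, "+", fam))
        remaining -= len(seq)
    truth.centromeres.append(
        GenomeInterval(name, cen_start, cen_start + c_len, ".", "centromere"))


def _emit_arm(rng, config, items, arm_len, name, truth, _emit):
    """Lay out one arm: planted items separated by random background, plus
    TE annotations filling toward the configured density."""
    te = config.te
    fixed_bp = 0
    for item in items:
        if item["kind"] == "cluster":
            n = len(item["genes"])
            item["bp"] = n * config.tdg.gene_length + (n - 1) * config.tdg.intergenic
        elif item["kind"] == "gene":
            item["bp"] = config.tdg.gene_length
        elif item["kind"] == "gap" and item["embedded"]:
            item["family"] = te.families[int(rng.integers(0, len(te.families)))]
            item["half"] = int(rng.integers(*te.length_range, endpoint=True)) // 2
            item["bp"] = item["length"] + 2 * item["half"]
        else:
            item["bp"] = item["length"]
        fixed_bp += item["bp"]
    if fixed_bp > 0.9 * arm_len:
        raise SimulationError(
            f"{name}: {fixed_bp} bp of planted features exceed arm of {arm_len} bp")
    te_budget = max(0, min(int(te.density * arm_len),
                           int(0.85 * arm_len) - fixed_bp))
    all_items = list(items)
    while te_budget > 0:
        te_len = int(rng.integers(*te.length_range, endpoint=True))
        te_len = min(te_len, te_budget)
        fam = te.families[int(rng.integers(0, len(te.families)))]
        all_items.append({"kind": "te", "family": fam, "bp": te_len})
        te_budget -= te_len
    order = rng.permutation(len(all_items))
    all_items = [all_items[i] for i in order]
    spare = arm_len - sum(item["bp"] for item in all_items)
    spacers = rng.multinomial(spare, np.full(len(all_items) + 1,
                                             1.0 / (len(all_items) + 1)))
    _emit(_background(rng, int(spacers[0])))
    for item, spacer in zip(all_items, spacers[1:]):
        _emit_item(rng, config, item, name, truth, _emit)
        _emit(_background(rng, int(spacer)))


def _emit_item(rng, config, item, name, truth, _emit):
    kind = item["kind"]
    if kind == "te":
        s, e = _emit(_background(rng, item["bp"]))
        truth.repeats.append(GenomeInterval(name, s, e, "+", item["family"]))
    elif kind == "gene":
        strand = "+" if rng.random() < 0.5 else "-"
        s, e = _emit(_background(rng, item["bp"]))
        truth.genes.append(GeneTruth(item["gene_id"], name, s, e, strand, None))
    elif kind == "cluster":
        strand = "+" if rng.random() < 0.5 else "-"
        for i, gene_id in enumerate(item["genes"]):
            if i > 0:
                _emit(_background(rng, config.tdg.intergenic))
            s, e = _emit(_background(rng, config.tdg.gene_length))
            truth.genes.append(GeneTruth(gene_id, name, s, e, strand,
                                         item["cluster_id"]))
    elif kind == "gap":
        if item["embedded"]:
            fam = item["family"]
            half = item["half"]
            s1, _ = _emit(_background(rng, half))
            gs, ge = _emit("N" * item["length"])
            _, e2 = _emit(_background(rng, half))
            truth.repeats.append(GenomeInterval(name, s1, e2, "+", fam))
        else:
            gs, ge = _emit("N" * item["length"])
        truth.gaps.append(GapTruth(name, gs, ge, item["known"]))
    else:
        raise AssertionError(kind)


# ---------------------------------------------------------------------------
# protein hit simulation
# ---------------------------------------------------------------------------

def simulate_hits(truth: TruthTables, false_pair_rate: float = 0.0,
                  seed: int = 0, hsp_split: bool = False) -> list[SimilarityHit]:
    """Blast-tab-style hits: every within-cluster pair passes the default
    TDG filters; decoy pairs (at ``false_pair_rate`` times the true pair
    count) fail at least one filter."""
    rng = np.random.default_rng(seed)
    hits: list[SimilarityHit] = []
    true_pairs = []
    for members in truth.clusters.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                true_pairs.append((members[i], members[j]))
    for a, b in true_pairs:
        la, lb = truth.protein_lengths[a], truth.protein_lengths[b]
        evalue = 10.0 ** rng.uniform(-180, -30)
        if hsp_split:
            # two half-coverage HSPs whose union still passes the filter
            cut_a, cut_b = int(la * 0.55), int(lb * 0.55)
            lo_a, lo_b = int(la * 0.45), int(lb * 0.45)
            hits.append(SimilarityHit(a, b, evalue, 0, cut_a, 0, cut_b,
                                      bitscore=2.0 * cut_a))
            hits.append(SimilarityHit(a, b, evalue, lo_a, la, lo_b, lb,
                                      bitscore=2.0 * (la - lo_a)))
        else:
            hits.append(SimilarityHit(a, b, evalue, 0, la, 0, lb,
                                      bitscore=2.0 * la))
    cluster_of = {g.gene_id: g.cluster_id for g in truth.genes}
    gene_ids = sorted(truth.protein_lengths)
    n_decoys = int(round(false_pair_rate * len(true_pairs)))
    made = 0
    while made < n_decoys and len(gene_ids) > 1:
        a, b = (gene_ids[int(k)] for k in rng.choice(len(gene_ids), 2,
                                                     replace=False))
        if cluster_of.get(a) is not None and cluster_of[a] == cluster_of.get(b):
            continue
        la, lb = truth.protein_lengths[a], truth.protein_lengths[b]
        small = min(la, lb)
        if rng.random() < 0.5:   # fails the e-value filter
            hits.append(SimilarityHit(a, b, 1e-5, 0, la, 0, lb, bitscore=50.0))
        else:                    # fails the coverage filter
            span = max(2, int(small * 0.3))
            hits.append(SimilarityHit(a, b, 1e-40, 0, span, 0, span,
                                      bitscore=100.0))
        made += 1
    return hits


# ---------------------------------------------------------------------------
# degraded sister assembly
# ---------------------------------------------------------------------------

@dataclass
class DegradeResult:
    degraded: Assembly
    blocks: list[AlignmentBlock]          # truth assembly (query) -> degraded
    new_regions: list[GenomeInterval]     # truth regions absent from degraded
    lifted_genes: list[GenomeInterval]    # surviving old genes on truth coords
    new_gene_ids: list[str]


def degrade_assembly(assembly: Assembly, truth: TruthTables,
                     config: SimConfig, seed: int = 0) -> DegradeResult:
    """Fragment the truth assembly and collapse repeat regions.

    Deletes a central fraction of every centromeric block (when the
    deletion reaches ``min_collapse_len``) plus optionally whole TDG-
    cluster regions, fragments the retained sequence into contigs around
    ``fragment_n50``, and emits the exact truth alignment blocks between
    retained segments and the original chromosomes.
    """
    rng = np.random.default_rng(seed)
    deg = config.degrade
    deletions: dict[str, list[tuple[int, int]]] = {n: [] for n in assembly.names}
    for cen in truth.centromeres:
        del_len = int(round(deg.collapse_fraction * cen.width))
        if del_len >= deg.min_collapse_len:
            start = cen.start + (cen.width - del_len) // 2
            deletions[cen.seq_name].append((start, start + del_len))
    if deg.collapse_fraction > 0 and deg.n_gene_region_deletions > 0:
        clusters = truth.clusters
        cluster_ids = sorted(clusters)
        picked = rng.choice(len(cluster_ids),
                            min(deg.n_gene_region_deletions, len(cluster_ids)),
                            replace=False)
        lengths = assembly.lengths
        for k in sorted(int(p) for p in picked):
            members = set(clusters[cluster_ids[k]])
            spans = [(g.seq_name, g.start, g.end) for g in truth.genes
                     if g.gene_id in members]
            seq_name = spans[0][0]
            lo = min(s for _, s, _ in spans)
            hi = max(e for _, _, e in spans)
            # pad the deleted window to a detectable size, keeping the full
            # width even when clipped at a chromosome end
            target = max(hi - lo, deg.gene_region_pad)
            start = max(1, lo - (target - (hi - lo)) // 2)
            end = min(lengths[seq_name] - 1, start + target)
            start = max(1, end - target)
            if all(e < start or s > end for s, e in deletions[seq_name]):
                deletions[seq_name].append((start, end))
    for name in deletions:
        deletions[name].sort()

    blocks: list[AlignmentBlock] = []
    contigs: list[SequenceRecord] = []
    for rec in assembly:
        retained = subtract(rec.length, deletions[rec.name])
        k = 0
        for seg_start, seg_end in retained:
            pos = seg_start
            while pos < seg_end:
                target_len = int(rng.uniform(0.5, 1.5) * deg.fragment_n50)
                end = min(pos + target_len, seg_end)
                if seg_end - end < 50_000:      # avoid slivers
                    end = seg_end
                k += 1
                cname = f"{rec.name}_ctg{k:02d}"
                contigs.append(SequenceRecord(cname, rec.residues[pos:end]))
                blocks.append(AlignmentBlock(
                    GenomeInterval(rec.name, pos, end, "+", "alignment"),
                    GenomeInterval(cname, 0, end - pos, "+", "alignment"),
                    strand="+", identity=1.0))
                pos = end

    new_regions = [GenomeInterval(name, s, e, ".", "new_region")
                   for name in assembly.names for s, e in deletions[name]]
    lifted, new_ids = [], []
    for g in truth.genes:
        overlaps = any(s < g.end and g.start < e for s, e in deletions[g.seq_name])
        if overlaps:
            new_ids.append(g.gene_id)
        else:
            lifted.append(GenomeInterval(g.seq_name, g.start, g.end,
                                         g.strand, "lifted_gene"))
    return DegradeResult(Assembly(contigs, label="degraded"), blocks,
                         new_regions, lifted, new_ids)


# ---------------------------------------------------------------------------
# genetic map simulation
# ---------------------------------------------------------------------------

@dataclass
class MarkerMapSim:
    markers: list[MarkerObservation]
    contig_lengths: dict[str, int]
    order: dict[str, list[tuple[str, str]]]   # chrom -> [(contig, orientation)]

    def contig_assembly(self, assembly: Assembly) -> Assembly:
        """Materialise the contig sequences implied by the cut (contigs cut
        sequentially from each chromosome; "-" contigs reverse-complemented)."""
        records = []
        for chrom, placed in self.order.items():
            start = 0
            residues = assembly[chrom].residues
            for contig, orientation in placed:
                size = self.contig_lengths[contig]
                seq = residues[start:start + size]
                if orientation == "-":
                    seq = revcomp(seq)
                records.append(SequenceRecord(contig, seq))
                start += size
        return Assembly(records, label="map_contigs")


def simulate_marker_map(assembly: Assembly, n_contigs_per_chrom: int = 4,
                        markers_per_contig: int = 10,
                        mislabel_rate: float = 0.0, noise_cm: float = 0.0,
                        cm_per_mb: float = 3.0, seed: int = 0) -> MarkerMapSim:
    """Cut chromosomes into oriented contigs and emit a marker map.

    Genetic positions increase monotonically with physical position along
    each chromosome (``cm_per_mb`` plus optional Gaussian noise);
    ``mislabel_rate`` markers are assigned a wrong chromosome.
    """
    rng = np.random.default_rng(seed)
    chrom_names = assembly.names
    markers: list[MarkerObservation] = []
    contig_lengths: dict[str, int] = {}
    order: dict[str, list[tuple[str, str]]] = {}
    counter = 0
    for rec in assembly:
        weights = rng.uniform(0.5, 1.5, n_contigs_per_chrom)
        sizes = np.floor(weights / weights.sum() * rec.length).astype(int)
        sizes[-1] = rec.length - int(sizes[:-1].sum())
        order[rec.name] = []
        start = 0
        for k, size in enumerate(sizes, 1):
            cname = f"{rec.name}_c{k:02d}"
            orientation = "+" if rng.random() < 0.5 else "-"
            contig_lengths[cname] = int(size)
            order[rec.name].append((cname, orientation))
            for _ in range(markers_per_contig):
                offset = int(rng.integers(0, size))
                genome_pos = start + offset
                physical = offset if orientation == "+" else int(size) - offset
                genetic = genome_pos / 1e6 * cm_per_mb
                if noise_cm > 0:
                    genetic += rng.normal(0, noise_cm)
                chrom = rec.name
                if rng.random() < mislabel_rate and len(chrom_names) > 1:
                    others = [c for c in chrom_names if c != rec.name]
                    chrom = others[int(rng.integers(0, len(others)))]
                counter += 1
                markers.append(MarkerObservation(
                    f"m{counter:05d}", chrom, round(genetic, 4),
                    cname, physical))
            start += int(size)
    return MarkerMapSim(markers, contig_lengths, order)


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_simulation(assembly: Assembly, truth: TruthTables,
                     out_dir: str | Path) -> None:
    """Write the fixture in the standard formats the analysis stages read:
    genome FASTA, genes GFF3, repeats BED, plus truth/*.tsv."""
    out_dir = Path(out_dir)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(assembly, out_dir / "genome.fasta")
    with open(out_dir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in truth.genes:
            fh.write(f"{g.seq_name}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
    write_bed(truth.repeats, out_dir / "repeats.bed")
    pd.DataFrame([asdict(t) for t in truth.telomeres]).to_csv(
        truth_dir / "telomeres.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(t) for t in truth.gaps]).to_csv(
        truth_dir / "gaps.tsv", sep="\t", index=False)
    write_bed(truth.centromeres, truth_dir / "centromeres.bed")
    pd.DataFrame([asdict(g) for g in truth.genes]).to_csv(
        truth_dir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": gid, "protein_length": n}
         for gid, n in sorted(truth.protein_lengths.items())]
    ).to_csv(truth_dir / "protein_lengths.tsv", sep="\t", index=False)


def write_degraded(result: DegradeResult, out_dir: str | Path,
                   query_lengths: dict[str, int] | None = None) -> None:
    """Write the degraded sister assembly, its truth alignments (PAF) and
    truth new-region/new-gene tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.degraded, out_dir / "degraded.fasta")
    lengths = result.degraded.lengths
    query_lengths = query_lengths or {}
    with open(out_dir / "alignments.paf", "w") as fh:
        for b in result.blocks:
            qlen = b.query.end - b.query.start
            fh.write("\t".join(map(str, [
                b.query.seq_name,
                query_lengths.get(b.query.seq_name, b.query.end),
                b.query.start, b.query.end, b.strand,
                b.target.seq_name, lengths[b.target.seq_name],
                b.target.start, b.target.end, qlen, qlen, 60])) + "\n")
    write_bed(result.new_regions, out_dir / "truth_new_regions.bed")
    write_bed(result.lifted_genes, out_dir / "lifted_genes.bed")
    with open(out_dir / "truth_new_genes.txt", "w") as fh:
        for gid in result.new_gene_ids:
            fh.write(gid + "\n")
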