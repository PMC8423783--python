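"""Domain types and readers/writers for assembly-audit inputs and outputs.

This module is the single source of coordinate conventions: everything in
memory is 0-based half-open (BED convention); conversion from 1-based
inclusive dialects (GFF3, RepeatMasker ``.out``, blast tabular, nucmer
``show-coords``) happens here and only here.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")

INTERVAL_DIALECTS = ("bed", "gff3", "repeatmasker_out", "blast_tab", "paf", "coords")
ALIGNMENT_DIALECTS = ("paf", "coords", "blast_tab")


class FormatError(ValueError):
    """Raised for unreadable or inconsistent input files."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeInterval:
    """A span on a named sequence, 0-based half-open.

    ``feature_class`` carries whatever label the source format provides: a
    repeat family, ``gap``, ``gene``, an alignment target, a telomere tag.
    """

    seq_name: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad interval {self.seq_name}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def as_pair(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercased on load."""

    name: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class Assembly:
    """Ordered collection of sequences plus optional genome-size estimate."""

    records: list[SequenceRecord] = field(default_factory=list)
    label: str = ""
    estimated_genome_size: int | None = None

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate sequence names: {dupes}")
        if self.estimated_genome_size is not None and self.estimated_genome_size <= 0:
            raise ValueError("estimated_genome_size must be positive")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> SequenceRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    @property
    def lengths(self) -> dict[str, int]:
        return {r.name: r.length for r in self.records}

    @property
    def cumulative_size(self) -> int:
        return sum(r.length for r in self.records)


@dataclass(frozen=True)
class SimilarityHit:
    """One all-vs-all protein alignment row (blast/diamond outfmt-6 style).

    Aligned spans are stored 0-based half-open and ascending on both
    proteins; a subject span given descending in the source implies minus
    strand and is normalised here.
    """

    query_id: str
    subject_id: str
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    bitscore: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.q_end <= self.q_start or self.s_end <= self.s_start:
            raise ValueError("aligned spans must be non-empty and ascending")


@dataclass(frozen=True)
class MarkerObservation:
    """A genetic-map marker tied to a physical position on a contig."""

    marker_id: str
    map_chromosome: str
    genetic_position: float
    contig: str
    physical_position: int


@dataclass(frozen=True)
class AlignmentBlock:
    """A whole-genome alignment block between two assemblies.

    ``query`` lives on the newer assembly being audited, ``target`` on the
    reference/older one.  Re-exported by :mod:`t2taudit.comparative`.
    """

    query: GenomeInterval
    target: GenomeInterval
    strand: str = "+"
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, label: str = "",
               estimated_genome_size: int | None = None) -> Assembly:
    """Load an assembly from FASTA.

    Residues are uppercased; characters outside {A,C,G,T,N} are coerced to N
    with a logged count.  Duplicate headers and empty files are hard errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    n_subst = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate header {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        cleaned, n = _NON_ACGTN.subn("N", residues)
        n_subst += n
        records.append(SequenceRecord(rec.id, cleaned))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if n_subst:
        logger.warning("%s: %d non-ACGTN characters coerced to N", path, n_subst)
    return Assembly(records, label=label or path.stem,
                    estimated_genome_size=estimated_genome_size)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in assembly:
            fh.write(f">{rec.name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# interval dialects
# ---------------------------------------------------------------------------

def _iter_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def _gff3_attr(attrs: str, *keys: str) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for key in keys:
        if key in fields:
            return fields[key]
    return None


def read_intervals(path: str | Path, dialect: str) -> list[GenomeInterval]:
    """Read any supported tabular annotation dialect into intervals.

    Coordinates are normalised to 0-based half-open; rows that are empty
    after normalisation are rejected with a logged line number.  For the
    pairwise dialects (blast_tab/paf/coords) the *query*-side interval is
    returned with ``feature_class`` set to the target name; use
    :func:`read_alignments` when both sides are needed.
    """
    path = Path(path)
    if dialect not in INTERVAL_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {INTERVAL_DIALECTS}")
    out: list[GenomeInterval] = []
    for lineno, cols in _iter_rows(path):
        try:
            iv = _parse_interval_row(cols, dialect)
        except (ValueError, IndexError) as exc:
            logger.warning("%s:%d: rejected row (%s)", path, lineno, exc)
            continue
        if iv is not None:
            out.append(iv)
    return out


def _parse_interval_row(cols: list[str], dialect: str) -> GenomeInterval | None:
    if dialect == "bed":
        name = cols[3] if len(cols) > 3 else "feature"
        strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
        return GenomeInterval(cols[0], int(cols[1]), int(cols[2]), strand, name)
    if dialect == "gff3":
        start, end = int(cols[3]) - 1, int(cols[4])
        strand = cols[6] if cols[6] in "+-" else "."
        name = _gff3_attr(cols[8], "Name", "ID") if len(cols) > 8 else None
        return GenomeInterval(cols[0], start, end, strand, name or cols[2])
    if dialect == "repeatmasker_out":
        try:
            int(cols[0])  # header lines don't start with a score
        except ValueError:
            return None
        start, end = int(cols[5]) - 1, int(cols[6])
        strand = "-" if cols[8] == "C" else "+"
        return GenomeInterval(cols[4], start, end, strand, cols[9])
    if dialect == "blast_tab":
        qstart, qend = sorted((int(cols[6]), int(cols[7])))
        sstart, send = int(cols[8]), int(cols[9])
        strand = "-" if sstart > send else "+"
        return GenomeInterval(cols[0], qstart - 1, qend, strand, cols[1])
    if dialect == "paf":
        return GenomeInterval(cols[0], int(cols[2]), int(cols[3]), cols[4], cols[5])
    if dialect == "coords":
        s2, e2 = int(cols[2]), int(cols[3])
        strand = "-" if s2 > e2 else "+"
        s2, e2 = sorted((s2, e2))
        qry = cols[8] if len(cols) > 8 else "query"
        ref = cols[7] if len(cols) > 7 else "ref"
        return GenomeInterval(qry, s2 - 1, e2, strand, ref)
    raise AssertionError(dialect)


def read_alignments(path: str | Path, dialect: str) -> list[AlignmentBlock]:
    """Read whole-genome alignment blocks (query on the newer assembly)."""
    path = Path(path)
    if dialect not in ALIGNMENT_DIALECTS:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    out: list[AlignmentBlock] = []
    for lineno, cols in _iter_rows(path):
        try:
            out.append(_parse_alignment_row(cols, dialect))
        except (ValueError, IndexError) as exc:
            logger.warning("%s:%d: rejected row (%s)", path, lineno, exc)
    return out


def _parse_alignment_row(cols: list[str], dialect: str) -> AlignmentBlock:
    if dialect == "paf":
        strand = cols[4]
        identity = None
        alnlen = int(cols[10])
        if alnlen > 0:
            identity = int(cols[9]) / alnlen
        return AlignmentBlock(
            GenomeInterval(cols[0], int(cols[2]), int(cols[3]), strand, "alignment"),
            GenomeInterval(cols[5], int(cols[7]), int(cols[8]), "+", "alignment"),
            strand=strand, identity=identity)
    if dialect == "coords":
        s1, e1 = sorted((int(cols[0]), int(cols[1])))
        s2raw, e2raw = int(cols[2]), int(cols[3])
        strand = "-" if s2raw > e2raw else "+"
        s2, e2 = sorted((s2raw, e2raw))
        identity = float(cols[6]) / 100 if len(cols) > 6 else None
        ref = cols[7] if len(cols) > 7 else "ref"
        qry = cols[8] if len(cols) > 8 else "query"
        return AlignmentBlock(
            GenomeInterval(qry, s2 - 1, e2, strand, "alignment"),
            GenomeInterval(ref, s1 - 1, e1, "+", "alignment"),
            strand=strand, identity=identity)
    if dialect == "blast_tab":
        qstart, qend = sorted((int(cols[6]), int(cols[7])))
        sraw, eraw = int(cols[8]), int(cols[9])
        strand = "-" if sraw > eraw else "+"
        s, e = sorted((sraw, eraw))
        return AlignmentBlock(
            GenomeInterval(cols[0], qstart - 1, qend, strand, "alignment"),
            GenomeInterval(cols[1], s - 1, e, "+", "alignment"),
            strand=strand, identity=float(cols[2]) / 100)
    raise AssertionError(dialect)


def read_similarity_hits(path: str | Path) -> list[SimilarityHit]:
    """Read all-vs-all protein hits from 12-column blast/diamond tabular."""
    path = Path(path)
    out: list[SimilarityHit] = []
    for lineno, cols in _iter_rows(path):
        try:
            qstart, qend = sorted((int(cols[6]), int(cols[7])))
            sraw, eraw = int(cols[8]), int(cols[9])
            strand = "-" if sraw > eraw else "+"
            sstart, send = sorted((sraw, eraw))
            out.append(SimilarityHit(
                query_id=cols[0], subject_id=cols[1],
                evalue=float(cols[10]), bitscore=float(cols[11]),
                q_start=qstart - 1, q_end=qend,
                s_start=sstart - 1, s_end=send, strand=strand))
        except (ValueError, IndexError) as exc:
            logger.warning("%s:%d: rejected hit row (%s)", path, lineno, exc)
    return out


def write_similarity_hits(hits: Sequence[SimilarityHit], path: str | Path) -> None:
    """Write hits back out as 12-column blast tabular (1-based inclusive)."""
    with open(path, "w") as fh:
        for h in hits:
            s_first, s_last = h.s_start + 1, h.s_end
            if h.strand == "-":
                s_first, s_last = s_last, s_first
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, "100.00", h.q_end - h.q_start,
                0, 0, h.q_start + 1, h.q_end, s_first, s_last,
                f"{h.evalue:.2e}", f"{h.bitscore:.1f}"])) + "\n")


# ---------------------------------------------------------------------------
# markers and genes
# ---------------------------------------------------------------------------

MARKER_COLUMNS = ["marker_id", "map_chromosome", "genetic_position",
                  "contig", "physical_position"]


def read_markers(path: str | Path) -> list[MarkerObservation]:
    """Read a marker TSV (columns: marker_id, map_chromosome,
    genetic_position, contig, physical_position; header required)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing marker columns {missing}")
    return [
        MarkerObservation(str(r.marker_id), str(r.map_chromosome),
                          float(r.genetic_position), str(r.contig),
                          int(r.physical_position))
        for r in df.itertuples()
    ]


def write_markers(markers: Sequence[MarkerObservation], path: str | Path) -> None:
    pd.DataFrame([asdict(m) for m in markers], columns=MARKER_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_genes(path: str | Path) -> list[tuple[str, GenomeInterval]]:
    """Read gene records (type ``gene``) from GFF3 as (gene_id, interval)."""
    path = Path(path)
    out: list[tuple[str, GenomeInterval]] = []
    for lineno, cols in _iter_rows(path):
        if len(cols) < 9 or cols[2] != "gene":
            continue
        gene_id = _gff3_attr(cols[8], "ID", "Name")
        if gene_id is None:
            logger.warning("%s:%d: gene row without ID", path, lineno)
            continue
        strand = cols[6] if cols[6] in "+-" else "."
        out.append((gene_id, GenomeInterval(cols[0], int(cols[3]) - 1,
                                            int(cols[4]), strand, "gene")))
    return out


# ---------------------------------------------------------------------------
# BED / report output
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomeInterval], path: str | Path,
              scores: Mapping[GenomeInterval, float] | None = None) -> None:
    """Write BED6, sort-ordered by (seq, start)."""
    rows = sorted(intervals, key=lambda iv: (iv.seq_name, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            score = 0 if scores is None else scores.get(iv, 0)
            fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t"
                     f"{iv.feature_class or 'feature'}\t{score:g}\t{iv.strand}\n")


@dataclass
class AuditReport:
    """Structured audit results, losslessly JSON-serialisable.

    ``tracks`` holds interval categories (telomeres, gaps, centromeres,
    new_regions, tdg_clusters); ``tables`` holds arbitrary row-dict tables;
    ``metrics`` maps assembly label -> column -> value.
    """

    assembly_label: str = ""
    metrics: dict = field(default_factory=dict)
    chromosomes: list = field(default_factory=list)
    tracks: dict[str, list[GenomeInterval]] = field(default_factory=dict)
    tables: dict[str, list] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "assembly_label": self.assembly_label,
            "metrics": self.metrics,
            "chromosomes": self.chromosomes,
            "tracks": {k: [asdict(iv) for iv in v] for k, v in self.tracks.items()},
            "tables": self.tables,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AuditReport":
        return cls(
            assembly_label=d.get("assembly_label", ""),
            metrics=d.get("metrics", {}),
            chromosomes=d.get("chromosomes", []),
            tracks={k: [GenomeInterval(**iv) for iv in v]
                    for k, v in d.get("tracks", {}).items()},
            tables=d.get("tables", {}),
            provenance=d.get("provenance", {}),
        )

    def validate(self, assembly: Assembly) -> None:
        """Check every reported interval against the loaded assembly."""
        lengths = assembly.lengths
        for category, ivs in self.tracks.items():
            for iv in ivs:
                if iv.seq_name not in lengths:
                    raise ValueError(f"{category}: unknown sequence {iv.seq_name}")
                if iv.end > lengths[iv.seq_name]:
                    raise ValueError(
                        f"{category}: {iv.seq_name}:{iv.start}-{iv.end} exceeds "
                        f"sequence length {lengths[iv.seq_name]}")


def write_report(report: AuditReport, out_dir: str | Path) -> list[Path]:
    """Emit report.json, metrics.tsv and one BED track per interval category."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(json_path)
    metrics_path = out_dir / "metrics.tsv"
    pd.DataFrame.from_dict(report.metrics, orient="index").rename_axis(
        "assembly").to_csv(metrics_path, sep="\t")
    written.append(metrics_path)
    for category, ivs in report.tracks.items():
        bed_path = out_dir / f"{category}.bed"
        write_bed(ivs, bed_path)
        written.append(bed_path)
    return written


def read_report(path: str | Path) -> AuditReport:
    with open(path) as fh:
        return AuditReport.from_dict(json.load(fh))
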