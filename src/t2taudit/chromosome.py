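"""Telomere detection, gap cataloguing and telomere-to-telomere status.

The plant telomere monomer is TTTAGGG (T3AG3), tandemly arrayed at
chromosome termini; its reverse complement CCCTAAA is the expected
orientation at the 5' end.  Detection is exact-monomer matching in every
phase within a bounded terminal window: an array is the maximal terminal
run of matches satisfying a copy-count and identity floor, where identity
is matched bp / array span.

A gap is a maximal run of N.  Scaffolders often encode gaps of unknown
(unestimated) size as a fixed sentinel run, conventionally 100 N.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .intervals import merge, overlap_bp
from .model import GenomeInterval, SequenceRecord

logger = logging.getLogger(__name__)

TELOMERE_MONOMER = "TTTAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TelomereCall:
    seq_name: str
    terminus: str                 # "five_prime" | "three_prime"
    array: GenomeInterval
    copy_count: int
    monomer_identity: float


@dataclass(frozen=True)
class GapRecord:
    interval: GenomeInterval
    length: int
    length_known: bool
    context: str = "unclassified"


@dataclass(frozen=True)
class T2TStatus:
    seq_name: str
    status: str                   # gapless_T2T | T2T_with_gaps | one_telomere | no_telomere
    n_gaps: int


def _occurrences(text: str, motif: str) -> list[int]:
    """Start positions of non-overlapping exact occurrences, left to right."""
    out, i = [], text.find(motif)
    while i != -1:
        out.append(i)
        i = text.find(motif, i + len(motif))
    return out


def _best_terminal_array(occ: list[int], m: int, window_len: int, anchor: str,
                         min_copies: int, min_identity: float,
                         max_offset: int) -> tuple[int, int, int] | None:
    """Best terminal array over windows of exact occurrences.

    Considers every window [i..j] of occurrences whose terminal edge lies
    within ``max_offset`` of the terminus (``anchor`` "left" = 5', "right"
    = 3'), requires >= ``min_copies`` matches and identity (matched bp /
    span) >= ``min_identity``, and returns the window with the most copies
    as (array_start, array_end, copy_count), or None.  Skipping a mutated
    leading copy is allowed as long as the array edge stays terminal.
    """
    if anchor == "right":
        occ = sorted(window_len - (o + m) for o in occ)
    n = len(occ)
    best: tuple[int, int, int] | None = None
    for i in range(n):
        if occ[i] > max_offset:
            break
        for j in range(n - 1, i + min_copies - 2, -1):
            k = j - i + 1
            span = occ[j] + m - occ[i]
            if k * m / span >= min_identity:
                if best is None or k > best[2] or \
                        (k == best[2] and span > best[1] - best[0]):
                    best = (occ[i], occ[j] + m, k)
                break
    if best is None or anchor == "left":
        return best
    start, end, k = best
    return (window_len - end, window_len - start, k)


def scan_telomere(seq: SequenceRecord, motif: str = TELOMERE_MONOMER,
                  scan_window: int = 20_000, min_copies: int = 10,
                  min_identity: float = 0.9,
                  max_terminal_offset: int = 1_000) -> list[TelomereCall]:
    """Detect telomere arrays at both termini of a sequence.

    Both the monomer and its reverse complement are searched at each
    terminus and the better-supported strand reported.  A call requires at
    least ``min_copies`` exact monomer matches, identity (matched bp /
    array span) >= ``min_identity``, and the array edge within
    ``max_terminal_offset`` bp of its terminus.  Interstitial telomere-like
    repeats beyond the terminal window never produce calls.
    """
    if len(motif) < 4:
        raise ValueError("motif too short")
    calls: list[TelomereCall] = []
    length = seq.length
    w = min(scan_window, length)
    m = len(motif)
    for terminus in ("five_prime", "three_prime"):
        if terminus == "five_prime":
            text, offset, anchor = seq.residues[:w], 0, "left"
        else:
            text, offset, anchor = seq.residues[length - w:], length - w, "right"
        best: tuple[int, TelomereCall] | None = None
        for strand, monomer in (("+", motif), ("-", revcomp(motif))):
            occ = _occurrences(text, monomer)
            if len(occ) < min_copies:
                continue
            found = _best_terminal_array(occ, m, w, anchor, min_copies,
                                         min_identity, max_terminal_offset)
            if found is None:
                continue
            start, end, copies = found
            call = TelomereCall(
                seq_name=seq.name, terminus=terminus,
                array=GenomeInterval(seq.name, offset + start, offset + end,
                                     strand, "telomere"),
                copy_count=copies,
                monomer_identity=copies * m / (end - start))
            if best is None or copies > best[0]:
                best = (copies, call)
        if best is not None:
            calls.append(best[1])
    return calls


_N_RUN = re.compile(r"N+")


def find_gaps(seq: SequenceRecord, min_run: int = 1,
              unknown_length_sentinels: Iterable[int] = (100,)) -> list[GapRecord]:
    """Maximal N-runs of length >= min_run; sentinel lengths are flagged
    as gaps of unknown true size."""
    sentinels = set(unknown_length_sentinels)
    gaps = []
    for match in _N_RUN.finditer(seq.residues):
        run = match.end() - match.start()
        if run < min_run:
            continue
        gaps.append(GapRecord(
            interval=GenomeInterval(seq.name, match.start(), match.end(), ".", "gap"),
            length=run,
            length_known=run not in sentinels))
    return gaps


def classify_t2t(seq_name: str, telomere_calls: Sequence[TelomereCall],
                 gaps: Sequence[GapRecord]) -> T2TStatus:
    """Telomere-to-telomere status of one sequence.

    gapless_T2T  <=> telomere calls at both termini and zero gaps.
    """
    termini = {c.terminus for c in telomere_calls if c.seq_name == seq_name}
    n_gaps = sum(1 for g in gaps if g.interval.seq_name == seq_name)
    if {"five_prime", "three_prime"} <= termini:
        status = "gapless_T2T" if n_gaps == 0 else "T2T_with_gaps"
    elif termini:
        status = "one_telomere"
    else:
        status = "no_telomere"
    return T2TStatus(seq_name, status, n_gaps)


def gap_context(gaps: Sequence[GapRecord],
                repeat_annotations: Sequence[GenomeInterval],
                flank: int = 10_000) -> list[GapRecord]:
    """Assign each gap the repeat class with the most annotated bp within
    gap +/- flank ("unclassified" on zero overlap; ties broken by name)."""
    by_seq: dict[str, list[GenomeInterval]] = {}
    for iv in repeat_annotations:
        by_seq.setdefault(iv.seq_name, []).append(iv)
    out = []
    for gap in gaps:
        lo = max(0, gap.interval.start - flank)
        hi = gap.interval.end + flank
        bp_by_class: dict[str, list[tuple[int, int]]] = {}
        for iv in by_seq.get(gap.interval.seq_name, ()):
            ov = overlap_bp((lo, hi), iv.as_pair())
            if ov > 0:
                clipped = (max(iv.start, lo), min(iv.end, hi))
                bp_by_class.setdefault(iv.feature_class, []).append(clipped)
        if not bp_by_class:
            out.append(replace(gap, context="unclassified"))
            continue
        totals = {cls: sum(e - s for s, e in merge(pairs))
                  for cls, pairs in bp_by_class.items()}
        best = min(totals, key=lambda c: (-totals[c], c))
        out.append(replace(gap, context=best))
    return out
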