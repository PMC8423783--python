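# t2taudit

Auditing toolkit for (near-)telomere-to-telomere genome assemblies, built
around the validation questions that chromosome-scale plant assemblies
raise: *how contiguous and complete is the assembly, are the chromosome
ends really telomeres, where are the remaining gaps and what repeats do
they sit in, where are the centromeres, which tandem gene clusters were
gained, what sequence is new relative to the previous release, and do the
genetic-map markers support the chromosome structure?*

It is written for assembly and comparative-genomics practitioners.  The
package consumes standard files (FASTA, GFF3, BED, RepeatMasker tabular,
blast/diamond outfmt-6, PAF or nucmer `show-coords`, marker TSV), never
runs an aligner or annotator itself, and ships a deterministic synthetic-
genome generator with truth tables so every stage is testable offline.

## What it computes

* **Contiguity / completeness** — cumulative and ACGT-only sizes,
  %N = 100·(cumulative − ACGT)/cumulative, Nx/Lx (Nx is the length at
  which sequences sorted by decreasing size cumulatively reach x% of the
  total; Lx the number of sequences needed), percent of an external
  (e.g. flow-cytometry) genome-size estimate, fold coverage.
* **Telomeres & T2T status** — exact-monomer scanning for the plant
  telomere repeat TTTAGGG/CCCTAAA at both termini; a chromosome is
  `gapless_T2T` iff it has telomere arrays at both ends and zero N-gaps.
* **Gap catalog** — maximal N-runs, unknown-length sentinel gaps (100 N),
  and per-gap repeat context (the class with the most annotated bp within
  ±10 kbp).
* **Centromere calls** — windowed repeat densities (100 kbp windows) and
  threshold-based delineation from designated centromeric families
  (Nanica LINE, CRM chromoviruses, satellites, rDNA ITS classes).
* **Tandemly duplicated genes (TDG)** — pairs from all-vs-all protein hits
  filtered at e-value < 1e-20 and > 80% coverage of the smaller protein,
  chained into single-linkage clusters of genes ≤ 10 ranks apart on one
  sequence; plus contig-containment redundancy filtering (95%/88%
  thresholds).
* **Assembly-vs-assembly comparison** — regions ≥ 100 kbp with zero
  alignment to the older assembly ("new regions"), their repeat fraction,
  and new genes (zero overlap with lifted old-gene alignments).
* **Marker anchoring** — majority-vote chromosome assignment, ordering by
  mean genetic position, orientation by Spearman sign, AGP v2.1 output.

See `docs/methods.md` for the exact rules, defaults and limitations.

## Worked example

Generate the default synthetic genome (5 chromosomes, ~7.5 Mbp, planted
telomeres, centromeres, TDG clusters, gaps, a degraded sister assembly and
a marker map) and audit it:

```bash
t2taudit simulate --seed 1 --out fix
t2taudit audit fix/genome.fasta --repeats fix/repeats.bed \
    --estimated-genome-size 8000000 --out audit
```

`audit/metrics.tsv` then contains one row per assembly:

```
assembly  n_sequences  cumulative_size  acgt_only_size  pct_n  longest   N50      L50  N90      L90  pct_of_estimated  pct_of_estimated_acgt
genome    5            7478485          7451336         0.36   1744653   1430639  3    1242037  5    93.5              93.1
```

i.e. 7,478,485 bp in 5 sequences of which 0.36% is N, an N50 of
1,430,639 bp reached with 3 sequences, and 93.5% of the 8 Mbp estimate.
`audit/report.json` carries the per-chromosome status — with seed 1 the
generator happens to leave chr03 without gaps:

```
chr01  1724315  T2T_with_gaps  3
chr02  1336841  T2T_with_gaps  3
chr03  1430639  gapless_T2T    0
chr04  1744653  T2T_with_gaps  1
chr05  1242037  T2T_with_gaps  1
```

and `audit/centromeres.bed` the window-aligned centromere calls
(`chr01  700000  1100000 ...`).  The remaining stages:

```bash
t2taudit tdg --genes fix/genes.gff3 --hits fix/hits.tsv \
    --protein-lengths fix/truth/protein_lengths.tsv --old-clusters 6 --out tdg
# tdg/tdg_summary.json: {"n_clusters": 8, "n_clustered_genes": 49,
#                        "largest": 10, "pct_more_clusters": 33.3}

t2taudit compare fix/genome.fasta --alignments fix/alignments.paf \
    --genes fix/genes.gff3 --lifted fix/lifted_genes.bed \
    --repeats fix/repeats.bed --out cmp
# cmp/compare_summary.json: {"n_new_regions": 6, "new_bp": 1010235,
#                            "pct_of_assembly": 13.5, "n_new_genes": 13}

t2taudit anchor --markers fix/markers.tsv \
    --contigs fix/map_contigs.fasta --out anchor
# anchor/scaffolds.agp: W/U/W rows with 100-bp unknown-length gaps
```

The 8 recovered TDG clusters, 6 new regions and 13 new genes match the
generator's truth tables under `fix/truth/` exactly; the same checks run
as tests.

Everything is also callable as a library:

```python
from t2taudit import read_fasta, size_stats, scan_telomere, find_gaps, classify_t2t

assembly = read_fasta("fix/genome.fasta")
stats = size_stats(assembly, min_length=50_000)
for rec in assembly:
    status = classify_t2t(rec.name, scan_telomere(rec), find_gaps(rec))
    print(rec.name, status.status, status.n_gaps)
```

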