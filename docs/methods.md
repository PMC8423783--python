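# Methods

`t2taudit` audits (near-)telomere-to-telomere plant genome assemblies.  This
note documents the procedures, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices made where the underlying publications leave the operational
details open.

## Coordinate conventions

All intervals in memory are 0-based half-open (BED convention).  Conversion
from 1-based inclusive dialects (GFF3, RepeatMasker `.out`, blast tabular,
nucmer `show-coords`) happens only in `t2taudit.model` readers/writers.  A
blast or coords row whose subject/query coordinates descend implies minus
strand and is normalised to ascending spans.  Rows that are empty after
normalisation are rejected with a logged line number rather than aborting a
load.  Characters outside {A,C,G,T,N} are coerced to N on FASTA load (with a
logged count): audited inputs are polished consensus sequences in which
stray IUPAC codes carry no information the audit uses.

## Contiguity statistics

Nx/Lx follow the standard definition: sequences sorted by decreasing length,
Nx is the length at which the running sum first reaches x% of the *filtered
set's own* total, Lx the number of sequences used.  NG50 (against an external
genome-size estimate) is deliberately omitted; percent-of-estimate columns
(`pct_of_estimated`, and its ACGT-only variant) cover the completeness
question directly.  A `min_length` filter (CLI `--min-contig`, e.g. 50000)
is applied before every statistic, matching the common practice of reporting
contigs above a size floor.  Percentages are reported with round-half-even:
two decimals for %N, one decimal otherwise.  Ties between equal lengths in
the Nx scan are interchangeable by construction.

## Telomere detection

The plant telomere monomer is TTTAGGG (T3AG3); its reverse complement
CCCTAAA is the expected orientation at the 5' terminus.  Published assembly
reports typically state the motif but not the search procedure, so the
detector here is deliberately simple and auditable: exact monomer matching
(both strands, every phase, via non-overlapping string search) within a
terminal window, default 20 kbp.  An array call is the window of matches
with the most copies satisfying

* copy count >= `min_copies` (default 10),
* identity = matched bp / array span >= `min_identity` (default 0.9),
* terminal edge within `max_terminal_offset` (default 1 kbp) of the
  sequence end — this is what rejects interstitial telomere-like arrays;
  they remain visible as ordinary annotation intervals, not telomere calls.

A leading mutated copy may be skipped as long as the array edge stays
terminal.  Identity is defined on the array span, so interior mutated copies
count against it; exact matching plus the 0.9 floor tolerates roughly one
point-mutated copy per ten.

T2T status per sequence: `gapless_T2T` iff telomere calls at both termini
and zero N-gaps; `T2T_with_gaps` with both telomeres and >= 1 gap;
otherwise `one_telomere` / `no_telomere`.

## Gap catalog

A gap is a maximal run of N with length >= `min_run` (default 1, so gap
totals reconcile exactly with %N accounting).  Runs whose length equals a
sentinel (default {100}) are flagged `length_known = False`: scaffolders
conventionally emit fixed 100-N runs where the true gap size is
unestimated.  The sentinel set is configurable because the encoding varies
between pipelines.  Gap context is the repeat class with the greatest
unioned annotated bp within gap ± `flank` (default 10 kbp), ties broken
alphabetically, `unclassified` on zero overlap — this reproduces the
observation that residual gaps concentrate in rDNA clusters and other
tandem repeats.

## Repeat landscape and centromere calls

Repeat coverage is computed per feature class on fixed non-overlapping
windows anchored at 0 (default 100 kbp, the usual scale for chromosome
repeat-density tracks); intervals of one class are unioned before coverage
and the last window is normalised by its true width.

Centromeres of monocentric plant chromosomes are delineated operationally
from the combined density of designated centromeric families — by default
`daterra-Maximus`, `ITS-5S`, `ITS-18S`, `ITS-26S`, `Nanica`, `maca-Angela`,
`caturra-Reina` (Nanica LINE, CRM-clade chromoviruses, centromeric
satellites and rDNA ITS classes).  The boundary rule is this package's own
operationalisation, since density-based centromere delineation is usually
described without one: windows with combined coverage >= `threshold`
(default 0.2) are kept, runs of kept windows separated by <= `merge_gap`
(default 500 kbp) are merged, and one call per sequence is chosen by `pick`
(`longest` default, `densest` available).  Families can be combined by
interval union (default; overlap counted once) or by summing per-class
fractions (`combine="sum"`).  `mean_density` averages the above-threshold
windows of the chosen run, so the reported density is not diluted by merged
sub-threshold windows.  Calls are window-aligned: boundaries are accurate
to one window per side, which is also the tolerance the recovery tests use.

## Tandemly duplicated genes

From all-vs-all protein similarity (12-column blast/diamond tabular), a
gene pair is retained iff the best e-value over its HSPs is `< 1e-20` and
the aligned coverage of the *smaller* protein is `> 0.8`.  Coverage pools
all HSPs of a pair by union on the smaller protein (best-single-HSP is
available via `pool_hsps=False`); the e-value threshold is read as 1e-20
(i.e. 10^-20).  Retained pairs on the same sequence with gene-rank
difference <= 10 become edges ("not distant by more than 10 genes" is
implemented as rank difference <= 10; strict `<` is a toggle, since
"counting intervening genes" vs "rank difference" is ambiguous in prose
descriptions).  Clusters are connected components (single linkage), which
is what lets a long cluster form by chaining even when its extreme members
are far apart — the behaviour needed for a 38-gene cluster whose fragments
appear as separate smaller clusters in a more fragmented assembly.
Components of size 1 are discarded; cluster ids are deterministic, ordered
by (sequence, leftmost rank).

Contig redundancy: a contig is flagged as contained when the unioned bp of
its alignments to strictly longer sequences covers >= `min_contained_fraction`
(default 0.95, with 0.88 the documented secondary operating point) of its
length.  Contigs with no alignments are kept.

## Assembly comparison

New regions are the complement of the union of all alignment blocks on the
newer assembly, kept when >= `min_length` (default 100 kbp).  "Without any
alignment" is strict zero overlap regardless of identity; an optional
`min_identity` pre-filter exists (off by default) because upstream aligner
settings vary.  New genes use subtract (`-v`) semantics: a gene of the new
assembly is new iff it overlaps no lifted old-gene alignment by even 1 bp.
Per-region repeat fraction is unioned repeat bp / region width.  The
package never invokes an aligner; PAF, `show-coords` tabular and blast
tabular are accepted as input.

## Marker anchoring

An explicit desk-scale stand-in for full genetic-map scaffolding pipelines
(marker binning, conflict resolution, iterative ordering), kept minimal so
it is end-to-end testable: majority-vote chromosome assignment per contig
(>= `min_markers` = 2 markers, vote fraction >= `min_vote` = 0.6, ties
unanchored and logged), ordering by mean genetic position of the supporting
(majority-chromosome) markers with ties broken by contig name, and
orientation by the sign of the Spearman correlation between physical and
genetic positions ("?" with < 3 markers or zero/undefined correlation).
AGP v2.1 output uses 100-bp `U` gaps ("scaffold, yes, map"), matching the
unknown-length gap sentinel of the gap catalog, so a scaffold rebuilt from
AGP + contigs round-trips through `find_gaps` exactly.

## Synthetic data generator

Each simulated chromosome is: 5' telomere array (CCCTAAA orientation) —
arm — centromeric block — arm — 3' telomere array (TTTAGGG).  Arms carry
uniform-ACGT background scrubbed of accidental telomere monomers,
interspersed TE annotations (families distinct from the centromeric list),
background genes, planted TDG clusters (consecutive genes with a shared
cluster id), and N-gaps, half of which are embedded inside a TE annotation
so gap-context classification has signal.  The centromeric block is tiled
edge-to-edge with satellite arrays of the default centromeric families,
plus a 5S rDNA gene/spacer cluster on designated chromosomes (emulating
rDNA arrays recruited into centromeres).  Defaults are desk-sized: 5
chromosomes of 1–2 Mbp (~7.5 Mbp, building in well under a second), 8 TDG
clusters of 2–12 genes, 150 background genes, 8 gaps with a 0.4
unknown-length sentinel fraction, telomere arrays of 30–120 copies with 2%
per-copy point mutation.

Generator self-consistency is a design rule: planted features must be
recoverable at the audit's default thresholds.  Concretely, telomere
mutations are spaced >= 10 copies apart (so an array always retains a run
satisfying the copy/identity floors), background is telomere-motif-free,
and centromere blocks are dense enough to clear the 0.2 window threshold.

The degraded sister assembly emulates an older, more fragmented release:
a central fraction (default 0.5) of every centromeric block is deleted when
the deletion reaches 120 kbp, one TDG-cluster region (padded to 150 kbp,
width preserved when clipped at a chromosome end) is deleted entirely so
that truth new *genes* exist, and the retained sequence is fragmented into
contigs around a 300 kbp N50.  Exact truth alignment blocks between
retained segments and the original chromosomes are emitted, so new-region
recovery is bit-exact by construction.  The simulated genetic map cuts each
chromosome into oriented contigs and emits markers whose genetic positions
grow monotonically along the chromosome (3 cM/Mbp) with optional Gaussian
noise and a configurable wrong-chromosome mislabel rate.

Everything is deterministic under (config, seed): one `numpy` generator,
consumed sequentially.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: sequencing-error and polishing artefacts,
heterozygosity, segmental duplications and interstitial telomere repeats,
diverged repeat copies (annotations are planted, not rediscovered),
gene-structure complexity (genes are intervals, proteins are length/3),
genetic-map error structure beyond uniform mislabeling, and real alignment
noise (truth alignments are exact).  Recovery on this generator validates
the bookkeeping and the decision rules, not robustness to annotation or
alignment error.

## Desk scale and known limitations

The package runs at desk scale.  Published full-genome figures — N50/L50
of the real ~484 Mbp assembly releases, the 15-gap count of the deposited
chromosomes, NLR locus counts, genome-wide TE bp, BUSCO and consensus-QV
scores — require the deposited assemblies and external tools (repeat
maskers, gene predictors, BUSCO, k-mer QV tools) that this package
deliberately consumes rather than reproduces.  What is reproduced exactly
is the summary arithmetic on the published size columns (%N,
percent-of-flow-cytometry-estimate, the 29.2% new-region fraction, the 31%
TDG-cluster gain) and, on synthetic genomes, the full recovery of planted
truth.  `scripts/acceptance.py` recomputes both families of quantities from
scratch.

Other limitations: the telomere detector uses exact monomer matching, so
highly diverged telomere variants (> ~10% of copies mutated) fall below the
identity floor; centromere calls are window-aligned and single (monocentric
assumption); the anchoring module is a simplified stand-in and does not
attempt conflict resolution; `repeat_fraction`/density computations trust
the input annotations entirely.
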