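# Methods

## Coordinate and interval conventions

All internal coordinates are 0-based half-open (the BED convention);
GTF gene records (1-based closed) are converted on read, so a GTF gene
spanning 1–10 becomes the interval [0, 10). "Intersect by at least one
nucleotide" therefore means overlap length ≥ 1: book-ended intervals
(end == next start) do **not** merge by default, with a
`merge_bookended` flag to flip that reading. Strand is parsed but
ignored by all contact and association logic — the procedure is
strand-agnostic. Chromosome names match by exact string equality (no
"chr" aliasing); a mismatch between reads and annotation is surfaced as
a warning with per-chromosome counts rather than silently dropping
reads.

## Contact calling

Within each replicate, reads are merged into the connected components
of their overlap graph by a sort-and-sweep; the component's count is
the number of reads it contains (read-count coverage, not base-level
depth — fragments are scored by their covering reads). Reproducibility
is then evaluated on merged per-replicate fragments: the bipartite
cross-replicate overlap graph is resolved into connected components,
each two-replicate component becomes one candidate spanning the union
of its members, and one-replicate components are dropped. The union
(rather than intersection) defines the retained coordinates: a
contact's extent is the full region either replicate supports, and the
downstream ±2.5 kb extension makes the distinction immaterial for gene
association in practice.

A candidate's `mean_coverage` is the arithmetic mean of its
per-replicate read counts, retained iff mean ≥ `min_mean_coverage`
(default 40). The comparison is inclusive — the detection threshold is
a lower bound on reliable coverage. The gene-selection threshold below
is strict (> 100) because it is phrased as an exceedance; the asymmetry
is deliberate.

Invariants the tests enforce: called fragments are disjoint and sorted
within a chromosome; raising the threshold never adds fragments; merge
and intersect agree exactly with a brute-force transitive-closure
oracle (pairwise overlap graph + connected components, and `bedtools
merge` was used as an external cross-check during development).

## Viewpoint proximity

rDNA viewpoints sit on acrocentric chromosomes; contacts overlapping
[viewpoint − r, viewpoint + r] on the viewpoint's own chromosome are
excluded as cis/near-bait artifacts. The genome-scale radius is 5 Mb;
the synthetic study scales it to 500 kb on its 10 Mb chromosomes. The
filter is a standalone stage returning a (kept, excluded) partition, so
it can be applied before or after gene selection; the pipeline applies
it immediately after calling.

## Gene association and selection

Each fragment is extended by `extension_nt` = 2,500 nt on **each** side
(total +5 kb), clipped at chromosome bounds — the per-side semantics
follow read-extension quantification conventions; a fixed-5 kb-window
alternative is available via `fixed_window`. A fragment counts fully
toward every gene body its extension overlaps by ≥ 1 nt (integer
multi-overlap counting, no fractional assignment); a gene's
`total_reads` sums both replicates' reads over its fragments (a
mean-based mode is available via `count_mode`). Selection keeps genes
with `total_reads` strictly greater than 100, ranked by total
descending with lexicographic tie-break.

The count matrix quantifies each (condition, replicate) sample
separately under the same extension rule, includes all-zero rows, and
is meant for export to a dedicated count-based differential package;
the companion `log2fc_table` is descriptive only (library-size scaling,
pseudocount 1, no inference).

Contact-site genomic context is reported by assigning each fragment
center the highest-precedence annotation class containing it
(precedence configurable, e.g. exon > intron > LINE), with
"intergenic" as the fallback; fractions sum to 1.

## Replicate QC

Merged fragments supported by exactly one read (singleton contacts) are
removed; surviving reads are assigned to fixed genomic bins (10 kb
default) by midpoint, each replicate's bin vector is RPKM-normalized
(count / ((bin_length/10³)·(total/10⁶))), and the Pearson correlation
over all bins is reported. Zero variance in either vector raises an
error rather than returning a meaningless coefficient. RPKM makes the
statistic invariant to uniform scaling of one replicate's counts.

## Gene-list overlap null

The reference list is the first k elements of one seeded shuffle of the
N-element universe; each of m repetitions re-shuffles and counts the
intersection of its first k elements with the reference. Sampling a
uniform k-subset is implemented with numpy's partial (Floyd-style)
`Generator.choice(N, k, replace=False)` — distributionally identical to
taking the first k positions of a full Fisher–Yates shuffle while
touching only k entries, which is what makes m = 100,000 repetitions at
N = 47,234, k = 4,920 run in seconds. The exact distribution of the
overlap is Hypergeometric(N, k, k), giving mean fraction k/N and the
closed-form sd used as the simulation's oracle; for N = 47,234,
k = 4,920 that is 0.10416 ± 0.00412. The empirical p-value is the
add-one estimator (b+1)/(m+1), one-sided for enrichment, bounded below
by 1/(m+1). All randomness flows through a named, seeded generator
(`numpy.random.Generator(PCG64)`, recorded in output metadata); no
global RNG state is touched.

## Metaprofiles

Fragment centers are floor((start+end)/2). Windows of ±`half_width`
(default 1,500 bp) are divided into `bin_size` (default 50 bp) bins —
the bin size is this package's choice, as plotting tools in this space
do not fix one — and each bin takes the length-weighted mean of the
overlapping track steps (uncovered bases contribute 0). Windows
crossing a chromosome edge are dropped and counted, not zero-padded,
since padding biases the mean. The z-score standardizes the mean
profile against the per-window mean signal of `n_background_windows`
(default 1,000) uniformly placed, seeded windows of the same width;
this random-window background is this package's documented convention
for standardization, with the seed recorded in the output. A constant
track has background sd 0 and raises an error, as the z-score is
undefined. Forward- and reverse-strand small-RNA tracks are profiled as
two independent tracks; no strand flipping is applied because contact
fragments are unstranded.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions every recovery test runs
under. Defaults: three 10 Mb chromosomes, the first acrocentric with
one viewpoint at 1.5 Mb and a 500 kb cis-exclusion radius; restriction
fragments every 4 kb (grid mode; sequence mode instead places sites at
exact GAATTC matches of a generated sequence, matching the six-cutter
EcoRI chemistry); 200 genes with lognormal lengths (median ≈ 15 kb) and
10% each labeled lincRNA, miRNA, ZNF; 50 reproducible contacts, 10
sub-threshold, 10 one-replicate-only, 30 singletons, 4 cis-proximal.
These scales keep the full pipeline in seconds while leaving every
class populated enough to measure exact recovery.

Each planted fragment occupies its own restriction fragment, so reads
from different contacts can never merge. Per-replicate counts for
reproducible contacts are floor + negative binomial (overdispersed
counts being the standard model for sequencing coverage, and the floor
guaranteeing separability from the threshold-40 decision): the
high-coverage class (60% of contacts) uses 60 + NB(15, shape 8), so
two-replicate totals exceed the 100-read gene threshold; the
low-coverage class draws each replicate uniformly in [40, 48], called
(mean ≥ 40) but never selected (total ≤ 96). Sub-threshold decoys draw
[5, 35] per replicate (mean < 40 by construction). Condition 2 rewires
a configurable 30% of reproducible contacts: half gain (counts ×3),
half lose (counts to [5, 15], dropping below threshold) — emulating
contact rewiring after a perturbation such as heat shock. Reads are
tiled evenly across the planted interval (first read at the start, last
ending at the end) so the merged read span reproduces the planted
interval exactly and counts are conserved; optional jitter perturbs
interior reads.

Ground-truth gene totals and the expected selected list are derived at
generation time by applying the same extension/overlap rule to the
planted geometry, so end-to-end tests assert set equality, not
approximate recovery. The `high_concordance()` variant removes
one-replicate-only contacts — the non-shared signal component — to
emulate well-correlated biological replicates of a single library
(r ≈ 0.99 at the defaults).

What the generator does **not** emulate: sequence-level library
artifacts (primers, ligation junctions, PCR duplicates), mappability
and GC biases, distance-decay of cis contact frequency, overlapping
planted contacts, or genome-scale interval densities. Passing recovery
tests therefore demonstrates correctness of the interval algebra,
thresholds and statistics under separable planted signal — not
robustness to alignment artifacts or to contacts straddling the
detection threshold, which on real data will produce boundary-sensitive
calls.

## Pipeline and determinism

One validated YAML config drives all stages; defaults (threshold 40,
±2,500 nt, >100 reads, 5 Mb radius, ±1,500 bp) are injected when
absent, and every violation is reported with its field path. Outputs
carry a SHA-256 hash (first 16 hex digits) of the canonical config;
reports contain no timestamps, so a rerun with the same config and
inputs is byte-identical. Stage failures abort with the stage name;
earlier outputs remain on disk.

## Known limitations

* Exactly two replicates are supported in calling (the design under
  emulation); all-pairs reproducibility for more replicates would be a
  config extension.
* Per-gene counting is O(fragments × genes per chromosome); fine at
  contact-fragment densities (thousands), not built for tens of
  millions of intervals.
* The descriptive log2 fold change is not a differential test — export
  the count matrix to a count-model package for inference.
* bigWig ingestion is not implemented; convert to bedGraph first.
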