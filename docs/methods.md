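# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the field leaves the
choice open.

## Read-structure parsing

Read 1 is consumed left to right as a sequence of typed segments
(barcode, UMI, linker, discard). Built-in presets:

| platform | layout |
|---|---|
| visium | barcode 16 + UMI 12 |
| slide_seq_v1 | barcode 8 + bridge 18 + barcode 8 + UMI 8 |
| slide_seq_v2 / curio_seeker | barcode 8 + bridge 18 + barcode 7 + UMI 9 |
| stereo_seq | barcode 25 + UMI (configurable, default 10) |

The Stereo-seq chemistry fixes only the 25-nt coordinate barcode; the UMI
length is exposed as `stereo_umi_len`. The Slide-seq bridge defaults to
the published 18-mer `TCTTCAGCGTTCCCGAGA` and is compared by Hamming
distance with `max_mismatch = 3` — tolerant enough for a long fixed
sequence, strict enough not to accept random sequence (the chance of a
random 18-mer passing is ≈ 2×10⁻⁷). At most one `N` is allowed in
barcode + UMI combined (`max_n = 1`); `N` counts as a mismatch in every
comparison. Rejection (too short, linker mismatch, too many `N`s) is a
counted return state, never an exception, and the reformatter's tallies
satisfy passed + Σ rejected = total pairs by construction.

The header contract is `<barcode>_<umi>#<original_id>`, with
multi-segment barcodes concatenated in segment order without separators.
`_` and `#` each occur exactly once, so the encoding is invertible after
alignment from the SAM query name. This is this package's own contract,
chosen for unambiguous parseability.

## Stereo-seq deconvolution

The coordinate map (TSV `barcode, x, y` or an HDF5 dialect of parallel
`barcodes`/`x`/`y` datasets — our own documented layout, since the vendor
format is proprietary) is held as a hash map. Lookup is exact by default;
`rescue_1mm` optionally accepts a barcode whose single-substitution
neighborhood contains exactly one map key (two or more → rejected as
ambiguous). Exact hashing is the default because production maps have
billions of keys and rescue costs 75 probes per miss at L = 25. The
emitted location token `<x>x<y>` is treated downstream as an opaque
barcode until coordinate matching parses it back.

## Barcode demultiplexing

A barcode is assigned to the allow list by (1) exact membership, then
(2) the unique entry at the minimal Hamming distance ≤ `max_dist`
(default 1); a tie at the minimal distance is ambiguous and the read is
left unassigned — correction never guesses. For `max_dist = 1` the search
enumerates the 3L+1 single-substitution variants against a hash set, so
the cost is independent of allow-list size; `max_dist = 2` extends the
enumeration pairwise. Raising `max_dist` can only convert unmatched or
ambiguous reads into assignments, so exact + corrected is monotone in
`max_dist` (property-tested against a brute-force distance table).

For random-barcode platforms without a fixed allow list, the observed
top-k rule selects the `expected_locations` most frequent barcodes,
breaking count ties lexicographically for determinism.

## Gene assignment

GTF/GFF3 annotations are converted to 0-based half-open coordinates at
the parse boundary (gffutils does the format handling; exons resolve to
genes via `gene_id` attributes or GFF3 `Parent` chains) and merged into
per-gene exon models. Alignment blocks are queried against an interval
tree of gene spans. Category resolution order, for a primary alignment:

1. unmapped flag → *unmapped*;
2. exon overlap of exactly one gene ≥ `min_overlap_frac` (default 0.5)
   of the aligned length → *exon*, with that gene; two or more → *ambiguous*;
3. otherwise span overlap with exactly one gene → *intron*; two or more
   → *ambiguous*; none → *intergenic*.

Exon uniqueness is resolved before span membership, so a read inside one
gene's exon and another gene's intron is exonic — the alternative
(ambiguous-first) would discard cleanly assignable reads. Strand
agreement (read strand = gene strand) is required by default in genome
mode and ignored in probe mode, where each reference sequence name *is*
the gene. Multi-gene overlap is ambiguous rather than fractionally
assigned, matching the report's category taxonomy. Secondary and
supplementary alignments are ignored; category totals therefore sum to
the number of primary records.

## UMI deduplication

Within each (location, gene) group — UMIs are never compared across
groups — a directed edge u → v exists when Hamming(u, v) ≤ `hamming_max`
(default 1) and reads(u) ≥ 2·reads(v) − 1. This is the established
directional-adjacency criterion formalizing "one UMI has substantially
more reads than the other": a sequencing error in a duplicate copy
produces a neighbor with far fewer reads than its parent, while two real
molecules that happen to be neighbors typically have comparable counts.
Nodes are processed in descending read count with lexicographic
tie-breaks, each unassigned node rooting a cluster that absorbs all
unassigned nodes reachable through qualifying edges; molecule count =
number of roots. The deterministic order makes results bit-reproducible.
At `hamming_max = 0` the rule reduces to exact-UMI counting. The
duplication histogram counts total member reads per surviving molecule,
so Σ k·hist[k] equals the input read count exactly (tested as an
invariant, plus equivalence with an exhaustive-edge brute-force oracle on
all groups of ≤ 8 UMIs).

## Location matching

Matrix columns are restricted to barcodes with known coordinates: layout
table for fixed and bead chips, parsed tokens for Stereo-seq. Unmatched
columns are dropped with their counts logged, never imputed; matched
columns keep their counts untouched (column-sum preservation is tested).
Coordinates follow image-style ordering — x in µm rightward along
columns, y in µm downward along rows — documented in the exported
`positions.csv` header. The synthetic Visium-like layout uses offset rows
with exactly 100 µm horizontal center-to-center spacing and 55 µm spot
diameter; the vertical row pitch is 100·√3⁄2 ≈ 86.6 µm, the close-packed
hexagonal choice, since only the horizontal spacing is pinned by the chip
specification. No proprietary chip barcode tables are bundled; real runs
supply their own layout CSV.

## QC filtering

**max_slope.** Locations are ranked by total UMI count (descending,
positives only, ≥ 10 required). On log10–log10 axes the slope between
adjacent ranks i, i+1 is (log c(i+1) − log c(i)) / (log(i+1) − log i);
the knee is the rank minimizing it (steepest drop, ties to the smallest
rank) among candidate ranks inside the fractional `ratio_window`. The
threshold is c(knee) and locations with total ≥ threshold pass. The
window is how the "ratio" tuning parameter is interpreted here: it bounds
where the transition is sought. That matters in practice because integer
count drops deep in the tail (2 → 1 between the last ranks) are as steep
on log axes as the tissue/background transition; a window like
(0.1, 0.9) keeps the search where the transition can actually be.

**empty_test.** A Monte-Carlo ambient-profile test in the spirit of
empty-droplet detection, deliberately simplified (no knee-anchored
retain-always set, no Dirichlet overdispersion). The ambient profile is
the per-gene sum over locations with total ≤ `ambient_max_count`
(default 10 — low enough to exclude tissue, high enough to pool a stable
profile), plus a 0.5 pseudocount per gene to avoid log 0, normalized.
For a location with depth t and counts y the statistic is
D(y) = −Σ_g y_g log(ambient_g), large when composition deviates from
ambient; the null is `mc_iterations` multinomial draws of size t from
the profile and p = (1 + #{D_sim ≥ D_obs}) / (mc_iterations + 1), the
standard never-zero Monte-Carlo estimator. FDR is Benjamini–Hochberg
across tested locations; a location passes when p ≤ `p_cut` **or**
FDR ≤ `fdr_cut` (the OR-combination is the documented behavior of the
method this mirrors). The generator is seeded; reruns are identical.
Because the ambient profile is estimated from the data, null p-values
are approximately — not exactly — uniform; on pure-ambient simulations
the 5%-level rejection rate stays within binomial bounds of nominal at
the tested sizes (200 locations, depth ~8, 100 genes, 2000 iterations).

## Synthetic data

The generator emulates: per-location molecule counts
~ Poisson(`mean_molecules_per_location`), split over genes by a
per-location Dirichlet(0.1) profile (sparse, location-specific — tissue);
empty locations draw Poisson(mean × `ambient_fraction`) molecules from
one shared Dirichlet(5) profile (flat — ambient); UMIs unique within
their (location, gene) group; PCR duplication as 1 + geometric extra
copies; single-base UMI errors on duplicate copies and single-base
barcode errors per read at the configured rates; read 2 drawn from the
source gene's exon sequence on the gene's strand. Default study
conditions: 50 tissue + 50 empty locations, 100 genes, 100 molecules per
location, PCR duplication 0.5, 1% barcode / 2% UMI error rates, 5%
ambient fraction.

The truth SAM places each read 2 at its true locus with the reformatted
header already applied, so the pipeline runs without an external aligner;
read names carry the *observed* (error-injected) barcode and UMI, which
is exactly what reformatting the corrupted FASTQ would produce. For
Stereo-seq the truth SAM carries the true location token (deconvolution
tests run on the FASTQ path instead, since reads that fail deconvolution
would never reach the aligner).

Not emulated: quality-dependent sequencing errors, indels, fragment-length
variation, splice-junction-spanning reads, intronic/intergenic reads,
barcode swapping between spots, and tissue spatial autocorrelation.
Passing tests therefore demonstrate correctness of the bookkeeping and
the error-correction rules under the stated error model — not robustness
to alignment artifacts or chemistry effects absent from the simulator.
All randomness flows from one seed; FASTQ/SAM outputs are byte-identical
across reruns (gzip timestamps pinned to zero).

## Orchestration

The flat `key = value` config mirrors the platform-conditional inputs:
polyA (genome-mode) runs need `fasta` + `annotation`; Stereo-seq needs
`coordinate_map`; Slide-seq/Curio need `coordinate_csv`. Unknown keys
warn, missing required keys fail naming the key and rule. Batches must
share one platform and species (checked before any work); samples run
independently — own output directory, no shared mutable state — up to
`threads` concurrently, so parallel and serial runs produce identical
outputs, and one sample's failure never aborts the rest. Stage
provenance is logged as stable `sample= stage= wall= sha256=` lines.
`max_reads` truncates input for smoke runs.

## Export

MatrixMarket: genes × locations, 1-based integer coordinate format in
column-major order, with `features.tsv`, `barcodes.tsv` and
`positions.csv` (`barcode,in_tissue,array_row,array_col,x_um,y_um`) —
the 10x-style interchange layout that R containers ingest directly.
h5ad: locations × genes with coordinates in `obsm["spatial"]`, `qc_pass`
in `obs`, and run metrics in `uns` — the Python ecosystem convention.
Both orientations are deliberate; cross-format count equality is tested.

## Problem sizes in the test and acceptance suites

Simulated fixtures use 20–100 locations, 25–100 genes and 40–100
molecules per location — small enough for sub-minute suites while every
rule still sees hundreds to thousands of reads; the accuracy checks
(≥ 99% dedup recovery, ≥ 99% barcode correction, binomial bounds on QC
type-I error) are computed at exactly the simulation conditions stated in
their docstrings.

## Known limitations

- BAM input for Slide-seq-style runs is consumed through the same
  SAM/BAM reader as everything else; pre-existing BC/UB auxiliary tags
  are not read — tags travel in the read name contract.
- The empty-location test is intentionally simpler than the full
  published empty-droplet algorithm and should be read as a screening
  filter, not a calibrated cell caller.
- Probe mode trusts reference names as gene identifiers; a malformed
  probe reference silently becomes a gene universe.
- The interactive region-of-interest selection, clustering/embedding and
  image-registration features of full commercial workflows are out of
  scope.
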