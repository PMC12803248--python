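# Methods

## The demultiplexing model

A split-pool library labels each nucleus with a triple of well barcodes
(rounds 1–3, 8 nt each) attached during in-well reverse transcription
(round 1) and two ligation rounds (2–3). Read 2 carries the label and a
10-nt UMI at fixed offsets, with two static ~30-nt linker sequences between
the barcode segments; read 1 carries transcript sequence. Demultiplexing
is therefore a fixed-position extraction problem, not an alignment problem:
the only inference steps are (i) confirming the offsets and (ii) correcting
sequencing errors in the barcodes.

**Position learning.** For each linker we scan a sample of read 2
(default 10 000 reads) for the leftmost window with the fewest mismatches,
count a read as matching when that minimum is ≤ `linker_mismatch_allowance`
(default 1), and adopt the modal start offset. Two guards reject
pathological inputs: each linker must be found in ≥ 10% of the sample, and
the modal offset must cover ≥ 50% of the matching reads (otherwise the
offset histogram is reported). Barcode and UMI offsets are then anchored to
the linkers: bc3 ends where linker A starts, the UMI precedes bc3, bc2
follows linker A, bc1 follows linker B. The scan is vectorized over a
padded byte matrix, so learning costs well under a second at the default
sample size.

**Barcode correction.** An observed 8-mer is assigned to the unique
whitelist entry at minimal distance ≤ *e* (default *e* = 1). Distance is
Hamming by default: the offsets are fixed, so substitutions are the error
mode the design anticipates. A tie at the minimal qualifying distance is
*ambiguous* and discards the read — with a whitelist of minimum pairwise
distance *d*, correction is guaranteed unambiguous iff *d* ≥ 2*e* + 1, and
whitelist validation warns when the configured tolerance violates this.
`N` counts as a mismatch against every base; any `N` in the UMI fails the
read (UMIs are never corrected, so an `N` there would fabricate a
molecule). The production path precomputes every sequence within distance
*e* of the whitelist (alphabet ACGTN) into a hash table, making correction
one dictionary lookup; the exhaustive-scan implementation is retained as
the reference and the two are cross-checked in the tests.

An optional Levenshtein metric (via edlib) is provided for libraries with
indel-prone chemistry. It computes full-alignment distance on the
fixed-length barcode slice; it does **not** re-anchor downstream offsets
after an indel, so a single indel early in read 2 still shifts later
segments. This is a deliberate simplification: proper resynchronization
would require per-read linker re-location, and the default Hamming path —
the mode actually matched to this read layout — never needs it.

**Failure taxonomy.** Each read resolves to `pass` or one reason:
`read_too_short`, `no_match_round{1,2,3}`, `ambiguous_round{1,2,3}`,
`umi_invalid`. Rounds are checked in round order (1, 2, 3), so the first
failing round names the reason. Metrics satisfy exact conservation
(`reads_total = reads_pass + Σ fail reasons`), checked at the end of every
run.

**Parallelism and determinism.** Input pairs are partitioned into
consecutive bins of `bin_size` records (default 1 000 000) by record
index — never by file offset — and bins are dispatched to a process pool
of `threads` workers. Outputs are concatenated in bin-index order, so the
merged FASTQ is byte-identical for any thread count; thread-count
invariance is an asserted property, not an aspiration. Mate files are
streamed in lock-step and a record-count discrepancy aborts at the first
unmatched index.

**Annotation.** Passing reads append `|<bc1>.<bc2>.<bc3>|<UMI>` to the
read-1 ID token (the `|` delimiter does not occur in instrument read
names; parsing splits from the right so it is unambiguous even if it did).
An optional sublibrary tag joins the cell label so separately indexed
sublibraries can be merged without label collisions. Barcodes with fewer
than `m` reads (default 200, the production setting) are dropped after
demultiplexing and before counting; low-read barcodes are dominated by
ambient molecules and index hopping, and removing them early bounds matrix
size.

## Counting

Gene assignment is consumed as a `read_id → gene_id` table — the
mapping/feature-assignment stage is external by design, and a text
interface keeps the tool testable without aligners. Reads aggregate by
exact (cell, gene, UMI); *unique* collapse counts distinct UMIs, and
*directional* collapse builds the standard adjacency graph (edge u → v
when Hamming(u, v) = 1 and reads(u) ≥ 2·reads(v) − 1) and counts the
clusters grown greedily from the highest-count unassigned UMI. Ties in
read count break lexicographically so the result is deterministic. Unique
is an upper bound on directional in every group; both are validated
against an independent graph-reachability oracle. The matrix is a scipy
CSR with lexicographically sorted gene and cell name vectors, so
construction is order-invariant; I/O is the MatrixMarket trio
(`matrix.mtx`, `features.tsv`, `barcodes.tsv`).

QC applies three filters in a fixed order: (1) cells with total UMIs
< 500; (2) genes detected in < 10 remaining cells; (3) cells with
mitochondrial fraction > 5% or total UMIs > 15 000, computed on the matrix
entering step 3. The outcome is order-sensitive (a removed gene changes
later totals), so the order is fixed and every removal is recorded in the
QC report, which reconciles exactly with the dimension change. The
mitochondrial fraction is computed on UMI counts rather than raw reads —
the count matrix is the only post-collapse object available — and a cell
exceeding both the mito and UMI ceilings is counted once, under mito.

## The simulator

The generator emulates exactly the structure the pipeline depends on:
whitelists drawn at a guaranteed minimum pairwise distance (default 3;
rejection-sampled 8-mers), a seeded random pair of 30-nt linkers recorded
in the emitted run config (the real linker sequences are proprietary to
the chemistry and not public, so simulation and demultiplexing share one
layout by construction), cells as well-triples sampled without replacement
(48 × 96 × 96 wells by default, mirroring the plate design), a fixed
number of molecules per cell (gene uniform, UMI uniform 10-mers), and
reads drawn uniformly from each cell's molecules (fixed count per cell by
default; negative binomial optional). Read 1 is a 106-nt fragment of a
random 500-nt transcript; quality strings are constant placeholders
because correction ignores quality.

Error modes: i.i.d. per-base substitutions at a stated rate (optionally
restricted to barcode segments), or exactly *k* substitutions in one
randomly chosen barcode segment per read — the regime that probes the
correction boundary (*k* = 1 with distance-3 whitelists is always
recoverable at *e* = 1; *k* = 2 with distance-5 whitelists is never).
Junk reads are uniform random sequence drawn per read with the stated
probability; their realized count is recorded in truth.

The truth tables record, per read, the cell, gene, UMI, injected error
positions and junk status; the truth matrix is the unique-UMI collapse of
the molecules observed in at least one read (a molecule that drew no read
is invisible to any pipeline, so including it would make exact round-trip
recovery undefined rather than falsifiable). Everything derives from one
`numpy` generator, so identical parameters and seed give byte-identical
outputs.

What the simulator does *not* model — and what passing tests therefore do
not show about real data: base-quality structure, indels, barcode
cross-contamination and hopping, ambient RNA, doublets, gene-length and
expression-level bias, and mapping ambiguity in the external alignment
stage. The simulator certifies the bookkeeping and the correction
mathematics, not the chemistry.

## Numerical and design choices

- Offsets are 0-based, end-exclusive everywhere.
- Whitelist files are two-column TSV with an auto-detected optional header;
  re-serialization is lossless.
- Default run parameters mirror the production settings (*e* = 1,
  *m* = 200); `threads` defaults to 1 and `bin_size` to 10⁶ pairs, which
  bounds resident memory to one bin per worker.
- The UMI length is a layout parameter (default 10) and is never assumed
  elsewhere.
- Acceptance-scale runs use 200-cell / 20 000-read libraries (100 000
  pairs for the thread-invariance check); these sizes exercise every code
  path — multi-bin parallel merging included — while keeping the full
  verification suite under a minute of compute.

## Known limitations

- The Levenshtein option does not resynchronize offsets after indels (see
  above).
- Min-read filtering counts demultiplexed reads, not aligned reads; a
  pipeline that filters post-alignment will retain slightly different
  barcode sets near the threshold.
- QC step order is fixed; applying the mito/ceiling filters before the
  gene filter would change results near the boundaries (the order used is
  recorded in the QC report).
- One invocation handles one sublibrary; merging across sublibraries is
  the caller's concern (the sublibrary tag keeps labels disjoint).
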