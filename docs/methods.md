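# Methods

This note documents the procedures scatterbam implements, the assumptions
they rest on, the parameters that matter, and the design choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Formats and coordinates

BGZF, BAM v1 and BAI are implemented exactly as the SAM/BAM format
specification lays them out: gzip members with the `BC` extra subfield
(total block size − 1 in 16 bits), little-endian binary records with
`MIDNSHP=X` CIGAR coding and 4-bit packed sequences, and the
binning-plus-linear BAI layout with pseudo-bin 37450 carrying per-reference
mapped/unmapped counts. Internally every coordinate is 0-based, half-open;
1-based numbers appear only at the VCF/CSV/CLI boundary. Tag bytes are
carried opaquely and round-tripped untouched — no consumer in this package
reads them.

Numerical/format choices:

* **Written blocks use DEFLATE level 6**, zeroed `MTIME`/`XFL` and OS byte
  `0xff`, so `write_block` is byte-deterministic and `write_block(b"")` is
  exactly the canonical 28-byte end-of-file marker. Determinism at a fixed
  level is part of the writer contract (byte-exact fixtures and tests).
* **The streaming writer flushes at 65280 bytes** (htslib's `0xff00`
  convention). The format caps a whole compressed member at 65536 bytes, so
  an incompressible payload near 65535 bytes cannot be framed at all;
  flushing early leaves headroom, and `write_block` raises a size error in
  the residual impossible cases rather than emitting an invalid block.
* **CRC32 is always verified** on block decode; there is no lazy mode. The
  boundary scanner relies on decode failures to reject false block starts,
  so a permissive reader would silently weaken it.
* **A mapped record whose CIGAR consumes zero reference bases is treated as
  spanning one base** for indexing, window assignment and overlap tests, so
  zero-width intervals cannot vanish from a partition.
* **Quality 255 means "missing", not "low"**: it passes any base-quality
  threshold in the pileup.
* **The `bin` field is recomputed on write** from the record's coordinates
  rather than trusted from input.
* **Virtual-offset representation at block boundaries.** A stream position
  at the exact end of a block can be written `(block, payload_len)` or
  `(next_block, 0)`; both denote the same byte. Readers report the
  start-of-next-block form (it is what record-start offsets need); the
  writer's end offsets may use the other form. Indices built through the
  two paths are therefore query-equivalent but not guaranteed byte-equal,
  and tests compare them by query results.
* **Linear-index gaps**: windows no record overlaps hold `None` in memory
  and are filled with the next non-empty window's offset at serialization
  time (a tighter, still-safe lower bound than filling backwards). After a
  round-trip through the on-disk format, filled entries are
  indistinguishable from occupied ones, so `window_start_offsets` on a
  *read* index reports every serialized entry; only on a freshly *built*
  index does it report exactly the non-empty windows.

## Boundary scanner

For files without an index (unsorted/unindexed BAMs, or the unplaced tail
that no BAI covers), parse start points are recovered in two layers:

1. **Block layer** — scan raw bytes for the 4-byte BGZF magic; accept an
   offset only if the full member test-inflates with matching CRC32 and
   ISIZE. Magic bytes occur by chance inside compressed payloads (~1 in
   2³² per position), and the test-inflate eliminates them.
2. **Record layer** — scan the inflated payload for an offset where
   `k_confirm` consecutive candidate records all validate, each beginning
   exactly where the previous one's declared `block_size` ends. The
   per-candidate predicate checks: `block_size ∈ [32, 2²⁵]`; refID and mate
   refID within the header's reference count; positions within the named
   reference (−1 allowed); read-name length in [1, 255] with a NUL byte at
   its declared end; every CIGAR op code ≤ 8; `l_seq ∈ [0, 2²⁸]`; and that
   the computed fixed+variable field sizes fit `block_size`.

Each check is cheap and individually weak; the chained conjunction makes the
false-positive probability on arbitrary bytes negligible, and the test suite
enforces soundness empirically against writer-recorded truth (500 randomized
probes, zero false positives required). `k_confirm` defaults to 4 and is
configurable: one or two links leave measurable false-positive risk on
adversarial payloads, four passed the zero-false-positive budget. Scanning
is left-to-right and the earliest validating offset wins, for determinism.
A chain cut short by the true end of data (at least one fully valid record,
ending exactly at the final byte) is accepted, so files with fewer records
than `k_confirm` past the last probe remain scannable. The scanner tolerates
a missing EOF marker and skips blocks that fail CRC, which is what makes
truncated or partially corrupted files scannable at all; it never attempts
to repair a corrupted block.

The probe set always includes the region start (first record after the
header, or the tail start), so the segments between consecutive hits cover
the stream exactly: parsing them independently and concatenating reproduces
the sequential parse with no loss and no duplication.

## Scatter/gather engine

Windows are 16384 bp because that is the exact granularity of the BAI
linear index: every window start maps to a virtual offset a worker can seek
to. The constant is configurable at the engine level for tests only; all
BAI I/O uses 16384.

* **Assignment rule**: a record belongs to the window containing its
  alignment start. Boundary-overlapping reads therefore land in the earlier
  window only — the start is unique per record, so windows partition the
  file and gather stages may simply sum.
* **Job sizing**: contiguous windows (or runs of consecutive SNP sites) are
  grouped greedily until the compressed bytes they span — estimated from
  merged BAI chunk extents — reach `total / n_jobs`; windowed pipelines aim
  for about 4 jobs per worker (load balancing without oversubscription).
  The estimate is monotone in the interval and sub-additive over adjacent
  regions, which is all the greedy accumulation needs.
* **Execution**: a thread pool runs workers that are pure functions of
  their job; results merge in job-ordinal order regardless of completion
  order. Output is consequently byte-identical for any worker count — the
  contract every pipeline in this package is tested against. A worker
  exception is re-raised carrying the failing job's ordinal and cancels the
  remaining jobs. Threads were chosen over processes so workers can share
  the in-memory compressed buffer without pickling; the engine contract
  (purity + ordered merge) does not depend on the pool type. `--threads`
  defaults to 1; the useful ceiling is hardware-dependent and is left to
  the user rather than auto-tuned.

## flagstat

Per-window counters with componentwise-additive merge (commutative,
associative, zero identity). Category semantics mirror samtools flagstat's
classic 13-line report: `mapped` excludes UNMAP; secondary/supplementary
records are excluded from all pairing counters; `properly paired` requires
PAIRED ∧ PROPER_PAIR ∧ ¬UNMAP; singletons are mapped reads with unmapped
mates; the `mapQ>=5` line gates the different-chromosome count on mapping
quality. samtools has since added "primary" lines to its output; the
numeric cross-validation test parses only the categories both report.
Unplaced records (refID −1) sit past the indexed region and are counted via
scanner-partitioned segments, so `total` covers every record exactly once.

## snp-pileup

Sites come from the CHROM/POS/REF/ALT columns of a VCF (plain or gzip);
rows whose REF or ALT is not one single A/C/G/T base are skipped with a
logged count. Duplicate coordinates are all retained and judged
independently — in particular a bi-allelic row whose earlier duplicate was
not a valid SNP is still processed (the stock FACETS tool skipped it; this
package deliberately does not reproduce that bug).

Per read, a CIGAR walk classifies what the alignment places at the site:
an aligned base (M/=/X), a spanning deletion (D), or nothing (N, S, I, H, P
or no coverage). Each passing read contributes exactly one of R/A/E/D.
Reads failing the exclusion mask (default UNMAP|SECONDARY|QCFAIL|DUP) or
the mapping-quality threshold contribute nothing, as do aligned bases below
the base-quality threshold (such reads also do not consume depth budget).

**Depth-limit semantics**: with `max_depth = d > 0`, reads are considered
in file order and counting stops once `R+A+E+D = d`. This cap lives in the
per-site count structure, unlike HTSLIB's pileup iterator, which stops
*admitting* reads while full; the two disagree only in extreme-coverage
regions, where the per-site cap samples coverage more evenly. The
divergence is intentional and tested directly.

Defaults are neutral — `min_map_quality 0`, `min_base_quality 0`,
`max_depth 0` (unlimited), `min_total_depth 0` — so zero-threshold runs are
exactly comparable to brute-force oracles; all are CLI-settable. Overlapping
mate pairs are counted independently (no overlap de-duplication). A VCF
chromosome missing from a BAM header produces a zero-count row and a
warning rather than an abort, so multi-sample runs with heterogeneous
headers degrade gracefully.

## Synthetic data generator

The simulator emulates a small paired-end resequencing experiment and is
the package's only data source; its defaults are the conditions the test
suite runs under.

| parameter | default | meaning |
|---|---|---|
| `references` | chr1:120 kb, chr2:90 kb, chr3:60 kb | toy genome |
| `n_read_pairs` | 2000 | pairs before secondary extras |
| `read_len` | 100 bp | fixed read length |
| `fragment_mean` / `fragment_sd` | 300 / 40 bp | Gaussian insert size |
| `base_error_rate` | 0.001 | per-base substitution errors |
| `dup_fraction` | 0.02 | pair-level PCR-duplicate flag rate |
| `unmapped_fraction` | 0.01 | per-read unmapped rate |
| `secondary_fraction` | 0.01 | pairs receiving a secondary alignment |
| `qcfail_fraction` | 0.01 | per-read QC-fail rate |
| `indel_fraction` | 0.08 | mapped reads with an S/I/D CIGAR feature |

These rates are in the range a short-read human resequencing run typically
shows after alignment. The reference genome is an implicit deterministic
function of (reference, position) — no FASTA is emitted. At listed variant
sites, reads draw the alternate allele with the configured fraction; base
errors then perturb whatever was drawn, so injected fractions are recovered
only up to sequencing error, exactly as in real data. Base qualities come
from a two-level alphabet (35 and 12, 9:1) so threshold-monotonicity tests
have exact expected effects. A pair is properly paired iff both ends map to
one reference with fragment length within `mean ± 4·sd`. Both-ends-unmapped
pairs become refID −1 records after the placed records, exercising the
scanner-reached tail; single-end-unmapped reads are placed at their mate's
coordinate, as aligners do.

Ground truth — block boundaries, per-record virtual offsets, flag tallies
(computed by the generator's own tally code, not the flagstat module), and
per-site allele counts under zero thresholds and the default exclusion
mask — is recorded *during* generation, never re-derived by the code under
test. One `random.Random(seed)` drives everything; placement, flags,
alleles and qualities use integer/uniform draws, and fragment lengths use
its Gaussian (deterministic in CPython), so one seed gives byte-identical
output across runs.

What the simulator does **not** model: realistic error profiles
(position-dependent quality, indel error), GC/coverage bias, chimeric and
supplementary alignments, mate-overlap correlation, reference ambiguity
(every simulated site is cleanly bi-allelic), and genome-scale data
volumes. Passing tests therefore demonstrate *correctness of the machinery*
— exact partitions, oracle-equal counts, determinism — on realistic record
structure, not robustness to every artifact of production sequencing, and
they say nothing about wall-clock throughput on real hardware.

## Problem sizes

The test suite and acceptance script use fixtures of about 50k records over
three references (index/oracle and scanner checks), an ~800-record unsorted
fixture, and a ~550× micro-fixture for allele-fraction recovery (44k reads
over 8 kb). These sizes keep every oracle brute-forceable in pure Python
while still spanning many BGZF blocks, many 16-kb windows, and all flag
categories; the parallelism guarantees being tested (exact partition,
ordinal-ordered merge, thread-count invariance) do not depend on volume.

## Known limitations

* References longer than 2²⁹ − 1 bp need CSI; not supported (BAI limit).
* Long-CIGAR (> 65535 ops) records using the CG-tag convention are not
  decoded.
* The pileup counts overlapping mates twice; FACETS-style downstream use
  typically tolerates this, but it is a measurable difference from tools
  that de-duplicate overlaps.
* `span_compressed_bytes` measures merged chunk extents, so a sparse region
  sharing blocks with a dense neighbour can be over-estimated; this only
  affects load balancing, never correctness.
* Thread-based workers share one interpreter; the engine's guarantees are
  about determinism and correctness, not about speedup in CPython.
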