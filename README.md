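# scatterbam

Parallel access to BAM alignment files, in pure Python: block-level codecs,
index-driven genome partitioning, a heuristic boundary scanner for unindexed
data, and two applications built on top — flag statistics (`flagstat`) and a
multi-sample SNP pileup (`snp-pileup`, the preprocessing step of the FACETS
copy-number workflow).

## The problem

A BAM file is a BGZF-compressed stream of binary alignment records: a series
of independent gzip members (≤ 64 KiB each), addressed by *virtual offsets*
`coffset << 16 | uoffset` (compressed block start, offset within the inflated
payload). Sequential tools decompress and parse this stream one record at a
time, which leaves modern multi-core machines and fast storage idle. The
observation this package is built on is that the BAM ecosystem already
contains everything needed for safe parallelism:

* the **BAI linear index** stores, for every 16-kb genomic window, the
  smallest virtual offset of any record overlapping it — a ready-made table
  of parallel entry points for coordinate-sorted, indexed files;
* for **unindexed or unsorted** files (and the unplaced-record tail that no
  index covers), valid parse start points can be recovered heuristically:
  scan raw bytes for BGZF framing that test-inflates with a matching CRC,
  then scan the inflated payload for an offset where `k` consecutive
  candidate records all pass a structural validation predicate, each starting
  exactly where the previous one's declared size ends.

On top of both sits a deterministic **scatter/gather** engine: work is split
into jobs (groups of contiguous 16-kb windows, or runs of consecutive SNP
sites, sized by the compressed bytes they span according to the index),
workers are pure functions of their job, and results are merged in job order
— so output is byte-identical for any worker count.

Reads that overlap a window boundary are assigned to the *earlier* window
(the one containing their alignment start), which makes the window counts a
partition: summing per-window flag tallies reproduces the sequential answer
exactly.

For the pileup, each site accumulates per-sample counts (R, A, E, D) =
(reads supporting the reference allele, the alternate allele, another
substitution, a deletion spanning the site); the variant allele fraction is
`A / (R + A)`. The depth limit is built into the per-site count structure:
every overlapping read is considered in file order and counting simply stops
once `R + A + E + D` reaches the cap — not the pileup-iterator admission
scheme HTSLIB uses, a deliberate divergence that yields more even coverage
in extreme-depth regions.

Everything is testable offline: a built-in simulator emits coordinate-sorted
(or deliberately unsorted) BAMs with paired-end reads, duplicates, QC
failures, secondary and unmapped records, and injected SNP alleles — and
records ground truth (block boundaries, record virtual offsets, flag
tallies, per-site allele counts) *while generating*, so oracles never depend
on the code under test.

## Worked example

```sh
$ scatterbam simulate --seed 3 --pairs 2000 --out demo
$ scatterbam flagstat demo.bam --threads 4
3983 + 31 in total (QC-passed reads + QC-failed reads)
14 + 0 secondary
0 + 0 supplementary
85 + 1 duplicates
3949 + 31 mapped (99.15% : 100.00%)
3969 + 31 paired in sequencing
1982 + 18 read1
1987 + 13 read2
3901 + 31 properly paired (98.29% : 100.00%)
3901 + 31 with itself and mate mapped
34 + 0 singletons (0.86% : 0.00%)
0 + 0 with mate mapped to a different chr
0 + 0 with mate mapped to a different chr (mapQ>=5)
```

Each line is `QC-passed + QC-failed <category>` over all 4014 records of the
simulated file (2000 pairs plus secondary alignments and a handful of
unplaced reads, which are reached through the scanner rather than the
index). The same command with `--threads 1` prints the identical report.

```sh
$ scatterbam snp-pileup demo.vcf demo.csv demo.bam --threads 4
$ head -3 demo.csv
Chromosome,Position,Ref,Alt,File1R,File1A,File1E,File1D
chr1,50001,A,C,1,1,0,0
chr2,30001,G,T,1,0,0,0
```

At chr1:50001 the simulator injected the alternate allele C at fraction 0.5:
of the 2 usable reads covering the site, 1 supports A and 1 supports C (VAF
0.50; coverage is shallow at 2000 pairs over 270 kb — the test suite uses a
~550× fixture for fraction recovery). Passing several BAMs appends one
`FileNR,FileNA,FileNE,FileND` quartet per sample.

The same operations are available as a library:

```python
from scatterbam import BamFile, flagstat, format_flagstat

bam = BamFile("demo.bam")                 # loads demo.bam.bai automatically
print(format_flagstat(flagstat(bam, n_threads=4)))
for rec in bam.fetch("chr1", 49_900, 50_100):
    print(rec.read_name, rec.pos, rec.cigar)
```

## Scope

CRAM, CSI/tabix indices, remote URLs, SAM text, tag decoding, mate-overlap
de-duplication in the pileup, and any downstream FACETS segmentation are out
of scope. See `docs/methods.md` for the model of the simulator, parameter
defaults, and numerical/design choices.
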