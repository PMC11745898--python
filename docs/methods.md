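# Methods

## The representation

A dataset is a pair of locus-sorted matrices over a shared, ordered sample
list:

* the **reference matrix**, whose rows are `(locus, {sample: block})` — each
  block a run-length encoded interval of homozygous-reference calls with
  fields `LEN` (span in bp), `DP`, `GQ`, and optionally an `LGT`;
* the **variant matrix**, whose rows are multiallelic sites: a locus, a
  global allele list (reference at index 0, alternates at index i+1), and at
  most one genotype per sample.

A genotype stores `LA` (injective local→global allele map, first element 0),
`LGT` (call over local indices), `LAD` (LR-numbered: one depth per local
allele including the reference), `LPL` (LG-numbered: one Phred-scaled
likelihood per local genotype; diploid count n(n+1)/2, haploid n), `DP`,
`GQ`, and an opaque `gvcf_info` payload carrying the originating
single-sample INFO fields. Genotype ordering follows the VCF PL convention:
unordered pair (j ≤ k) sits at index k(k+1)/2 + j.

Dataset-level metadata includes `MAXIMUM_REFERENCE_BLOCK_LENGTH`, an upper
bound on any block's span. Point-query densification at position p only
searches rows with start positions in `[p − max + 1, p]`; per-sample block
disjointness guarantees at most one covering block.

Coordinates are 1-based with closed intervals throughout (VCF POS/END
semantics): a block starting at 4500 with `LEN` 10000 covers 4500–14499.
Contig order comes from header contig lines, falling back to first
appearance. Ploidy is per-call, inferred from the call's arity; only haploid
and diploid calls are supported (the genotype-count formulas cover no more).
Phase separators are preserved verbatim.

## GVCF conversion and losslessness

A single-sample dataset is equivalent to a GVCF. Import turns END-tagged
reference rows into blocks (`LEN = END − POS + 1`; a hom-ref row without END
becomes a block spanning its reference allele) and variant rows into sites
with identity `LA`, `LAD = AD`, `LPL = PL`, `LGT = GT`. Two NON_REF policies
exist: `drop` (default for combining) removes the sample-local `<NON_REF>`
allele, deleting its AD entry and every PL entry touching it and reindexing
the rest — the allele is meaningless in a multi-sample global list; `retain`
keeps everything for exact round trips.

Export is the inverse. Two conventions matter:

* the exporter always writes an explicit `END` key on reference rows (the
  importer strips it), so a hypothetical source block that lacked END while
  spanning one base round-trips with an added `END=POS`;
* alleles are emitted *through LA*: the genotype's local order is the
  original file's allele order, and after a merge the translation may be
  non-monotonic, so requiring literal identity would be too strict. Export
  requires the LA image to cover the site's allele list — i.e. run
  `prune_alleles` first on subset data — and rejects anything else rather
  than silently dropping alleles.

Site-level ID/QUAL/FILTER of a variant row are per-sample facts once samples
are merged; they travel in `gvcf_info` under reserved keys (`_ID`, `_QUAL`,
`_FILTER`) and are restored on export.

Recovering a sample's original GVCF from a merged dataset is
`subset_samples → prune_alleles → trim_alleles → export_gvcf`. Pruning drops
global alleles no remaining genotype observes, touching only the `LA` maps
(the operation local indexing exists to make cheap). Trimming reverses merge
right-extension: while every non-symbolic allele at a site has length ≥ 2
and all share their final base, that base is removed. The length-1 guard
means sites containing a pure indel (which always keeps a length-1 allele)
are never over-trimmed; a site whose alleles all legitimately share a suffix
at length ≥ 2 (an un-normalized MNP) would lose it — a known limitation.

## Merging

`merge` outer-joins both matrices by locus. Blocks are copied verbatim.
Variant sites sharing a locus are unified: the merged reference is the
longest input reference and every input's reference must be a prefix of it
(same reference genome — violations are rejected, not guessed around);
shorter inputs' non-symbolic alleles are right-extended with the missing
reference suffix; symbolic alleles (`<NON_REF>`, `*`) unify by exact string
match. Merged alternate order is first appearance by (input rank, input
index) — deterministic, so merging is reproducible; it is associative only
up to allele order, which is why tree-vs-flat comparisons in the tests are
made on densified rows keyed by allele string. Genotypes are rewritten by
translation of `LA` alone. No genotype adjustment of any kind is performed.

`plan_hierarchical(n, fanout)` builds the balanced bottom-up merge tree
(100 000 inputs at fanout 100 → 1000 + 10 + 1 tasks); tasks share no mutable
state and may execute in any dependency-respecting order.

## Block splitting

Two strategies bound block span by K, preserving per-base coverage exactly:

* **size threshold**: a block of length L > K becomes ⌈L/K⌉ consecutive
  pieces, the first ⌈L/K⌉−1 spanning exactly K — the minimum number of new
  blocks;
* **fixed period**: blocks are cut at every position p with (p−1) mod K = 0,
  anchoring partitions to 1-based coordinates so partition i covers
  [(i−1)K+1, iK]; afterwards no block crosses a partition boundary and a
  partition's dense sub-matrix is computable from the partition alone
  (`densify_stream(..., assume_partitioned=True)`).

Fixed-period piece counts are ≥ size-threshold counts by construction; we
assert the inequality, not magnitudes. We split existing blocks only, and do
not additionally materialize a fresh block for every covered sample at each
boundary; the partition-containment guarantee is the same. DP/GQ/LGT are
copied to every piece; splitting never merges adjacent blocks (it is a pure
refinement). `max_ref_block_length` is recomputed as the maximum surviving
span.

## Densification

`project_lad_to_ad` sets `AD[LA[i]] = LAD[i]` and 0 elsewhere — zero
informative reads is a statement of fact for unobserved alleles, so AD uses
0, not missing. `project_lpl_to_pl` fills only genotypes whose both alleles
are local; the rest are missing by default (the data never assigned them a
likelihood) with an optional integer sentinel for tools that need dense
arrays. Hom-ref rows synthesized from blocks get `GT 0/0` (ploidy
configurable, default diploid everywhere including sex chromosomes) with
AD/PL missing, since blocks carry only LEN/DP/GQ. Read totals are conserved:
sum(AD) = sum(LAD).

`densify_at_locus` is the bounded backward search described above;
`densify_stream` sweeps the merged record stream keeping one active block
per sample and must agree with the point query at every site (tested).

## SVCR-VCF serialization

One row per locus present in either matrix; block-only rows carry `ALT=.`
with REF set to the stored base (`N` when unknown, e.g. non-initial split
pieces). Emitted as VCF 4.3 with `Number="."` for the locally indexed
fields, since 4.3 lacks local Number codes; the LR/LG length rules are
enforced semantically by the reader and validator. `LA` (with its leading 0)
and `LGT` are used exclusively — globally indexed fields never appear in the
sparse encoding. Reference-block columns carry `LGT` whenever the block has
one ("auto"; "always"/"never" available), because dropping it would break
dataset-equality round trips for caller output that writes `GT 0/0` on
blocks.

Per-sample `gvcf_info` and non-modeled FORMAT fields ride in a `GINFO`
FORMAT string of percent-encoded `key=value` pairs; it is omitted entirely
when no sample has a payload. This makes `read(write(ds)) == ds` hold
exactly, at the cost of one nonstandard (but VCF-legal) FORMAT field.
Output is byte-stable: fixed FORMAT key order, fixed integer rendering.

The reader enforces the encoding rules: LA and LEN are mutually exclusive in
one genotype; every FORMAT field of a sample must be missing strictly inside
that sample's blocks; a declared maximum block length smaller than an actual
block is rejected. Files may be plain text or bgzip (via pysam's BGZF
layer). The dense exports are `export_hardcalls_pvcf` (GT only, no blocks,
`./.` where uncovered) and `export_dense_pvcf` (GT/AD/DP/GQ/PL; super-linear
by design, for small regions).

## Synthetic cohorts

The generator emulates GATK-style whole-genome GVCFs at desk scale. Its
defaults are the study conditions of the test suite and are not tuned per
run:

| parameter | default | meaning |
| --- | --- | --- |
| `k_variants_per_sample` | 500 | expected nonreference records per sample |
| `genome_length` | 100 000 bp | single contig `chr1`, uniform random bases |
| `freq_min`, `freq_max` | 1e-4, 0.5 | truncated 1/f (log-uniform) allele-frequency law |
| `site_pool_size` | auto | grown until Σ per-locus carrier probability = K |
| `indel_fraction` | 0.15 | of pool variants; lengths 1–6 bp |
| `max_alts_per_locus` | 4 | multiallelic pool loci (P ≈ 0.10 of ≥ 2 alts) |
| `block_gq_bands` | (15, 150), (30, 400), (50, 1200) | (GQ, mean span) tiling bands |
| `mean_depth` | 30 | Poisson per-record depth |

A sample carries a variant of frequency f with probability 1 − (1−f)², and
is homozygous with conditional probability f²/(2f − f²) (Hardy–Weinberg).
The 1/f law is what produces sub-linear site discovery: common variants
saturate the site pool early while rare variants keep adding singletons, so
M(N) grows roughly logarithmically over the tested range — the fitted site
exponent (~0.23–0.32 for the default law at N = 8…128) is model-dependent
and deliberately not pinned to any empirical cohort's value, which varies
with ancestry mix. The suite asserts ranges: sparse records b ∈ [0.95,
1.05], dense records b ≥ 1.1, sites b ∈ (0, 1). Dense genotype records are
exactly N × M(N), so b_dense = 1 + b_sites identically.

Per-sample streams are seeded by `SeedSequence(seed, spawn_key=(1, index))`
(the pool uses `spawn_key=(0,)`), making cohorts extensible: adding sample
N+1 leaves samples 1…N byte-identical. AD/PL/DP/GQ are generated
consistently (PL = 0 at the called genotype; GQ = the smallest non-called
PL, capped at 99); reference blocks tile every base not covered by a variant
record's reference-allele footprint, so samples are fully covered and
hom-ref fills are everywhere resolvable.

What the generator does **not** model: linkage disequilibrium,
recombination, mutation-rate heterogeneity, sequencing-error structure,
coverage dropout (every base is covered), sex chromosomes, or multi-contig
genomes. Passing tests therefore demonstrate representation-level
correctness (losslessness, merge/densify algebra, scaling of record counts)
— not caller realism, and byte sizes of the text encodings are reported as
informational only, since compressed size depends on the compressor more
than on the representation.

## Scaling measurement

`scaling_sweep` builds each checkpoint by merging the previous checkpoint
with the next batch of single-sample imports — the incremental N+K workflow
itself. `fit_loglog` is an ordinary least-squares line in (log10 N, log10
measure) with ≥ 3 points, reporting intercept a, exponent b and R². The
acceptance sweep uses N ∈ {8, 16, 32, 64, 128} with K ≈ 500 on the 100 kb
toy genome; these sizes keep the whole suite comfortably fast while leaving
a decade of N for the fit.

## Numerical and degenerate-case conventions

* `n_genotypes` rejects ploidy ∉ {1, 2}; `genotype_index` rejects j > k
  (callers canonicalize unordered pairs).
* `expected_length` implements the seven Number codes (LA, LR, LG, A, R, G,
  1) and rejects unknown codes.
* Validation returns violations as data (rule id, locus, sample), never
  raises; writers validate before emitting.
* Empty datasets export header-only files; an empty record stream imports to
  an empty dataset with `max_ref_block_length = 0`.
* Reference-block `LGT` is validated for arity only, not allele values
  (whether a block's call must be hom-ref is left open by the format).
* `gvcf_info` values never merge across samples; key collisions between
  samples are impossible by construction (the payload is per-sample).
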