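# Methods

This note records the models, numerical choices and design decisions
behind `snptop`, in the order the pipeline uses them.

## Input dialect

The parser reads a simplified, SNP-only VCF dialect: `##` meta lines,
one `#` header, then 8-column data lines (CHROM, POS, ID, REF, ALT,
QUAL, FILTER, TYPE) sorted by (chromosome, position).  Fields may be
separated by any run of whitespace; the writer emits tabs.  Choices
where the dialect is underspecified:

* **Chromosome codes.**  The packed format allots 5 bits, so symbolic
  contigs map to codes: "1".."22" → 1..22, "X" → 23, "Y" → 24,
  "MT" → 25; numeric aliases 23–25 are accepted on input.  Other
  contigs are rejected.
* **Ordering.**  Strictly non-decreasing (chrom, pos); equal loci are
  allowed so multi-allelic sites (distinguished by REF/ALT) can
  coexist.
* **Coordinates** are taken verbatim (1-based, as in VCF); nothing in
  the pipeline converts them.
* QUAL and FILTER are parsed and discarded; the writer always emits
  `100` / `PASS`.

## 80-bit SNP codec

A record packs into one 80-bit big-endian integer, fields
most-significant first: CHROM (5) | POS (32) | ID (37) | REF&ALT (5) |
TYPE (1).  Decisions:

* **Field order and endianness** are not forced by the on-disk tables
  alone; this layout was fixed because big-endian serialization makes
  unsigned byte-wise comparison of packed records agree with
  (chrom, pos) order, which the tests verify and the engine's sorted
  streams rely on conceptually.
* **REF&ALT code.**  The 20 ordered non-equal pairs over {A,C,G,T,N}
  enumerate ref-major in ASCII order (A, C, G, N, T): (A,C)=0,
  (A,G)=1, (A,N)=2, (A,T)=3, (C,A)=4, …, (T,N)=19.  Any fixed
  bijection into 5 bits works; this one is canonical and frozen in a
  test.
* **TYPE bit**: 0 = heterozygous, 1 = homozygous (arbitrary, fixed).
* **ID field.**  37 bits store the numeric suffix of an rs identifier.
  Non-`rs<digits>` IDs and numbers ≥ 2³⁷ are rejected loudly rather
  than encoded lossily: the dialect only ever contains rsIDs, and
  silent truncation would corrupt round-trips.

## Block encryption

Blocks of B packed SNPs (default B = 2080, a common multiple of the
10-byte SNP and 16-byte AES block sizes, ≈ 20 KB per block) are
encrypted with AES-128-GCM and serialized as
`count (4, little-endian) | IV (12) | MAC (16) | ciphertext (10·n)`.

* The count field sits outside the ciphertext; it is **bound as
  associated data**, so altering it — e.g. truncating the block —
  fails tag verification rather than silently shortening the payload.
  (Whether to authenticate it was an open choice; binding is strictly
  safer and format-compatible.)
* IVs are 12 random bytes per block from the OS CSPRNG; no counter
  scheme.  One key serves all files; multi-key operation is out of
  scope.
* The AES-GCM core is implemented in the package: the S-box is
  generated from GF(2⁸) arithmetic (not typed in), all CTR keystream
  blocks of a message run through the ten rounds as one numpy array,
  and GHASH uses per-key precomputed 8-bit tables.  Tests pin it to
  the FIPS-197 AES example and the standard GCM known-answer test
  cases.  Tag comparison is constant-time; the table lookups are *not*
  hardened against cache-timing adversaries — this is a research
  artifact, not a production cipher.

## Counter tables

CTRL_CNT and CASE_CNT are fixed-capacity open-addressing maps keyed by
the 42-bit identity chrom (5) | pos (32) | refalt (5).  Zygosity and
rs number are excluded from the key, so a site seen heterozygous in
one file and homozygous in another aggregates with amounts 1 and 2.

* **Hashing**: Fibonacci hashing — the key XOR a 64-bit mask drawn
  once per run, multiplied by 0x9E3779B97F4A7C15 mod 2⁶⁴; the top 22
  bits of the product reduce modulo the capacity.  The random mask
  re-randomizes slot placement between runs, limiting what repeated
  access traces reveal; it provably never changes the (key → count)
  mapping, which a test checks directly.
* **Collisions**: linear probing.  Simple, cache-friendly, and any
  fixed scheme preserves all observable results.
* **Capacity** defaults to 282914 slots — sized so both tables stay
  within a typical L3 cache during a range scan at a ~50–60% fill
  ratio.  If every slot fills, the table reallocates to twice the
  capacity with a warning instead of failing: the default is tuned so
  this never happens at contest scale, but hard failure would be
  hostile to other datasets.
* **States.**  Each slot carries empty/update/wait states mirroring
  the element-level synchronization of concurrent deployments.  This
  implementation is sequential; the observable contract — final
  contents independent of the order of a fixed multiset of increments
  — is what the tests enforce, and a lock-per-element concurrent
  implementation would satisfy the same contract.

## χ² statistic

`chi2_statistic(n_ctrl, n_case, N_ctrl, N_case)` evaluates the Pearson
form over O = [n_ctrl, n_case, N_ctrl − n_ctrl, N_case − n_case] and
E = [N_ctrl·f, N_case·f, N_ctrl·(1−f), N_case·(1−f)].  Notes:

* The third O entry is N_ctrl − n_ctrl; with it the four cells sum to
  N_ctrl + N_case and the value reproduces the standard 2×2 Pearson
  statistic exactly (tested to 1e−9 relative against the closed form
  on 10⁴ random tuples).
* Degrees of freedom: 1 (the 2×2 presence/absence table).
* Degenerate pooled frequencies f ∈ {0, 1} return 0: such a table
  carries no discriminative information and the E denominators vanish.
* Real-valued counts are accepted so the synthetic generator can
  evaluate the statistic at expected counts.
* **Ranking direction.**  The engine ranks by *largest* statistic =
  *smallest* p-value, the statistically standard notion of "most
  significant".  A `rank_lowest` flag flips the direction for
  completeness; the output header always records the convention in
  force.

## Survival function

P-values use a precomputed df=1 survival table with a data-independent
query path.

* **Transformation.**  The df=1 density has an x^(−1/2) singularity at
  zero; integrating in t = √x turns it into the half-normal density
  √(2/π)·exp(−t²/2), which is smooth, so plain trapezoidal rules
  converge cleanly.
* **Grid**: n_grid = 1024 equally spaced points on [0, x_max = 64]
  (survival(64) ≈ 1e−15, below any representable ranking difference).
  Grid values are computed once by fine trapezoidal integration (1024
  sub-steps per cell) accumulated **from the tail upward**, including
  the mass beyond x_max integrated until it underflows; a forward
  1 − cumsum would flatten the deep tail at ~1e−9 through floating-
  point cancellation.  Values are normalized so S(0) = 1 exactly.
* **Query**: two full scans of the grid (index location, then
  branch-free selection of the bracketing entries) followed by a
  trapezoidal refinement with exactly refine_steps = 32 sub-steps —
  the same table positions and the same arithmetic count for every
  x in [0, x_max].  Inputs above x_max return the tail value
  (monotone floor).  The refinement integrates from the **nearest**
  grid point, above or below, selected arithmetically: integrating
  always from below has a worst-case trapezoid error ≈ 1.0e−6 at the
  far edge of the first (widest-in-t) cell, right at the accuracy
  target, while the nearest-endpoint rule halves the integration
  width and brings the worst case to ≈ 1.3e−7.  Measured accuracy
  against erfc(√(x/2)) is ≤ 2e−7 over [0, 50].
* `instrument=True` records each query's touched-position trace;
  the access-pattern contract is tested by comparing traces across
  extreme inputs.

## Streaming engine

* **Ranges.**  Each iteration takes the next range_blocks = 4 blocks
  of the first registered file; the range runs from the first SNP of
  the first block to the last SNP of the last one, inclusive at the
  end locus so multi-allelic sites at the boundary stay together.
* **Cursors.**  Ranges are defined by one file's positions, so a block
  of another file can straddle a boundary.  Cursors therefore store
  (block index, intra-block offset): a straddling block is split
  logically, its decrypted remainder retained for the next iteration
  — every SNP is counted exactly once, with no re-decryption.
* **Final sweep.**  SNPs in other files positioned after the first
  file's last locus (or on chromosomes it lacks) would otherwise never
  be counted; one terminal open-ended range drains them.
* **Merging.**  After each range, every key present in either table is
  scored (a key absent from one cohort counts 0 there) and merged into
  the global top-K: statistic descending, ties broken by
  (chrom, pos, refalt) ascending — fully deterministic output.
  P-values are computed only for the K survivors at termination.
* **Invariance.**  Block size, range width, table capacity and hash
  mask shape the schedule, not the answer; tests check byte-identical
  output tables across B ∈ {13, 160, 2080} × range_blocks ∈ {1, 4, 7}
  and equality with a naive full-decrypt single-pass oracle over
  random cohorts.
* The paper-shaped five-call surface (init / register / begin / run /
  end) maps to `engine_init`, `register`, `next_range`,
  `consume_range`, `end_range`; `run_search` drives the loop.
  Execution is sequential — parallel inner loops are an implementation
  freedom the contract deliberately leaves open.

## Synthetic cohorts

The generator emulates the contest-style dataset shape: one shared
template of n_snps sites (chromosomes 1–22, strictly increasing
positions within a chromosome, unique rs numbers, random non-equal
base pairs), with each file carrying site i independently with its
cohort's probability and homozygous with a fixed fraction.

Defaults are the planted-effect study condition exercised throughout
the tests: 50 control + 50 case files, one planted site at carrier
probability 0.9 (case) vs 0.1 (control).  The remaining values are
desk-scale choices fixed once: 200 sites per template (large enough
that the planted site must beat ~200 null competitors, small enough
for hundreds of seeded runs in a test session), background carrier
probability 0.3 and homozygous fraction 0.3 (mid-range values giving
non-trivial presence counts in both cohorts).  The truth table stores
E[n] = files · p · (1 + hom_fraction) per site and the statistic at
those expectations.

What the generator does *not* emulate: linkage disequilibrium,
realistic allele-frequency spectra, population structure, genotyping
error.  Passing tests therefore demonstrate correctness of the
counting, statistics and ranking machinery on independent-draw
cohorts — not calibration of the χ² test on real populations, where
confounding and LD would matter.

## Problem sizes in the test and acceptance runs

Scales are the package's own verification choices: codec round-trips
at 10⁴ records; 10³ random single-bit tampers; counter-table/dict
equivalence on 100 workloads of 10⁵ operations; χ² closed-form
agreement on 10⁴ tuples; survival accuracy at 10³ points on [0, 50];
engine/oracle equivalence on 50 random cohorts of 5–40 files ×
100–5000 template SNPs; planted-SNP recovery over 100 seeded runs of
the default condition.

## Known limitations

* The crypto core is correctness-oriented; it resists no physical or
  microarchitectural side channels, and key management (exchange,
  attestation, rotation) is entirely out of scope.
* Only the rs-numbered SNP dialect is supported; generic VCF
  (INFO/FORMAT columns, indels, arbitrary contigs) is rejected.
* The engine reads each encrypted file sequentially per range; no
  parallel I/O or multi-threaded counting is implemented.
* No multiple-testing correction is applied; reported p-values are
  per-SNP marginals.
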