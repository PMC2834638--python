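# Methods

## Scope and model

`oligomap` updates the genomic coordinates of fixed-length array probes
(50-mers by default) by alignment against an assembly, and audits the new
annotation against an existing one. The core model is deliberately simple
and fully deterministic: every probe either has a best-scoring alignment
that is unambiguous, ambiguous within one chromosome, ambiguous across
chromosomes, or no acceptable alignment at all — and each of those four
outcomes maps to exactly one (chromosome, position) pattern. The SNP base
itself is taken to sit one base beyond the aligned probe on the probe's
3' side, which yields the strand-aware position rule: subject end + 1 on
the plus strand, subject end − 1 on the minus strand (where the reported
subject end of a minus-strand hit is its smaller coordinate, per the BLAST
column convention).

## Alignment backends

Hits are an interchangeable input. The external route parses 12-column
BLAST tabular output (`-m 8`/`-m 9` dialects); nothing is recomputed from
it, so bitscores are compared exactly as printed. The internal scanner is
an exhaustive ungapped aligner specialised for short fixed-length probes:

- candidate alignment lengths are the full probe length *L* and *L*−1
  with one terminal base trimmed (including probes overhanging a sequence
  end by one base). This is sufficient to realise every accepted hit
  class under the default length filter (≥ *L*−1) while keeping the
  search space exactly enumerable; gapped or shorter alignments are the
  external backend's job.
- acceptance is `matches / length ≥ min_identity / 100` (default 95%).
  `N` never matches anything on either side.
- when the full-length alignment at a locus passes, its contained trimmed
  alignments are suppressed, so each (subject, locus, strand) yields one
  hit. A terminal mismatch therefore reports as a length-*L* hit with one
  mismatch rather than a perfect (*L*−1)-mer — the two have the same
  match count, and one canonical representative keeps tie semantics
  stable.
- the bitscore is proxied by the integer match count. This makes
  "equally high bitscore" an exact integer comparison, reproducible
  across platforms, and means a full-length hit always outscores a
  trimmed hit at the same identity. E-values are carried but never
  computed (0.0).

Candidate loci are generated by a pigeonhole seed index: for a maximum of
*k* allowed mismatches, *k*+1 disjoint seeds are taken from the probe
interior (positions 1 … *L*−2, so the same seeds are valid for both
trimmed variants), and every exact seed match proposes a candidate that is
then verified base by base. Any alignment with ≤ *k* mismatches must
contain at least one exact seed, so seeding is lossless; seeds shorter
than 6 bases (very short probes or very high mismatch allowances) trigger
a fallback that simply verifies every position. The test suite re-derives
all hits with an independent naive per-position Hamming scan and requires
set equality.

## Decision tree

Filtering precedes disambiguation: hits outside the placed-chromosome
whitelist (default "1"–"29" plus "X") or shorter than `min_len` (default
*L*−1) are discarded first, so a probe whose only matches are on unplaced
scaffolds is indistinguishable from an absent probe downstream. For
backends whose hit streams are already filtered differently, a
no-prefilter mode keeps the alternative reading, in which a best hit on an
unplaced sequence yields its own status (`best_hit_unplaced`); when a
best-bitscore tie mixes placed and unplaced subjects in that mode, the
unplaced members are dropped and the tree continues on the placed ones.
Only the filter-first mode is the default.

Ties are resolved on the *derived* locus, not the raw hit rows: duplicate
identical rows collapse, and tied best hits on one chromosome that derive
the same SNP position also collapse to a unique call — ambiguity requires
genuinely different positions. The outcome is invariant under permutation
of the hit list (all selection is via max/set operations).

A derived position of 0 — a probe flush against a sequence start on the
minus strand — is an error, not a silent clamp; the caller sees a
coordinate exception naming the probe.

## Annotation audit

Comparisons operate on annotation tables (ID, CHROM, POS; missing values
read from "0" or "NA", written as "NA"). Discrepancy classes are assigned
with fixed precedence: chromosome in exactly one source → one-sided
chromosome; different chromosomes → conflict (positions on different
chromosomes are never differenced); same chromosome but position in one
source only → one-sided locus; positions more than two bases apart →
substantial positional shift; everything else, including SNPs unmapped by
both sources, is consistent. The |Δ| > 2 cut treats off-by-one and
off-by-two shifts as convention noise — different pipelines disagree on
which base adjacent to the probe the "SNP position" names — while three
or more bases cannot be explained that way. The ≥3 difference bin of the
histogram coincides with the positional-shift class by construction.

Cross-tables are reported with source *a* on rows and source *b* on
columns; swapping the sources transposes the tables and leaves the bins
and the substantial total unchanged (tested as a property).

## Duplicate detection

Probe pairs sharing a sequence are found by hashing sequences (identical
pairs: all pairs within a bucket; reverse-complement pairs: cross-bucket
pairs between a sequence and its reverse complement). A palindromic
shared sequence is reported as identical only, and a palindromic probe
never pairs with itself. The production path is hash-based; the tests
compare it against an all-pairs O(n²) oracle.

## Synthetic fixtures

The generator emulates the pipeline's real inputs at desk scale. Defaults
(3 chromosomes × 200 kb, 5 unplaced scaffolds × 20 kb, 1,000 probes:
700 unique plus-strand, 100 unique minus-strand, 60 same-chromosome
duplicates, 40 cross-chromosome duplicates, 30 scaffold-only, 40 absent,
20 single-mismatch, 10 triple-mismatch) keep every decision-tree branch
populated with a realistic dominance of cleanly mappable probes, while
staying small enough that generation plus mapping takes about a second.
The default annotation perturbation (3 dropped chromosomes, 2 chromosome
moves, 4 dropped positions, 5 shifts of 3–10 bases, 20 off-by-one shifts)
plants each audit class in a known, disjoint row set.

Design choices that matter for interpreting test results:

- sequences are i.i.d. uniform ACGT. Spontaneous 50-mer near-matches are
  then vanishingly rare, which makes planted fates provable; real genomes
  contain repeat families, so real probes produce far more multi-locus
  ambiguity than the fixture's planted rate. Passing tests demonstrate
  the correctness of the bookkeeping, not the field rate of ambiguous
  probes.
- plantings are non-overlapping and at least a probe length apart, with a
  probe-length margin at sequence ends, so every planted probe's hit set
  is exactly its planted loci.
- mutated-probe fates mutate interior bases only, so recoverability is a
  pure function of the identity threshold ((L−k)/L against 95%): one or
  two mismatches in a 50-mer are recoverable, three are not. Terminal
  mutations would instead exercise the trimmed-hit path, which is covered
  separately by randomized scanner/oracle tests.
- "absent" probes are random oligomers verified by a scan to have no
  acceptable hit anywhere, so their expected no-hit status is checked,
  not assumed.
- all randomness flows from the integer seed in the fixture spec; rerun
  outputs are byte-identical.

Duplicate-pair fates add two manifest records per planted pair, and the
generator records the pair linkage in its truth table so duplicate
detection can be scored against planted ground truth rather than against
a re-derivation from the sequences.

## Numerical and formatting conventions

- identity thresholds are evaluated as `matches·100 ≥ min_identity·length`
  with a 1e-9 slack, so 47/50 = 94% fails a 95% cutoff and 2 mismatches in
  49 (95.9%) passes, with no float-boundary surprises.
- chromosome labels are always text ("1"…"29", "X", scaffold names);
  positions are 1-based nullable integers.
- probe FASTA headers join Name, design-strand flag, genome-strand flag
  and alleles with `|`; only the token before the first `|` is a probe ID.
- CLI exit codes: 0 success, 2 usage/input validation, 1 internal.

## Limitations

- the internal scanner is ungapped and fixed-length by design; probes
  needing gapped or heavily truncated alignments must come through the
  external tabular route.
- no rescue of scaffold-only probes, no paralog masking, no genotype
  concordance analysis for duplicate pairs.
- with real megablast input, bitscore ties depend on the aligner's own
  scoring; the internal match-count proxy cannot represent, e.g., a tie
  between a 50-base hit with one mismatch and a perfect 49-base hit
  being broken differently by an external scorer.
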