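# oligomap

Re-map fixed-length SNP-array oligomer probes onto a genome assembly and
audit the result against the manufacturer's annotation.

## The problem

High-density genotyping arrays interrogate each SNP with a short
fixed-length oligomer (typically a 50-mer abutting the SNP base). The
chromosome/position annotation shipped with the array is tied to one
genome build — and for species whose assemblies are still moving, or even
being silently patched within a build, those positions go stale. Probes
with dbSNP rs-IDs can be repositioned through databases; the rest must be
re-aligned to the current assembly. A probe position that is wrong by even
a few bases can flip a SNP between synonymous/non-synonymous or attach it
to the wrong gene, so the re-mapping has to be auditable base by base.

`oligomap` implements that workflow for anyone maintaining array
annotations: manifest → probe FASTA → alignment hits → per-SNP calls →
audit report.

## The method

1. **Hits.** Each probe is aligned to every placed chromosome and unplaced
   scaffold, either by parsing standard 12-column BLAST/megablast tabular
   output, or with the built-in exhaustive ungapped scanner (both strands,
   alignment lengths *L* and *L*−1, percent identity ≥ a cutoff, default
   95%). Minus-strand hits follow the BLAST convention `s_start > s_end`.
2. **Filter.** Only hits on the placed chromosomes (autosomes + X by
   default) with alignment length ≥ *L*−1 (49 for 50-mers) are accepted.
3. **Decision tree on the best bitscore.** For each SNP:
   - no surviving hit → chromosome NA, position NA;
   - a strictly best hit → unique call;
   - best hits tied on one chromosome at several positions → chromosome
     assigned, position NA;
   - best hits tied across chromosomes → both NA.
4. **Position rule.** The SNP sits one base beyond the probe: position =
   subject end of the hit **+1** if probe and chromosome share orientation,
   **−1** otherwise.
5. **Audit.** Two annotations over the same SNP set are compared:
   per-source summary triples, 2×2 chromosome- and position-presence
   cross-tables, |Δposition| bins (0 / 1 / 2 / ≥3), and a per-SNP
   discrepancy class (`chrom_one_side`, `chrom_conflict`,
   `locus_one_side`, `pos_gt2` — positions more than two bases apart — or
   `consistent`). Probe pairs sharing a sequence (verbatim or as reverse
   complements) are detected separately.

A seeded fixture generator (`oligomap.fixtures`) builds toy genomes and
manifests in which every probe has a planted fate and a known expected
call, so the entire pipeline is testable without any downloads.

## Worked example

```sh
oligomap simulate --outdir fx --seed 9 --chromosomes 2 --chrom-length 15000 \
    --unplaced 2 --unplaced-length 2000 \
    --fate unique_plus=20 --fate unique_minus=6 --fate dup_same_chrom=3 \
    --fate dup_cross_chrom=3 --fate unplaced_only=2 --fate absent=3 \
    --fate mismatched_1=2 --fate mismatched_3=1 \
    --fate duplicate_id_pair=2 --fate revcomp_pair=1 \
    --perturb chrom_one_side=1 --perturb chrom_conflict=1 \
    --perturb locus_one_side=1 --perturb pos_gt2=2 --perturb off_by_one=3
oligomap build-fasta fx/manifest.csv fx/probes.fasta
oligomap map --probes-fasta fx/probes.fasta --genome fx/genome.fasta \
    --out fx/ann.csv --whitelist 1-2
```

`map` prints the filtering funnel and the three-way tally:

```
probes:              46
raw hits:            48
hits after filter:   46
  status chrom_only: 3
  status cross_chrom_tie: 3
  status no_hit: 6
  status unique: 34
unique locus / chromosome only / neither: 34 / 3 / 9
```

Every probe planted with a clean fate is recovered: the 34 unique calls
are the 20 plus-strand and 6 minus-strand probes, the 2 recoverable
single-mismatch probes, and the 6 members of the planted duplicate pairs;
the 3 same-chromosome duplicates keep their chromosome but lose their
position; absent, heavily mutated and scaffold-only probes get NA/NA.
Auditing the fresh annotation against the fixture's perturbed
"manufacturer" file then recovers the planted discrepancies:

```sh
oligomap diagnose fx/ann.csv fx/annotation.vendor.csv --out-prefix fx/diag
# ...
# Discrepancy classes:
#   chrom_one_side: 1
#   chrom_conflict: 1
#   locus_one_side: 1
#   pos_gt2: 2
#   consistent: 41
# Substantial discrepancies: 5
oligomap dedupe --manifest fx/manifest.csv --out fx/dups.csv
# 3 duplicate pairs (2 identical, 1 reverse-complement) written to fx/dups.csv
```

For a real chip, replace the simulated inputs with the vendor manifest
(`--skip-head`/`--skip-tail` control the metadata lines, `--rename
OLD=NEW` harmonizes probe-ID prefixes between vendor files), the assembly
FASTA, and optionally a megablast tabular file via `--hits`.

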