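"""Per-SNP chromosome/position assignment from alignment hits.

The decision tree: hits are first restricted to the placed chromosomes
(autosomes + X by default) and to alignments of at least ``min_len`` bases
(49 for 50-mers). A SNP with no surviving hit is unassigned. Otherwise the
best bitscore decides: a strictly unique best hit gives a unique call; best
hits tied on one chromosome at more than one position give the chromosome
only; best hits tied across chromosomes give nothing.

The SNP position itself sits one base beyond the probe: the subject-end
coordinate of the hit plus 1 when probe and chromosome have the same
orientation, minus 1 otherwise (on minus-strand hits the reported subject
end is the smaller coordinate, so "minus 1" steps further outward).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .aligner import AlignmentHit, PLUS, hit_strand
from .errors import CoordinateError, ValidationError
from .manifest_io import annotation_table

#: Status vocabulary for a locus call.
NO_HIT = "no_hit"
UNIQUE = "unique"
BEST_HIT_UNPLACED = "best_hit_unplaced"
CHROM_ONLY = "chrom_only"
CROSS_CHROM_TIE = "cross_chrom_tie"
STATUSES = (NO_HIT, UNIQUE, BEST_HIT_UNPLACED, CHROM_ONLY, CROSS_CHROM_TIE)

#: Statuses that leave both chromosome and position unassigned.
UNMAPPED_STATUSES = (NO_HIT, BEST_HIT_UNPLACED, CROSS_CHROM_TIE)

#: Default whitelist: 29 autosomes plus the X chromosome (cattle assembly).
BOVINE_WHITELIST = frozenset({str(i) for i in range(1, 30)} | {"X"})

DEFAULT_MIN_LEN = 49


@dataclass(frozen=True)
class LocusCall:
    """Outcome for one SNP: chromosome and position (either may be missing)."""

    snp_id: str
    chromosome: str | None
    position: int | None
    status: str
    n_hits_kept: int = 0


def filter_hits(
    hits: Sequence[AlignmentHit],
    whitelist: frozenset[str] | set[str],
    min_len: int = DEFAULT_MIN_LEN,
) -> list[AlignmentHit]:
    """Keep hits on whitelisted subjects with alignment length >= min_len."""
    return [
        h
        for h in hits
        if h.subject_id in whitelist and h.alignment_length >= min_len
    ]


def snp_position_from_hit(hit: AlignmentHit) -> int:
    """SNP position = subject end of the hit, stepped 1 base outward.

    Plus strand: ``s_end + 1``. Minus strand: ``s_end - 1`` (the reported
    subject end of a minus hit is its smaller coordinate). A result below 1
    (probe flush against the sequence start on the minus strand) raises
    :class:`CoordinateError`.
    """
    strand = hit_strand(hit)
    pos = hit.s_end + 1 if strand == PLUS else hit.s_end - 1
    if pos < 1:
        raise CoordinateError(
            f"hit {hit.query_id} vs {hit.subject_id}: derived SNP position {pos}"
            " falls before the start of the sequence"
        )
    return pos


def call_locus(
    snp_id: str,
    hits: Sequence[AlignmentHit],
    whitelist: frozenset[str] | set[str] = BOVINE_WHITELIST,
    min_len: int = DEFAULT_MIN_LEN,
    prefilter: bool = True,
) -> LocusCall:
    """Run the decision tree for one SNP over its hits.

    With ``prefilter`` (the default), non-whitelisted hits are discarded
    before best-hit selection, so a probe whose only hits sit on unplaced
    scaffolds simply has no hit. With ``prefilter=False`` the best-bitscore
    set is formed over all length-passing hits and a best set lying entirely
    off the whitelist yields :data:`BEST_HIT_UNPLACED`; whitelisted members
    of a mixed best set are kept and the tree continues on them.

    Duplicate identical hit rows are collapsed. The outcome is invariant
    under permutation of the hit list.
    """
    if not snp_id:
        raise ValidationError("empty SNP ID")
    uniq = list(dict.fromkeys(hits))
    if prefilter:
        kept = filter_hits(uniq, whitelist, min_len)
    else:
        kept = [h for h in uniq if h.alignment_length >= min_len]
    if not kept:
        return LocusCall(snp_id, None, None, NO_HIT, 0)
    best = max(h.bitscore for h in kept)
    ties = [h for h in kept if h.bitscore == best]
    if not prefilter:
        placed = [h for h in ties if h.subject_id in whitelist]
        if not placed:
            return LocusCall(snp_id, None, None, BEST_HIT_UNPLACED, len(kept))
        ties = placed
    loci = {(h.subject_id, snp_position_from_hit(h)) for h in ties}
    chroms = {c for c, _ in loci}
    if len(chroms) > 1:
        return LocusCall(snp_id, None, None, CROSS_CHROM_TIE, len(kept))
    if len(loci) == 1:
        chrom, pos = next(iter(loci))
        return LocusCall(snp_id, chrom, pos, UNIQUE, len(kept))
    return LocusCall(snp_id, next(iter(chroms)), None, CHROM_ONLY, len(kept))


@dataclass
class MappingResult:
    """All locus calls plus the annotation table and status tally."""

    calls: list[LocusCall]
    annotation: pd.DataFrame
    tally: dict[str, int]

    @property
    def summary(self) -> tuple[int, int, int]:
        """(unique locus, chromosome only, neither) counts."""
        unique = self.tally.get(UNIQUE, 0)
        chrom_only = self.tally.get(CHROM_ONLY, 0)
        neither = sum(self.tally.get(s, 0) for s in UNMAPPED_STATUSES)
        return unique, chrom_only, neither


def group_hits_by_query(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    """Bucket a hit stream by query (probe) identifier, order-preserving."""
    out: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        out.setdefault(h.query_id, []).append(h)
    return out


def call_all(
    hits_by_snp: Mapping[str, Sequence[AlignmentHit]],
    all_snp_ids: Sequence[str],
    whitelist: frozenset[str] | set[str] = BOVINE_WHITELIST,
    min_len: int = DEFAULT_MIN_LEN,
    prefilter: bool = True,
) -> MappingResult:
    """Call every SNP in ``all_snp_ids`` (hit-less SNPs are unassigned).

    ``all_snp_ids`` must cover every key of ``hits_by_snp``; the statuses of
    the calls always partition the SNP set, so the three-way summary sums to
    ``len(all_snp_ids)``.
    """
    known = set(all_snp_ids)
    if len(known) != len(all_snp_ids):
        dup = [s for s, c in Counter(all_snp_ids).items() if c > 1]
        raise ValidationError(f"duplicate SNP IDs in call_all input: {dup[:10]}")
    stray = sorted(set(hits_by_snp) - known)
    if stray:
        raise ValidationError(
            f"hits for SNPs absent from the probe set: {stray[:10]}"
        )
    calls = [
        call_locus(snp_id, hits_by_snp.get(snp_id, ()), whitelist, min_len, prefilter)
        for snp_id in all_snp_ids
    ]
    tally = dict(Counter(c.status for c in calls))
    table = annotation_table(
        (c.snp_id, c.chromosome, c.position) for c in calls
    )
    return MappingResult(calls=calls, annotation=table, tally=tally)
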