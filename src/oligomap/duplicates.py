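"""Detection of probes that share a sequence under different identifiers.

A genotyping array can carry the same oligomer twice, either verbatim or as
the reverse complement of another probe. Such pairs interrogate the same
genomic site and are useful as built-in technical replicates. This module
finds all of them by exact sequence comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import ValidationError
from .manifest_io import OligoRecord

IDENTICAL = "identical"
REVCOMP = "revcomp"

_VALID = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class DuplicatePair:
    """An unordered probe pair sharing a sequence; ``id1 < id2``."""

    id1: str
    id2: str
    kind: str  # IDENTICAL or REVCOMP


def reverse_complement(seq: str) -> str:
    """Reverse complement over ACGTN (N maps to N)."""
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValidationError(f"sequence contains non-ACGTN characters: {bad}")
    return str(Seq(seq).reverse_complement())


def _ordered(a: str, b: str, kind: str) -> DuplicatePair:
    return DuplicatePair(min(a, b), max(a, b), kind)


def find_duplicates(records: Sequence[OligoRecord]) -> list[DuplicatePair]:
    """All unordered probe pairs with identical or reverse-complement sequences.

    A sequence carried by k distinct identifiers yields k*(k-1)/2 identical
    pairs. A pair related both ways (a palindromic shared sequence) is
    labelled identical only, and a palindromic probe never pairs with
    itself.
    """
    by_seq: dict[str, list[str]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, []).append(rec.oligo_id)
    pairs: list[DuplicatePair] = []
    for ids in by_seq.values():
        for a, b in combinations(ids, 2):
            pairs.append(_ordered(a, b, IDENTICAL))
    for seq, ids in by_seq.items():
        rc = reverse_complement(seq)
        if rc == seq or rc not in by_seq or seq > rc:
            continue  # palindrome, no rc partner, or already handled from rc side
        for a in ids:
            for b in by_seq[rc]:
                pairs.append(_ordered(a, b, REVCOMP))
    return sorted(pairs)


def duplicate_report(
    pairs: Sequence[DuplicatePair],
    annotation_a: pd.DataFrame | None = None,
    annotation_b: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabulate pairs, optionally decorated with each source's coordinates.

    With an annotation supplied, columns CHROM.<S><i> and POS.<S><i> give the
    chromosome and position of each pair member in that source.
    """
    df = pd.DataFrame(
        {
            "SNP1": [p.id1 for p in pairs],
            "SNP2": [p.id2 for p in pairs],
            "KIND": [p.kind for p in pairs],
        }
    )
    for suffix, ann in (("A", annotation_a), ("B", annotation_b)):
        if ann is None:
            continue
        idx = ann.set_index("ID")
        for member, col in (("SNP1", "1"), ("SNP2", "2")):
            present = df[member].isin(idx.index)
            df[f"CHROM.{suffix}{col}"] = [
                idx.at[s, "CHROM"] if ok else pd.NA
                for s, ok in zip(df[member], present)
            ]
            df[f"POS.{suffix}{col}"] = pd.array(
                [
                    idx.at[s, "POS"] if ok else pd.NA
                    for s, ok in zip(df[member], present)
                ],
                dtype="Int64",
            )
    return df
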