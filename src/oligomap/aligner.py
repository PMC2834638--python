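"""Alignment-hit acquisition: BLAST tabular parsing and an internal scanner.

Two backends produce the same :class:`AlignmentHit` stream. The first parses
standard 12-column BLAST tabular output (``-m 8``/``-m 9`` dialects, with or
without ``#`` comment lines). The second, :func:`scan_oligos`, is an
exhaustive ungapped scanner for fixed-length probes: it finds every locus on
either strand where a probe aligns at full length ``L`` or one-end-trimmed
length ``L - 1`` with at least the requested percent identity.

The internal scanner models BLAST conventions where they matter downstream:
subject coordinates are 1-based inclusive, minus-strand hits are reported
with ``s_start > s_end``, and the bitscore is proxied by the integer number
of matching bases so that "equally high bitscore" ties are exact and
reproducible. E-values are never computed (always 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import MalformedHitError, ParseError
from .manifest_io import OligoRecord

PLUS = "plus"
MINUS = "minus"

_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """Encode DNA as uint8: A,C,G,T -> 0..3, anything else (incl. N) -> 4."""
    return _CODES[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, codes)
    return out[::-1].copy()


@dataclass(frozen=True)
class AlignmentHit:
    """One row of BLAST-style tabular output, with typed fields."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


def hit_strand(hit: AlignmentHit) -> str:
    """Return ``"plus"`` or ``"minus"`` from the subject coordinate order.

    BLAST reports minus-strand hits with ``s_start > s_end``. Equal subject
    coordinates with alignment length > 1 are malformed.
    """
    if hit.s_start == hit.s_end and hit.alignment_length > 1:
        raise MalformedHitError(
            f"hit {hit.query_id} vs {hit.subject_id}: s_start == s_end == "
            f"{hit.s_start} with alignment_length {hit.alignment_length}"
        )
    return PLUS if hit.s_start <= hit.s_end else MINUS


def parse_blast_tabular(path) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output; ``#`` comment lines are skipped."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns,"
                    f" got {len(parts)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric value in numeric column"
                    f" ({exc})"
                ) from exc
    return hits


def write_blast_tabular(hits: Sequence[AlignmentHit], path) -> int:
    """Serialize hits back to 12-column tabular form (loss-free re-parse)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        repr(h.evalue),
                        repr(h.bitscore),
                    )
                )
                + "\n"
            )
    return len(hits)


@dataclass
class Genome:
    """Ordered label -> upper-case sequence map plus a placed-chromosome set."""

    sequences: dict[str, str]
    whitelist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path, whitelist: Iterable[str] = ()) -> "Genome":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(sequences=seqs, whitelist=frozenset(whitelist))

    def to_fasta(self, path) -> int:
        recs = [
            SeqRecord(Seq(s), id=label, description="")
            for label, s in self.sequences.items()
        ]
        return SeqIO.write(recs, str(path), "fasta")


class _SeedIndex:
    """Sorted rolling-hash index of all length-``s`` windows per subject."""

    def __init__(self, codes_by_label: Mapping[str, np.ndarray], s: int) -> None:
        self.s = s
        self._tables: dict[str, tuple[np.ndarray, np.ndarray] | None] = {}
        for label, c in codes_by_label.items():
            n = c.size
            if n < s:
                self._tables[label] = None
                continue
            acc = np.zeros(n - s + 1, dtype=np.int64)
            for j in range(s):
                acc *= 5
                acc += c[j : j + n - s + 1]
            order = np.argsort(acc, kind="stable")
            self._tables[label] = (acc[order], order)

    def positions(self, label: str, value: int) -> np.ndarray:
        t = self._tables[label]
        if t is None:
            return np.empty(0, dtype=np.int64)
        vals, order = t
        lo = int(np.searchsorted(vals, value, "left"))
        hi = int(np.searchsorted(vals, value, "right"))
        return order[lo:hi]


def _seed_value(codes: np.ndarray) -> int:
    v = 0
    for c in codes.tolist():
        v = v * 5 + int(c)
    return v


def _identity_ok(matches: int, length: int, min_identity: float) -> bool:
    return matches * 100.0 >= min_identity * length - 1e-9


def scan_oligos(
    genome: Genome,
    records: Sequence[OligoRecord],
    min_identity: float = 95.0,
    min_len: int | None = None,
) -> list[AlignmentHit]:
    """Exhaustively align probes to every subject sequence on both strands.

    Candidate alignments have length ``L`` (full probe) or ``L - 1`` (one
    terminal base trimmed, including probes hanging one base off a sequence
    end). A hit is emitted when ``matches / length >= min_identity / 100``.
    When the full-length alignment at a locus passes, the contained trimmed
    alignments are suppressed, so the scanner reports one hit per
    (subject, locus, strand).

    ``min_len`` drops hits shorter than the given length (default ``L - 1``).
    The bitscore of each hit is its integer match count; evalue is 0.

    Candidate loci are found with a pigeonhole seed index (``k + 1`` disjoint
    interior seeds guarantee an exact seed for any alignment with at most
    ``k`` mismatches) and verified by direct comparison; for very short
    probes the scanner falls back to checking every position. ``N`` never
    matches anything, in the probe or the subject.
    """
    codes_by_label = {lab: _encode(s) for lab, s in genome.sequences.items()}
    hits: list[AlignmentHit] = []
    seed_indexes: dict[int, _SeedIndex] = {}

    for rec in records:
        L = len(rec.sequence)
        if L < 2:
            continue
        lo_len = (L - 1) if min_len is None else min_len
        k = int(math.floor(L * (1.0 - min_identity / 100.0)))
        s = (L - 2) // (k + 1)
        pc = _encode(rec.sequence)
        mc = _revcomp_codes(pc)
        use_seeds = s >= 6
        if use_seeds and s not in seed_indexes:
            seed_indexes[s] = _SeedIndex(codes_by_label, s)
        seed_offsets = [1 + i * s for i in range(k + 1)]

        for label, S in codes_by_label.items():
            n = S.size
            if n < L - 1:
                continue
            for strand, probe_codes in ((PLUS, pc), (MINUS, mc)):
                if use_seeds:
                    cand: set[int] = set()
                    index = seed_indexes[s]
                    for o in seed_offsets:
                        v = _seed_value(probe_codes[o : o + s])
                        for q in index.positions(label, v).tolist():
                            p = q - o
                            if -1 <= p <= n - L + 1:
                                cand.add(p)
                    candidates: Iterable[int] = sorted(cand)
                else:
                    candidates = range(-1, n - L + 2)
                for p in candidates:
                    _evaluate_candidate(
                        hits, rec, label, S, probe_codes, strand, p, L, lo_len,
                        min_identity,
                    )
    return hits


def _make_hit(
    rec: OligoRecord,
    label: str,
    strand: str,
    sub_lo: int,
    sub_hi: int,
    q_lo: int,
    q_hi: int,
    length: int,
    mm: int,
) -> AlignmentHit:
    """Build a hit for subject window [sub_lo, sub_hi) (0-based, half-open)."""
    matches = length - mm
    if strand == PLUS:
        s_start, s_end = sub_lo + 1, sub_hi
    else:
        s_start, s_end = sub_hi, sub_lo + 1
    return AlignmentHit(
        query_id=rec.oligo_id,
        subject_id=label,
        percent_identity=round(100.0 * matches / length, 2),
        alignment_length=length,
        mismatches=mm,
        gap_opens=0,
        q_start=q_lo,
        q_end=q_hi,
        s_start=s_start,
        s_end=s_end,
        evalue=0.0,
        bitscore=float(matches),
    )


def _evaluate_candidate(
    hits: list[AlignmentHit],
    rec: OligoRecord,
    label: str,
    S: np.ndarray,
    probe_codes: np.ndarray,
    strand: str,
    p: int,
    L: int,
    lo_len: int,
    min_identity: float,
) -> None:
    n = S.size

    def mm_count(window: np.ndarray, probe: np.ndarray) -> int:
        return int(np.count_nonzero((window != probe) | (window >= 4) | (probe >= 4)))

    # query coordinates: for minus-strand hits probe_codes is the reverse
    # complement, so dropping its first base drops the probe's LAST base.
    if strand == PLUS:
        q_full = (1, L)
        q_drop_first = (2, L)
        q_drop_last = (1, L - 1)
    else:
        q_full = (1, L)
        q_drop_first = (1, L - 1)
        q_drop_last = (2, L)

    if 0 <= p <= n - L:
        window = S[p : p + L]
        mask = (window != probe_codes) | (window >= 4) | (probe_codes >= 4)
        mm = int(np.count_nonzero(mask))
        if L >= lo_len and _identity_ok(L - mm, L, min_identity):
            hits.append(_make_hit(rec, label, strand, p, p + L, *q_full, L, mm))
            return
        if L - 1 < lo_len:
            return
        mm_first = mm - (1 if mask[0] else 0)
        if _identity_ok(L - 1 - mm_first, L - 1, min_identity):
            hits.append(
                _make_hit(rec, label, strand, p + 1, p + L, *q_drop_first, L - 1, mm_first)
            )
        mm_last = mm - (1 if mask[-1] else 0)
        if _identity_ok(L - 1 - mm_last, L - 1, min_identity):
            hits.append(
                _make_hit(rec, label, strand, p, p + L - 1, *q_drop_last, L - 1, mm_last)
            )
    elif p == -1 and L - 1 >= lo_len and n >= L - 1:
        # probe hangs one base off the left end: only the first-trimmed
        # alignment exists
        mm = mm_count(S[0 : L - 1], probe_codes[1:])
        if _identity_ok(L - 1 - mm, L - 1, min_identity):
            hits.append(_make_hit(rec, label, strand, 0, L - 1, *q_drop_first, L - 1, mm))
    elif p == n - L + 1 and L - 1 >= lo_len and n >= L - 1:
        # probe hangs one base off the right end
        mm = mm_count(S[p : p + L - 1], probe_codes[: L - 1])
        if _identity_ok(L - 1 - mm, L - 1, min_identity):
            hits.append(
                _make_hit(rec, label, strand, p, p + L - 1, *q_drop_last, L - 1, mm)
            )
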