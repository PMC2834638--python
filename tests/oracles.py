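"""Independent brute-force oracles used only by the tests.

These deliberately share no candidate-generation machinery with the package:
the alignment oracle checks every subject position directly (naive sliding
Hamming count), and the duplicate oracle compares every probe pair.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

_CODE = {b: i for i, b in enumerate("ACGT")}


def _enc(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int64)


def _ok(matches: int, length: int, min_identity: float) -> bool:
    return matches * 100.0 >= min_identity * length - 1e-9


def _hamming_matches(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero((a == b) & (a < 4) & (b < 4)))


def naive_scan(genome, records, min_identity: float = 95.0, min_len: int | None = None):
    """Set of (query, subject, s_start, s_end, strand, mismatches) tuples.

    Enumerates every full-length window and both one-end-trimmed windows at
    every position on both strands, applies the identity threshold, and
    suppresses a trimmed alignment when the full-length alignment containing
    it already passes.
    """
    out = set()
    for rec in records:
        L = len(rec.sequence)
        lo_len = (L - 1) if min_len is None else min_len
        for label, subject in genome.sequences.items():
            g = _enc(subject)
            n = g.size
            if n < L - 1:
                continue
            for strand, probe in (
                ("plus", rec.sequence),
                ("minus", str(Seq(rec.sequence).reverse_complement())),
            ):
                pr = _enc(probe)

                def coords(lo: int, hi: int) -> tuple[int, int]:
                    # subject window [lo, hi) 0-based -> 1-based BLAST coords
                    return (lo + 1, hi) if strand == "plus" else (hi, lo + 1)

                def emit(lo: int, hi: int, mm: int) -> None:
                    s_start, s_end = coords(lo, hi)
                    out.add((rec.oligo_id, label, s_start, s_end, strand, mm))

                # match count of the full-length window at every position
                W = n - L + 1
                if W >= 1:
                    M = np.zeros(W, dtype=np.int64)
                    first = last = None
                    for j in range(L):
                        okj = (g[j : j + W] == pr[j]) & (pr[j] < 4) & (g[j : j + W] < 4)
                        M += okj
                        if j == 0:
                            first = okj.astype(np.int64)
                        if j == L - 1:
                            last = okj.astype(np.int64)

                    def ok_vec(matches, length):
                        return matches * 100.0 >= min_identity * length - 1e-9

                    full_pass = ok_vec(M, L) if L >= lo_len else np.zeros(W, bool)
                    for p in np.flatnonzero(full_pass):
                        emit(int(p), int(p) + L, L - int(M[p]))
                    if L - 1 >= lo_len:
                        tf = M - first  # drop the probe's first aligned base
                        for p in np.flatnonzero(ok_vec(tf, L - 1) & ~full_pass):
                            emit(int(p) + 1, int(p) + L, L - 1 - int(tf[p]))
                        tl = M - last
                        for p in np.flatnonzero(ok_vec(tl, L - 1) & ~full_pass):
                            emit(int(p), int(p) + L - 1, L - 1 - int(tl[p]))
                if L - 1 >= lo_len:
                    # probe hanging one base off either sequence end
                    m = _hamming_matches(g[0 : L - 1], pr[1:])
                    if _ok(m, L - 1, min_identity):
                        emit(0, L - 1, L - 1 - m)
                    m = _hamming_matches(g[n - L + 1 : n], pr[: L - 1])
                    if _ok(m, L - 1, min_identity):
                        emit(n - L + 1, n, L - 1 - m)
    return out


def hits_as_tuples(hits):
    """Project package hits onto the oracle's comparison tuple."""
    from oligomap.aligner import hit_strand

    return {
        (h.query_id, h.subject_id, h.s_start, h.s_end, hit_strand(h), h.mismatches)
        for h in hits
    }


def all_pairs_duplicates(records):
    """O(n^2) duplicate-pair oracle: compare every pair both ways."""
    pairs = set()
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            id1, id2 = sorted((a.oligo_id, b.oligo_id))
            if a.sequence == b.sequence:
                pairs.add((id1, id2, "identical"))
            elif a.sequence == str(Seq(b.sequence).reverse_complement()):
                pairs.add((id1, id2, "revcomp"))
    return pairs
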