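import pytest
from hypothesis import given
from hypothesis import strategies as st

from oligomap.aligner import AlignmentHit
from oligomap.errors import CoordinateError, ValidationError
from oligomap.locus import (
    BEST_HIT_UNPLACED,
    BOVINE_WHITELIST,
    CHROM_ONLY,
    CROSS_CHROM_TIE,
    NO_HIT,
    UNIQUE,
    call_all,
    call_locus,
    filter_hits,
    snp_position_from_hit,
)


def _hit(subject="1", s_start=101, s_end=150, length=50, bitscore=50.0, query="Q"):
    mism = length - int(bitscore)
    return AlignmentHit(
        query_id=query, subject_id=subject,
        percent_identity=round(100.0 * bitscore / length, 2),
        alignment_length=length, mismatches=max(mism, 0), gap_opens=0,
        q_start=1, q_end=length, s_start=s_start, s_end=s_end,
        evalue=0.0, bitscore=bitscore,
    )


class TestFilterHits:
    def test_unplaced_scaffold_removed(self):
        h = _hit(subject="ChrUn_scaffold_17")
        assert filter_hits([h], BOVINE_WHITELIST, 49) == []

    def test_short_alignment_removed_49_kept(self):
        h48 = _hit(subject="12", length=48, bitscore=48.0)
        h49 = _hit(subject="X", length=49, bitscore=49.0)
        assert filter_hits([h48, h49], BOVINE_WHITELIST, 49) == [h49]

    def test_order_preserved(self):
        hits = [_hit(s_start=i * 100 + 1, s_end=i * 100 + 50) for i in range(5)]
        assert filter_hits(hits, BOVINE_WHITELIST, 49) == hits


class TestPositionRule:
    def test_plus_strand_end_plus_one(self):
        assert snp_position_from_hit(_hit(s_start=9951, s_end=10000)) == 10001

    def test_minus_strand_end_minus_one(self):
        assert snp_position_from_hit(_hit(s_start=2000, s_end=1951)) == 1950

    def test_minus_at_sequence_start_underflows(self):
        with pytest.raises(CoordinateError):
            snp_position_from_hit(_hit(s_start=50, s_end=1))


class TestCallLocus:
    def test_single_hit_unique(self):
        call = call_locus("S", [_hit(subject="19", s_start=9951, s_end=10000)])
        assert (call.chromosome, call.position, call.status) == ("19", 10001, UNIQUE)

    def test_same_chrom_tie_gives_chromosome_only(self):
        hits = [
            _hit(subject="1", s_start=10_001 - 50, s_end=10_000),
            _hit(subject="1", s_start=50_001 - 50, s_end=50_000),
        ]
        call = call_locus("S", hits)
        assert (call.chromosome, call.position, call.status) == ("1", None, CHROM_ONLY)

    def test_cross_chrom_tie_gives_nothing(self):
        hits = [_hit(subject="10"), _hit(subject="4", s_start=901, s_end=950)]
        call = call_locus("S", hits)
        assert (call.chromosome, call.position, call.status) == (None, None, CROSS_CHROM_TIE)

    def test_strict_best_bitscore_wins(self):
        hits = [
            _hit(subject="2", bitscore=50.0),
            _hit(subject="7", length=49, bitscore=48.0, s_start=300, s_end=348),
        ]
        call = call_locus("S", hits)
        assert (call.chromosome, call.status) == ("2", UNIQUE)

    def test_no_hits(self):
        call = call_locus("S", [])
        assert (call.chromosome, call.position, call.status) == (None, None, NO_HIT)

    def test_duplicate_rows_collapse_to_unique(self):
        h = _hit(subject="3")
        call = call_locus("S", [h, h, h])
        assert call.status == UNIQUE

    def test_tied_hits_at_same_derived_position_collapse(self):
        # same locus reported at lengths yielding the same end: still unique
        a = _hit(subject="3", s_start=101, s_end=150)
        b = _hit(subject="3", s_start=102, s_end=150, length=49, bitscore=50.0)
        call = call_locus("S", [a, b])
        assert (call.status, call.position) == (UNIQUE, 151)

    def test_empty_snp_id_rejected(self):
        with pytest.raises(ValidationError):
            call_locus("", [])

    def test_prefilter_ignores_off_whitelist_best(self):
        hits = [
            _hit(subject="ChrUn_scaffold_1", bitscore=50.0),
            _hit(subject="5", length=49, bitscore=49.0, s_start=200, s_end=248),
        ]
        call = call_locus("S", hits, prefilter=True)
        assert (call.chromosome, call.status) == ("5", UNIQUE)

    def test_no_prefilter_best_off_whitelist_is_unplaced(self):
        hits = [
            _hit(subject="ChrUn_scaffold_1", bitscore=50.0),
            _hit(subject="5", length=49, bitscore=49.0, s_start=200, s_end=248),
        ]
        call = call_locus("S", hits, prefilter=False)
        assert (call.chromosome, call.position, call.status) == (
            None, None, BEST_HIT_UNPLACED,
        )

    @given(st.permutations(range(6)))
    def test_permutation_invariant(self, perm):
        hits = []
        for i in range(6):
            hits.append(
                _hit(
                    subject=str((i % 3) + 1),
                    s_start=1000 * i + 1,
                    s_end=1000 * i + 50,
                    bitscore=float(48 + (i % 2) * 2),
                )
            )
        baseline = call_locus("S", hits)
        shuffled = [hits[i] for i in perm]
        assert call_locus("S", shuffled) == baseline


class TestCallAll:
    def test_hitless_snps_still_called(self):
        res = call_all({}, ["A", "B"])
        assert [c.status for c in res.calls] == [NO_HIT, NO_HIT]
        assert res.summary == (0, 0, 2)

    def test_stray_snp_rejected(self):
        with pytest.raises(ValidationError):
            call_all({"X": [_hit(query="X")]}, ["A"])

    def test_summary_partitions_probe_set(self, tiny_fixture):
        from oligomap.aligner import scan_oligos
        from oligomap.locus import group_hits_by_query

        spec, genome, records, truths = tiny_fixture
        hits = scan_oligos(genome, records, spec.min_identity)
        res = call_all(
            group_hits_by_query(hits),
            [r.oligo_id for r in records],
            whitelist=genome.whitelist,
        )
        assert sum(res.summary) == len(records)
        assert sum(res.tally.values()) == len(records)

    def test_fixture_truth_recovered(self, tiny_fixture):
        from oligomap.aligner import scan_oligos
        from oligomap.locus import group_hits_by_query

        spec, genome, records, truths = tiny_fixture
        hits = scan_oligos(genome, records, spec.min_identity)
        res = call_all(
            group_hits_by_query(hits),
            [r.oligo_id for r in records],
            whitelist=genome.whitelist,
        )
        by_id = {t.snp_id: t for t in truths}
        for call in res.calls:
            t = by_id[call.snp_id]
            assert (call.chromosome, call.position, call.status) == (
                t.expected_chromosome, t.expected_position, t.expected_status,
            )
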