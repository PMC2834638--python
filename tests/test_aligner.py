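import numpy as np
import pytest

from oligomap.aligner import (
    AlignmentHit,
    Genome,
    hit_strand,
    parse_blast_tabular,
    scan_oligos,
    write_blast_tabular,
)
from oligomap.errors import MalformedHitError, ParseError
from oligomap.manifest_io import OligoRecord

from oracles import hits_as_tuples, naive_scan


def _hit(**kw):
    base = dict(
        query_id="Q", subject_id="1", percent_identity=100.0,
        alignment_length=50, mismatches=0, gap_opens=0,
        q_start=1, q_end=50, s_start=1, s_end=50, evalue=0.0, bitscore=50.0,
    )
    base.update(kw)
    return AlignmentHit(**base)


def _random_genome(rng, sizes):
    seqs = {
        str(i + 1): "".join(rng.choice(list("ACGT"), n))
        for i, n in enumerate(sizes)
    }
    return Genome(sequences=seqs, whitelist=frozenset(seqs))


class TestBlastTabular:
    def test_comments_skipped_fields_typed(self, tmp_path):
        p = tmp_path / "h.tab"
        p.write_text(
            "# megablast run\n"
            "S1\tChr5\t100.00\t50\t0\t0\t1\t50\t9951\t10000\t1e-20\t99.0\n"
            "S2\tChr5\t98.00\t50\t1\t0\t1\t50\t2000\t1951\t1e-18\t91.0\n"
        )
        hits = parse_blast_tabular(p)
        assert len(hits) == 2
        assert hits[0].s_start == 9951 and hits[0].s_end == 10000
        assert hit_strand(hits[0]) == "plus"
        assert hit_strand(hits[1]) == "minus"
        assert hits[0].evalue == pytest.approx(1e-20)

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "h.tab"
        p.write_text("S1\tChr5\t100.00\n")
        with pytest.raises(ParseError, match="line 1"):
            parse_blast_tabular(p)

    def test_non_numeric_field_rejected(self, tmp_path):
        p = tmp_path / "h.tab"
        p.write_text("S1\tChr5\txx\t50\t0\t0\t1\t50\t1\t50\t0\t50\n")
        with pytest.raises(ParseError):
            parse_blast_tabular(p)

    def test_round_trip_loss_free(self, tmp_path):
        hits = [
            _hit(),
            _hit(query_id="Q2", percent_identity=95.92, alignment_length=49,
                 mismatches=2, s_start=2000, s_end=1952, evalue=1.5e-18,
                 bitscore=47.0),
        ]
        write_blast_tabular(hits, tmp_path / "h.tab")
        assert parse_blast_tabular(tmp_path / "h.tab") == hits


class TestHitStrand:
    def test_plus_minus(self):
        assert hit_strand(_hit(s_start=10, s_end=59)) == "plus"
        assert hit_strand(_hit(s_start=59, s_end=10)) == "minus"

    def test_degenerate_coordinates_rejected(self):
        with pytest.raises(MalformedHitError):
            hit_strand(_hit(s_start=5, s_end=5, alignment_length=50))


class TestScanOligos:
    def test_planted_plus_probe_found_exactly(self):
        rng = np.random.default_rng(0)
        genome = _random_genome(rng, [12_000])
        probe = genome.sequences["1"][9950:10000]  # 0-based -> coords 9951..10000
        hits = scan_oligos(genome, [OligoRecord("P", probe)])
        assert len(hits) == 1
        h = hits[0]
        assert (h.s_start, h.s_end, h.alignment_length) == (9951, 10000, 50)
        assert h.percent_identity == 100.0 and h.bitscore == 50.0

    def test_planted_minus_probe_has_descending_coords(self):
        from oligomap.duplicates import reverse_complement

        rng = np.random.default_rng(1)
        genome = _random_genome(rng, [5_000])
        probe = reverse_complement(genome.sequences["1"][1950:2000])
        hits = scan_oligos(genome, [OligoRecord("P", probe)])
        assert len(hits) == 1
        assert (hits[0].s_start, hits[0].s_end) == (2000, 1951)
        assert hit_strand(hits[0]) == "minus"

    def test_three_interior_mismatches_below_threshold(self):
        rng = np.random.default_rng(2)
        genome = _random_genome(rng, [5_000])
        probe = list(genome.sequences["1"][100:150])
        for i in (10, 25, 40):
            probe[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[probe[i]]
        hits = scan_oligos(genome, [OligoRecord("P", "".join(probe))], 95.0)
        assert hits == []  # 47/50 matches = 94% < 95%

    def test_terminal_mismatch_yields_full_length_hit(self):
        # one mismatched terminal base: the 50-mer still passes at 98%, and
        # the contained perfect 49-mer is suppressed
        rng = np.random.default_rng(3)
        genome = _random_genome(rng, [5_000])
        probe = list(genome.sequences["1"][300:350])
        probe[0] = {"A": "C", "C": "G", "G": "T", "T": "A"}[probe[0]]
        hits = scan_oligos(genome, [OligoRecord("P", "".join(probe))], 95.0)
        assert len(hits) == 1
        assert hits[0].alignment_length == 50 and hits[0].mismatches == 1

    def test_all_n_probe_has_no_hits(self):
        rng = np.random.default_rng(4)
        genome = _random_genome(rng, [2_000])
        assert scan_oligos(genome, [OligoRecord("P", "N" * 50)]) == []

    def test_every_hit_meets_length_and_identity_contract(self, tiny_fixture):
        _, genome, records, _ = tiny_fixture
        for h in scan_oligos(genome, records, 95.0):
            assert h.alignment_length in (49, 50)
            matches = h.alignment_length - h.mismatches
            assert matches * 100.0 >= 95.0 * h.alignment_length - 1e-9
            assert h.bitscore == float(matches)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_oracle_with_planted_mutants(self, seed):
        rng = np.random.default_rng(seed)
        genome = _random_genome(rng, [4_000, 2_500])
        records = []
        labels = list(genome.sequences)
        for i in range(12):
            lab = labels[i % 2]
            seq = genome.sequences[lab]
            p = int(rng.integers(0, len(seq) - 50))
            probe = list(seq[p : p + 50])
            for j in rng.choice(50, size=int(rng.integers(0, 4)), replace=False):
                probe[int(j)] = str(rng.choice([c for c in "ACGT" if c != probe[int(j)]]))
            records.append(OligoRecord(f"P{i}", "".join(probe)))
        got = hits_as_tuples(scan_oligos(genome, records, 95.0))
        assert got == naive_scan(genome, records, 95.0)
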