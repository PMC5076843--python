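import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadloop.candidates import get_candidate
from quadloop.g4_scanner import (
    CANONICAL,
    PLL1,
    PLL3,
    G4Hit,
    PatternSpec,
    classify_hit,
    deduplicate_hits,
    scan_sequence,
    scan_transcript,
    write_hits,
)
from quadloop.oracle import exhaustive_scan
from quadloop.sequence_model import TranscriptRecord


def hit_key(hit):
    return (hit.start, hit.end, hit.track_lengths, hit.loop_lengths)


class TestPatternSpec:
    def test_builtin_bounds(self):
        assert PLL1.loop_bounds == ((1, 40), (1, 7), (1, 7))
        assert PLL3.loop_bounds == ((1, 7), (1, 7), (1, 40))
        assert CANONICAL.loop_bounds == ((1, 7), (1, 7), (1, 7))

    def test_min_track_below_three_rejected(self):
        with pytest.raises(ValueError):
            PatternSpec("BAD", ((1, 7),) * 3, min_track_len=2)

    def test_bad_loop_bounds_rejected(self):
        with pytest.raises(ValueError):
            PatternSpec("BAD", ((0, 7), (1, 7), (1, 7)))


class TestScanSequence:
    def test_tef_lazy_parse_carves_loop1_from_g_run(self):
        # loop 1 is "GGGC" despite the leading 6-G run; loops (4, 1, 26)
        seq = (
            "GGG" + "GGGC" + "GGG" + "C" + "GGG"
            + "GGAGGCGAGGUGCGCGAGCCGAGUCC" + "GGG"
        )
        assert len(seq) == 43
        (hit,) = scan_sequence(seq, PLL3)
        assert hit.loop_lengths == (4, 1, 26)
        assert hit.loop_seq(0) == "GGGC"
        assert (hit.start, hit.end) == (0, 43)

    def test_no_g_no_hit(self):
        assert scan_sequence("AUAUAUAU", PLL3) == []

    @pytest.mark.parametrize("pattern", [PLL1, PLL3, CANONICAL])
    def test_unique_tiling(self, pattern):
        (hit,) = scan_sequence("GGGAGGGAGGGAGGG", pattern)
        assert hit.loop_lengths == (1, 1, 1)
        assert hit.track_lengths == (3, 3, 3, 3)

    def test_lazy_parse_matches_frozen_oracle_value(self):
        # expected computed with the exhaustive-tiling reference parser:
        # minimal parse leaves the final G outside the match
        (hit,) = scan_sequence("GGGGAGGGAGGGAGGGG", CANONICAL)
        assert hit_key(hit) == (0, 16, (3, 3, 3, 3), (2, 1, 1))

    def test_non_overlap_resumes_at_hit_end(self):
        one = "GGGAGGGAGGGAGGG"
        hits = scan_sequence(one + "AU" + one, CANONICAL)
        assert len(hits) == 2
        assert hits[0].end <= hits[1].start

    def test_sentinel_counts_as_loop_nucleotide_only(self):
        (hit,) = scan_sequence("GGGNGGGAGGGAGGG", CANONICAL)
        assert hit.loop_seq(0) == "N"
        assert scan_sequence("GGNGGGGAU", CANONICAL) == []

    def test_decomposition_tiles_hit(self):
        for pattern in (PLL1, PLL3):
            for hit in scan_sequence("GGGACGGGUGGGAAGGGCCGGGUGGGAGGGAAAGGG", pattern):
                spans = [s for pair in zip(hit.tracks, hit.loops + ((None, None),)) for s in pair][:-1]
                assert spans[0][0] == hit.start
                assert spans[-1][1] == hit.end
                for (_, a_end), (b_start, _) in zip(spans, spans[1:]):
                    assert a_end == b_start
                for i in range(4):
                    assert set(hit.track_seq(i)) == {"G"}


class TestCandidateReconstruction:
    @pytest.mark.parametrize(
        "gene", ["TEF", "B3GNT8", "CYSRT1", "DCTN5", "STRIP2", "KIF26A", "GRIA1"]
    )
    def test_published_rows_rescan_exactly(self, gene):
        row = get_candidate(gene)
        (hit,) = scan_sequence(row.reconstruct(), row.pattern)
        assert hit.loop_lengths == row.loop_lengths
        assert hit.end - hit.start == row.length


class TestScanTranscript:
    def test_hit_inside_utr3_kept(self, make_transcript):
        motif = "GGGAGGGAGGGAGGG"
        rec = make_transcript(utr3="AAAA" + motif + "AAAA")
        (hit,) = scan_transcript(rec, CANONICAL)
        assert hit.region_kind == "utr3"
        assert hit.utr_position == 5
        assert hit.gene == rec.gene

    def test_hit_straddling_cds_utr3_boundary_kept_with_negative_position(self):
        # 55-nt hit starting 6 nt before the 3'-UTR: 49/55 nt in UTR
        row = get_candidate("TADA3")
        motif = row.reconstruct()
        assert len(motif) == 55
        utr5 = "A" * 30
        cds_before = "C" * 54
        cds_end = len(utr5) + len(cds_before) + 6
        seq = utr5 + cds_before + motif + "U" * 40
        rec = TranscriptRecord("NM_006354", "TADA3", seq, len(utr5), cds_end)
        (hit,) = scan_transcript(rec, PLL1)
        assert hit.region_kind == "utr3"
        assert hit.utr_position == -6

    def test_hit_fully_in_cds_dropped(self, make_transcript):
        rec = make_transcript(cds="AUG" + "GGGAGGGAGGGAGGG" + "C" * 12)
        assert scan_transcript(rec, CANONICAL) == []

    def test_majority_cds_hit_dropped(self, make_transcript):
        # 15-nt hit with only 5 nt in the 3'-UTR: majority in CDS
        motif = "GGGAGGGAGGGAGGG"
        rec = make_transcript(
            cds="AUG" + "C" * 10 + motif[:10], utr3=motif[10:] + "U" * 30
        )
        assert scan_transcript(rec, CANONICAL) == []


class TestClassifyHit:
    def _hit(self, loops):
        parts = []
        for i, L in enumerate(loops):
            parts.append("GGG")
            parts.append("A" * L)
        parts.append("GGG")
        seq = "".join(parts)
        bounds = []
        p = 0
        lengths = [3, loops[0], 3, loops[1], 3, loops[2], 3]
        for length in lengths:
            bounds.append((p, p + length))
            p += length
        return G4Hit(0, p, tuple(bounds[0::2]), tuple(bounds[1::2]), seq, "X")

    def test_long_loop1(self):
        assert classify_hit(self._hit((38, 1, 4))) == "long_loop1"

    def test_canonical(self):
        assert classify_hit(self._hit((1, 1, 1))) == "canonical"

    def test_long_loop3(self):
        assert classify_hit(self._hit((4, 1, 26))) == "long_loop3"

    def test_long_both_warns(self):
        with pytest.warns(UserWarning):
            assert classify_hit(self._hit((10, 1, 10))) == "long_both"

    def test_overlong_loop_rejected(self):
        with pytest.raises(ValueError):
            classify_hit(self._hit((41, 1, 1)))


class TestDeduplicateHits:
    def _hit(self, gene, seq="GGGAGGGAGGGAGGG", region="utr3", acc="NM_1"):
        h = scan_sequence(seq, CANONICAL)[0]
        h.gene = gene
        h.region_kind = region
        h.transcript_accession = acc
        return h

    def test_isoform_duplicates_collapse(self):
        hits = [self._hit("G1", acc="NM_1"), self._hit("G1", acc="NM_2")]
        out = deduplicate_hits(hits)
        assert len(out) == 1
        assert out[0].multiplicity == 2
        assert out[0].transcript_accession == "NM_1"

    def test_same_sequence_different_genes_kept(self):
        out = deduplicate_hits([self._hit("G1"), self._hit("G2")])
        assert len(out) == 2

    def test_same_gene_different_region_kept(self):
        out = deduplicate_hits([self._hit("G1", region="utr5"), self._hit("G1")])
        assert len(out) == 2

    def test_idempotent(self):
        hits = [self._hit("G1"), self._hit("G1"), self._hit("G2")]
        once = deduplicate_hits(hits)
        twice = deduplicate_hits(once)
        assert [(h.gene, h.multiplicity) for h in twice] == [
            (h.gene, h.multiplicity) for h in once
        ]

    def test_input_not_mutated(self):
        hits = [self._hit("G1"), self._hit("G1")]
        deduplicate_hits(hits)
        assert all(h.multiplicity == 1 for h in hits)


class TestWriteHits:
    def test_zero_hits_header_only(self, tmp_path):
        path = tmp_path / "hits.tsv"
        write_hits([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("accession\tgene")

    def test_one_hit_parts_sum_to_length(self, tmp_path, make_transcript):
        rec = make_transcript(utr3="AA" + "GGGAGGGAGGGAGGG" + "UU" * 10)
        hits = scan_transcript(rec, CANONICAL)
        path = tmp_path / "hits.tsv"
        write_hits(hits, path)
        header, row = path.read_text().splitlines()
        fields = dict(zip(header.split("\t"), row.split("\t")))
        parts = sum(
            len(fields[c]) for c in ("track1", "track2", "track3", "track4",
                                     "loop1", "loop2", "loop3")
        )
        assert parts == int(fields["length"]) == len(fields["sequence"])

    def test_bed_reproduces_span(self, tmp_path, make_transcript):
        rec = make_transcript(utr3="AA" + "GGGAGGGAGGGAGGG" + "U" * 20)
        (hit,) = scan_transcript(rec, CANONICAL)
        path = tmp_path / "hits.bed"
        write_hits([hit], path, format="bed")
        chrom, start, end, name, score, strand = (
            path.read_text().strip().split("\t")
        )
        assert (chrom, int(start), int(end)) == (
            rec.accession, hit.start, hit.end,
        )
        assert name.endswith("|canonical") and strand == "+"

    def test_bad_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_hits([], tmp_path / "x", format="gff")


class TestOracleEquivalence:
    @settings(max_examples=300, deadline=None)
    @given(
        seq=st.text(alphabet="GGGACU", min_size=1, max_size=60),
        pattern=st.sampled_from([PLL1, PLL3, CANONICAL]),
    )
    def test_scan_equals_exhaustive_tiling(self, seq, pattern):
        assert [hit_key(h) for h in scan_sequence(seq, pattern)] == [
            hit_key(h) for h in exhaustive_scan(seq, pattern)
        ]

    @settings(max_examples=200, deadline=None)
    @given(seq=st.text(alphabet="GGACU", min_size=1, max_size=60))
    def test_non_overlap_invariant(self, seq):
        for pattern in (PLL1, PLL3):
            hits = scan_sequence(seq, pattern)
            for a, b in zip(hits, hits[1:]):
                assert a.end <= b.start

    def test_adversarial_fixtures(self):
        fixtures = [
            "G" * 60,                      # one long run
            "GGG" * 8,                     # runs only
            "GGGG" + "G" * 3 + "CGGGAGGGAGGG",
            "GGGCGGGGCGGGGGCGGGGGG",
            "GGGGGGC" + "GGG" + "C" + "GGG" + "A" * 26 + "GGG",
            "AGGGAGGGAGGGAGGGAGGGAGGGA",   # more tracks than needed
        ]
        for seq in fixtures:
            for pattern in (PLL1, PLL3, CANONICAL):
                assert [hit_key(h) for h in scan_sequence(seq, pattern)] == [
                    hit_key(h) for h in exhaustive_scan(seq, pattern)
                ], (seq, pattern.name)
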