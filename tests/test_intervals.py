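"""Interval model, overlap algebra, format parsing and contact QC stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopscape.intervals import (
    ContactStats,
    GenomicInterval,
    Loop,
    ParseError,
    Peak,
    SignalTrack,
    aggregate_contact_stats,
    find_overlaps,
    merge_intervals,
    overlap_length,
    read_genes_bed12,
    read_intervals,
    read_loops,
    write_bed,
    write_bedgraph,
    write_loops,
)


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)

    def test_midpoint_and_length(self):
        iv = GenomicInterval("chr1", 100000, 110000)
        assert iv.length == 10000
        assert iv.midpoint == 105000


class TestOverlapAlgebra:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 0, 100), ("chr1", 50, 150), 50),
            (("chr1", 0, 100), ("chr1", 100, 200), 0),  # half-open abutment
            (("chr1", 0, 100), ("chr2", 0, 100), 0),
            (("chr1", 10, 20), ("chr1", 0, 100), 10),  # containment
        ],
    )
    def test_overlap_length_examples(self, a, b, expected):
        assert overlap_length(GenomicInterval(*a), GenomicInterval(*b)) == expected

    @given(
        s1=st.integers(0, 1000), l1=st.integers(1, 500),
        s2=st.integers(0, 1000), l2=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_overlap_symmetric_and_bounded(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        ov = overlap_length(a, b)
        assert ov == overlap_length(b, a)
        assert 0 <= ov <= min(a.length, b.length)

    def test_find_overlaps_simple(self):
        q = [GenomicInterval("chr1", 0, 10)]
        s = [GenomicInterval("chr1", 5, 8), GenomicInterval("chr1", 20, 30)]
        assert find_overlaps(q, s) == [(0, 0)]
        assert find_overlaps(q, []) == []

    def test_find_overlaps_matches_quadratic_oracle(self):
        rng = np.random.default_rng(42)

        def random_set(n):
            out = []
            for _ in range(n):
                chrom = f"chr{rng.integers(1, 4)}"
                start = int(rng.integers(0, 5000))
                out.append(
                    GenomicInterval(chrom, start, start + int(rng.integers(1, 300)))
                )
            return out

        for _ in range(5):
            q, s = random_set(200), random_set(200)
            expected = {
                (qi, si)
                for qi, a in enumerate(q)
                for si, b in enumerate(s)
                if overlap_length(a, b) > 0
            }
            got = find_overlaps(q, s)
            assert set(got) == expected
            assert got == find_overlaps(q, s)  # deterministic order

    def test_merge_intervals_abutting_do_not_merge(self):
        merged = merge_intervals(
            [
                GenomicInterval("chr1", 0, 100),
                GenomicInterval("chr1", 100, 200),
                GenomicInterval("chr1", 150, 300),
            ]
        )
        assert [(m.start, m.end) for m in merged] == [(0, 100), (100, 300)]


class TestLoopParsing:
    def test_loop_size_from_midpoints(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t100000\t110000\tchr1\t500000\t510000\n")
        res = read_loops(p)
        assert len(res.loops) == 1
        assert res.loops[0].size == 400000

    def test_anchor_order_normalised(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t500000\t510000\tchr1\t100000\t110000\n")
        lp = read_loops(p).loops[0]
        assert lp.anchor1.midpoint < lp.anchor2.midpoint
        assert lp.anchor1.start == 100000

    def test_interchromosomal_skipped_with_census(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text(
            "chr1\t0\t10000\tchr2\t0\t10000\n"
            "chr1\t0\t10000\tchr1\t50000\t60000\n"
        )
        res = read_loops(p)
        assert len(res.loops) == 1
        assert res.n_skipped_interchromosomal == 1

    def test_hiccups_header_skipped_silently(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text(
            "chr1\tx1\tx2\tchr2\ty1\ty2\tcolor\n"
            "chr1\t0\t10000\tchr1\t50000\t60000\t0,0,255\n"
        )
        res = read_loops(p)
        assert len(res.loops) == 1
        assert res.loops[0].extras == ("0,0,255",)

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text(
            "chr1\t0\t10000\tchr1\t50000\t60000\n"
            "chr1\t0\tBAD\tchr1\t50000\t60000\n"
        )
        with pytest.raises(ParseError, match=":2"):
            read_loops(p)

    def test_loop_roundtrip(self, tmp_path, small_sim):
        _, _, outdir = small_sim
        res = read_loops(outdir / "loops_epi.bedpe")
        out = tmp_path / "rt.bedpe"
        write_loops(out, res.loops)
        res2 = read_loops(out)
        assert [
            (l.anchor1.start, l.anchor2.end) for l in res.loops
        ] == [(l.anchor1.start, l.anchor2.end) for l in res2.loops]


class TestBedFamilyParsing:
    def test_bed3(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        (iv,) = read_intervals(p, format="bed3")
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 0, 100)

    def test_narrowpeak_summit_absolute(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t200\t400\tpk1\t0\t.\t8.5\t-1\t-1\t50\n")
        (pk,) = read_intervals(p, format="narrowPeak")
        assert pk.center == 250
        assert pk.signal == 8.5

    def test_narrowpeak_missing_summit(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t200\t400\tpk1\t0\t.\t8.5\t-1\t-1\t-1\n")
        (pk,) = read_intervals(p, format="narrowPeak")
        assert pk.summit_offset is None
        assert pk.center == 300  # midpoint fallback

    def test_bedgraph_overlap_rejected(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t10\t0.5\nchr1\t5\t15\t0.6\n")
        with pytest.raises(ParseError, match="overlap"):
            read_intervals(p, format="bedGraph")

    def test_start_ge_end_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(ParseError):
            read_intervals(p, format="bed3")

    def test_bed_roundtrip(self, tmp_path):
        ivs = [
            GenomicInterval("chr1", 0, 100, "+", "x", 3.0),
            GenomicInterval("chr2", 50, 70, "-", "y", 1.0),
        ]
        p = tmp_path / "rt.bed"
        write_bed(p, ivs, columns=6)
        back = read_intervals(p, format="bed6")
        assert [(b.chrom, b.start, b.end, b.strand, b.name) for b in back] == [
            (a.chrom, a.start, a.end, a.strand, a.name) for a in ivs
        ]

    def test_bedgraph_roundtrip(self, tmp_path):
        track = SignalTrack(
            [
                (GenomicInterval("chr1", 0, 50), 0.5),
                (GenomicInterval("chr1", 50, 80), 0.25),
            ]
        )
        p = tmp_path / "rt.bedgraph"
        write_bedgraph(p, track)
        back = read_intervals(p, format="bedGraph")
        assert [
            (iv.start, iv.end, v) for iv, v in back.iter_records()
        ] == [(0, 50, 0.5), (50, 80, 0.25)]

    def test_bed12_gene_models(self, small_sim):
        _, truth, outdir = small_sim
        genes = read_genes_bed12(outdir / "genes.bed12")
        assert len(genes) == len(truth.genes)
        by_id = {g.gene_id: g for g in genes}
        for rec in truth.genes:
            g = by_id[rec["gene_id"]]
            assert (g.tx_start, g.tx_end, g.strand, g.coding) == (
                rec["tx_start"], rec["tx_end"], rec["strand"], rec["coding"],
            )
            assert g.exons[0][0] == g.tx_start and g.exons[-1][1] == g.tx_end


class TestSignalTrack:
    def test_mean_over_is_length_weighted(self):
        track = SignalTrack(
            [
                (GenomicInterval("chr1", 0, 10), 1.0),
                (GenomicInterval("chr1", 10, 40), 2.0),
            ]
        )
        # [0,20): 10 bp at 1.0 and 10 bp at 2.0
        assert track.mean_over("chr1", 0, 20) == pytest.approx(1.5)
        # uncovered bases contribute nothing, not zero
        assert track.mean_over("chr1", 35, 100) == pytest.approx(2.0)
        assert np.isnan(track.mean_over("chr1", 50, 60))
        assert np.isnan(track.mean_over("chrX", 0, 10))


class TestContactStats:
    def test_printed_totals_aggregate_to_billions(self):
        stats = [
            ContactStats("ES", 643.2e6, 0.108),
            ContactStats("epithelium", 588.0e6, 0.241),
            ContactStats("fiber", 699.1e6, 0.322),
        ]
        summary = aggregate_contact_stats(stats)
        assert summary.total_billions == 1.93

    def test_rounding_and_errors(self):
        s = aggregate_contact_stats([ContactStats("x", 1e6, 0.0)])
        assert s.total_millions == 1.0
        assert s.total_billions == 0.0
        with pytest.raises(ValueError):
            aggregate_contact_stats([])
        with pytest.raises(ValueError):
            ContactStats("x", -5, 0.0)
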