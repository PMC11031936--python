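"""Peak sharing, CTCF-anchored loops, meta-profiles and the cross-analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from loopscape.ctcf import (
    classify_loop_ctcf,
    classify_loops_ctcf,
    classify_sharing,
    cross_analysis,
    metaprofile,
    sharing_percent_from_counts,
    three_way_sharing,
)
from loopscape.intervals import (
    GeneModel,
    GenomicInterval,
    Loop,
    Peak,
    SignalTrack,
    read_intervals,
    read_loops,
)


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestClassifySharing:
    def test_overlapping_pair_is_shared(self):
        res, labeled = classify_sharing([_iv(0, 100)], [_iv(50, 150)])
        assert (res.n_shared, res.n_specific1, res.n_specific2) == (1, 0, 0)
        assert res.union == 1 and res.percent_shared == 100.0
        assert labeled[0][1] == "shared"

    def test_disjoint_singletons(self):
        res, _ = classify_sharing([_iv(0, 100)], [_iv(200, 300)])
        assert (res.n_shared, res.union, res.percent_shared) == (0, 2, 0.0)

    def test_union_identity_and_symmetry(self):
        rng = np.random.default_rng(8)

        def peaks(n):
            return [
                _iv(int(s), int(s) + int(rng.integers(10, 200)))
                for s in rng.integers(0, 5000, size=n)
            ]

        for _ in range(20):
            s1, s2 = peaks(15), peaks(15)
            res, _ = classify_sharing(s1, s2)
            assert res.union == res.n_shared + res.n_specific1 + res.n_specific2
            rev, _ = classify_sharing(s2, s1)
            assert (rev.n_shared, rev.n_specific1, rev.n_specific2) == (
                res.n_shared, res.n_specific2, res.n_specific1,
            )

    def test_printed_count_arithmetic(self):
        """With 16,424 and 23,859 peaks of which 11,947 match one-to-one,
        the shared share of the union is 42.2%."""
        assert sharing_percent_from_counts(16_424, 23_859, 11_947) == 42.2

    def test_generator_membership_recovered_exactly(self, tmp_path):
        from conftest import SMALL_CONFIG_KWARGS
        from loopscape.synthetic import SimConfig, generate

        kwargs = dict(
            SMALL_CONFIG_KWARGS,
            ctcf_at_anchor_prob=0.0,
            n_peaks_epi_only=30,
            n_peaks_fib_only=50,
            n_peaks_shared=20,
            seed=3,
        )
        generate(SimConfig(**kwargs), tmp_path)
        epi = read_intervals(tmp_path / "ctcf_epi.narrowPeak", format="narrowPeak")
        fib = read_intervals(tmp_path / "ctcf_fib.narrowPeak", format="narrowPeak")
        res, _ = classify_sharing(epi, fib)
        assert (res.n_specific1, res.n_specific2, res.n_shared) == (30, 50, 20)


class TestThreeWaySharing:
    def test_identical_sets_only_triple_region(self):
        sets = {name: [_iv(0, 100), _iv(500, 600)] for name in "ABC"}
        counts = three_way_sharing(sets)
        assert counts[("A", "B", "C")] == 2
        assert sum(counts.values()) == 2

    def test_disjoint_sets_only_singletons(self):
        sets = {"A": [_iv(0, 10)], "B": [_iv(100, 110)], "C": [_iv(200, 210)]}
        counts = three_way_sharing(sets)
        assert counts[("A",)] == counts[("B",)] == counts[("C",)] == 1
        assert sum(counts.values()) == 3

    def test_matches_per_basepair_oracle(self):
        # abutting intervals are kept as separate events by design, which a
        # per-basepair oracle cannot see; resample the rare abutting draws
        rng = np.random.default_rng(17)
        done = 0
        while done < 10:
            sets = {
                name: [
                    _iv(int(s), int(s) + int(rng.integers(5, 60)))
                    for s in rng.integers(0, 800, size=6)
                ]
                for name in "ABC"
            }
            all_ivs = [iv for ivs in sets.values() for iv in ivs]
            if any(
                a.end == b.start for a in all_ivs for b in all_ivs
            ):
                continue
            done += 1
            counts = three_way_sharing(sets)
            # brute force: per-basepair coverage, then contiguous runs of
            # covered bases form the union events
            cover = {name: np.zeros(1000, dtype=bool) for name in sets}
            for name, ivs in sets.items():
                for iv in ivs:
                    cover[name][iv.start:iv.end] = True
            any_cov = cover["A"] | cover["B"] | cover["C"]
            expected: dict[tuple[str, ...], int] = {}
            pos = 0
            while pos < 1000:
                if not any_cov[pos]:
                    pos += 1
                    continue
                end = pos
                while end < 1000 and any_cov[end]:
                    end += 1
                combo = tuple(
                    n for n in sorted(sets) if cover[n][pos:end].any()
                )
                expected[combo] = expected.get(combo, 0) + 1
                pos = end
            assert {k: v for k, v in counts.items() if v} == expected


class TestLoopCtcfClass:
    LOOP = Loop(_iv(1000, 2000), _iv(5000, 6000))

    def test_zero_one_two_bound_anchors(self):
        both = [_iv(1400, 1600), _iv(5400, 5600)]
        assert classify_loop_ctcf(self.LOOP, both) == 2
        assert classify_loop_ctcf(self.LOOP, both[:1]) == 1
        assert classify_loop_ctcf(self.LOOP, []) == 0

    def test_abutting_peak_needs_slack(self):
        abutting = [_iv(2000, 2100)]  # half-open: no overlap at slack 0
        assert classify_loop_ctcf(self.LOOP, abutting, slack=0) == 0
        assert classify_loop_ctcf(self.LOOP, abutting, slack=1) == 1

    def test_negative_slack_rejected(self):
        with pytest.raises(ValueError):
            classify_loop_ctcf(self.LOOP, [], slack=-1)

    def test_proportions_partition(self):
        rng = np.random.default_rng(9)
        loops = [
            Loop(_iv(int(m), int(m) + 100, "chr1"), _iv(int(m) + 500, int(m) + 600))
            for m in rng.integers(0, 50_000, size=40)
        ]
        peaks = [
            _iv(int(s), int(s) + 80) for s in rng.integers(0, 55_000, size=30)
        ]
        counts, props = classify_loops_ctcf(loops, peaks)
        assert sum(counts.values()) == 40
        assert sum(props.values()) == pytest.approx(1.0)

    def test_all_anchors_bound_when_planted(self, tmp_path):
        from conftest import SMALL_CONFIG_KWARGS
        from loopscape.synthetic import SimConfig, generate

        kwargs = dict(
            SMALL_CONFIG_KWARGS,
            ctcf_at_anchor_prob=1.0,
            n_peaks_epi_only=0,
            n_peaks_fib_only=0,
            n_peaks_shared=0,
            seed=4,
        )
        generate(SimConfig(**kwargs), tmp_path)
        loops = read_loops(tmp_path / "loops_epi.bedpe").loops
        peaks = read_intervals(tmp_path / "ctcf_epi.narrowPeak", format="narrowPeak")
        counts, _ = classify_loops_ctcf(loops, peaks)
        assert counts == {0: 0, 1: 0, 2: len(loops)}


class TestMetaProfile:
    def test_constant_track_gives_constant_profile(self):
        track = SignalTrack([(_iv(0, 100_000), 0.8)])
        peaks = [
            Peak(_iv(c - 200, c + 200), summit_offset=200)
            for c in (20_000, 50_000, 80_000)
        ]
        profile = metaprofile(peaks, track, flank=5000, bin_size=100)
        assert np.allclose(profile.mean_value, 0.8)
        assert np.all(profile.n_contributing == 3)

    def test_flank_must_divide_into_bins(self):
        with pytest.raises(ValueError):
            metaprofile([], SignalTrack([]), flank=5000, bin_size=300)

    def test_uncovered_bins_are_missing(self):
        track = SignalTrack([(_iv(9_900, 10_100), 1.0)])
        peaks = [Peak(_iv(9_800, 10_200), summit_offset=200)]
        profile = metaprofile(peaks, track, flank=1000, bin_size=100)
        center = profile.center_index
        assert profile.mean_value[center] == pytest.approx(1.0)
        assert profile.n_contributing[0] == 0
        assert math.isnan(profile.mean_value[0])

    def test_planted_dip_matches_closed_form(self):
        """A linear methylation dip (baseline 0.8, depth 0.7, half-width 250)
        sampled on a 50-bp CpG grid: the profile must equal the closed-form
        average of the dip over the CpGs covered by each offset bin."""
        baseline, depth, halfwidth, spacing = 0.8, 0.7, 250, 50
        center = 10_000
        records = []
        for g in range(0, 20_000, spacing):
            v = baseline
            if abs(g - center) <= halfwidth:
                v = baseline - depth * (1 - abs(g - center) / halfwidth)
            records.append((_iv(g, g + 2), v))
        track = SignalTrack(records)
        peaks = [Peak(_iv(center - 200, center + 200), summit_offset=200)]
        profile = metaprofile(peaks, track, flank=5000, bin_size=100)

        # independent closed-form oracle: unweighted mean over the CpGs in
        # each 100-bp bin (each CpG record has identical width)
        for i, off in enumerate(profile.offsets):
            lo, hi = center + off, center + off + 100
            cpgs = [g for g in range(0, 20_000, spacing) if lo < g + 2 and g < hi]
            vals = []
            for g in cpgs:
                v = baseline
                if abs(g - center) <= halfwidth:
                    v = baseline - depth * (1 - abs(g - center) / halfwidth)
                vals.append(v)
            assert profile.mean_value[i] == pytest.approx(np.mean(vals))
        center_bin = profile.center_index
        # CpGs at offsets 0 and +50 -> (0.10 + 0.24) / 2
        assert profile.mean_value[center_bin] == pytest.approx(0.17)
        # beyond the dip the profile sits at baseline
        assert profile.mean_value[0] == pytest.approx(baseline)


def _tx(gene_id, tx_id, start, end, coding=True):
    return GeneModel(
        gene_id=gene_id, transcript_id=tx_id, chrom="chr1", strand="+",
        tx_start=start, tx_end=end, coding=coding,
    )


class TestCrossAnalysis:
    def _expr(self, values):
        return pd.DataFrame(
            {"fib": list(values.values())}, index=pd.Index(values, name="gene_id")
        )

    def test_constant_track_mean_independent_of_length(self):
        expr = self._expr({"g1": 100.0})
        genes = [_tx("g1", "g1.t1", 1000, 9000)]
        track = SignalTrack([(_iv(0, 20_000), 2.0)])
        df, _ = cross_analysis(expr, genes, {"epi": track}, track, rank_by="fib")
        assert df["ctcf_epi_mean"].iloc[0] == pytest.approx(2.0)
        assert df["polii_mean"].iloc[0] == pytest.approx(2.0)

    def test_longest_transcript_chosen(self):
        expr = self._expr({"g1": 10.0})
        genes = [
            _tx("g1", "g1.short", 1000, 6000),
            _tx("g1", "g1.long", 1000, 9000),
        ]
        track = SignalTrack([(_iv(0, 20_000), 1.0)])
        df, _ = cross_analysis(expr, genes, {}, track, rank_by="fib")
        assert df["transcript_id"].iloc[0] == "g1.long"

    def test_coding_only_filter_counts(self):
        # 120 genes; the top 100 by expression contain 20 non-coding
        values = {f"g{i:03d}": 1000.0 - i for i in range(120)}
        expr = self._expr(values)
        genes = [
            _tx(f"g{i:03d}", f"g{i:03d}.t", 1000 + 100 * i, 1050 + 100 * i,
                coding=not (i < 100 and i % 5 == 0))
            for i in range(120)
        ]
        track = SignalTrack([(_iv(0, 20_000), 1.0)])
        df, _ = cross_analysis(
            expr, genes, {}, track, rank_by="fib", top_n=100, coding_only=True
        )
        assert len(df) == 80
        df_all, _ = cross_analysis(
            expr, genes, {}, track, rank_by="fib", top_n=100, coding_only=False
        )
        assert len(df_all) == 100

    def test_missing_model_censused(self):
        expr = self._expr({"g1": 10.0, "ghost": 5.0})
        genes = [_tx("g1", "g1.t", 1000, 2000)]
        track = SignalTrack([(_iv(0, 20_000), 1.0)])
        df, warns = cross_analysis(expr, genes, {}, track, rank_by="fib")
        assert len(df) == 1
        assert any("ghost" in w for w in warns)

    def test_crystallin_like_genes_lead_joint_signal(self, small_sim):
        """Planted high-expression genes carry the highest joint gene-body
        Pol II / CTCF signal in the generator output."""
        from loopscape.intervals import read_expression, read_genes_bed12

        _, truth, outdir = small_sim
        expr = read_expression(outdir / "expression.tsv")
        genes = read_genes_bed12(outdir / "genes.bed12")
        tracks = {
            cell: read_intervals(
                outdir / f"ctcf_cov_{cell}.bedgraph", format="bedGraph"
            )
            for cell in ("epi", "fib")
        }
        polii = read_intervals(outdir / "polII.bedgraph", format="bedGraph")
        df, _ = cross_analysis(
            expr, genes, tracks, polii, rank_by="fib", top_n=20
        )
        crystallin = {g["gene_id"] for g in truth.genes if g["crystallin"]}
        joint = (df["polii_mean"] * df["ctcf_fib_mean"]).sort_values(
            ascending=False
        )
        top_ids = set(df.loc[joint.index[: len(crystallin)], "gene_id"])
        assert top_ids == crystallin

    def test_deterministic_and_bounded(self, small_sim):
        from loopscape.intervals import read_expression, read_genes_bed12

        _, _, outdir = small_sim
        expr = read_expression(outdir / "expression.tsv")
        genes = read_genes_bed12(outdir / "genes.bed12")
        track = read_intervals(outdir / "polII.bedgraph", format="bedGraph")
        df1, _ = cross_analysis(expr, genes, {}, track, rank_by="fib", top_n=30)
        df2, _ = cross_analysis(expr, genes, {}, track, rank_by="fib", top_n=30)
        assert len(df1) <= 30
        pd.testing.assert_frame_equal(df1, df2)
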