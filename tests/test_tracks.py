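"""Binned tracks, z-scoring, metaplots and boundary contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from chromage.genome import DataError, GenomeLayout, RegionSet
from chromage.tracks import (BinnedTrack, bin_coverage, boundary_contrast,
                             compute_matrix, log2_ratio_track, read_bedgraph,
                             replicate_correlation, summarize_matrix,
                             track_to_windows, windowed_read_counts,
                             write_bedgraph, zscore_track)

from conftest import regions


def make_track(values, bin_size=20, kind="log2ratio", mask=None, chrom="chrI"):
    values = np.asarray(values, float)
    layout = GenomeLayout({chrom: len(values) * bin_size})
    m = None if mask is None else {chrom: np.asarray(mask, bool)}
    return BinnedTrack(layout, bin_size, {chrom: values}, m, kind)


def reads(*triples):
    df = pd.DataFrame(triples, columns=["chrom", "start", "end"])
    df["strand"] = "."
    return df


class TestBinCoverage:
    def test_single_read_extends(self):
        layout = GenomeLayout({"chrI": 1000})
        track, clipped = bin_coverage(reads(("chrI", 0, 50)), layout, bin_size=20, extend=200)
        assert clipped == 0
        v = track.values["chrI"]
        assert np.array_equal(v[:10], np.ones(10))   # bins covering [0, 200)
        assert np.array_equal(v[10:], np.zeros(40))

    def test_empty_placements(self):
        layout = GenomeLayout({"chrI": 1000})
        track, clipped = bin_coverage(pd.DataFrame(columns=["chrom", "start", "end"]), layout)
        assert track.total() == 0 and clipped == 0

    def test_clipping_counted(self):
        layout = GenomeLayout({"chrI": 300})
        _, clipped = bin_coverage(reads(("chrI", 200, 250)), layout, extend=200)
        assert clipped == 1

    def test_unknown_chromosome(self):
        with pytest.raises(DataError):
            bin_coverage(reads(("chrX", 0, 50)), GenomeLayout({"chrI": 1000}))

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(3)
        L, bs, ext = 5_000, 20, 200
        layout = GenomeLayout({"chrI": L})
        starts = rng.integers(0, L - 60, size=100)
        rws = reads(*[("chrI", int(s), int(s) + 50) for s in starts])
        track, _ = bin_coverage(rws, layout, bin_size=bs, extend=ext)
        oracle = np.zeros(L // bs)
        for s in starts:
            lo, hi = int(s), min(int(s) + ext, L)
            oracle[lo // bs:(hi - 1) // bs + 1] += 1  # 1 per overlapped bin
        assert np.array_equal(track.values["chrI"], oracle)


class TestLog2Ratio:
    def test_identity(self):
        t = make_track(np.full(50, 7.0), kind="coverage")
        out = log2_ratio_track(t, t, smooth=0)
        assert np.allclose(out.flat(), 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(20, 100).astype(float) + 1
        t = make_track(base, kind="coverage")
        t2 = make_track(base * 2, kind="coverage")
        c = make_track(rng.poisson(20, 100).astype(float) + 1, kind="coverage")
        a = log2_ratio_track(t, c, smooth=0).flat()
        b = log2_ratio_track(t2, c, smooth=0).flat()
        # readCount scaling absorbs a global depth change up to pseudocount effects
        assert np.abs(a - b).max() < 0.05

    def test_hand_case_unscaled(self):
        t = make_track(np.array([8.0, 8.0, 8.0]), kind="coverage")
        c = make_track(np.array([2.0, 2.0, 2.0]), kind="coverage")
        out = log2_ratio_track(t, c, smooth=0, pseudocount=0.5, scale=False)
        assert np.allclose(out.flat(), math.log2(8.5 / 2.5))
        assert abs(out.flat()[0] - 1.7655) < 5e-5

    def test_both_zero_masked(self):
        t = make_track(np.array([4.0, 0.0, 4.0]), kind="coverage")
        c = make_track(np.array([4.0, 0.0, 4.0]), kind="coverage")
        out = log2_ratio_track(t, c, smooth=0)
        assert not out.mask["chrI"][1] and out.mask["chrI"][0]

    def test_bin_size_mismatch(self):
        t = make_track(np.ones(10), bin_size=20, kind="coverage")
        c = make_track(np.ones(10), bin_size=40, kind="coverage")
        # layouts differ too; bin size check fires first
        with pytest.raises(DataError):
            log2_ratio_track(t, c)

    def test_smoothing_is_centered_boxcar(self):
        vals = np.array([0.0, 0.0, 3.0, 0.0, 0.0])
        t = make_track(2 ** vals * 10, kind="coverage")
        c = make_track(np.full(5, 10.0), kind="coverage")
        out = log2_ratio_track(t, c, smooth=60, pseudocount=0.0, scale=False)  # 3-bin boxcar
        v = out.flat()
        assert np.allclose(v, [0.0, 1.0, 1.0, 1.0, 0.0])


class TestZscore:
    def test_hand_case(self):
        z = zscore_track(make_track([1.0, 2.0, 3.0]))
        assert np.allclose(z.flat(), [-1.2247, 0.0, 1.2247], atol=5e-5)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        z = zscore_track(make_track(rng.normal(3, 2, 500)))
        v = z.flat()
        assert abs(v.mean()) < 1e-12
        assert abs(v.std(ddof=0) - 1) < 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        a = zscore_track(make_track(x)).flat()
        b = zscore_track(make_track(3.5 * x - 2.0)).flat()
        assert np.allclose(a, b)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        z1 = zscore_track(make_track(rng.normal(0, 1, 200)))
        z2 = zscore_track(z1)
        assert np.allclose(z1.flat(), z2.flat())

    def test_constant_track_errors(self):
        with pytest.raises(DataError, match="constant"):
            zscore_track(make_track(np.full(10, 2.0)))

    def test_wrong_kind_errors(self):
        with pytest.raises(DataError):
            zscore_track(make_track(np.arange(10.0), kind="coverage"))

    def test_mask_excluded_from_moments(self):
        z = zscore_track(make_track([1.0, 2.0, 3.0, 99.0], mask=[True, True, True, False]))
        assert np.allclose(z.flat(), [-1.2247, 0.0, 1.2247], atol=5e-5)


class TestWindowedCounts:
    def test_window_count_1mb(self):
        layout = GenomeLayout({"chrI": 1_000_000})
        v = windowed_read_counts(pd.DataFrame(columns=["chrom", "start", "end"]), layout, 15_000)
        assert len(v) == 67 and not v.any()

    def test_all_reads_one_window(self):
        layout = GenomeLayout({"chrI": 100_000})
        r = reads(*[("chrI", 42_000 + i, 42_050 + i) for i in range(10)])
        v = windowed_read_counts(r, layout, 15_000)
        assert v[2] == 10 and v.sum() == 10

    def test_five_prime_assignment(self):
        layout = GenomeLayout({"chrI": 30_000})
        r = reads(("chrI", 14_990, 15_040))  # 5' end 14990 -> window 0
        assert windowed_read_counts(r, layout, 15_000).tolist() == [1, 0]

    def test_bad_window(self):
        with pytest.raises(DataError):
            windowed_read_counts(reads(), GenomeLayout({"chrI": 100}), 0)


class TestReplicateCorrelation:
    def test_self_and_negation(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        mat, defined = replicate_correlation([v, v, -v])
        assert mat[0, 1] == pytest.approx(1.0)
        assert mat[0, 2] == pytest.approx(-1.0)
        assert defined.all()

    def test_zero_variance_flagged(self):
        mat, defined = replicate_correlation([np.array([1.0, 2.0]), np.array([3.0, 3.0])])
        assert np.isnan(mat[0, 1]) and not defined[0, 1]

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            replicate_correlation([np.zeros(3), np.zeros(4)])

    def test_fixture_replicates_highly_correlated(self, fx):
        # 15 kb windows of the control coverage tracks; the assay design
        # makes H3 profiles nearly identical across replicates and ages
        vecs = [track_to_windows(fx.tracks[("control", age, rep)], 15_000)
                for age in ("young", "old") for rep in (1, 2)]
        mat, defined = replicate_correlation(vecs)
        assert defined.all()
        off = mat[~np.eye(4, dtype=bool)]
        assert off.min() >= 0.95
        # young vs old control agreement specifically
        assert mat[0, 2] >= 0.99


class TestComputeMatrix:
    def test_constant_track(self):
        track = make_track(np.full(500, 2.5), kind="zscore")
        m, short = compute_matrix(track, regions(("chrI", 2000, 4000)), flank=400, body_bins=10)
        assert short == 0
        assert m.values.shape == (1, 2 * 20 + 10)
        assert np.allclose(m.values[m.mask], 2.5)

    def test_shape_contract_defaults(self):
        track = make_track(np.arange(2000.0), bin_size=20, kind="zscore")
        rs = regions(("chrI", 10_000, 14_000), ("chrI", 20_000, 26_000))
        m, _ = compute_matrix(track, rs)  # flank=2000, body_bins=100
        assert m.values.shape == (2, 300)
        assert m.flank_bins == 100

    def test_flank_past_chrom_end_masked(self):
        track = make_track(np.ones(100), bin_size=20, kind="zscore")
        m, _ = compute_matrix(track, regions(("chrI", 0, 400)), flank=200, body_bins=5)
        assert not m.mask[0, :10].any()      # upstream flank off the chromosome
        assert m.mask[0, 10:].all()

    def test_short_region_masked_and_counted(self):
        track = make_track(np.ones(100), bin_size=20, kind="zscore")
        m, short = compute_matrix(track, regions(("chrI", 500, 510), ("chrI", 600, 900)),
                                  flank=100, body_bins=5)
        assert short == 1
        assert not m.mask[0].any() and m.mask[1].any()

    def test_empty_regions_error(self):
        track = make_track(np.ones(10), kind="zscore")
        with pytest.raises(DataError):
            compute_matrix(track, RegionSet())

    def test_mirror_image_reverses_columns(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 400)
        bs = 20
        L = len(vals) * bs
        fwd = make_track(vals, bin_size=bs, kind="zscore")
        rev = make_track(vals[::-1].copy(), bin_size=bs, kind="zscore")
        s, e = 3000, 3000 + 10 * bs  # body of 10 bins aligned to the grid
        m_f, _ = compute_matrix(fwd, regions(("chrI", s, e)), flank=400, body_bins=10)
        m_r, _ = compute_matrix(rev, regions(("chrI", L - e, L - s)), flank=400, body_bins=10)
        assert np.allclose(m_f.values[0], m_r.values[0][::-1])


class TestSummarizeMatrix:
    def test_identical_rows_zero_ci(self):
        track = make_track(np.full(200, 1.5), kind="zscore")
        m, _ = compute_matrix(track, regions(("chrI", 1000, 2000), ("chrI", 2500, 3500)),
                              flank=200, body_bins=5)
        s = summarize_matrix(m)
        assert np.allclose(s["mean"], 1.5)
        assert np.allclose(s["ci95_halfwidth"], 0.0)

    def test_hand_two_rows(self):
        from chromage.tracks import MetaMatrix
        m = MetaMatrix(values=np.array([[0.0, 0.0], [2.0, 2.0]]),
                       mask=np.ones((2, 2), dtype=bool), flank_bins=1, body_bins=0,
                       region_names=["a", "b"])
        s = summarize_matrix(m)
        assert np.allclose(s["mean"], 1.0)
        assert np.allclose(s["ci95_halfwidth"], 1.96)  # sd(ddof=1)=sqrt(2), /sqrt(2)=1

    def test_ci_shrinks_with_sqrt_n(self):
        from chromage.tracks import MetaMatrix
        base = np.array([[0.0], [2.0]])
        m2 = MetaMatrix(base, np.ones((2, 1), bool), 1, 0, ["a", "b"])
        m8 = MetaMatrix(np.tile(base, (4, 1)), np.ones((8, 1), bool), 1, 0, list("abcdefgh"))
        ci2 = summarize_matrix(m2)["ci95_halfwidth"][0]
        ci8 = summarize_matrix(m8)["ci95_halfwidth"][0]
        # duplicating rows 4x shrinks the CI by a bit more than 2 (sample SD shrinks too)
        assert ci8 < ci2 / 2 + 1e-9

    def test_single_row_errors(self):
        from chromage.tracks import MetaMatrix
        m = MetaMatrix(np.zeros((1, 2)), np.ones((1, 2), bool), 1, 0, ["a"])
        with pytest.raises(DataError):
            summarize_matrix(m)

    def test_fully_masked_column_flagged(self):
        from chromage.tracks import MetaMatrix
        mask = np.array([[True, False], [True, False]])
        m = MetaMatrix(np.ones((2, 2)), mask, 1, 0, ["a", "b"])
        s = summarize_matrix(m)
        assert s["defined"].tolist() == [True, False]
        assert np.isnan(s["mean"][1])


class TestBoundaryContrast:
    def test_step_track(self):
        vals = np.ones(100)
        vals[25:75] = 0.0  # region [500, 1500) at bin 20
        track = make_track(vals, kind="zscore")
        table, skipped = boundary_contrast(track, regions(("chrI", 500, 1500)), w=200, mark="active")
        assert skipped == 0
        assert np.allclose(table["contrast"], 1.0)

    def test_repressive_sign_flipped(self):
        vals = np.zeros(100)
        vals[25:75] = 1.0
        track = make_track(vals, kind="zscore")
        table, _ = boundary_contrast(track, regions(("chrI", 500, 1500)), w=200, mark="repressive")
        assert np.allclose(table["contrast"], 1.0)

    def test_constant_track_zero(self):
        track = make_track(np.full(100, 3.0), kind="zscore")
        table, _ = boundary_contrast(track, regions(("chrI", 500, 1500)), w=200)
        assert np.allclose(table["contrast"], 0.0)

    def test_edge_near_chrom_end_skipped(self):
        track = make_track(np.ones(50), kind="zscore")
        table, skipped = boundary_contrast(track, regions(("chrI", 0, 400)), w=200)
        assert skipped == 1          # left edge outside window leaves chromosome
        assert len(table) == 1

    def test_window_smaller_than_bin_errors(self):
        track = make_track(np.ones(50), kind="zscore")
        with pytest.raises(DataError):
            boundary_contrast(track, regions(("chrI", 100, 200)), w=10)


class TestBedgraphIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        vals = np.round(rng.normal(0, 1, 60), 3)
        mask = np.ones(60, bool)
        mask[10:15] = False
        track = make_track(vals, bin_size=25, kind="zscore", mask=mask)
        write_bedgraph(track, tmp_path / "t.bedgraph")
        back = read_bedgraph(tmp_path / "t.bedgraph", track.layout, 25, kind="zscore")
        assert np.array_equal(back.mask["chrI"], mask)
        assert np.allclose(back.values["chrI"][mask], vals[mask], atol=1e-4)

    def test_runs_collapsed(self, tmp_path):
        track = make_track(np.array([1.0, 1.0, 2.0]), bin_size=10, kind="zscore")
        write_bedgraph(track, tmp_path / "t.bedgraph")
        assert (tmp_path / "t.bedgraph").read_text() == "chrI\t0\t20\t1\nchrI\t20\t30\t2\n"
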