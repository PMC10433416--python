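import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cutregulon import enrichment
from cutregulon.enrichment import (
    EnrichmentParams,
    local_enrichment_track,
    midpoint,
    read_alignments,
    read_track,
    window_grid,
    write_track,
)
from cutregulon.errors import InvalidParameterError, ParseError, UnsupportedInputError
from conftest import naive_window_counts, readset_from_midpoints


class TestWindowGrid:
    def test_default_geometry(self):
        starts, ends = window_grid(3000)
        assert len(starts) == 199  # floor((3000-30)/15)+1
        assert starts[0] == 0 and starts[-1] == 2970
        assert (np.diff(starts) == 15).all()
        assert (ends - starts == 30).all()

    def test_single_window(self):
        starts, _ = window_grid(30)
        assert list(starts) == [0]

    def test_shorter_than_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            window_grid(29)


@pytest.mark.parametrize(
    "read,expected", [((100, 175), 137), ((0, 1), 0), ((10, 12), 11)]
)
def test_midpoint_floor(read, expected):
    assert midpoint(read) == expected


class TestParams:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidParameterError):
            EnrichmentParams(window_len=40, step=15, bg_span=30)
        with pytest.raises(InvalidParameterError):
            EnrichmentParams(window_len=30, step=31)

    def test_default_pseudo_density(self):
        assert EnrichmentParams().eps == pytest.approx(1 / 3000)


class TestLocalEnrichment:
    def test_uniform_coverage_gives_unity(self):
        # exactly one midpoint per nt everywhere: window and background
        # densities are both 1, so E = (1+eps)/(1+eps) = 1 at every window,
        # including clipped terminal ones
        L = 6000
        rs = readset_from_midpoints(range(L), genome_length=L)
        track = local_enrichment_track(rs, L)
        assert (track.enrichment == 1.0).all()

    def test_tenfold_spike(self):
        # 10 midpoints in one interior window, 90 spread over the rest of its
        # background: E ~ (10/30)/(100/3000) = 10 within 2%
        L = 10_000
        win_start = 4995  # a grid window (4995 = 333*15), centre 5010
        mids = [win_start + 3 * k for k in range(10)]
        lo, hi = 5010 - 1500, 5010 + 1500
        bg = np.linspace(lo, hi - 1, 90).astype(int)
        bg = [int(b) for b in bg if not (win_start <= b < win_start + 30)]
        rs = readset_from_midpoints(mids + bg, genome_length=L)
        track = local_enrichment_track(rs, L)
        idx = int(np.flatnonzero(track.starts == win_start)[0])
        expected = (10 / 30) / (len(rs) / 3000)
        assert track.enrichment[idx] == pytest.approx(expected, rel=0.02)
        assert track.enrichment[idx] == pytest.approx(10.0, rel=0.05)

    def test_empty_readset_gives_unity(self):
        rs = readset_from_midpoints([], genome_length=12_000)
        track = local_enrichment_track(rs, 12_000)
        assert (track.enrichment == 1.0).all()

    def test_containment_invariant(self, rng):
        L = 8000
        mids = rng.integers(0, L, 400)
        track = local_enrichment_track(readset_from_midpoints(mids, L), L)
        assert (track.n_window <= track.n_background).all()
        assert (track.bg_len <= track.params.bg_span).all()

    def test_monotonicity_adding_midpoint(self, rng):
        L = 9000
        mids = list(rng.integers(0, L, 300))
        t0 = local_enrichment_track(readset_from_midpoints(mids, L), L)
        target = 300  # a window index well in the interior
        extra = int(t0.starts[target]) + 5
        t1 = local_enrichment_track(readset_from_midpoints(mids + [extra], L), L)
        assert t1.enrichment[target] >= t0.enrichment[target]

    def test_duplication_invariance_without_pseudo(self, rng):
        L = 6000
        params = EnrichmentParams(pseudo_density=0.0)
        mids = list(rng.integers(0, L, 500))
        t1 = local_enrichment_track(readset_from_midpoints(mids, L), L, params)
        t2 = local_enrichment_track(readset_from_midpoints(mids + mids, L), L, params)
        valid = t1.n_background > 0
        assert np.array_equal(t1.enrichment[valid], t2.enrichment[valid])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        L=st.integers(min_value=100, max_value=5000),
        n=st.integers(min_value=0, max_value=500),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_sweep_matches_bruteforce_oracle(self, L, n, seed):
        params = EnrichmentParams()
        if L < params.window_len:
            return
        mids = np.random.default_rng(seed).integers(0, L, n)
        track = local_enrichment_track(readset_from_midpoints(mids, L), L, params)
        win, bg = naive_window_counts(mids, L, params)
        assert np.array_equal(track.n_window, win)
        assert np.array_equal(track.n_background, bg)


class TestTrackIO:
    def test_round_trip(self, tmp_path, rng):
        L = 6000
        mids = rng.integers(0, L, 200)
        track = local_enrichment_track(readset_from_midpoints(mids, L), L)
        p = tmp_path / "t.bedgraph"
        write_track(track, p)
        back = read_track(p, genome_length=L)
        assert np.array_equal(back.starts, track.starts)
        assert np.allclose(back.enrichment, track.enrichment, rtol=1e-5)

    def test_empty_track_header_only(self, tmp_path):
        import cutregulon.enrichment as E

        empty = E.EnrichmentTrack(
            sample=None, params=EnrichmentParams(), genome_length=0,
            starts=np.empty(0, dtype=np.int64), n_window=np.empty(0, dtype=np.int64),
            n_background=np.empty(0, dtype=np.int64),
            bg_len=np.empty(0, dtype=np.int64), enrichment=np.empty(0),
        )
        p = tmp_path / "e.bedgraph"
        write_track(empty, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")

    def test_overlapping_windows_emitted_as_is(self, tmp_path):
        L = 3000
        track = local_enrichment_track(readset_from_midpoints([10, 20], L), L)
        p = tmp_path / "o.bedgraph"
        write_track(track, p)
        rows = [l.split("\t") for l in p.read_text().splitlines()[1:]]
        starts = [int(r[1]) for r in rows]
        assert starts == list(track.starts)  # overlap preserved, 15-nt steps


class TestReadAlignments:
    def test_bed_line(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr\t100\t175\tr1\t0\t+\n")
        rs = read_alignments(p)
        assert list(rs) == [(100, 175, "+")]

    def test_bed_bad_interval(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr\t175\t100\tr1\t0\t+\n")
        with pytest.raises(ParseError, match="2|end"):
            read_alignments(p)

    def test_bed_multi_chromosome_rejected(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t0\t10\tr\t0\t+\nchr2\t0\t10\tr\t0\t+\n")
        with pytest.raises(UnsupportedInputError):
            read_alignments(p)

    def test_sam_unmapped_skipped(self, tmp_path):
        p = tmp_path / "r.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr\tLN:1000\n"
            "m\t0\tchr\t101\t60\t50M\t*\t0\t0\t*\t*\n"
            "u\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
        )
        rs = read_alignments(p)
        assert len(rs) == 1 and rs.n_skipped == 1
        assert list(rs) == [(100, 150, "+")]  # SAM is 1-based
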