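import numpy as np
import pytest

from cutregulon.model import ReadSet, SampleSpec


def readset_from_midpoints(midpoints, genome_length=None, sample=None):
    """Build a ReadSet of 1-nt reads whose midpoints are exactly ``midpoints``.

    A read (m, m+1) has midpoint floor((2m+1)/2) = m, so window counts over
    these reads are direct counts of the given positions.
    """
    m = np.asarray(sorted(midpoints), dtype=np.int64)
    return ReadSet(
        sample=sample,
        starts=m,
        ends=m + 1,
        strands=np.array(["+"] * len(m)),
        genome_length=genome_length,
    )


def naive_window_counts(midpoints, genome_length, params):
    """Brute-force oracle: recount midpoints per window and per background
    region by scanning every midpoint for every window independently of the
    sweep implementation."""
    mids = list(midpoints)
    win, bg = [], []
    start = 0
    while start + params.window_len <= genome_length:
        end = start + params.window_len
        centre = start + params.window_len // 2
        lo = max(centre - params.bg_span // 2, 0)
        hi = min(centre + params.bg_span // 2, genome_length)
        win.append(sum(1 for m in mids if start <= m < end))
        bg.append(sum(1 for m in mids if lo <= m < hi))
        start += params.step
    return np.array(win), np.array(bg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def sample_tag():
    return SampleSpec("Sc", True, "DNAD", 1, seed=11)


@pytest.fixture
def sample_ctrl():
    return SampleSpec("Sc", False, "DNAD", 1, seed=12)
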