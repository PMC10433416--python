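"""Replicate-aware binding-site calling from tagged/control enrichment.

A window is significantly bound when the tagged:control enrichment ratio
exceeds the fold threshold (default, strictly greater than 2) in every
replicate — the most conservative reading of a duplicate design, under
which one noisy replicate cannot manufacture a peak.  Flagged windows are
merged into peaks, bridging at most ``max_gap_windows`` sub-threshold
windows (adjacent 30/15 windows overlap, so one ragged window should not
split a biological site).  The summit is the centre of the window with the
highest min-over-replicates ratio, leftmost on ties.

No library-size scaling is applied anywhere: E is locally normalized, so
sequencing depth cancels in the tagged:control ratio by construction.
No multiple-testing correction is applied either — the plain fold rule is
the method; its false-positive behaviour is characterised empirically in
:mod:`cutregulon.benchmarks`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncompatibleTrackError, InvalidParameterError
from .enrichment import EnrichmentParams, EnrichmentTrack, local_enrichment_track
from .model import ReadSet


@dataclass(frozen=True)
class PeakCallParams:
    """Fold threshold and merge behaviour for binding-site calling."""

    threshold: float = 2.0
    min_replicates: int | None = None  # None = all replicates must exceed
    max_gap_windows: int = 1

    def __post_init__(self):
        if self.threshold <= 1:
            raise InvalidParameterError("threshold must be > 1")
        if self.max_gap_windows < 0:
            raise InvalidParameterError("max_gap_windows must be >= 0")
        if self.min_replicates is not None and self.min_replicates < 1:
            raise InvalidParameterError("min_replicates must be >= 1")


@dataclass
class RatioTrack:
    """Per-window tagged:control enrichment ratio on a shared grid."""

    tag_label: str
    control_label: str
    starts: np.ndarray
    centres: np.ndarray
    genome_length: int
    params: EnrichmentParams
    ratio: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class Peak:
    """A merged run of significantly enriched windows.

    ``start``/``end`` are 0-based half-open; ``summit`` is the 0-based
    centre of the best window (use :attr:`summit_1based` in reports).
    ``per_replicate_ratios`` are each replicate's ratio at the summit
    window.
    """

    start: int
    end: int
    summit: int
    max_ratio: float
    per_replicate_ratios: tuple[float, ...]
    n_windows: int

    @property
    def summit_1based(self) -> int:
        return self.summit + 1


def ratio_track(tag: EnrichmentTrack, control: EnrichmentTrack) -> RatioTrack:
    """Per-window R = E_tag / E_control for one replicate pair."""
    if not tag.same_grid(control) or tag.params != control.params:
        raise IncompatibleTrackError(
            "tagged and control tracks must share grid and parameters"
        )
    return RatioTrack(
        tag_label=tag.sample.label if tag.sample else "tag",
        control_label=control.sample.label if control.sample else "control",
        starts=tag.starts,
        centres=tag.centres,
        genome_length=tag.genome_length,
        params=tag.params,
        ratio=tag.enrichment / control.enrichment,
    )


def call_enriched_windows(
    ratios: list[RatioTrack], params: PeakCallParams = PeakCallParams()
) -> np.ndarray:
    """Boolean flag per grid window: ratio strictly above threshold in
    (by default) every replicate."""
    if not ratios:
        raise InvalidParameterError("need at least one replicate ratio track")
    n = len(ratios[0])
    for r in ratios[1:]:
        if len(r) != n or r.params.step != ratios[0].params.step:
            raise IncompatibleTrackError("replicate ratio tracks must share a grid")
    need = len(ratios) if params.min_replicates is None else min(
        params.min_replicates, len(ratios))
    above = np.stack([r.ratio > params.threshold for r in ratios])
    return above.sum(axis=0) >= need


def merge_windows(
    flags: np.ndarray,
    ratios: list[RatioTrack],
    params: PeakCallParams = PeakCallParams(),
) -> list[Peak]:
    """Merge flagged windows into peaks, bridging short sub-threshold gaps.

    The replicate-combined score per window is the min over replicates
    (matching the flag rule); the summit is the centre of the best-scoring
    window in the run, leftmost on ties.
    """
    grid = ratios[0]
    if len(flags) != len(grid):
        raise IncompatibleTrackError("flag vector does not match the grid")
    idx = np.flatnonzero(flags)
    if len(idx) == 0:
        return []
    min_ratio = np.min(np.stack([r.ratio for r in ratios]), axis=0)
    window_len = grid.params.window_len

    runs: list[tuple[int, int]] = []
    run_start = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= params.max_gap_windows + 1:
            prev = i
        else:
            runs.append((run_start, prev))
            run_start = prev = i
    runs.append((run_start, prev))

    peaks = []
    for a, b in runs:
        flagged = idx[(idx >= a) & (idx <= b)]
        best = flagged[np.argmax(min_ratio[flagged])]  # argmax -> leftmost tie
        peaks.append(
            Peak(
                start=int(grid.starts[a]),
                end=int(grid.starts[b]) + window_len,
                summit=int(grid.centres[best]),
                max_ratio=float(min_ratio[best]),
                per_replicate_ratios=tuple(float(r.ratio[best]) for r in ratios),
                n_windows=int(len(flagged)),
            )
        )
    return peaks


def call_peaks(
    tag_readsets: list[ReadSet],
    control_readsets: list[ReadSet],
    genome_length: int,
    enrichment_params: EnrichmentParams = EnrichmentParams(),
    peak_params: PeakCallParams = PeakCallParams(),
) -> list[Peak]:
    """End-to-end: enrichment per sample → per-replicate ratio → flags → peaks.

    Tagged and control read sets are paired replicate-wise and must come in
    equal numbers.
    """
    if not tag_readsets or len(tag_readsets) != len(control_readsets):
        raise InvalidParameterError(
            "need equal, non-zero numbers of tagged and control read sets"
        )
    ratios = []
    for tag_rs, ctl_rs in zip(tag_readsets, control_readsets):
        tag_tr = local_enrichment_track(tag_rs, genome_length, enrichment_params)
        ctl_tr = local_enrichment_track(ctl_rs, genome_length, enrichment_params)
        ratios.append(ratio_track(tag_tr, ctl_tr))
    flags = call_enriched_windows(ratios, peak_params)
    return merge_windows(flags, ratios, peak_params)


# ---------------------------------------------------------------------------
# I/O


def write_peaks_tsv(peaks: list[Peak], path) -> None:
    """TSV report: 1-based summit, extent, combined and per-replicate ratios."""
    with open(path, "w") as fh:
        fh.write("summit\tstart\tend\tmax_ratio\tn_windows\tper_replicate_ratios\n")
        for p in peaks:
            reps = ",".join(f"{r:.4g}" for r in p.per_replicate_ratios)
            fh.write(
                f"{p.summit_1based}\t{p.start}\t{p.end}\t{p.max_ratio:.4g}\t"
                f"{p.n_windows}\t{reps}\n"
            )


def read_peaks_tsv(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            summit, start, end, max_ratio, n_windows, reps = line.rstrip("\n").split("\t")
            peaks.append(
                Peak(
                    start=int(start), end=int(end), summit=int(summit) - 1,
                    max_ratio=float(max_ratio), n_windows=int(n_windows),
                    per_replicate_ratios=tuple(
                        float(x) for x in reps.split(",") if x),
                )
            )
    return peaks


def write_peaks_bed(peaks: list[Peak], path, chrom: str = "chr") -> None:
    """BED6 peaks; score = 100 x max_ratio capped at 1000."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = min(int(round(100 * p.max_ratio)), 1000)
            fh.write(f"{chrom}\t{p.start}\t{p.end}\tpeak{i}\t{score}\t.\n")
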