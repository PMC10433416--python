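"""Normalized local enrichment along the chromosome.

The statistic: slide a 30-nt window in 15-nt steps along the chromosome and
compare the density of fragment midpoints inside the window to the density
in the 3000-nt region surrounding (and containing) the window,

    E = (n_window / window_len + eps) / (n_background / bg_len + eps)

with a pseudo-density ``eps = 1 / bg_span`` added to both densities so that
empty regions score exactly 1 and deep-coverage values are asymptotically
unchanged.  Because the window is contained in its background, E is capped
at ``bg_span / window_len`` (100 at defaults) and ``n_window <=
n_background`` always holds.

Each read contributes once, at its midpoint ``floor((start + end) / 2)``;
strand is ignored.  At the chromosome ends the background is clipped to the
chromosome and the density uses the actual clipped length, so terminal
windows are not penalized.  The chromosome is linear: nothing wraps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, ParseError, UnsupportedInputError
from .model import ReadSet, SampleSpec


@dataclass(frozen=True)
class EnrichmentParams:
    """Window geometry and zero-safety for the local-enrichment sweep."""

    window_len: int = 30
    step: int = 15
    bg_span: int = 3000
    pseudo_density: float | None = None  # defaults to 1 / bg_span

    def __post_init__(self):
        if self.window_len <= 0 or self.step <= 0 or self.bg_span <= 0:
            raise InvalidParameterError("window_len, step and bg_span must be > 0")
        if self.window_len > self.bg_span:
            raise InvalidParameterError("window_len must be <= bg_span")
        if self.step > self.window_len:
            raise InvalidParameterError("step must be <= window_len")
        if self.pseudo_density is not None and self.pseudo_density < 0:
            raise InvalidParameterError("pseudo_density must be >= 0")

    @property
    def eps(self) -> float:
        return 1.0 / self.bg_span if self.pseudo_density is None else self.pseudo_density


@dataclass(frozen=True)
class WindowScore:
    """One window's counts and enrichment value."""

    window_start: int
    window_end: int
    n_window: int
    n_background: int
    bg_len_actual: int
    enrichment: float


@dataclass
class EnrichmentTrack:
    """Per-window enrichment over the full grid, as parallel arrays."""

    sample: SampleSpec | None
    params: EnrichmentParams
    genome_length: int
    starts: np.ndarray  # window starts, 0-based
    n_window: np.ndarray
    n_background: np.ndarray
    bg_len: np.ndarray
    enrichment: np.ndarray

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.params.window_len

    @property
    def centres(self) -> np.ndarray:
        return self.starts + self.params.window_len // 2

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def scores(self) -> list[WindowScore]:
        return [
            WindowScore(int(s), int(s) + self.params.window_len, int(nw), int(nb),
                        int(bl), float(e))
            for s, nw, nb, bl, e in zip(
                self.starts, self.n_window, self.n_background, self.bg_len,
                self.enrichment)
        ]

    def same_grid(self, other: "EnrichmentTrack") -> bool:
        return (
            self.genome_length == other.genome_length
            and self.params.window_len == other.params.window_len
            and self.params.step == other.params.step
            and len(self) == len(other)
        )


def window_grid(genome_length: int, params: EnrichmentParams = EnrichmentParams()):
    """Window starts/ends covering the chromosome: 0, step, 2*step, ...

    The last window is the largest start with ``start + window_len <=
    genome_length``; there is no wraparound.
    """
    if genome_length < params.window_len:
        raise InvalidParameterError(
            f"genome_length {genome_length} shorter than window {params.window_len}"
        )
    starts = np.arange(0, genome_length - params.window_len + 1, params.step,
                       dtype=np.int64)
    return starts, starts + params.window_len


def midpoint(read) -> int:
    """Midpoint of a read interval: floor((start + end) / 2)."""
    start, end = read[0], read[1]
    return (start + end) // 2


def local_enrichment_track(
    reads: ReadSet,
    genome_length: int,
    params: EnrichmentParams = EnrichmentParams(),
) -> EnrichmentTrack:
    """Compute the normalized local enrichment E for every grid window.

    Counts are midpoint counts obtained by a sorted sweep
    (``searchsorted``); the background region is the ``bg_span`` region
    centred on the window, clipped to the chromosome, including the window
    itself.  An empty read set is allowed and yields E = 1 everywhere.
    """
    starts, ends = window_grid(genome_length, params)
    mids = reads.midpoints if len(reads) else np.empty(0, dtype=np.int64)
    if len(mids) and (mids[-1] >= genome_length or mids[0] < 0):
        raise InvalidParameterError("reads extend beyond the stated genome length")
    centres = starts + params.window_len // 2
    half = params.bg_span // 2
    bg_lo = np.clip(centres - half, 0, genome_length)
    bg_hi = np.clip(centres + half, 0, genome_length)
    n_win = np.searchsorted(mids, ends) - np.searchsorted(mids, starts)
    n_bg = np.searchsorted(mids, bg_hi) - np.searchsorted(mids, bg_lo)
    bg_len = bg_hi - bg_lo
    eps = params.eps
    E = (n_win / params.window_len + eps) / (n_bg / bg_len + eps)
    return EnrichmentTrack(
        sample=reads.sample,
        params=params,
        genome_length=genome_length,
        starts=starts,
        n_window=n_win.astype(np.int64),
        n_background=n_bg.astype(np.int64),
        bg_len=bg_len.astype(np.int64),
        enrichment=E,
    )


# ---------------------------------------------------------------------------
# I/O


def read_alignments(path, fmt: str | None = None, sample: SampleSpec | None = None,
                    genome_length: int | None = None) -> ReadSet:
    """Load aligned reads from BED6 or SAM into a sorted ReadSet.

    ``fmt`` is inferred from the file suffix when omitted.  SAM records that
    are unmapped, secondary or supplementary are skipped (the count of
    skipped records is attached as ``readset.n_skipped``).  Multi-chromosome
    input is refused: the analysis is defined along one linear chromosome.
    """
    path = str(path)
    if fmt is None:
        fmt = "sam" if path.endswith((".sam", ".bam")) else "bed"
    if fmt == "bed":
        return _read_bed(path, sample, genome_length)
    if fmt == "sam":
        return _read_sam(path, sample, genome_length)
    raise InvalidParameterError(f"unknown alignment format {fmt!r}")


def _read_bed(path, sample, genome_length) -> ReadSet:
    starts, ends, strands = [], [], []
    chrom_seen = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 fields", path, lineno)
            chrom = fields[0]
            if chrom_seen is None:
                chrom_seen = chrom
            elif chrom != chrom_seen:
                raise UnsupportedInputError(
                    f"multi-chromosome BED not supported ({chrom_seen!r} vs "
                    f"{chrom!r} at {path}:{lineno})"
                )
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", path, lineno) from None
            if e <= s:
                raise ParseError(f"BED end {e} <= start {s}", path, lineno)
            starts.append(s)
            ends.append(e)
            strands.append(fields[5] if len(fields) >= 6 else "+")
    rs = ReadSet(
        sample=sample,
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        strands=np.array(strands),
        genome_length=genome_length,
    )
    rs.n_skipped = 0
    return rs


def _read_sam(path, sample, genome_length) -> ReadSet:
    import pysam

    starts, ends, strands = [], [], []
    skipped = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        if fh.header.nreferences is not None and fh.header.nreferences > 1:
            raise UnsupportedInputError(
                f"{path}: {fh.header.nreferences} reference sequences; "
                "exactly one linear chromosome is supported"
            )
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
    rs = ReadSet(
        sample=sample,
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        strands=np.array(strands),
        genome_length=genome_length,
    )
    rs.n_skipped = skipped
    return rs


def write_track(track: EnrichmentTrack, path, chrom: str = "chr") -> None:
    """Write a track as bedGraph, one interval per grid window.

    Grid windows overlap (step < window), and they are emitted as-is; this
    overlapping dialect is intentional and consumers must tolerate it.
    Values carry 6 significant figures.
    """
    try:
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{chrom}_local_enrichment"\n')
            for s, e, v in zip(track.starts, track.ends, track.enrichment):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
    except OSError as exc:
        raise OSError(f"cannot write bedGraph to {path}: {exc}") from exc


def read_track(path, params: EnrichmentParams = EnrichmentParams(),
               genome_length: int | None = None) -> EnrichmentTrack:
    """Reload a bedGraph written by :func:`write_track` (grid + E only)."""
    starts, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError("bedGraph line needs 4 fields", path, lineno)
            starts.append(int(fields[1]))
            vals.append(float(fields[3]))
    starts = np.array(starts, dtype=np.int64)
    if genome_length is None:
        genome_length = int(starts[-1]) + params.window_len if len(starts) else 0
    n = len(starts)
    zeros = np.zeros(n, dtype=np.int64)
    return EnrichmentTrack(
        sample=None, params=params, genome_length=genome_length, starts=starts,
        n_window=zeros, n_background=zeros,
        bg_len=zeros + params.bg_span, enrichment=np.array(vals),
    )
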