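"""Shared domain types.

Coordinates are 0-based half-open throughout the library; positions shown to
users (reports, summits) are converted to 1-based at the formatting boundary.
The chromosome is linear — *Streptomyces* chromosomes do not circularise, so
no interval ever wraps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

#: Minimum genome length accepted by the simulator; must exceed the default
#: 3000-nt local-background span so every window has a meaningful background.
MIN_GENOME_LENGTH = 10_000


@dataclass(frozen=True)
class GenomeSpec:
    """A named linear chromosome of known length (no sequence is modelled)."""

    name: str
    length: int
    topology: str = "linear"

    def __post_init__(self):
        if self.length < MIN_GENOME_LENGTH:
            raise InvalidParameterError(
                f"genome length {self.length} < minimum {MIN_GENOME_LENGTH}"
            )
        if self.topology != "linear":
            raise InvalidParameterError("only linear chromosomes are supported")


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth binding site used by the simulator.

    ``strength`` is the expected number of immunoprecipitated fragments the
    site contributes per tagged sample; ``width`` is the nominal protein
    footprint (metadata only — fragment midpoints scatter far wider than the
    footprint because sonicated fragments average ~500 bp).
    """

    position: int
    strength: float
    width: int = 30

    def __post_init__(self):
        if self.position < 0:
            raise InvalidParameterError("site position must be >= 0")
        if self.strength < 0:
            raise InvalidParameterError("site strength must be >= 0")


@dataclass(frozen=True)
class SampleSpec:
    """Identity of one ChIP-seq sample.

    ``tagged`` distinguishes the Flag-tagged regulator strain from the
    untagged wild-type control processed identically; ``medium_label`` is the
    growth condition (e.g. ``"DNA"`` vs ``"DNAD"``, i.e. without/with
    D-glucose).
    """

    strain_label: str
    tagged: bool
    medium_label: str
    replicate: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.replicate < 1:
            raise InvalidParameterError("replicate index must be >= 1")

    @property
    def label(self) -> str:
        tag = "tag" if self.tagged else "ctrl"
        return f"{self.strain_label}_{self.medium_label}_{tag}_rep{self.replicate}"


@dataclass
class ReadSet:
    """Aligned reads of one sample as parallel arrays, sorted by start.

    Intervals are 0-based half-open.  ``n_background`` / ``n_site`` record the
    simulator's internal draws when the set is synthetic (None for reads
    loaded from disk), so conservation can be asserted exactly.
    """

    sample: SampleSpec | None
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray
    genome_length: int | None = None
    n_background: int | None = None
    n_site: tuple[int, ...] | None = None

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.strands = np.asarray(self.strands)
        if not (len(self.starts) == len(self.ends) == len(self.strands)):
            raise InvalidParameterError("read arrays must have equal length")
        if len(self.starts):
            if (self.starts >= self.ends).any():
                raise InvalidParameterError("every read needs start < end")
            if (self.starts < 0).any():
                raise InvalidParameterError("negative read coordinate")
            if self.genome_length is not None and (self.ends > self.genome_length).any():
                raise InvalidParameterError("read extends past the chromosome end")
            if (np.diff(self.starts) < 0).any():
                order = np.argsort(self.starts, kind="stable")
                self.starts = self.starts[order]
                self.ends = self.ends[order]
                self.strands = self.strands[order]

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        for s, e, st in zip(self.starts, self.ends, self.strands):
            yield int(s), int(e), str(st)

    @property
    def midpoints(self) -> np.ndarray:
        """Fragment midpoints, floor((start+end)/2), sorted ascending."""
        return np.sort((self.starts + self.ends) // 2)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its translational start implied by strand.

    Internal coordinates are 0-based half-open; the translational start is
    ``start`` for ``+`` genes and ``end`` for ``-`` genes (the half-open
    boundary just past the first translated base).
    """

    gene_id: str
    start: int
    end: int
    strand: str
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise InvalidParameterError(
                f"gene {self.gene_id}: start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise InvalidParameterError(f"gene {self.gene_id}: bad strand")

    @property
    def tss(self) -> int:
        """Coordinate of the translational start on this gene's strand."""
        return self.start if self.strand == "+" else self.end
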