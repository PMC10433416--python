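"""Self-calibration experiments: parameter recovery and null behaviour.

These experiments characterise the sliding-window fold-enrichment caller on
simulations where the truth is known: how reliably planted sites are
recovered and localized, and how often pure background produces spurious
peaks under the plain >2-fold rule (which applies no multiple-testing
correction).  They are run by the test suite and the acceptance script;
docs/methods.md discusses the signal-to-noise regime they map out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import EnrichmentParams, local_enrichment_track
from .model import SampleSpec
from .peaks import PeakCallParams, call_peaks
from .simulate import make_genome, plant_sites, simulate_sample


@dataclass
class RecoveryResult:
    """Per-seed outcome of one planted-site recovery experiment.

    ``site_offsets[i]`` is the distance from planted site *i* to the nearest
    called summit (None when no peaks were called); ``peak_offsets[j]`` is
    the distance from summit *j* to the nearest planted site.  Scoring at
    any tolerance is then a question, not a re-run: a site is *recovered*
    within ``tol`` when its offset is <= tol, a peak is *extra* when its
    offset exceeds the tolerance.  Summit localization is physically limited
    by the fragment-midpoint spread (sd = fragment_len_mean / 4), so
    fragment-scale tolerances are the realistic ones.
    """

    seed: int
    n_sites: int
    n_peaks: int
    site_offsets: tuple[int | None, ...]
    peak_offsets: tuple[int, ...]

    def n_recovered(self, tol: int) -> int:
        return sum(1 for d in self.site_offsets if d is not None and d <= tol)

    def n_extra(self, tol: int) -> int:
        return sum(1 for d in self.peak_offsets if d > tol)

    def perfect(self, summit_tol: int, extra_tol: int | None = None) -> bool:
        """All sites recovered within ``summit_tol`` and no extra peaks."""
        extra_tol = summit_tol if extra_tol is None else extra_tol
        return (self.n_recovered(summit_tol) == self.n_sites
                and self.n_extra(extra_tol) == 0)


def _seed(base: int, k: int) -> int:
    return (base * 6007 + k * 127) % (2**31 - 1)


def site_recovery(
    seed: int,
    genome_length: int = 1_000_000,
    n_sites: int = 10,
    strength: float = 30.0,
    background_depth: float = 0.05,
    min_spacing: int = 10_000,
    replicates: int = 2,
    fragment_len_mean: float = 500.0,
    enrichment_params: EnrichmentParams = EnrichmentParams(),
    peak_params: PeakCallParams = PeakCallParams(),
) -> RecoveryResult:
    """Simulate one duplicate tagged/control experiment and measure how the
    called peaks relate to the planted truth (see :class:`RecoveryResult`)."""
    genome = make_genome(genome_length, seed)
    sites = plant_sites(genome, n_sites, strength, min_spacing, _seed(seed, 0))
    tag_sets, ctl_sets = [], []
    for rep in range(1, replicates + 1):
        for tagged, bucket in ((True, tag_sets), (False, ctl_sets)):
            spec = SampleSpec(
                "bench", tagged, "DNAD", rep,
                seed=_seed(seed, 10 + 2 * rep + int(tagged)),
            )
            bucket.append(
                simulate_sample(
                    genome, sites, spec, background_depth,
                    fragment_len_mean=fragment_len_mean,
                )
            )
    called = call_peaks(tag_sets, ctl_sets, genome.length,
                        enrichment_params, peak_params)
    positions = np.array([s.position for s in sites]) if sites else np.empty(0)
    summits = np.array([p.summit for p in called]) if called else np.empty(0)
    site_offsets = tuple(
        int(np.abs(summits - pos).min()) if len(summits) else None
        for pos in positions
    )
    peak_offsets = tuple(
        int(np.abs(positions - s).min()) if len(positions) else int(genome.length)
        for s in summits
    )
    return RecoveryResult(
        seed=seed, n_sites=n_sites, n_peaks=len(called),
        site_offsets=site_offsets, peak_offsets=peak_offsets,
    )


def calibration_fraction(
    seed: int,
    genome_length: int = 1_000_000,
    depth: float = 1.0,
    band: tuple[float, float] = (0.5, 2.0),
    params: EnrichmentParams = EnrichmentParams(),
) -> float:
    """Fraction of interior windows with E inside ``band`` under pure
    uniform background (no sites).

    Interior = windows whose background span is not clipped by a chromosome
    end.  This is the empirical footing of the twofold significance rule:
    local enrichment of plain background should essentially never look
    twofold enriched at realistic depth.
    """
    genome = make_genome(genome_length, seed)
    spec = SampleSpec("calib", False, "DNAD", 1, seed=_seed(seed, 1))
    rs = simulate_sample(genome, [], spec, depth)
    track = local_enrichment_track(rs, genome.length, params)
    half = params.bg_span // 2
    interior = (track.centres >= half) & (track.centres <= genome.length - half)
    E = track.enrichment[interior]
    return float(np.mean((E >= band[0]) & (E <= band[1])))


def null_peak_rate(
    seed: int,
    genome_length: int = 1_000_000,
    depth: float = 1.0,
    replicates: int = 2,
    enrichment_params: EnrichmentParams = EnrichmentParams(),
    peak_params: PeakCallParams = PeakCallParams(),
) -> float:
    """Peaks per Mb when tagged and control are i.i.d. pure background."""
    genome = make_genome(genome_length, seed)
    tag_sets, ctl_sets = [], []
    for rep in range(1, replicates + 1):
        for tagged, bucket in ((True, tag_sets), (False, ctl_sets)):
            spec = SampleSpec(
                "null", tagged, "DNAD", rep,
                seed=_seed(seed, 50 + 2 * rep + int(tagged)),
            )
            bucket.append(simulate_sample(genome, [], spec, depth))
    called = call_peaks(tag_sets, ctl_sets, genome.length,
                        enrichment_params, peak_params)
    return len(called) * 1e6 / genome_length
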