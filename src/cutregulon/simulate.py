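"""Synthetic ChIP-seq experiment generator.

Emulates the statistical structure of a plate-grown *Streptomyces* ChIP-seq
experiment: a linear chromosome, a set of planted regulator binding sites,
and per-sample read sets in which background fragments fall uniformly along
the chromosome while tagged (immunoprecipitated) samples carry extra
fragments whose midpoints scatter normally around each bound site.  Untagged
wild-type control samples never see the site list, so with a fixed seed they
are byte-identical whether or not sites exist — the property the
tagged/control enrichment ratio relies on.

No nucleotide sequence is modelled: the downstream statistic consumes only
aligned intervals, so reads are intervals from the start.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, PackingError
from .model import MIN_GENOME_LENGTH, GeneModel, GenomeSpec, PlantedSite, ReadSet, SampleSpec

DEFAULT_FRAGMENT_LEN_MEAN = 500.0  # sonication smear centre, bp
DEFAULT_FRAGMENT_LEN_SD = 50.0
DEFAULT_BACKGROUND_DEPTH = 1.0  # fragments per nt; see docs/methods.md

_PACKING_RETRIES = 1000


def make_genome(length: int, seed: int, name: str | None = None) -> GenomeSpec:
    """Create a linear chromosome spec.

    ``seed`` participates only in the default name so that independently
    seeded experiments are visibly distinct; the returned object is
    deterministic.
    """
    if length < MIN_GENOME_LENGTH:
        raise InvalidParameterError(
            f"genome length must be >= {MIN_GENOME_LENGTH} nt, got {length}"
        )
    return GenomeSpec(name=name or f"synthetic_chr_s{seed}", length=int(length))


def plant_sites(
    genome: GenomeSpec,
    n_sites: int,
    strength: float,
    min_spacing: int,
    seed: int,
    width: int = 30,
) -> list[PlantedSite]:
    """Place ``n_sites`` binding sites uniformly with pairwise spacing.

    Rejection-samples positions until all pairwise gaps are >= ``min_spacing``;
    raises :class:`PackingError` after a bounded number of retries when the
    request cannot fit (``n_sites * min_spacing`` approaching genome length).
    """
    if n_sites < 0:
        raise InvalidParameterError("n_sites must be >= 0")
    if n_sites == 0:
        return []
    if n_sites * min_spacing >= genome.length:
        raise PackingError(
            f"{n_sites} sites with spacing {min_spacing} cannot fit in "
            f"{genome.length} nt"
        )
    rng = np.random.default_rng(seed)
    margin = min(min_spacing, genome.length // (n_sites + 1))
    for _ in range(_PACKING_RETRIES):
        pos = np.sort(rng.integers(margin, genome.length - margin, n_sites))
        if n_sites == 1 or (np.diff(pos) >= min_spacing).all():
            return [
                PlantedSite(position=int(p), strength=float(strength), width=width)
                for p in pos
            ]
    raise PackingError(
        f"could not place {n_sites} sites with spacing {min_spacing} in "
        f"{genome.length} nt after {_PACKING_RETRIES} attempts"
    )


def simulate_sample(
    genome: GenomeSpec,
    sites: list[PlantedSite],
    sample: SampleSpec,
    background_depth: float = DEFAULT_BACKGROUND_DEPTH,
    fragment_len_mean: float = DEFAULT_FRAGMENT_LEN_MEAN,
    fragment_len_sd: float = DEFAULT_FRAGMENT_LEN_SD,
) -> ReadSet:
    """Draw one sample's aligned fragments.

    Background: ``Poisson(background_depth * length)`` fragments with uniform
    start positions.  If the sample is tagged, each site adds
    ``Poisson(strength)`` fragments whose midpoints are normal around the
    site position with sd = ``fragment_len_mean / 4``, truncated to the
    chromosome.  Untagged samples never consume randomness that depends on
    the site list, so identical seeds give identical controls with or
    without sites.
    """
    if background_depth <= 0:
        raise InvalidParameterError("background_depth must be > 0")
    if fragment_len_mean <= 0 or fragment_len_sd < 0:
        raise InvalidParameterError("fragment length parameters must be positive")
    L = genome.length
    rng = np.random.default_rng(sample.seed)

    n_bg = int(rng.poisson(background_depth * L))
    bg_starts = rng.integers(0, L, n_bg)
    bg_lens = _fragment_lengths(rng, n_bg, fragment_len_mean, fragment_len_sd)
    starts = [bg_starts]
    ends = [bg_starts + bg_lens]

    n_site: list[int] = []
    if sample.tagged:
        mid_sd = fragment_len_mean / 4.0
        for site in sites:
            k = int(rng.poisson(site.strength))
            n_site.append(k)
            mids = rng.normal(site.position, mid_sd, k)
            mids = np.clip(np.rint(mids), 0, L - 1).astype(np.int64)
            lens = _fragment_lengths(rng, k, fragment_len_mean, fragment_len_sd)
            s = mids - lens // 2
            starts.append(s)
            ends.append(s + lens)

    s = np.concatenate(starts)
    e = np.concatenate(ends)
    # clip to the linear chromosome; drop anything clipped to zero length
    s = np.clip(s, 0, L - 1)
    e = np.clip(e, 1, L)
    keep = s < e
    s, e = s[keep], e[keep]
    strands = np.where(rng.random(len(s)) < 0.5, "+", "-")
    order = np.argsort(s, kind="stable")
    return ReadSet(
        sample=sample,
        starts=s[order],
        ends=e[order],
        strands=strands[order],
        genome_length=L,
        n_background=n_bg,
        n_site=tuple(n_site) if sample.tagged else None,
    )


def _fragment_lengths(rng, n, mean, sd) -> np.ndarray:
    lens = np.rint(rng.normal(mean, sd, n)).astype(np.int64)
    return np.maximum(lens, 1)


def make_gene_models(
    genome: GenomeSpec,
    n_genes: int,
    divergent_fraction: float,
    seed: int,
    gene_length: int = 900,
    intergenic: int = 200,
) -> list[GeneModel]:
    """Lay out non-overlapping genes, a fraction of them as divergent pairs.

    ``divergent_fraction`` of all possible gene pairs (``n_genes / 2``) are
    arranged head-to-head around a shared intergenic region — the geometry
    that lets one binding site regulate two genes.  Remaining genes are
    co-oriented on ``+``.  Placement is deterministic under ``seed``: genes
    occupy equal-width slots in genome order with a random offset inside each
    slot.
    """
    if not 0 <= divergent_fraction <= 1:
        raise InvalidParameterError("divergent_fraction must be in [0, 1]")
    if n_genes <= 0:
        raise InvalidParameterError("n_genes must be > 0")
    n_pairs = int(round(divergent_fraction * n_genes / 2))
    n_single = n_genes - 2 * n_pairs
    n_units = n_pairs + n_single
    pair_span = 2 * gene_length + intergenic
    slot = genome.length // n_units
    if slot <= pair_span + intergenic:
        raise PackingError(
            f"{n_genes} genes of {gene_length} nt do not fit in {genome.length} nt"
        )
    rng = np.random.default_rng(seed)
    # spread pair units evenly among single units, deterministically
    unit_is_pair = np.zeros(n_units, dtype=bool)
    if n_pairs:
        unit_is_pair[np.linspace(0, n_units - 1, n_pairs).astype(int)] = True

    genes: list[GeneModel] = []
    idx = 1
    for u in range(n_units):
        span = pair_span if unit_is_pair[u] else gene_length
        offset = int(rng.integers(0, slot - span))
        left = u * slot + offset
        if unit_is_pair[u]:
            genes.append(
                GeneModel(f"SYN{idx:04d}", left, left + gene_length, "-")
            )
            right = left + gene_length + intergenic
            genes.append(
                GeneModel(f"SYN{idx + 1:04d}", right, right + gene_length, "+")
            )
            idx += 2
        else:
            genes.append(GeneModel(f"SYN{idx:04d}", left, left + gene_length, "+"))
            idx += 1
    return genes


# ---------------------------------------------------------------------------
# writers


def write_bed(readset: ReadSet, path, chrom: str | None = None) -> None:
    """Write reads as BED6 (0-based half-open; score column fixed at 0)."""
    chrom = chrom or (readset.sample.strain_label if readset.sample else "chr")
    with open(path, "w") as fh:
        for i, (s, e, st) in enumerate(readset):
            fh.write(f"{chrom}\t{s}\t{e}\tr{i}\t0\t{st}\n")


def write_sam(readset: ReadSet, path, genome: GenomeSpec) -> None:
    """Write reads as mapped SAM records with a proper @SQ header.

    Reads carry no sequence (``*``); CIGAR is a full-length match, which is
    all the downstream statistic needs.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome.name, "LN": genome.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (s, e, st) in enumerate(readset):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = s
            a.cigartuples = [(0, e - s)]
            a.mapping_quality = 60
            a.flag = 16 if st == "-" else 0
            out.write(a)


def write_sites_tsv(sites: list[PlantedSite], path) -> None:
    """Write planted-site truth as TSV (position, strength, width)."""
    with open(path, "w") as fh:
        fh.write("position\tstrength\twidth\n")
        for s in sites:
            fh.write(f"{s.position}\t{s.strength:g}\t{s.width}\n")


def write_gene_models_gff3(genes: list[GeneModel], genome: GenomeSpec, path) -> None:
    """Write gene models as GFF3 (1-based inclusive per the standard)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {genome.length}\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.name or g.gene_id}"
            fh.write(
                f"{genome.name}\tcutregulon\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


TABLE5_FILENAME = "table5_act_bgc.tsv"
TABLE6_FILENAME = "table6_core_regulon.tsv"


def write_fixtures(out_dir) -> list[Path]:
    """Copy the packaged proteomics/regulon fixture tables into ``out_dir``.

    ``table5_act_bgc.tsv`` — actinorhodin BGC protein levels, mutant vs
    wild-type, on DNAD (with glucose) and DNA (without); blank cells mean the
    protein was not detected.  ``table6_core_regulon.tsv`` — the 16-site core
    regulon with per-experiment enrichment, downstream gene(s) and protein
    ratios ('nd' not detected, 'na' not applicable).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fname in (TABLE5_FILENAME, TABLE6_FILENAME):
        src = resources.files("cutregulon.data").joinpath(fname)
        dst = out / fname
        with resources.as_file(src) as p:
            shutil.copy(p, dst)
        written.append(dst)
    return written
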