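"""Peak-to-promoter target assignment.

A gene is a target of a peak when the peak summit lies within
``max_upstream_dist`` nt upstream of the gene's translational start and no
other gene body intervenes between summit and start.  Both strands are
evaluated independently, so a summit sitting in the shared intergenic
region of a divergent (head-to-head) gene pair is assigned to both genes —
one binding site, two regulated promoters.  Summits inside gene bodies are
left unassigned by default (``allow_intragenic`` relaxes this to the
nearest downstream start).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError, ParseError
from .model import GeneModel
from .peaks import Peak

DEFAULT_MAX_UPSTREAM_DIST = 500  # conventional bacterial promoter span, nt


@dataclass(frozen=True)
class TargetCall:
    """A peak with its 0, 1 or 2 downstream target genes.

    Two genes occur only for divergent promoters; ``distances`` are nt from
    summit to each gene's translational start.  An empty ``genes`` tuple
    marks an unassigned peak.
    """

    peak: Peak
    genes: tuple[GeneModel, ...]
    distances: tuple[int, ...]

    @property
    def assigned(self) -> bool:
        return bool(self.genes)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)


def read_gene_models(path) -> list[GeneModel]:
    """Read ``gene`` features from GFF3 into internal 0-based half-open
    coordinates.

    Only one sequence region is supported; duplicate gene IDs and
    coordinates outside a declared ``##sequence-region`` are errors.
    Non-gene features are skipped.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except ValueError as exc:
        raise ParseError(f"invalid GFF3: {exc}", path) from exc
    region_len = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                region_len = int(line.split()[3])
            elif not line.startswith("#"):
                break
    genes: list[GeneModel] = []
    seen: set[str] = set()
    seqids: set[str] = set()
    for feat in db.features_of_type("gene", order_by="start"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise ParseError(f"duplicate gene id {gid!r}", path)
        seen.add(gid)
        seqids.add(feat.seqid)
        if len(seqids) > 1:
            raise ParseError("multiple sequence regions in GFF3", path)
        if region_len is not None and feat.end > region_len:
            raise ParseError(
                f"gene {gid!r} end {feat.end} outside sequence region "
                f"(length {region_len})", path
            )
        name = feat.attributes.get("Name", [gid])[0]
        genes.append(
            GeneModel(gene_id=gid, start=feat.start - 1, end=feat.end,
                      strand=feat.strand, name=name)
        )
    return genes


def assign_targets(
    peaks: list[Peak],
    genes: list[GeneModel],
    max_upstream_dist: int = DEFAULT_MAX_UPSTREAM_DIST,
    allow_intragenic: bool = False,
) -> list[TargetCall]:
    """Assign each peak to its promoter target gene(s).

    Per strand, the candidate is the gene with the nearest translational
    start downstream of the summit (nearer start wins when starts nest);
    it is kept if the distance is within ``max_upstream_dist`` and no other
    gene body overlaps the stretch between summit and start.
    """
    if max_upstream_dist < 0:
        raise InvalidParameterError("max_upstream_dist must be >= 0")
    calls = []
    for peak in peaks:
        s = peak.summit
        inside = [g for g in genes if g.start <= s < g.end]
        if inside:
            if not allow_intragenic:
                calls.append(TargetCall(peak=peak, genes=(), distances=()))
                continue
            # relaxed rule: nearest downstream translational start on either
            # strand, with no promoter-span cap (the summit already sits in
            # transcribed territory)
            cands = [
                ((g.tss - s) if g.strand == "+" else (s - g.tss), g)
                for g in genes
                if g not in inside
                and ((g.strand == "+" and g.tss >= s) or (g.strand == "-" and g.tss <= s))
            ]
            cands.sort(key=lambda h: (h[0], h[1].gene_id))
            best = cands[:1]
            calls.append(
                TargetCall(
                    peak=peak,
                    genes=tuple(g for _, g in best),
                    distances=tuple(d for d, _ in best),
                )
            )
            continue
        hits: list[tuple[int, GeneModel]] = []
        for strand in ("+", "-"):
            cand = _nearest_downstream(s, genes, strand)
            if cand is None:
                continue
            dist = (cand.tss - s) if strand == "+" else (s - cand.tss)
            if dist > max_upstream_dist:
                continue
            lo, hi = (s, cand.tss) if strand == "+" else (cand.tss, s)
            if _intervening(lo, hi, genes, exclude=cand):
                continue
            hits.append((dist, cand))
        hits.sort(key=lambda h: (h[0], h[1].gene_id))
        calls.append(
            TargetCall(
                peak=peak,
                genes=tuple(g for _, g in hits),
                distances=tuple(d for d, _ in hits),
            )
        )
    return calls


def _nearest_downstream(summit: int, genes: list[GeneModel], strand: str):
    """Gene on ``strand`` whose translational start is nearest downstream of
    the summit (ahead of it in the gene's reading direction)."""
    best, best_d = None, None
    for g in genes:
        if g.strand != strand:
            continue
        d = (g.tss - summit) if strand == "+" else (summit - g.tss)
        if d < 0:
            continue
        if best_d is None or d < best_d:
            best, best_d = g, d
    return best


def _intervening(lo: int, hi: int, genes: list[GeneModel], exclude: GeneModel) -> bool:
    """True when any other gene body overlaps the open interval (lo, hi)."""
    return any(
        g is not exclude and g.start < hi and g.end > lo for g in genes
    )


def write_targets_tsv(calls: list[TargetCall], path) -> None:
    """TSV: 1-based summit, peak ratio, gene id(s), distance(s)."""
    with open(path, "w") as fh:
        fh.write("summit\tmax_ratio\tgene_ids\tdistances\n")
        for c in calls:
            gids = ",".join(c.gene_ids) or "."
            dists = ",".join(str(d) for d in c.distances) or "."
            fh.write(
                f"{c.peak.summit_1based}\t{c.peak.max_ratio:.4g}\t{gids}\t{dists}\n"
            )
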