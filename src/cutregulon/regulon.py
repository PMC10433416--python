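"""Core-regulon intersection and binding/proteomics integration.

The core regulon is the set of binding positions shared (within a small
positional tolerance) by every required ChIP-seq experiment — here the
native and the orthologous Flag-tagged regulator assayed in the same host.
Each bound gene is then classified against quantitative proteomics of the
regulator-deletion mutant versus wild type:

* ratio (mutant/WT) < 1/fold_threshold  → the regulator **activates** the
  gene (its product falls when the regulator is gone);
* ratio > fold_threshold                → the regulator **represses** it;
* otherwise                             → unchanged;
* protein not detected ('nd'/'na'/blank) → not_detected.

All comparisons are strict, with fold_threshold defaulting to 1.5 — the
value under which a borderline mutant/WT ratio of exactly 1.5 stays
"unchanged".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ParseError

CALL_ACTIVATED = "activated"
CALL_REPRESSED = "repressed"
CALL_UNCHANGED = "unchanged"
CALL_NOT_DETECTED = "not_detected"

#: actinorhodin biosynthetic gene cluster
ACT_BGC_GENES = tuple(f"SCO{i}" for i in range(5071, 5093))


@dataclass(frozen=True)
class ProteinRatio:
    """Mutant/wild-type protein abundance on one medium.

    ``detected`` is False for 'nd' (not detected) and 'na' (not applicable,
    e.g. genes absent from the mutant); ``single_peptide`` flags
    quantifications supported by only one unique peptide (kept as a quality
    flag, never used to change a call).
    """

    gene_id: str
    medium_label: str
    ratio: float | None
    detected: bool = True
    single_peptide: bool = False
    raw: str | None = None  # literal token for undetected entries ('nd'/'na')

    def __post_init__(self):
        if self.detected:
            if self.ratio is None or not self.ratio > 0:
                raise InvalidParameterError(
                    f"{self.gene_id}: detected protein ratio must be > 0"
                )


@dataclass(frozen=True)
class RegulonParams:
    """Classification threshold and which experiments must agree."""

    fold_threshold: float = 1.5
    merge_tolerance: int = 15  # nt; one grid step
    require_regulators: tuple[str, ...] | None = None
    require_media: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.fold_threshold <= 1:
            raise InvalidParameterError("fold_threshold must be > 1")
        if self.merge_tolerance < 0:
            raise InvalidParameterError("merge_tolerance must be >= 0")


@dataclass
class RegulonEntry:
    """One core binding position with its genes, evidence and calls."""

    position: int  # 1-based, as reported
    gene_ids: tuple[str, ...]
    annotation: str = ""
    enrichment: dict = field(default_factory=dict)  # (regulator, medium) -> fold
    ratios: dict = field(default_factory=dict)  # gene_id -> ProteinRatio | None
    calls: dict = field(default_factory=dict)  # gene_id -> call


def core_regulon(
    target_sets: Mapping[tuple[str, str], Iterable[int]],
    merge_tolerance: int = 15,
    required: Iterable[tuple[str, str]] | None = None,
) -> list[int]:
    """Positions present, within ``merge_tolerance`` nt, in every required set.

    ``target_sets`` maps (regulator, medium) to summit positions.  The
    representative position of a matched site is the one from the
    first-listed required set.  Requiring more sets can only shrink the
    result (anti-monotone).
    """
    keys = list(required) if required is not None else list(target_sets)
    if not keys:
        raise InvalidParameterError("core_regulon needs at least one required set")
    missing = [k for k in keys if k not in target_sets]
    if missing:
        raise InvalidParameterError(f"required sets absent from input: {missing}")
    ref = sorted(target_sets[keys[0]])
    others = [np.sort(np.fromiter(target_sets[k], dtype=np.int64))
              for k in keys[1:]]
    core = []
    for p in ref:
        if all(
            len(o) and np.abs(o - p).min() <= merge_tolerance for o in others
        ):
            core.append(int(p))
    return core


def read_protein_ratios(path) -> list[ProteinRatio]:
    """Read a long-format TSV with columns gene, medium, ratio.

    'nd', 'na' and blank ratios become undetected entries; a trailing '*'
    on a numeric ratio marks a single-peptide quantification.  Zero or
    negative numeric ratios are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    try:
        gene_c, medium_c, ratio_c = cols["gene"], cols["medium"], cols["ratio"]
    except KeyError as exc:
        raise ParseError(f"missing column {exc} (need gene, medium, ratio)", path)
    out = []
    for i, row in df.iterrows():
        out.append(
            _parse_ratio(str(row[gene_c]), str(row[medium_c]),
                         row[ratio_c], path, i + 2)
        )
    return out


def _parse_ratio(gene: str, medium: str, raw, path=None, line=None) -> ProteinRatio:
    txt = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
    if txt.lower() in ("", "nd", "na", "nan"):
        token = txt if txt.lower() in ("nd", "na") else "nd"
        return ProteinRatio(gene, medium, None, detected=False, raw=token)
    single = txt.endswith("*")
    if single:
        txt = txt[:-1]
    try:
        val = float(txt)
    except ValueError:
        raise ParseError(f"unparseable ratio {raw!r} for {gene}", path, line) from None
    if val <= 0:
        raise ParseError(f"ratio must be > 0, got {val} for {gene}", path, line)
    return ProteinRatio(gene, medium, val, detected=True, single_peptide=single)


def classify_regulation(
    gene_id: str,
    ratio: ProteinRatio | None,
    params: RegulonParams = RegulonParams(),
) -> str:
    """Call a bound gene from its mutant/WT protein ratio (strict bounds)."""
    if ratio is None or not ratio.detected:
        return CALL_NOT_DETECTED
    if ratio.ratio < 1.0 / params.fold_threshold:
        return CALL_ACTIVATED
    if ratio.ratio > params.fold_threshold:
        return CALL_REPRESSED
    return CALL_UNCHANGED


def regulon_report(
    entries: list[RegulonEntry],
    params: RegulonParams = RegulonParams(),
    enrichment_keys: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Tabulate core entries, sorted by position, one row per site.

    Fills each entry's per-gene ``calls`` in place using
    :func:`classify_regulation` and returns a tidy DataFrame with 1-based
    positions, per-experiment enrichment, gene ids, ratios and calls.
    """
    if enrichment_keys is None:
        seen = {}
        for e in entries:
            for k in e.enrichment:
                seen[k] = None
        enrichment_keys = list(seen)
    rows = []
    for e in sorted(entries, key=lambda x: x.position):
        for g in e.gene_ids:
            e.calls[g] = classify_regulation(g, e.ratios.get(g), params)
        row = {"position": e.position}
        for key in enrichment_keys:
            row[f"enrichment_{key[0]}_{key[1]}"] = e.enrichment.get(key)
        row["genes"] = " ".join(e.gene_ids)
        row["annotation"] = e.annotation
        row["ratios"] = " ".join(
            _format_ratio(e.ratios.get(g)) for g in e.gene_ids
        )
        row["calls"] = " ".join(e.calls[g] for g in e.gene_ids)
        rows.append(row)
    cols = (["position"]
            + [f"enrichment_{r}_{m}" for r, m in enrichment_keys]
            + ["genes", "annotation", "ratios", "calls"])
    return pd.DataFrame(rows, columns=cols)


def _format_ratio(r: ProteinRatio | None) -> str:
    if r is None:
        return "na"
    if not r.detected:
        return r.raw or "nd"
    return f"{r.ratio:g}" + ("*" if r.single_peptide else "")


def bgc_summary(
    ratios: Iterable[ProteinRatio],
    medium: str,
    gene_set: Iterable[str] | None = None,
    fold: float = 2.0,
) -> dict:
    """Summary of detected protein changes across a gene cluster.

    Restricted to ``gene_set`` (default: the actinorhodin BGC) and
    ``medium``; undetected entries are excluded from every statistic.
    """
    genes = set(gene_set) if gene_set is not None else set(ACT_BGC_GENES)
    if not genes:
        raise InvalidParameterError("bgc_summary needs a non-empty gene set")
    vals = [
        r.ratio for r in ratios
        if r.gene_id in genes and r.medium_label == medium and r.detected
    ]
    if not vals:
        return {"n_detected": 0, "max_ratio": None, "min_ratio": None,
                "n_above": 0, "n_below": 0}
    arr = np.asarray(vals)
    return {
        "n_detected": len(arr),
        "max_ratio": float(arr.max()),
        "min_ratio": float(arr.min()),
        "n_above": int((arr > fold).sum()),
        "n_below": int((arr < 1.0 / fold).sum()),
    }


# ---------------------------------------------------------------------------
# Packaged fixture tables


def _fixture_path(fname: str):
    return resources.files("cutregulon.data").joinpath(fname)


def load_table5(path=None) -> pd.DataFrame:
    """Actinorhodin-BGC protein table: sco_id, protein, function and
    mutant/WT ratios on DNAD and DNA (NaN = not detected)."""
    src = path if path is not None else _fixture_path("table5_act_bgc.tsv")
    with open(src) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"sco_id": str})
    for col in ("ratio_dnad", "ratio_dna"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def table5_ratios(path=None) -> list[ProteinRatio]:
    """Table-5 fixture unpivoted to one ProteinRatio per gene and medium."""
    df = load_table5(path)
    out = []
    for _, row in df.iterrows():
        for medium, col in (("DNAD", "ratio_dnad"), ("DNA", "ratio_dna")):
            v = row[col]
            out.append(_parse_ratio(row["sco_id"], medium,
                                    None if pd.isna(v) else v))
    return out


def load_table6(path=None) -> pd.DataFrame:
    """Core-regulon fixture: positions (with the thousands spacing of the
    original preserved in ``position_text``), per-experiment enrichment,
    downstream gene(s), annotation and mutant/WT protein ratio strings."""
    src = path if path is not None else _fixture_path("table6_core_regulon.tsv")
    with open(src) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    df = df.rename(columns={"position": "position_text"})
    df["position"] = df["position_text"].str.replace(" ", "").astype(np.int64)
    for col in ("sc_dnad", "sc_dna", "sv_dnad", "sv_dna"):
        df[col] = df[col].astype(float)
    return df


def table6_entries(path=None, medium: str = "DNAD") -> list[RegulonEntry]:
    """Table-6 fixture as RegulonEntry objects ready for classification.

    Multi-gene rows (divergent promoters) pair the whitespace-separated
    genes with the whitespace-separated ratio tokens one-to-one; a single
    ratio token spanning a fused locus tag (e.g. an operon deleted in the
    mutant, ratio 'na') maps to that single entry.
    """
    df = load_table6(path)
    entries = []
    for _, row in df.iterrows():
        genes = tuple(row["genes"].split())
        tokens = str(row["ratio"]).split()
        if len(tokens) != len(genes):
            raise ParseError(
                f"row at {row['position']}: {len(genes)} genes but "
                f"{len(tokens)} ratio tokens"
            )
        ratios = {
            g: _parse_ratio(g, medium, tok) for g, tok in zip(genes, tokens)
        }
        entries.append(
            RegulonEntry(
                position=int(row["position"]),
                gene_ids=genes,
                annotation=row["annotation"],
                enrichment={
                    ("ScCutR", "DNAD"): row["sc_dnad"],
                    ("ScCutR", "DNA"): row["sc_dna"],
                    ("SvCutR", "DNAD"): row["sv_dnad"],
                    ("SvCutR", "DNA"): row["sv_dna"],
                },
                ratios=ratios,
            )
        )
    return entries
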