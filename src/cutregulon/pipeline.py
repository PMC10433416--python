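"""End-to-end orchestration: simulate → enrich → callpeaks → annotate → regulon.

A run is driven by a nested configuration (YAML on disk, plain dicts in
memory) whose defaults are the analysis defaults throughout the library:
30/15/3000 window geometry, strict >2-fold tagged:control rule in every one
of two replicates.  Unknown keys are rejected (typo safety), a normalized
copy of the config plus a manifest with per-stage timings and output
checksums is written into the output directory, and re-running the same
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import annotate, enrichment, peaks, regulon, simulate
from .errors import ConfigError
from .model import SampleSpec

log = logging.getLogger("cutregulon")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "cutregulon_run",
    "genome": {"length": 1_000_000, "name": None},
    "simulation": {
        "n_sites": 10,
        "strength": 2000.0,
        "min_spacing": 10_000,
        "background_depth": simulate.DEFAULT_BACKGROUND_DEPTH,
        "fragment_len_mean": simulate.DEFAULT_FRAGMENT_LEN_MEAN,
        "fragment_len_sd": simulate.DEFAULT_FRAGMENT_LEN_SD,
        "replicates": 2,
        "medium": "DNAD",
        "strain": "synthetic",
    },
    "enrichment": {
        "window_len": 30,
        "step": 15,
        "bg_span": 3000,
        "pseudo_density": None,
    },
    "peaks": {"threshold": 2.0, "min_replicates": None, "max_gap_windows": 1},
    "annotation": {
        "n_genes": 50,
        "divergent_fraction": 0.2,
        "max_upstream_dist": 500,
    },
    "regulon": {"fold_threshold": 1.5, "merge_tolerance": 15},
}


def validate_config(config: dict | None) -> dict:
    """Fill defaults, reject unknown keys, check cross-field invariants."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    _merge(cfg, config or {}, path="")
    ep = cfg["enrichment"]
    if ep["bg_span"] < ep["window_len"]:
        raise ConfigError("enrichment.bg_span must be >= window_len")
    if ep["step"] > ep["window_len"]:
        raise ConfigError("enrichment.step must be <= window_len")
    if cfg["peaks"]["threshold"] <= 1:
        raise ConfigError("peaks.threshold must be > 1")
    if cfg["simulation"]["replicates"] < 1:
        raise ConfigError("simulation.replicates must be >= 1")
    if (ep["window_len"] - ep["step"]) and ep["window_len"] % ep["step"]:
        log.warning(
            "window_len %d not divisible by step %d: grid windows tile unevenly",
            ep["window_len"], ep["step"],
        )
    return cfg


def _merge(base: dict, override: dict, path: str) -> None:
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            _merge(base[key], val, path + key + ".")
        else:
            base[key] = val


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return validate_config(raw)


def run_pipeline(config: dict | None = None) -> dict:
    """Execute every stage; return (and write) the run manifest.

    Stage failures propagate with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    manifest = {"stages": [], "outputs": {}, "seed": cfg["seed"]}
    state: dict = {}
    for name, fn in (
        ("simulate", _stage_simulate),
        ("enrich", _stage_enrich),
        ("callpeaks", _stage_callpeaks),
        ("annotate", _stage_annotate),
        ("regulon", _stage_regulon),
    ):
        t0 = time.perf_counter()
        try:
            outputs = fn(cfg, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs", name, dt)
        manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
        for p in outputs:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sample_seed(master: int, index: int) -> int:
    return (master * 1009 + index * 9176) % (2**31 - 1)


def _stage_simulate(cfg, out, state):
    g, s = cfg["genome"], cfg["simulation"]
    genome = simulate.make_genome(g["length"], cfg["seed"], name=g["name"])
    sites = simulate.plant_sites(
        genome, s["n_sites"], s["strength"], s["min_spacing"], cfg["seed"]
    )
    annotate_cfg = cfg["annotation"]
    gene_models = simulate.make_gene_models(
        genome, annotate_cfg["n_genes"], annotate_cfg["divergent_fraction"],
        cfg["seed"],
    )
    files = []
    state.update(genome=genome, sites=sites, genes=gene_models,
                 tag_sets=[], ctl_sets=[])
    for rep in range(1, s["replicates"] + 1):
        for tagged, bucket in ((True, state["tag_sets"]), (False, state["ctl_sets"])):
            spec = SampleSpec(
                strain_label=s["strain"], tagged=tagged,
                medium_label=s["medium"], replicate=rep,
                seed=_sample_seed(cfg["seed"], rep * 2 + int(tagged)),
            )
            rs = simulate.simulate_sample(
                genome, sites, spec, s["background_depth"],
                s["fragment_len_mean"], s["fragment_len_sd"],
            )
            bucket.append(rs)
            p = out / f"reads_{spec.label}.bed"
            simulate.write_bed(rs, p, chrom=genome.name)
            files.append(p)
    p = out / "planted_sites.tsv"
    simulate.write_sites_tsv(sites, p)
    files.append(p)
    p = out / "genes.gff3"
    simulate.write_gene_models_gff3(gene_models, genome, p)
    files.append(p)
    return files


def _stage_enrich(cfg, out, state):
    e = cfg["enrichment"]
    params = enrichment.EnrichmentParams(
        window_len=e["window_len"], step=e["step"], bg_span=e["bg_span"],
        pseudo_density=e["pseudo_density"],
    )
    state["eparams"] = params
    state["tag_tracks"], state["ctl_tracks"] = [], []
    files = []
    for rs_list, tracks in ((state["tag_sets"], state["tag_tracks"]),
                            (state["ctl_sets"], state["ctl_tracks"])):
        for rs in rs_list:
            tr = enrichment.local_enrichment_track(
                rs, state["genome"].length, params)
            tracks.append(tr)
            p = out / f"enrichment_{rs.sample.label}.bedgraph"
            enrichment.write_track(tr, p, chrom=state["genome"].name)
            files.append(p)
    return files


def _stage_callpeaks(cfg, out, state):
    pc = cfg["peaks"]
    params = peaks.PeakCallParams(
        threshold=pc["threshold"], min_replicates=pc["min_replicates"],
        max_gap_windows=pc["max_gap_windows"],
    )
    ratios = [
        peaks.ratio_track(t, c)
        for t, c in zip(state["tag_tracks"], state["ctl_tracks"])
    ]
    flags = peaks.call_enriched_windows(ratios, params)
    state["peaks"] = peaks.merge_windows(flags, ratios, params)
    p_tsv, p_bed = out / "peaks.tsv", out / "peaks.bed"
    peaks.write_peaks_tsv(state["peaks"], p_tsv)
    peaks.write_peaks_bed(state["peaks"], p_bed, chrom=state["genome"].name)
    return [p_tsv, p_bed]


def _stage_annotate(cfg, out, state):
    calls = annotate.assign_targets(
        state["peaks"], state["genes"],
        max_upstream_dist=cfg["annotation"]["max_upstream_dist"],
    )
    state["targets"] = calls
    p = out / "targets.tsv"
    annotate.write_targets_tsv(calls, p)
    return [p]


def _stage_regulon(cfg, out, state):
    """Summarise assigned targets as a single-experiment regulon report.

    The demo pipeline runs one regulator on one medium, so the "core" set
    is that experiment's own target list; protein ratios are synthesised
    deterministically for bound genes (an alternating activated/repressed
    pattern) purely so the classification path is exercised end to end.
    """
    rc = cfg["regulon"]
    params = regulon.RegulonParams(
        fold_threshold=rc["fold_threshold"], merge_tolerance=rc["merge_tolerance"])
    key = (cfg["simulation"]["strain"], cfg["simulation"]["medium"])
    rng = np.random.default_rng(_sample_seed(cfg["seed"], 99))
    entries = []
    for call in state["targets"]:
        if not call.assigned:
            continue
        ratios = {}
        for g in call.gene_ids:
            val = float(rng.choice([0.3, 3.0]) * rng.uniform(0.8, 1.25))
            ratios[g] = regulon.ProteinRatio(g, key[1], val)
        entries.append(
            regulon.RegulonEntry(
                position=call.peak.summit_1based,
                gene_ids=call.gene_ids,
                annotation="synthetic",
                enrichment={key: call.peak.max_ratio},
                ratios=ratios,
            )
        )
    report = regulon.regulon_report(entries, params)
    p = out / "regulon.tsv"
    report.to_csv(p, sep="\t", index=False)
    return [p]
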