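"""Config-driven orchestration of the full analysis.

Stages run in dependency order: simulate (or load) -> consensus ->
classify -> partition -> burden -> profile -> clump -> enrich.  Every
parameter and seed is echoed into ``summary.json``; re-running an
identical config produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .classify import classify_tads
from .clumping import DosageLD, clump
from .consensus import shared_tads
from .core import CHROMHMM_STATES, TADRecord
from .enrichment import (annotate_drivers, driver_tables, enrichment_frame,
                         matched_randomization)
from .partition import (burden_by_label, define_boundaries, partition_genome,
                        per_tad_burden_test, promoter_methylation_by_category)
from .profiles import attach_null, profile, shuffle_null
from .simulate import SimConfig, simulate_dataset, simulate_promoter_betas

logger = logging.getLogger(__name__)

STAGES = ("simulate", "consensus", "classify", "partition", "burden",
          "profile", "clump", "enrich")

DEFAULT_PARAMS: dict = {
    "seed": 0,
    "simulate": {},                      # SimConfig field overrides
    "consensus": {"min_frac": 0.2, "mode": "reciprocal"},
    "classify": {"k": 5, "n_init": 50, "mixed_margin": 0.1},
    "partition": {"half_width": 50_000},
    "profile": {"n_bins": 40, "n_shuffles": 100, "smooth_window": 5,
                "mode": "half_delta"},
    "clump": {"p1": 1e-4, "p2": 0.01, "r2_min": 0.5, "window_kb": 250.0},
    "enrich": {"n_trials": 1000, "maf_tol": 0.05},
}


def load_config(config: Union[str, Path, dict]) -> dict:
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    merged = {}
    for key, defaults in DEFAULT_PARAMS.items():
        if isinstance(defaults, dict):
            merged[key] = {**defaults, **config.get(key, {})}
        else:
            merged[key] = config.get(key, defaults)
    unknown = set(config) - set(DEFAULT_PARAMS) - {"outdir"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "outdir" in config:
        merged["outdir"] = config["outdir"]
    return merged


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: Union[str, Path, dict],
                 outdir: Optional[Union[str, Path]] = None) -> dict:
    """Run every stage; returns (and writes) the JSON summary."""
    params = load_config(config)
    outdir = Path(outdir or params.get("outdir", "tadmeqtl_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(params["seed"])
    summary: dict = {"stages": [], "params": _jsonable(params)}

    # ------------------------------------------------------------- simulate
    sim_cfg = SimConfig(**{**params["simulate"], "seed": seed})
    sim = simulate_dataset(sim_cfg)
    sim.write(outdir / "inputs")
    summary["stages"].append("simulate")
    summary["simulate"] = {"n_tads_true": len(sim.true_tads),
                           "n_meqtl_rows": int(len(sim.meqtls)),
                           "config": _jsonable(asdict(sim_cfg))}

    # ------------------------------------------------------------ consensus
    cell_lines = sorted(sim.tad_sets)
    consensus = shared_tads([sim.tad_sets[c] for c in cell_lines],
                            **params["consensus"])
    tio.write_bed(outdir / "consensus_tads.bed", consensus)
    summary["stages"].append("consensus")
    summary["consensus"] = {"n_cell_lines": len(cell_lines),
                            "n_consensus_tads": len(consensus)}

    # ------------------------------------------------------------- classify
    result = classify_tads(consensus, sim.segments, seed=seed,
                           **params["classify"])
    cls = pd.DataFrame({
        "chrom": [t.chrom for t in consensus],
        "start": [t.start for t in consensus],
        "end": [t.end for t in consensus],
        "cluster": result.cluster,
        "category5": result.tad_category5,
        "category3": result.tad_category3,
    })
    for i, st in enumerate(CHROMHMM_STATES):
        cls[f"frac_{st.replace('/', '_')}"] = [
            t.composition.fractions[i] for t in consensus]
    _write_tsv(outdir / "tads_classified.tsv", cls)
    summary["stages"].append("classify")
    summary["classify"] = {
        "inertia": result.inertia,
        "cluster_labels": result.category5,
        "category3_counts": {c: int((cls["category3"] == c).sum())
                             for c in ("Active", "Inactive", "Mixed")}}

    # ------------------------------------------------------------ partition
    half_width = int(params["partition"]["half_width"])
    boundaries = define_boundaries(consensus, sim.chrom_sizes,
                                   half_width=half_width)
    partition = partition_genome(consensus, boundaries, sim.chrom_sizes)
    partition.df.to_csv(outdir / "partition.bed", sep="\t", index=False,
                        header=False)
    summary["stages"].append("partition")
    summary["partition"] = {"half_width": half_width,
                            "label_bp": partition.label_bp}

    # --------------------------------------------------------------- burden
    burden = burden_by_label(sim.meqtls, partition)
    _write_tsv(outdir / "burden_by_label.tsv", burden)
    per_tad, t_stat, t_p = per_tad_burden_test(sim.meqtls, consensus)
    _write_tsv(outdir / "per_tad_burden.tsv", per_tad)
    betas = simulate_promoter_betas(
        sim_cfg, _promoter_categories(sim.promoters, consensus),
        seed=seed + 1)
    meth_summary, kw_h, kw_p, n_drop = promoter_methylation_by_category(
        betas, sim.promoters, consensus)
    _write_tsv(outdir / "promoter_methylation.tsv", meth_summary)
    summary["stages"].append("burden")
    summary["burden"] = {
        "per_label": {row.label: {"count": int(row.count), "bp": int(row.bp),
                                  "per_mb": row.per_mb}
                      for row in burden.itertuples(index=False)},
        "per_tad_t": t_stat, "per_tad_p": t_p,
        "kruskal_h": kw_h, "kruskal_p": kw_p,
        "promoters_outside_tads": n_drop}

    # -------------------------------------------------------------- profile
    prof_par = params["profile"]
    profiles = profile(sim.meqtls, consensus, n_bins=prof_par["n_bins"],
                       smooth_window=prof_par["smooth_window"])
    null = shuffle_null(consensus, sim.meqtls,
                        n_shuffles=prof_par["n_shuffles"], seed=seed + 2,
                        n_bins=prof_par["n_bins"])
    attach_null(profiles, null, mode=prof_par["mode"])
    rows = []
    for tr, p in sorted(profiles.items()):
        for b in range(prof_par["n_bins"]):
            rows.append((tr, b + 1, p.densities[b], p.smoothed[b],
                         None if p.null_mean is None else p.null_mean[b],
                         None if p.null_sd is None else p.null_sd[b]))
    _write_tsv(outdir / "boundary_profiles.tsv",
               pd.DataFrame(rows, columns=["transition", "bin", "density",
                                           "smoothed", "null_mean",
                                           "null_sd"]))
    summary["stages"].append("profile")
    summary["profile"] = {
        tr: {"n_boundaries": p.n_boundaries, "statistic": p.statistic,
             "pvalue": p.pvalue}
        for tr, p in sorted(profiles.items())}

    # ---------------------------------------------------------------- clump
    if sim.dosages is None:
        raise ValueError("clumping requires dosages; set n_samples > 0")
    clumped = clump(sim.meqtls, DosageLD(sim.dosages), **params["clump"])
    _write_tsv(outdir / "clumped.tsv", clumped)
    summary["stages"].append("clump")
    summary["clump"] = {"n_snps": int(len(clumped)),
                        "n_index": int(clumped["is_index"].sum())}

    # --------------------------------------------------------------- enrich
    annotated = annotate_drivers(sim.meqtls, sim.promoters, sim.gene_roles)
    drivers, pool = driver_tables(annotated, clumped)
    enr_par = params["enrich"]
    results = {}
    for i, role in enumerate(("oncogene", "TSG")):
        if len(drivers[role]) == 0:
            logger.warning("no %s driver meQTLs; skipping", role)
            continue
        results[role] = matched_randomization(
            drivers[role], pool, partition, n_trials=enr_par["n_trials"],
            maf_tol=enr_par["maf_tol"], seed=seed + 3 + i, role=role)
    enr = enrichment_frame(results)
    _write_tsv(outdir / "driver_enrichment.tsv", enr)
    summary["stages"].append("enrich")
    summary["enrich"] = {
        "n_driver": {r: int(len(d)) for r, d in drivers.items()},
        "n_pool": int(len(pool)),
        "results": {r: {lab: {"observed_per_mb": res.observed_per_mb,
                              "expected_mean": res.expected_mean,
                              "z": res.z, "p_two": res.p_two}
                        for lab, res in per.items()}
                    for r, per in results.items()}}

    summary["seed"] = seed
    summary["output_sha256"] = output_checksums(outdir)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)
    return summary


def _promoter_categories(promoters, tads: list[TADRecord]):
    by_chrom: dict[str, list[TADRecord]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    cats = []
    for p in promoters:
        cat = None
        ts = by_chrom.get(p.interval.chrom, [])
        starts = np.array([t.start for t in ts])
        if len(ts):
            mid = p.interval.midpoint
            j = int(np.searchsorted(starts, mid, side="right")) - 1
            if j >= 0 and ts[j].end > mid:
                cat = ts[j].category3
        cats.append(cat)
    return cats


def output_checksums(outdir: Path) -> dict[str, str]:
    """SHA-256 of every TSV/BED output (determinism check)."""
    out = {}
    for path in sorted(Path(outdir).glob("*.*")):
        if path.suffix in (".tsv", ".bed"):
            out[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
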