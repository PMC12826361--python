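"""Synthetic multi-cell-line TAD / chromHMM / meQTL datasets.

Real inputs for this analysis (Hi-C TAD calls, Roadmap chromHMM tracks,
pan-cancer meQTL catalogues, genotypes) are controlled-access or very
large.  This module generates complete synthetic stand-ins with the
statistical structure the analysis assumes, plus a truth record of every
planted quantity, so each downstream estimator can be tested for recovery:

* TADs laid out per chromosome with Gaussian lengths and gaps; one jittered
  copy per cell line (jitter sd 0 makes all cell lines identical).
* A true activity archetype per TAD (Active-1/2, Inactive-1/2, Mixed);
  15-state segmentations drawn from per-archetype Dirichlet compositions.
* meQTLs placed with piecewise-constant density: per-category multipliers
  inside TADs, and a 40-step linear ramp across inter-TAD spans running
  from the active-flank multiplier (1) to the inactive-flank multiplier
  (the boundary gradient g) when g != 1.
* Driver meQTLs whose probes sit in promoters of oncogenes/TSGs, placed
  with per-(role, region) density multipliers.
* Beta-distributed MAFs, block LD with configurable within-block r^2.

Everything is driven by one seed; identical configs produce byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .core import (GenomicInterval, PromoterRecord, TADRecord,
                   collapse_category)

CATEGORY5 = ("Active-1", "Active-2", "Inactive-1", "Inactive-2", "Mixed")

# Archetype state compositions (15 chromHMM states).  Active archetypes
# concentrate mass in TssA..Enh, inactive ones in Het/ReprPC/ReprPCWk/Quies,
# Mixed balances the two sides (gap < 0.1 so its centroid labels as Mixed).
ARCHETYPE_PROFILES: dict[str, np.ndarray] = {
    "Active-1": np.array([.25, .15, .05, .23, .10, .03, .07,
                          .02, .01, .005, .005, .01, .005, .015, .05]),
    "Active-2": np.array([.03, .03, .03, .10, .30, .10, .21,
                          .02, .02, .01, .01, .02, .01, .02, .09]),
    "Inactive-1": np.array([.01, .01, .01, .02, .02, .01, .02,
                            .02, .25, .01, .01, .01, .20, .15, .25]),
    "Inactive-2": np.array([.005, .005, .005, .01, .02, .005, .02,
                            .01, .05, .005, .005, .01, .03, .10, .72]),
    "Mixed": np.array([.05, .03, .02, .15, .10, .02, .08,
                       .05, .06, .02, .02, .05, .04, .10, .21]),
}
for _name, _p in ARCHETYPE_PROFILES.items():
    assert abs(_p.sum() - 1) < 1e-9, _name


def _default_archetype_probs() -> dict[str, float]:
    # proportions echoing the roughly 20% active / 57% inactive / 23% mixed
    # split of consensus TADs in human cell lines
    return {"Active-1": 0.10, "Active-2": 0.10,
            "Inactive-1": 0.30, "Inactive-2": 0.27, "Mixed": 0.23}


def _default_tad_density() -> dict[str, float]:
    return {"Active": 1.0, "Inactive": 1.0, "Mixed": 1.0}


def _default_driver_counts() -> dict[str, int]:
    return {"oncogene": 54, "TSG": 102}


def _default_driver_enrichment() -> dict[str, dict[str, float]]:
    # oncogene-proximal meQTLs depleted in active TADs and enriched in
    # inactive ones; TSG-proximal the opposite, with a boundary excess
    return {"oncogene": {"Active": 0.5, "Inactive": 2.0, "Mixed": 1.0,
                         "Boundary": 1.0},
            "TSG": {"Active": 2.0, "Inactive": 0.5, "Mixed": 1.0,
                    "Boundary": 1.5}}


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_chroms: int = 5
    chrom_length: int = 230_000_000
    n_tads: int = 220                      # per chromosome
    tad_length_mean: float = 800_000.0
    tad_length_sd: float = 200_000.0
    gap_mean: float = 200_000.0
    gap_sd: float = 60_000.0
    min_tad_length: int = 50_000
    min_gap: int = 1_000
    n_cell_lines: int = 5
    boundary_jitter: float = 10_000.0      # sd of endpoint jitter, bp
    archetype_probs: dict[str, float] = field(
        default_factory=_default_archetype_probs)
    dirichlet_concentration: float = 50.0
    n_epigenomes: int = 2                  # 0 skips segmentation tracks
    segment_length: int = 2_000
    n_meqtls: int = 60_000
    boundary_gradient: float = 1.5         # g; 1 = flat placement in gaps
    tad_density: dict[str, float] = field(default_factory=_default_tad_density)
    n_genes: int = 500
    frac_oncogene: float = 0.1
    frac_tsg: float = 0.2
    promoter_width: int = 1_000
    n_driver_meqtls: dict[str, int] = field(
        default_factory=_default_driver_counts)
    driver_enrichment: dict[str, dict[str, float]] = field(
        default_factory=_default_driver_enrichment)
    maf_beta: tuple[float, float] = (1.5, 4.0)
    neglog10_p_range: tuple[float, float] = (1.0, 12.0)
    ld_block_size: int = 10
    ld_r2: float = 0.7
    n_samples: int = 100                   # 0 skips the dosage matrix
    beta_base: float = 0.45                # promoter methylation baseline
    beta_shift: float = 0.15               # inactive minus active mean beta
    beta_sd: float = 0.10
    probe_offset: int = 50_000             # max |probe - SNP| for non-drivers
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.archetype_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"archetype probabilities sum to {tot}, not 1")
        for role, mults in self.driver_enrichment.items():
            if any(m <= 0 for m in mults.values()):
                raise ValueError(f"non-positive driver multiplier for {role}")
        if any(m <= 0 for m in self.tad_density.values()):
            raise ValueError("non-positive tad_density multiplier")
        if self.boundary_gradient <= 0:
            raise ValueError("boundary_gradient must be > 0")


@dataclass
class SimulatedDataset:
    config: SimConfig
    chrom_sizes: dict[str, int]
    true_tads: list[TADRecord]                 # with planted category5/3
    tad_sets: dict[str, list[TADRecord]]       # per cell line (jittered)
    segments: list[list[tuple[GenomicInterval, int]]]   # per epigenome
    meqtls: pd.DataFrame
    promoters: list[PromoterRecord]
    gene_roles: dict[str, str]
    dosages: Optional[pd.DataFrame]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write every input file the analysis readers understand."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_chrom_sizes(outdir / "chrom.sizes", self.chrom_sizes)
        for cl, tads in self.tad_sets.items():
            tio.write_bed(outdir / f"tads_{cl}.bed", tads)
        for e, track in enumerate(self.segments):
            tio.write_bed(outdir / f"chromhmm_E{e:03d}.bed", track)
        tio.write_meqtl_table(outdir / "meqtls.tsv", self.meqtls)
        tio.write_bed(outdir / "promoters.bed", self.promoters)
        tio.write_gene_roles(outdir / "gene_roles.tsv", self.gene_roles)
        if self.dosages is not None:
            tio.write_dosages(outdir / "dosages.tsv", self.dosages)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    rng = np.random.default_rng(config.seed)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length
                   for i in range(config.n_chroms)}

    true_tads, categories5 = _layout_tads(config, rng, chrom_sizes)
    tad_sets = _jitter_cell_lines(config, rng, true_tads, chrom_sizes)
    segments = _segmentations(config, rng, true_tads, chrom_sizes)
    promoters, gene_roles = _genes(config, rng, chrom_sizes)
    meqtls, driver_ids = _meqtls(config, rng, true_tads, chrom_sizes,
                                 promoters, gene_roles)
    dosages = _dosages(config, rng, meqtls) if config.n_samples > 0 else None

    truth = {
        "config": _jsonable(dataclasses.asdict(config)),
        "tads": [
            {"chrom": t.chrom, "start": t.start, "end": t.end,
             "category5": t.category5, "category3": t.category3}
            for t in true_tads],
        "driver_snp_ids": {role: sorted(ids)
                           for role, ids in driver_ids.items()},
        "boundary_gradient": config.boundary_gradient,
        "tad_density": dict(config.tad_density),
        "driver_enrichment": {r: dict(m)
                              for r, m in config.driver_enrichment.items()},
    }
    return SimulatedDataset(config, chrom_sizes, true_tads, tad_sets,
                            segments, meqtls, promoters, gene_roles,
                            dosages, truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _layout_tads(config: SimConfig, rng, chrom_sizes):
    names = list(ARCHETYPE_PROFILES)
    probs = np.array([config.archetype_probs[n] for n in names])
    tads: list[TADRecord] = []
    cats: list[str] = []
    for chrom, size in chrom_sizes.items():
        lengths = np.maximum(
            rng.normal(config.tad_length_mean, config.tad_length_sd,
                       config.n_tads),
            config.min_tad_length).astype(np.int64)
        gaps = np.maximum(
            rng.normal(config.gap_mean, config.gap_sd, config.n_tads),
            config.min_gap).astype(np.int64)
        total = int(lengths.sum() + gaps.sum())
        if total > size:
            raise ValueError(
                f"infeasible config: {config.n_tads} TADs need {total} bp "
                f"but {chrom} is {size} bp")
        pos = gaps[0]
        arch = rng.choice(len(names), size=config.n_tads, p=probs)
        for i in range(config.n_tads):
            start, end = int(pos), int(pos + lengths[i])
            cat5 = names[arch[i]]
            tads.append(TADRecord(GenomicInterval(chrom, start, end),
                                  cell_line="truth", category5=cat5))
            cats.append(cat5)
            pos = end + (gaps[i + 1] if i + 1 < config.n_tads else 0)
    return tads, cats


def _jitter_cell_lines(config: SimConfig, rng, true_tads, chrom_sizes):
    by_chrom: dict[str, list[TADRecord]] = {}
    for t in true_tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    sets: dict[str, list[TADRecord]] = {}
    for c in range(config.n_cell_lines):
        name = f"cell{c + 1}"
        out: list[TADRecord] = []
        for chrom, ts in by_chrom.items():
            size = chrom_sizes[chrom]
            prev_end = 0
            for t in ts:
                if config.boundary_jitter > 0:
                    js = t.start + int(round(rng.normal(0, config.boundary_jitter)))
                    je = t.end + int(round(rng.normal(0, config.boundary_jitter)))
                else:
                    js, je = t.start, t.end
                js = max(prev_end, max(0, js))
                je = min(size, max(js + 1000, je))
                out.append(TADRecord(GenomicInterval(chrom, js, je),
                                     cell_line=name))
                prev_end = je
        sets[name] = out
    return sets


def _segmentations(config: SimConfig, rng, true_tads, chrom_sizes):
    tracks = []
    for _ in range(config.n_epigenomes):
        track: list[tuple[GenomicInterval, int]] = []
        by_chrom: dict[str, list[TADRecord]] = {}
        for t in true_tads:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            size = chrom_sizes[chrom]
            cursor = 0
            for t in ts:
                if t.start > cursor:        # inter-TAD: quiescent
                    track.append((GenomicInterval(chrom, cursor, t.start), 15))
                comp = rng.dirichlet(config.dirichlet_concentration
                                     * ARCHETYPE_PROFILES[t.category5])
                n_seg = max(1, -(-len(t.interval) // config.segment_length))
                states = rng.choice(15, size=n_seg, p=comp) + 1
                edges = np.minimum(
                    t.start + np.arange(n_seg + 1) * config.segment_length,
                    t.end)
                for s, e, st in zip(edges[:-1], edges[1:], states):
                    if e > s:
                        track.append((GenomicInterval(chrom, int(s), int(e)),
                                      int(st)))
                cursor = t.end
            if cursor < size:
                track.append((GenomicInterval(chrom, cursor, size), 15))
        tracks.append(track)
    return tracks


def _genes(config: SimConfig, rng, chrom_sizes):
    chroms = list(chrom_sizes)
    promoters: list[PromoterRecord] = []
    roles: dict[str, str] = {}
    n_onco = int(round(config.n_genes * config.frac_oncogene))
    n_tsg = int(round(config.n_genes * config.frac_tsg))
    role_list = (["oncogene"] * n_onco + ["TSG"] * n_tsg
                 + ["none"] * (config.n_genes - n_onco - n_tsg))
    rng.shuffle(role_list)
    for i in range(config.n_genes):
        gene = f"GENE{i + 1:04d}"
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_sizes[chrom] - config.promoter_width))
        promoters.append(PromoterRecord(
            GenomicInterval(chrom, start, start + config.promoter_width), gene))
        if role_list[i] != "none":
            roles[gene] = role_list[i]
    return promoters, roles


def _placement_segments(config: SimConfig, true_tads, chrom_sizes,
                        driver_mult: Optional[dict[str, float]] = None):
    """Weighted elementary segments for meQTL placement.

    Returns (chrom array, start array, end array, weight array).  TAD spans
    get their category multiplier; inter-TAD spans get a 40-step ramp from
    the active-flank weight (1) to the inactive-flank weight (g); edges get
    weight 1.  ``driver_mult`` further multiplies per-region weights
    (keys Active/Inactive/Mixed for TAD spans, Boundary for inter-TAD
    spans).
    """
    g = config.boundary_gradient
    dm = driver_mult or {}
    chroms, starts, ends, weights = [], [], [], []

    def add(chrom, s, e, w):
        if e > s and w > 0:
            chroms.append(chrom)
            starts.append(int(s))
            ends.append(int(e))
            weights.append(float(w))

    by_chrom: dict[str, list[TADRecord]] = {}
    for t in true_tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        size = chrom_sizes[chrom]
        add(chrom, 0, ts[0].start, dm.get("Boundary", 1.0))
        for i, t in enumerate(ts):
            add(chrom, t.start, t.end,
                config.tad_density[t.category3] * dm.get(t.category3, 1.0))
            nxt = ts[i + 1] if i + 1 < len(ts) else None
            gap_end = nxt.start if nxt is not None else size
            if gap_end <= t.end:
                continue
            bmult = dm.get("Boundary", 1.0)
            lcat = t.category3
            rcat = nxt.category3 if nxt is not None else None
            wl = g if lcat == "Inactive" else 1.0
            wr = g if rcat == "Inactive" else 1.0
            if rcat not in ("Active", "Inactive") or \
                    lcat not in ("Active", "Inactive") or wl == wr == 1.0:
                # mixed-adjacent or chrom-edge spans: flat base weight
                add(chrom, t.end, gap_end, bmult)
                continue
            if wl == wr:
                add(chrom, t.end, gap_end, bmult * wl)
            else:
                # 40-step piecewise-constant approximation of the ramp
                edges = np.linspace(t.end, gap_end, 41).astype(np.int64)
                mids = (np.arange(40) + 0.5) / 40
                for s, e, f in zip(edges[:-1], edges[1:], mids):
                    add(chrom, s, e, bmult * (wl + (wr - wl) * f))
    return (np.array(chroms, dtype=object), np.array(starts, dtype=np.int64),
            np.array(ends, dtype=np.int64), np.array(weights))


def _sample_positions(rng, n, segs):
    chroms, starts, ends, weights = segs
    lens = (ends - starts).astype(float)
    p = weights * lens
    p /= p.sum()
    counts = rng.multinomial(n, p)
    seg_idx = np.repeat(np.arange(len(starts)), counts)
    offs = (rng.random(n) * lens[seg_idx]).astype(np.int64)
    return chroms[seg_idx], starts[seg_idx] + offs


def _meqtls(config: SimConfig, rng, true_tads, chrom_sizes, promoters,
            gene_roles):
    cancer_types = np.array(["BRCA", "COAD", "LUAD", "PRAD", "STAD"],
                            dtype=object)
    bases = np.array(list("ACGT"), dtype=object)
    role_proms: dict[str, dict[str, list[PromoterRecord]]] = {
        "oncogene": {}, "TSG": {}}
    for p in promoters:
        role = gene_roles.get(p.gene)
        if role:
            role_proms[role].setdefault(p.interval.chrom, []).append(p)

    frames = []
    driver_ids: dict[str, list[str]] = {"oncogene": [], "TSG": []}
    counter = 0

    def build(n, chroms, pos, probe_pos, probe_prefix):
        nonlocal counter
        ids = [f"rs{counter + i + 1}" for i in range(n)]
        counter += n
        ref = bases[rng.integers(0, 4, n)]
        alt_shift = rng.integers(1, 4, n)
        alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
        lo, hi = config.neglog10_p_range
        pval = 10.0 ** (-rng.uniform(lo, hi, n))
        a, b = config.maf_beta
        maf = np.clip(0.5 * rng.beta(a, b, n), 0.005, 0.5)
        return pd.DataFrame({
            "snp_id": ids, "chrom": chroms, "pos": pos,
            "ref": ref, "alt": alt, "pvalue": pval, "maf": maf,
            "probe_id": [f"{probe_prefix}{counter - n + i + 1:07d}"
                         for i in range(n)],
            "probe_chrom": chroms, "probe_pos": probe_pos,
            "cancer_type": cancer_types[rng.integers(0, len(cancer_types), n)],
        })

    # non-driver meQTLs: probes near the SNP, kept out of driver promoters
    segs = _placement_segments(config, true_tads, chrom_sizes)
    chroms, pos = _sample_positions(rng, config.n_meqtls, segs)
    probe_pos = pos + rng.integers(-config.probe_offset,
                                   config.probe_offset + 1,
                                   config.n_meqtls)
    sizes = np.array([chrom_sizes[c] for c in chroms])
    probe_pos = np.clip(probe_pos, 0, sizes - 1)
    probe_pos = _evict_from_promoters(probe_pos, chroms, role_proms, sizes)
    frames.append(build(config.n_meqtls, chroms, pos, probe_pos, "cg"))

    # driver meQTLs: probes inside a same-chromosome driver promoter
    for role, n_drv in config.n_driver_meqtls.items():
        if n_drv == 0:
            continue
        if not any(role_proms[role].values()):
            raise ValueError(f"no {role} promoters available; increase "
                             f"n_genes or frac_{role.lower()}")
        dsegs = _placement_segments(config, true_tads, chrom_sizes,
                                    config.driver_enrichment[role])
        ok_chroms = set(role_proms[role])
        keep = np.array([c in ok_chroms for c in dsegs[0]])
        dsegs = tuple(a[keep] for a in dsegs)
        dchroms, dpos = _sample_positions(rng, n_drv, dsegs)
        dprobe = np.empty(n_drv, dtype=np.int64)
        for i in range(n_drv):
            cands = role_proms[role][dchroms[i]]
            prom = cands[int(rng.integers(len(cands)))]
            dprobe[i] = int(rng.integers(prom.interval.start,
                                         prom.interval.end))
        df = build(n_drv, dchroms, dpos, dprobe, "cgdrv")
        driver_ids[role] = df["snp_id"].tolist()
        frames.append(df)

    meqtls = pd.concat(frames, ignore_index=True)
    return meqtls, driver_ids


def _evict_from_promoters(probe_pos, chroms, role_proms, sizes):
    """Nudge non-driver probes out of any driver-gene promoter."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    for role_map in role_proms.values():
        for chrom, proms in role_map.items():
            ivs.setdefault(chrom, []).extend(
                (p.interval.start, p.interval.end) for p in proms)
    probe_pos = probe_pos.copy()
    for chrom, pairs in ivs.items():
        pairs.sort()
        starts = np.array([s for s, _ in pairs])
        ends = np.array([e for _, e in pairs])
        mask = np.asarray(chroms, dtype=object) == chrom
        for _ in range(5):
            pos = probe_pos[mask]
            j = np.searchsorted(starts, pos, side="right") - 1
            inside = (j >= 0) & (pos < ends[np.maximum(j, 0)])
            if not inside.any():
                break
            pos[inside] = ends[np.maximum(j, 0)][inside] + 1
            pos = np.minimum(pos, sizes[mask] - 1)
            probe_pos[mask] = pos
    return probe_pos


def _dosages(config: SimConfig, rng, meqtls: pd.DataFrame) -> pd.DataFrame:
    """Block-LD dosage matrix: within-block pairwise r^2 ~= ld_r2."""
    snps = meqtls.drop_duplicates("snp_id")[["snp_id", "chrom", "pos"]]
    snps = snps.sort_values(["chrom", "pos", "snp_id"],
                            kind="stable").reset_index(drop=True)
    n = len(snps)
    a = config.ld_r2 ** 0.25        # pairwise corr a^2 -> r^2 = a^4
    block = np.zeros(n, dtype=np.int64)
    b = 0
    prev_chrom = None
    in_block = 0
    for i, chrom in enumerate(snps["chrom"]):
        if chrom != prev_chrom or in_block >= config.ld_block_size:
            b += 1
            in_block = 0
            prev_chrom = chrom
        block[i] = b
        in_block += 1
    z_block = rng.normal(size=(b + 1, config.n_samples))
    eps = rng.normal(size=(n, config.n_samples))
    mat = a * z_block[block] + np.sqrt(1 - a * a) * eps
    return pd.DataFrame(mat, index=pd.Index(snps["snp_id"], name="snp_id"),
                        columns=[f"S{j + 1}" for j in range(config.n_samples)])


# ---------------------------------------------------------------------------
# promoter methylation
# ---------------------------------------------------------------------------

def simulate_promoter_betas(config: SimConfig,
                            categories: Sequence[Optional[str]],
                            seed: Optional[int] = None) -> np.ndarray:
    """Beta values per promoter given the containing-TAD category.

    Active promoters centre on ``beta_base``; inactive promoters on
    ``beta_base + beta_shift``; Mixed (and unassigned) promoters half-way.
    Values are clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shift = {"Active": 0.0, "Mixed": config.beta_shift / 2,
             "Inactive": config.beta_shift}
    mu = np.array([config.beta_base + shift.get(c, config.beta_shift / 2)
                   for c in categories])
    return np.clip(rng.normal(mu, config.beta_sd), 0.0, 1.0)


def true_tad_copy(sim: SimulatedDataset) -> list[TADRecord]:
    """Fresh TADRecord list with the planted categories (truth bypass)."""
    return [TADRecord(t.interval, cell_line="consensus",
                      category5=t.category5) for t in sim.true_tads]
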