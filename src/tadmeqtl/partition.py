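"""Boundary construction, genome partition and region-normalised burden.

The boundary of a TAD endpoint is the 50 kb on either side of it (a 100 kb
window).  When two consecutive TADs are separated by less than 100 kb the
outward extent of each boundary is truncated to the proximal half of the
gap, so boundaries never overlap.  Boundaries take precedence over TAD
interiors when labelling the genome; inter-TAD bases outside any boundary
are "Other".  meQTL burden is counted over unique SNP positions and
normalised by labelled region length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (LABEL_ACTIVE, LABEL_BOUNDARY, LABEL_INACTIVE, LABEL_MIXED,
                   LABEL_OTHER, REGION_LABELS, GenomicInterval,
                   PromoterRecord, TADRecord, sort_tads, validate_tad_set)

_CAT2LABEL = {"Active": LABEL_ACTIVE, "Inactive": LABEL_INACTIVE,
              "Mixed": LABEL_MIXED}


@dataclass(frozen=True)
class BoundaryRegion:
    """A boundary interval with its flanking-TAD transition tag.

    ``transition`` is AA/AI/IA/II for boundaries between two classified
    non-Mixed TADs, ``mixed-adjacent`` when either flank is Mixed, and
    ``chrom-edge`` for the outermost endpoints of a chromosome.
    """
    interval: GenomicInterval
    transition: str


def define_boundaries(tads: Sequence[TADRecord],
                      chrom_sizes: dict[str, int],
                      half_width: int = 50_000) -> list[BoundaryRegion]:
    """Boundary regions around every consensus-TAD endpoint.

    Per endpoint the boundary is ``[endpoint - half_width,
    endpoint + half_width)`` clipped to the chromosome.  For gaps shorter
    than ``2 * half_width`` each side keeps its inward half_width plus the
    proximal half of the gap, and the two abutting pieces are merged into a
    single boundary spanning the whole inter-TAD window.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    validate_tad_set(tads) if tads else None
    out: list[BoundaryRegion] = []
    if half_width == 0:
        return out
    for chrom, ts in _group_sorted(tads).items():
        size = chrom_sizes[chrom]
        # chromosome-edge boundaries at the outermost endpoints
        first, last = ts[0], ts[-1]
        out.append(_clipped(chrom, first.start - half_width,
                            first.start + half_width, size, "chrom-edge"))
        out.append(_clipped(chrom, last.end - half_width,
                            last.end + half_width, size, "chrom-edge"))
        for left, right in zip(ts, ts[1:]):
            gap = right.start - left.end
            tag = _transition_tag(left.category3, right.category3)
            if gap < 2 * half_width:
                # proximal-half rule; the two pieces abut -> one merged region
                out.append(_clipped(chrom, left.end - half_width,
                                    right.start + half_width, size, tag))
            else:
                out.append(_clipped(chrom, left.end - half_width,
                                    left.end + half_width, size, tag))
                out.append(_clipped(chrom, right.start - half_width,
                                    right.start + half_width, size, tag))
    out.sort(key=lambda b: (b.interval.chrom, b.interval.start))
    return out


def _transition_tag(left: Optional[str], right: Optional[str]) -> str:
    if left is None or right is None:
        return "mixed-adjacent"
    if "Mixed" in (left, right):
        return "mixed-adjacent"
    return left[0] + right[0]      # e.g. "A" + "I" -> "AI"


def _clipped(chrom: str, start: int, end: int, size: int,
             tag: str) -> BoundaryRegion:
    return BoundaryRegion(
        GenomicInterval(chrom, max(0, start), min(size, end)), tag)


def _group_sorted(tads: Sequence[TADRecord]) -> dict[str, list[TADRecord]]:
    groups: dict[str, list[TADRecord]] = {}
    for t in sort_tads(tads):
        groups.setdefault(t.chrom, []).append(t)
    return groups


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Disjoint labelled intervals tiling every chromosome exactly."""

    df: pd.DataFrame                    # chrom, start, end, label
    chrom_sizes: dict[str, int]
    label_bp: dict[str, int] = field(init=False)
    _index: dict[str, tuple[np.ndarray, np.ndarray]] = field(init=False,
                                                             repr=False)

    def __post_init__(self) -> None:
        lengths = self.df["end"] - self.df["start"]
        self.label_bp = {lab: 0 for lab in REGION_LABELS}
        for lab, bp in lengths.groupby(self.df["label"]).sum().items():
            self.label_bp[str(lab)] = int(bp)
        self._index = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != self.chrom_sizes[str(chrom)]:
                raise ValueError(f"partition does not tile {chrom}")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"partition has gaps/overlaps on {chrom}")
            self._index[str(chrom)] = (starts,
                                       sub["label"].to_numpy(dtype=object))

    def label_positions(self, chroms: np.ndarray,
                        positions: np.ndarray) -> np.ndarray:
        """Vectorised point-in-partition lookup (0-based positions)."""
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.empty(len(positions), dtype=object)
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            starts, labels = self._index[str(chrom)]
            pos = positions[mask]
            if pos.min() < 0 or pos.max() >= self.chrom_sizes[str(chrom)]:
                raise ValueError(f"position outside {chrom}")
            out[mask] = labels[np.searchsorted(starts, pos, side="right") - 1]
        return out


def partition_genome(tads: Sequence[TADRecord],
                     boundaries: Sequence[BoundaryRegion],
                     chrom_sizes: dict[str, int]) -> RegionPartition:
    """Tile every chromosome with labels, precedence Boundary > TAD > Other."""
    validate_tad_set(tads) if tads else None
    tad_by_chrom = _group_sorted(tads)
    bnd_by_chrom: dict[str, list[BoundaryRegion]] = {}
    for b in boundaries:
        bnd_by_chrom.setdefault(b.interval.chrom, []).append(b)

    rows = []
    for chrom, size in chrom_sizes.items():
        cuts = {0, size}
        for t in tad_by_chrom.get(chrom, []):
            cuts.update((t.start, t.end))
        for b in bnd_by_chrom.get(chrom, []):
            cuts.update((b.interval.start, b.interval.end))
        cuts = np.array(sorted(c for c in cuts if 0 <= c <= size))
        tstarts = np.array([t.start for t in tad_by_chrom.get(chrom, [])])
        tends = np.array([t.end for t in tad_by_chrom.get(chrom, [])])
        tcats = [t.category3 for t in tad_by_chrom.get(chrom, [])]
        bl = sorted((b.interval.start, b.interval.end)
                    for b in bnd_by_chrom.get(chrom, []))
        bl = _merge(bl)
        bstarts = np.array([s for s, _ in bl])
        bends = np.array([e for _, e in bl])
        prev_label = None
        seg_start = 0
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            label = LABEL_OTHER
            if len(bstarts):
                j = np.searchsorted(bstarts, lo, side="right") - 1
                if j >= 0 and bends[j] > lo:
                    label = LABEL_BOUNDARY
            if label is not LABEL_BOUNDARY and len(tstarts):
                j = np.searchsorted(tstarts, lo, side="right") - 1
                if j >= 0 and tends[j] > lo:
                    cat = tcats[j]
                    if cat is None:
                        raise ValueError("TAD without category3 in partition")
                    label = _CAT2LABEL[cat]
            if label != prev_label:
                if prev_label is not None:
                    rows.append((chrom, seg_start, int(lo), prev_label))
                seg_start = int(lo)
                prev_label = label
        rows.append((chrom, seg_start, int(size), prev_label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return RegionPartition(df, dict(chrom_sizes))


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# burden
# ---------------------------------------------------------------------------

def unique_snps(meqtls: pd.DataFrame) -> pd.DataFrame:
    """One row per SNP: first position seen, smallest association p-value.

    A SNP associated with several probes or cancer types counts once in
    burden analyses; its clumping p-value is the best (minimum) across its
    associations.
    """
    df = meqtls.sort_values(["snp_id", "pvalue"], kind="stable")
    agg = df.groupby("snp_id", sort=True).agg(
        chrom=("chrom", "first"), pos=("pos", "first"),
        pvalue=("pvalue", "min"), maf=("maf", "first"))
    return agg.reset_index()


def density_per_label(label_counts: dict[str, int],
                      label_bp: dict[str, int]) -> pd.DataFrame:
    """Shared count -> density conversion used by burden and randomisation."""
    rows = []
    for lab in REGION_LABELS:
        bp = label_bp.get(lab, 0)
        n = label_counts.get(lab, 0)
        dens = n / bp if bp > 0 else 0.0
        rows.append((lab, n, bp, dens, dens * 1e6))
    return pd.DataFrame(rows, columns=["label", "count", "bp",
                                       "density", "per_mb"])


def burden_by_label(meqtls: pd.DataFrame,
                    partition: RegionPartition) -> pd.DataFrame:
    """Unique-SNP counts and per-bp / per-Mb densities per region label."""
    snps = unique_snps(meqtls)
    if len(snps) == 0:
        return density_per_label({}, partition.label_bp)
    labels = partition.label_positions(snps["chrom"].to_numpy(),
                                       snps["pos"].to_numpy())
    counts = {str(k): int(v)
              for k, v in pd.Series(labels).value_counts().items()}
    return density_per_label(counts, partition.label_bp)


def per_tad_burden_test(meqtls: pd.DataFrame, tads: Sequence[TADRecord],
                        equal_var: bool = False):
    """Per-TAD length-normalised meQTL burden and an Active-vs-Inactive t-test.

    Counts use the full TAD span (boundaries are not subtracted here) over
    unique SNP positions; densities are count / TAD length.  The default is
    the Welch unequal-variance two-sample t-test.

    Returns (per_tad DataFrame, t statistic, p-value).
    """
    snps = unique_snps(meqtls)
    by_chrom = _group_sorted(tads)
    rows = []
    for chrom, ts in by_chrom.items():
        starts = np.array([t.start for t in ts])
        ends = np.array([t.end for t in ts])
        pos = np.sort(snps.loc[snps["chrom"] == chrom, "pos"].to_numpy())
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        for t, n in zip(ts, hi - lo):
            rows.append((t.chrom, t.start, t.end, t.category3, int(n),
                         n / len(t.interval)))
    per_tad = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                          "category3", "count", "density"])
    act = per_tad.loc[per_tad["category3"] == "Active", "density"]
    ina = per_tad.loc[per_tad["category3"] == "Inactive", "density"]
    if len(act) < 2 or len(ina) < 2:
        raise ValueError("need >=2 Active and >=2 Inactive TADs for the t-test")
    t, p = stats.ttest_ind(act, ina, equal_var=equal_var)
    return per_tad, float(t), float(p)


def promoter_methylation_by_category(betas: np.ndarray,
                                     promoters: Sequence[PromoterRecord],
                                     tads: Sequence[TADRecord]):
    """Promoter methylation grouped by the activity of the containing TAD.

    Each promoter is assigned to the TAD containing its midpoint; promoters
    outside every consensus TAD are dropped.  Returns (summary DataFrame,
    Kruskal-Wallis H, p-value, n_dropped).
    """
    betas = np.asarray(betas, dtype=float)
    if len(betas) != len(promoters):
        raise ValueError("betas and promoters differ in length")
    by_chrom = _group_sorted(tads)
    groups: dict[str, list[float]] = {}
    n_dropped = 0
    for beta, prom in zip(betas, promoters):
        ts = by_chrom.get(prom.interval.chrom)
        cat = None
        if ts:
            starts = np.array([t.start for t in ts])
            mid = prom.interval.midpoint
            j = int(np.searchsorted(starts, mid, side="right")) - 1
            if j >= 0 and ts[j].end > mid:
                cat = ts[j].category3
        if cat is None:
            n_dropped += 1
            continue
        groups.setdefault(cat, []).append(beta)
    if any(len(v) == 0 for v in groups.values()) or len(groups) < 2:
        raise ValueError("need promoters in at least two TAD categories")
    summary = pd.DataFrame(
        [(cat, len(v), float(np.mean(v)), float(np.median(v)))
         for cat, v in sorted(groups.items())],
        columns=["category3", "n", "mean_beta", "median_beta"])
    vals = [np.asarray(groups[c]) for c in sorted(groups)]
    if all(np.ptp(np.concatenate(vals)) == 0 for _ in [0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*vals)
    return summary, float(h), float(p), n_dropped
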