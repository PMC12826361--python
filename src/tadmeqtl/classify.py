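"""TAD activity classification from chromHMM 15-state compositions.

Each consensus TAD is summarised as the fraction of its annotated bases in
each of the 15 chromatin states (averaged over the supplied epigenomes),
the composition vectors are clustered with k-means (k=5 by default), and
the cluster centroids are labelled Active-1/2, Inactive-1/2 or Mixed from
the balance of active-state mass (TssA..Enh) versus inactive-state mass
(Het, ReprPC, ReprPCWk, Quies).  Collapsing the 5-way labels gives the
3-way Active / Inactive / Mixed categorisation used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core import (ACTIVE_STATE_IDX, INACTIVE_STATE_IDX, N_STATES,
                   GenomicInterval, StateComposition, TADRecord,
                   collapse_category)

SegmentTrack = Sequence[tuple[GenomicInterval, int]]


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def state_composition(tad: TADRecord,
                      segment_tracks: Sequence[SegmentTrack]) -> StateComposition:
    """15-state composition of one TAD, averaged across epigenome tracks."""
    mat = state_compositions([tad], segment_tracks)
    return StateComposition(mat[0])


def state_compositions(tads: Sequence[TADRecord],
                       segment_tracks: Sequence[SegmentTrack]) -> np.ndarray:
    """Composition matrix (n_tads x 15) for many TADs at once.

    Per epigenome, the fraction of a TAD in state ``s`` is the bp covered by
    ``s`` divided by the annotated bp inside the TAD; fractions are averaged
    across epigenomes with equal weight and renormalised.  Segments within
    one epigenome must be non-overlapping.  A TAD with zero annotated bp in
    every track is an error.
    """
    if not segment_tracks:
        raise ValueError("need at least one segmentation track")
    n = len(tads)
    acc = np.zeros((n, N_STATES))
    n_tracks_cover = np.zeros(n)
    for track in segment_tracks:
        idx = _index_track(track)
        frac = np.zeros((n, N_STATES))
        covered = np.zeros(n, dtype=bool)
        for i, tad in enumerate(tads):
            entry = idx.get(tad.chrom)
            if entry is None:
                continue
            starts, ends, states = entry
            lo = np.searchsorted(ends, tad.start, side="right")
            hi = np.searchsorted(starts, tad.end, side="left")
            if hi <= lo:
                continue
            ov = (np.minimum(ends[lo:hi], tad.end)
                  - np.maximum(starts[lo:hi], tad.start))
            ov = np.maximum(ov, 0)
            bp = np.bincount(states[lo:hi] - 1, weights=ov,
                             minlength=N_STATES)
            tot = bp.sum()
            if tot > 0:
                frac[i] = bp / tot
                covered[i] = True
        acc[covered] += frac[covered]
        n_tracks_cover += covered
    empty = n_tracks_cover == 0
    if empty.any():
        t = tads[int(np.flatnonzero(empty)[0])]
        raise ValueError(
            f"TAD {t.chrom}:{t.start}-{t.end} has zero annotated bp")
    acc /= n_tracks_cover[:, None]
    acc /= acc.sum(axis=1, keepdims=True)
    return acc


def _index_track(track: SegmentTrack):
    by_chrom: dict[str, list[list[int]]] = {}
    for iv, state in track:
        by_chrom.setdefault(iv.chrom, [[], [], []])
        by_chrom[iv.chrom][0].append(iv.start)
        by_chrom[iv.chrom][1].append(iv.end)
        by_chrom[iv.chrom][2].append(state)
    out = {}
    for chrom, (s, e, st) in by_chrom.items():
        s, e, st = (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64),
                    np.asarray(st, dtype=np.int64))
        order = np.argsort(s, kind="stable")
        s, e, st = s[order], e[order], st[order]
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"overlapping segments on {chrom}")
        out[chrom] = (s, e, st)
    return out


# ---------------------------------------------------------------------------
# clustering and labelling
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    cluster: np.ndarray          # cluster id per TAD
    centroids: np.ndarray        # k x 15
    inertia: float
    category5: list[str]         # per cluster
    tad_category5: list[str]     # per TAD
    tad_category3: list[str]     # per TAD


def cluster_tads(compositions: np.ndarray, k: int = 5, seed: int = 0,
                 n_init: int = 50) -> tuple[np.ndarray, np.ndarray, float]:
    """K-means on composition vectors; deterministic under a fixed seed.

    Returns (labels, centroids, inertia).  Clusters are re-indexed into
    lexicographic centroid order so the numbering does not depend on
    k-means initialisation order.
    """
    comps = np.asarray(compositions, dtype=float)
    if comps.ndim != 2 or comps.shape[1] != N_STATES:
        raise ValueError(f"expected (n, {N_STATES}) composition matrix")
    n_distinct = len(np.unique(comps.round(12), axis=0))
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct composition vectors for k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(comps)
    order = np.lexsort(km.cluster_centers_.T[::-1])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels], km.cluster_centers_[order], float(km.inertia_)


def label_clusters(centroids: np.ndarray,
                   mixed_margin: float = 0.1) -> list[str]:
    """Assign Active-k / Inactive-k / Mixed labels to cluster centroids.

    active_mass sums centroid fractions over TssA..Enh (states 1-7);
    inactive_mass over Het, ReprPC, ReprPCWk, Quies (states 9, 13, 14, 15).
    A centroid is Mixed when ``|active_mass - inactive_mass| < mixed_margin``,
    else takes the larger side.  Within a side, suffixes -1, -2, ... are
    ordered by descending dominant mass.
    """
    cent = np.asarray(centroids, dtype=float)
    am = cent[:, list(ACTIVE_STATE_IDX)].sum(axis=1)
    im = cent[:, list(INACTIVE_STATE_IDX)].sum(axis=1)
    side = np.where(np.abs(am - im) < mixed_margin, "Mixed",
                    np.where(am > im, "Active", "Inactive"))
    labels = [""] * len(cent)
    for base, mass in (("Active", am), ("Inactive", im)):
        members = np.flatnonzero(side == base)
        for rank, ci in enumerate(members[np.argsort(-mass[members],
                                                     kind="stable")], start=1):
            labels[ci] = f"{base}-{rank}"
    for ci in np.flatnonzero(side == "Mixed"):
        labels[ci] = "Mixed"
    return labels


def classify_tads(tads: Sequence[TADRecord],
                  segment_tracks: Sequence[SegmentTrack],
                  k: int = 5, seed: int = 0, n_init: int = 50,
                  mixed_margin: float = 0.1) -> ClassificationResult:
    """Compose -> cluster -> label; annotates the TAD records in place."""
    comps = state_compositions(tads, segment_tracks)
    cluster, centroids, inertia = cluster_tads(comps, k=k, seed=seed,
                                               n_init=n_init)
    cat5 = label_clusters(centroids, mixed_margin=mixed_margin)
    tad_cat5 = [cat5[c] for c in cluster]
    tad_cat3 = [collapse_category(c) for c in tad_cat5]
    for tad, comp, c5, c3 in zip(tads, comps, tad_cat5, tad_cat3):
        tad.composition = StateComposition(comp)
        tad.category5 = c5
        tad.category3 = c3
    return ClassificationResult(cluster, centroids, inertia, cat5,
                                tad_cat5, tad_cat3)
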