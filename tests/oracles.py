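"""Independent brute-force re-implementations used as test oracles.

Deliberately naive: plain Python loops, no shared code with the package
internals beyond the core record types.
"""

from __future__ import annotations

import numpy as np

from tadmeqtl.core import GenomicInterval, TADRecord


def brute_shared_tads(tad_sets, min_frac=0.2):
    """All-pairs greedy consensus matching (loops over every candidate)."""
    ref = sorted(tad_sets[0], key=lambda t: (t.chrom, t.start, t.end))
    others = [sorted(ts, key=lambda t: (t.chrom, t.start, t.end))
              for ts in tad_sets[1:]]
    consumed = [set() for _ in others]
    out = []
    for rt in ref:
        picks = []
        ok = True
        for si, other in enumerate(others):
            best = None
            for j, ot in enumerate(other):
                if j in consumed[si] or ot.chrom != rt.chrom:
                    continue
                ov = min(rt.end, ot.end) - max(rt.start, ot.start)
                if ov < min_frac * (rt.end - rt.start):
                    continue
                if ov < min_frac * (ot.end - ot.start):
                    continue
                key = (-ov, ot.start)
                if best is None or key < best[0]:
                    best = (key, j)
            if best is None:
                ok = False
                break
            picks.append((si, best[1]))
        if ok:
            for si, j in picks:
                consumed[si].add(j)
            out.append((rt.chrom, rt.start, rt.end))
    return out


def brute_point_label(pos, chrom, tads, boundaries):
    """Label one genomic position by scanning every interval."""
    for b in boundaries:
        iv = b.interval
        if iv.chrom == chrom and iv.start <= pos < iv.end:
            return "Boundary"
    for t in tads:
        if t.chrom == chrom and t.start <= pos < t.end:
            return {"Active": "ActiveTAD", "Inactive": "InactiveTAD",
                    "Mixed": "MixedTAD"}[t.category3]
    return "Other"


def brute_composition(tad, tracks):
    """Per-base state counting for one TAD (tiny TADs only)."""
    per_track = []
    for track in tracks:
        counts = np.zeros(15)
        for iv, state in track:
            if iv.chrom != tad.chrom:
                continue
            for p in range(max(iv.start, tad.start), min(iv.end, tad.end)):
                counts[state - 1] += 1
        if counts.sum() > 0:
            per_track.append(counts / counts.sum())
    mean = np.mean(per_track, axis=0)
    return mean / mean.sum()


def brute_clump(snps, r2_of, p1, p2, r2_min, window_bp):
    """Greedy clumping re-derived by full sort-and-sweep.

    ``snps``: list of (snp_id, chrom, pos, pvalue).  ``r2_of(a, b)`` returns
    the LD between two SNP ids.  Returns (index ids, {snp_id: clump_id}).
    """
    order = sorted(snps, key=lambda s: (s[3], s[1], s[2], s[0]))
    assigned = {}
    indexes = []
    for sid, chrom, pos, p in order:
        if sid in assigned or p > p1:
            continue
        assigned[sid] = sid
        indexes.append(sid)
        for oid, ochrom, opos, op in order:
            if oid in assigned or ochrom != chrom or op > p2:
                continue
            if abs(opos - pos) > window_bp:
                continue
            if r2_of(sid, oid) >= r2_min:
                assigned[oid] = sid
    return indexes, assigned


def brute_welch_t(x, y):
    """Welch two-sample t statistic from the textbook formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x.var(ddof=1) / len(x)
    vy = y.var(ddof=1) / len(y)
    return (x.mean() - y.mean()) / np.sqrt(vx + vy)


def brute_kruskal_h(groups):
    """Kruskal-Wallis H from ranks (no ties expected in the input)."""
    allv = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(allv)
    ranks = np.empty(n)
    ranks[np.argsort(allv)] = np.arange(1, n + 1)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i:i + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        i += len(g)
    return 12.0 / (n * (n + 1)) * h


def brute_annotate_count(meqtls, promoters, roles):
    """Double-loop count of probe-in-driver-promoter annotations."""
    n = 0
    for row in meqtls.itertuples(index=False):
        hit_roles = set()
        for p in promoters:
            if roles.get(p.gene) is None:
                continue
            if (p.interval.chrom == row.probe_chrom
                    and p.interval.start <= row.probe_pos < p.interval.end):
                hit_roles.add(roles[p.gene])
        n += len(hit_roles) if hit_roles else 0
    return n
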