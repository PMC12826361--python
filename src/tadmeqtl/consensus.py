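"""Consensus TADs shared across cell lines via a 20% overlap rule.

A TAD from the reference cell line (the first input set) is kept iff every
other cell line contains at least one TAD that overlaps it reciprocally by
at least ``min_frac`` of *both* lengths.  Matching is greedy by largest
overlap with each non-reference TAD consumed at most once, which makes the
output deterministic.  Consensus coordinates are the reference TAD's.

A one-sided mode (overlap >= min_frac of the reference TAD only) is
available because the overlap rule in the literature is not always stated
reciprocally.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import TADRecord, sort_tads, validate_tad_set


def reciprocal_match(a: TADRecord, b: TADRecord, min_frac: float = 0.2,
                     mode: str = "reciprocal") -> bool:
    """True iff the two TADs overlap by >= ``min_frac`` of both lengths.

    In ``one-sided`` mode only the fraction of ``a`` (the reference TAD)
    is required.
    """
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    if a.chrom != b.chrom:
        return False
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    if ov < min_frac * len(a.interval):
        return False
    if mode == "reciprocal":
        return ov >= min_frac * len(b.interval)
    if mode == "one-sided":
        return True
    raise ValueError(f"unknown mode {mode!r}")


def shared_tads(tad_sets: Sequence[Sequence[TADRecord]],
                min_frac: float = 0.2,
                mode: str = "reciprocal") -> list[TADRecord]:
    """Consensus TADs present in every cell line.

    Parameters
    ----------
    tad_sets
        One TAD list per cell line (>= 2).  Each set must be non-overlapping
        within a chromosome.  The first set is the reference: consensus
        coordinates are taken from it.
    min_frac
        Minimum overlap fraction (default 0.2, the 20% rule).
    mode
        ``"reciprocal"`` (default) or ``"one-sided"``.

    Returns
    -------
    Sorted list of consensus :class:`TADRecord` with ``cell_line="consensus"``.
    """
    if len(tad_sets) < 2:
        raise ValueError("need at least 2 cell lines")
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    for ts in tad_sets:
        validate_tad_set(ts)

    ref = sort_tads(tad_sets[0])
    others = [_by_chrom(sort_tads(ts)) for ts in tad_sets[1:]]

    consensus: list[TADRecord] = []
    consumed = [
        {chrom: np.zeros(len(arr[0]), dtype=bool) for chrom, arr in o.items()}
        for o in others
    ]
    for rt in ref:
        partners: list[tuple[int, int]] = []   # (set index, tad index)
        ok = True
        for si, other in enumerate(others):
            arr = other.get(rt.chrom)
            if arr is None:
                ok = False
                break
            starts, ends = arr
            free = ~consumed[si][rt.chrom]
            ov = np.minimum(ends, rt.end) - np.maximum(starts, rt.start)
            ov = np.maximum(ov, 0)
            cond = free & (ov >= min_frac * len(rt.interval))
            if mode == "reciprocal":
                cond &= ov >= min_frac * (ends - starts)
            if not cond.any():
                ok = False
                break
            # greedy: largest overlap, ties broken by smaller start
            cand = np.flatnonzero(cond)
            best = cand[np.lexsort((starts[cand], -ov[cand]))][0]
            partners.append((si, int(best)))
        if ok:
            for si, bi in partners:
                consumed[si][rt.chrom][bi] = True
            consensus.append(TADRecord(rt.interval, cell_line="consensus"))
    return consensus


def _by_chrom(tads: Sequence[TADRecord]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, list[list[int]]] = {}
    for t in tads:
        out.setdefault(t.chrom, [[], []])
        out[t.chrom][0].append(t.start)
        out[t.chrom][1].append(t.end)
    return {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in out.items()}
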