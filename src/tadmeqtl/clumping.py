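"""Greedy LD clumping of meQTL SNPs to index SNPs (PLINK-style).

SNPs are reduced to approximately independent index SNPs: repeatedly take
the unassigned SNP with the smallest association p-value <= p1 as an index,
then assign to it every unassigned SNP within ``window_kb`` kilobases with
p <= p2 and r^2 >= r2_min.  Per-SNP p-values are the minimum across a SNP's
probe/cancer-type associations.  Defaults follow the PLINK clumping
defaults used for meQTL data: p1=1e-4, p2=0.01, r^2=0.5, 250 kb.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .partition import unique_snps


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dosage vectors must be equal-length 1-D arrays")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero-variance dosage vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


class DosageLD:
    """r^2 source backed by a SNP x sample dosage matrix."""

    def __init__(self, dosages: pd.DataFrame):
        mat = dosages.to_numpy(dtype=float)
        sd = mat.std(axis=1)
        if np.any(sd == 0):
            bad = dosages.index[np.flatnonzero(sd == 0)[:5]].tolist()
            raise ValueError(f"zero-variance dosage vector(s): {bad}")
        self._z = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
        self._row = {snp: i for i, snp in enumerate(dosages.index)}
        self._n = mat.shape[1]

    def r2(self, snp: str, others: Sequence[str]) -> np.ndarray:
        zi = self._z[self._row[snp]]
        rows = [self._row[o] for o in others]
        r = self._z[rows] @ zi / self._n
        return r * r


def clump(meqtls: pd.DataFrame, ld: DosageLD | Callable,
          p1: float = 1e-4, p2: float = 0.01, r2_min: float = 0.5,
          window_kb: float = 250.0) -> pd.DataFrame:
    """Greedy LD clumping; returns a SNP-level table with clump assignments.

    Parameters
    ----------
    meqtls
        Canonical meQTL table (one row per association); collapsed to one
        row per SNP with the minimum p-value before clumping.
    ld
        Either a :class:`DosageLD` or any object with an
        ``r2(snp_id, [snp_ids]) -> array`` method.

    Returns
    -------
    DataFrame with columns ``snp_id, chrom, pos, pvalue, maf, is_index,
    clump_id`` where ``clump_id`` is the index SNP's id (empty string for
    SNPs never indexed nor assigned).  Ties on p-value are broken by
    position then id, which makes the output deterministic.
    """
    snps = unique_snps(meqtls)
    snps = snps.sort_values(["pvalue", "chrom", "pos", "snp_id"],
                            kind="stable").reset_index(drop=True)
    n = len(snps)
    window = int(round(window_kb * 1000))
    pos = snps["pos"].to_numpy()
    chrom = snps["chrom"].to_numpy(dtype=object)
    pval = snps["pvalue"].to_numpy()
    ids = snps["snp_id"].to_numpy(dtype=object)

    # per-chromosome position-sorted views for windowed candidate lookup
    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chrom):
        rows = np.flatnonzero(chrom == c)
        by_chrom[str(c)] = rows[np.argsort(pos[rows], kind="stable")]

    assigned = np.zeros(n, dtype=bool)
    clump_id = np.full(n, "", dtype=object)
    is_index = np.zeros(n, dtype=bool)
    for i in range(n):
        if assigned[i] or pval[i] > p1:
            continue
        assigned[i] = True
        is_index[i] = True
        clump_id[i] = ids[i]
        rows = by_chrom[str(chrom[i])]
        cpos = pos[rows]
        lo = np.searchsorted(cpos, pos[i] - window, side="left")
        hi = np.searchsorted(cpos, pos[i] + window, side="right")
        cand = rows[lo:hi]
        cand = cand[~assigned[cand] & (pval[cand] <= p2)]
        if len(cand):
            r2 = np.asarray(ld.r2(ids[i], list(ids[cand]))
                            if hasattr(ld, "r2") else ld(ids[i], list(ids[cand])))
            hit = cand[r2 >= r2_min]
            assigned[hit] = True
            clump_id[hit] = ids[i]
    out = snps.copy()
    out["is_index"] = is_index
    out["clump_id"] = clump_id
    return out


def index_snps(clumped: pd.DataFrame) -> pd.DataFrame:
    return clumped[clumped["is_index"]].reset_index(drop=True)
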