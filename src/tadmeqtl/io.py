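"""Readers and writers for the plain-text formats the pipeline touches.

Formats
-------
* BED3/BED4 for TADs, chromatin-state segmentations and promoters.  The
  optional 4th column carries a state number or a gene/TAD name.
* A header-bearing TSV for the meQTL table, emulating a pan-cancer meQTL
  database export.  Positions in that table are 1-based and converted to the
  internal 0-based half-open convention on read.
* TSV for gene roles and genotype dosage matrices.

All readers validate invariants and report offending line numbers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (GeneRole, GenomicInterval, MeQTLRecord, PromoterRecord,
                   TADRecord)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MEQTL_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "pvalue", "maf",
                 "probe_id", "probe_chrom", "probe_pos", "cancer_type"]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike, kind: str = "interval"):
    """Read a BED3/BED4 file.

    Parameters
    ----------
    path
        Tab-separated file with >=3 columns: chrom, start, end and an
        optional name/state column.
    kind
        ``"interval"`` -> list of :class:`GenomicInterval`;
        ``"tad"`` -> list of :class:`TADRecord` (cell line from col 4 when
        present, else the file stem);
        ``"promoter"`` -> list of :class:`PromoterRecord` (gene from col 4);
        ``"segment"`` -> list of ``(GenomicInterval, state:int)`` tuples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: expected >=3 tab-separated columns at line {lineno}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric coordinate at line {lineno}") from exc
            if start < 0:
                raise ValueError(
                    f"{path}: negative coordinate at line {lineno}")
            if start >= end:
                raise ValueError(f"{path}: start >= end at line {lineno}")
            iv = GenomicInterval(chrom, start, end)
            name = fields[3] if len(fields) > 3 else None
            if kind == "interval":
                out.append(iv)
            elif kind == "tad":
                out.append(TADRecord(iv, cell_line=name or path.stem))
            elif kind == "promoter":
                if name is None:
                    raise ValueError(
                        f"{path}: promoter BED needs a gene name column "
                        f"(line {lineno})")
                out.append(PromoterRecord(iv, gene=name))
            elif kind == "segment":
                if name is None:
                    raise ValueError(
                        f"{path}: segment BED needs a state column (line {lineno})")
                try:
                    state = int(str(name).lstrip("E"))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric state at line {lineno}") from exc
                if not 1 <= state <= 15:
                    raise ValueError(
                        f"{path}: state {state} outside 1..15 at line {lineno}")
                out.append((iv, state))
            else:
                raise ValueError(f"unknown kind {kind!r}")
    return out


def write_bed(path: PathLike, records: Iterable, name_of=None) -> None:
    """Write intervals / TADs / promoters / (interval, state) pairs as BED."""
    with open(path, "w") as fh:
        for rec in records:
            name = None
            if isinstance(rec, tuple):           # (interval, state)
                iv, name = rec
            elif isinstance(rec, TADRecord):
                iv, name = rec.interval, rec.cell_line
            elif isinstance(rec, PromoterRecord):
                iv, name = rec.interval, rec.gene
            else:
                iv = rec
            if name_of is not None:
                name = name_of(rec)
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if name is not None:
                cols.append(str(name))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# meQTL table
# ---------------------------------------------------------------------------

def read_meqtl_table(path: PathLike) -> pd.DataFrame:
    """Read a meQTL TSV into the canonical in-memory table.

    The file is tab-separated with a header naming at least the columns in
    :data:`MEQTL_COLUMNS`.  ``pos`` and ``probe_pos`` are 1-based in the file
    and converted to 0-based here.  Rows duplicated on the uniqueness key
    (snp_id, probe_id, cancer_type) are dropped (count logged).

    Returns a DataFrame with columns ``snp_id, chrom, pos, ref, alt, pvalue,
    maf, probe_id, probe_chrom, probe_pos, cancer_type`` where positions are
    0-based single-bp coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_chrom": str})
    missing = [c for c in MEQTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df[MEQTL_COLUMNS].copy()
    # 1-based file positions -> 0-based internal positions
    df["pos"] = df["pos"].astype(np.int64) - 1
    df["probe_pos"] = df["probe_pos"].astype(np.int64) - 1
    _validate_meqtl_frame(df, str(path))
    n0 = len(df)
    df = df.drop_duplicates(subset=["snp_id", "probe_id", "cancer_type"],
                            keep="first").reset_index(drop=True)
    if len(df) < n0:
        logger.info("%s: dropped %d duplicate meQTL row(s)", path, n0 - len(df))
    return df


def _validate_meqtl_frame(df: pd.DataFrame, origin: str) -> None:
    bad = df.index[(df["maf"] <= 0) | (df["maf"] > 0.5)]
    if len(bad):
        raise ValueError(
            f"{origin}: MAF outside (0, 0.5] at row(s) {list(bad[:5])}")
    bad = df.index[(df["pvalue"] <= 0) | (df["pvalue"] > 1)]
    if len(bad):
        raise ValueError(
            f"{origin}: p-value outside (0, 1] at row(s) {list(bad[:5])}")
    bad = df.index[df["pos"] < 0]
    if len(bad):
        raise ValueError(f"{origin}: non-positive SNP position at row(s) "
                         f"{list(bad[:5])}")
    cis_bad = df.index[df["chrom"] != df["probe_chrom"]]
    if len(cis_bad):
        raise ValueError(
            f"{origin}: SNP and probe on different chromosomes at row(s) "
            f"{list(cis_bad[:5])} (cis records required)")


def write_meqtl_table(path: PathLike, df: pd.DataFrame) -> None:
    """Write the canonical meQTL table back to TSV (1-based positions)."""
    out = df[MEQTL_COLUMNS].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out["probe_pos"] = out["probe_pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def meqtl_records(df: pd.DataFrame) -> list[MeQTLRecord]:
    """Materialise table rows as :class:`MeQTLRecord` objects (validating)."""
    recs = []
    for row in df.itertuples(index=False):
        recs.append(MeQTLRecord(
            snp_id=row.snp_id,
            snp_pos=GenomicInterval(row.chrom, int(row.pos), int(row.pos) + 1),
            ref=row.ref, alt=row.alt,
            pvalue=float(row.pvalue), maf=float(row.maf),
            probe_id=row.probe_id,
            probe_pos=GenomicInterval(row.probe_chrom, int(row.probe_pos),
                                      int(row.probe_pos) + 1),
            cancer_type=row.cancer_type))
    return recs


# ---------------------------------------------------------------------------
# gene roles, chrom sizes, dosages
# ---------------------------------------------------------------------------

def read_gene_roles(path: PathLike) -> dict[str, str]:
    """Read a two-column (gene, role) TSV; conflicting duplicates rejected."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "role"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'gene' and 'role'")
    roles: dict[str, str] = {}
    for gene, role in zip(df["gene"], df["role"]):
        GeneRole(gene, role)  # validates role value
        if gene in roles and roles[gene] != role:
            raise ValueError(f"{path}: conflicting roles for gene {gene!r}")
        roles[gene] = role
    return roles


def write_gene_roles(path: PathLike, roles: dict[str, str]) -> None:
    pd.DataFrame({"gene": list(roles), "role": [roles[g] for g in roles]}
                 ).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(path: PathLike, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_dosages(path: PathLike) -> pd.DataFrame:
    """Dosage matrix TSV: first column ``snp_id``, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "snp_id":
        raise ValueError(f"{path}: first column must be 'snp_id'")
    return df.set_index("snp_id")


def write_dosages(path: PathLike, dosages: pd.DataFrame) -> None:
    dosages.to_csv(path, sep="\t", index=True, index_label="snp_id",
                   float_format="%.6g")
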