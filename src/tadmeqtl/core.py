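"""Core domain types and coordinate conventions.

All genomic coordinates in this package are 0-based, half-open
(``[start, end)``), the BED convention.  Inputs that use 1-based positions
(meQTL SNP/probe coordinates) are converted on read by the IO layer, so no
other module ever has to think about the offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# chromHMM 15-state model (Roadmap Epigenomics core model)
# ---------------------------------------------------------------------------

CHROMHMM_STATES: tuple[str, ...] = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh",
    "ZNF/Rpts", "Het", "TssBiv", "BivFlnk", "EnhBiv",
    "ReprPC", "ReprPCWk", "Quies",
)
N_STATES = 15

# 0-based indices of states counted as transcriptionally active / inactive
# when labelling clusters.  Active: TssA..Enh (states 1-7).  Inactive:
# Het, ReprPC, ReprPCWk, Quies (states 9, 13, 14, 15).
ACTIVE_STATE_IDX: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
INACTIVE_STATE_IDX: tuple[int, ...] = (8, 12, 13, 14)

CATEGORY3 = ("Active", "Inactive", "Mixed")

# Region labels used by the genome partition.
LABEL_ACTIVE = "ActiveTAD"
LABEL_INACTIVE = "InactiveTAD"
LABEL_MIXED = "MixedTAD"
LABEL_BOUNDARY = "Boundary"
LABEL_OTHER = "Other"
REGION_LABELS = (LABEL_ACTIVE, LABEL_INACTIVE, LABEL_MIXED,
                 LABEL_BOUNDARY, LABEL_OTHER)

TRANSITIONS = ("AA", "AI", "IA", "II")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start >= end ({self.start} >= {self.end}) on {self.chrom}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 on different chromosomes.

    Half-open convention: adjacent intervals overlap by 0.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class StateComposition:
    """Fraction of annotated bp in each of the 15 chromHMM states."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} state fractions, got {f.shape}")
        if np.any(f < 0):
            raise ValueError("state fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {f.sum()}, expected 1")
        object.__setattr__(self, "fractions", f)

    def active_mass(self) -> float:
        return float(self.fractions[list(ACTIVE_STATE_IDX)].sum())

    def inactive_mass(self) -> float:
        return float(self.fractions[list(INACTIVE_STATE_IDX)].sum())


def collapse_category(category5: str) -> str:
    """Deterministic collapse of a 5-way activity label to 3 ways.

    ``Active-1``/``Active-2`` (or any ``Active-k``) -> ``Active``; likewise
    for ``Inactive``; ``Mixed`` stays ``Mixed``.
    """
    base = category5.split("-")[0]
    if base not in CATEGORY3:
        raise ValueError(f"unrecognised category5: {category5!r}")
    return base


@dataclass
class TADRecord:
    """A topologically associating domain, per cell line or consensus."""

    interval: GenomicInterval
    cell_line: str = "consensus"
    composition: Optional[StateComposition] = None
    category5: Optional[str] = None
    category3: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category5 is not None:
            expected = collapse_category(self.category5)
            if self.category3 is None:
                self.category3 = expected
            elif self.category3 != expected:
                raise ValueError(
                    f"category3 {self.category3!r} is not the collapse of "
                    f"category5 {self.category5!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class PromoterRecord:
    interval: GenomicInterval
    gene: str


@dataclass(frozen=True)
class GeneRole:
    """Cancer driver gene with its role (oncogene or tumor suppressor)."""

    gene: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("oncogene", "TSG"):
            raise ValueError(f"role must be 'oncogene' or 'TSG', got {self.role!r}")


@dataclass(frozen=True)
class MeQTLRecord:
    """A cis SNP-CpG association from a pan-cancer meQTL catalogue."""

    snp_id: str
    snp_pos: GenomicInterval
    ref: str
    alt: str
    pvalue: float
    maf: float
    probe_id: str
    probe_pos: GenomicInterval
    cancer_type: str
    is_clumped_index: bool = False
    driver_gene: Optional[str] = None
    driver_role: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside (0, 1]")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"MAF {self.maf} outside (0, 0.5]")
        if self.snp_pos.chrom != self.probe_pos.chrom:
            raise ValueError(
                f"cis record with SNP on {self.snp_pos.chrom} but probe on "
                f"{self.probe_pos.chrom}")
        if self.driver_role not in ("oncogene", "TSG", "none"):
            raise ValueError(f"bad driver role {self.driver_role!r}")


def validate_tad_set(tads: Sequence[TADRecord]) -> None:
    """Check that a per-cell-line TAD set is valid.

    Within each chromosome TADs must be sorted by start and non-overlapping
    (half-open adjacency is allowed).
    """
    if len(tads) == 0:
        raise ValueError("empty TAD set")
    by_chrom: dict[str, list[TADRecord]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        for prev, cur in zip(ts, ts[1:]):
            if cur.start < prev.start:
                raise ValueError(f"TADs not sorted on {chrom} at {cur.start}")
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping TADs on {chrom}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})")


def sort_tads(tads: Sequence[TADRecord]) -> list[TADRecord]:
    return sorted(tads, key=lambda t: (t.chrom, t.start, t.end))
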