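"""Domain types shared across the pipeline.

Coordinate convention: all in-memory positions are 0-based; exon intervals
are half-open [start, end).  File readers/writers are the only place the
shift to 1-based file conventions happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "MarkerSNP",
    "GeneModel",
    "GeneticMap",
    "HaplotypePanel",
    "EQTLRecord",
    "ConsensusEQTL",
    "MissenseAnnotation",
    "SpliceScoreRecord",
    "MechanismCall",
    "CandidateSNP",
    "Locus",
    "LocusSummary",
    "ProteinRecord",
    "MECHANISMS",
]

MECHANISMS = ("missense_high", "missense_low", "expression", "aux_splice",
              "direct_splice")

MARKER_SOURCES = ("primary_scan", "catalog")


@dataclass(frozen=True)
class MarkerSNP:
    """A GWAS association marker: the genotyped SNP reported for a locus."""

    id: str
    chrom: str
    pos: int  # 0-based
    risk_allele: str
    other_allele: str
    odds_ratio: float
    p_value: float
    source: str
    disease: str

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.id}: odds_ratio must be > 0")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.id}: p_value must be in (0, 1]")
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.id}: risk_allele equals other_allele")
        if self.source not in MARKER_SOURCES:
            raise ValueError(f"{self.id}: unknown source {self.source!r}")


@dataclass(frozen=True)
class GeneModel:
    """One transcript per gene; exons sorted by genomic coordinate."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, genomic order
    is_mhc: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty or inverted exon ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping/unsorted exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class GeneticMap:
    """Piecewise-linear bp -> cM map, per chromosome.

    Positions outside the anchor range are clamped to the end anchors'
    cM values; ``n_clamped`` counts such lookups.
    """

    def __init__(self, anchors: Mapping[str, Sequence[tuple[int, float]]]):
        self._pos: dict[str, np.ndarray] = {}
        self._cm: dict[str, np.ndarray] = {}
        self.n_clamped = 0
        for chrom, pts in anchors.items():
            pts = sorted((int(p), float(c)) for p, c in pts)
            if len(pts) < 2:
                raise ValueError(f"{chrom}: need >= 2 anchor points")
            pos = np.array([p for p, _ in pts], dtype=np.int64)
            cm = np.array([c for _, c in pts], dtype=float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: cM must be non-decreasing in pos")
            self._pos[chrom] = pos
            self._cm[chrom] = cm

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._pos)

    def anchors(self, chrom: str) -> list[tuple[int, float]]:
        return list(zip(self._pos[chrom].tolist(), self._cm[chrom].tolist()))

    def cm_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._pos:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        p, c = self._pos[chrom], self._cm[chrom]
        if pos < p[0] or pos > p[-1]:
            self.n_clamped += 1
        return float(np.interp(pos, p, c))

    def cm_distance(self, chrom1: str, pos1: int, chrom2: str, pos2: int) -> float:
        if chrom1 != chrom2:
            raise ValueError("genetic distance undefined across chromosomes")
        return abs(self.cm_at(chrom1, pos1) - self.cm_at(chrom2, pos2))


@dataclass
class HaplotypePanel:
    """Phased haplotypes: matrix of 0/1 alleles, one row per haplotype.

    ``allele0``/``allele1`` record which base each code means per SNP;
    positions are optional (TSV panels without a sites file).
    """

    snp_ids: list[str]
    matrix: np.ndarray  # shape (n_hap, n_snp), dtype uint8
    chrom: dict[str, str] = field(default_factory=dict)
    pos: dict[str, int] = field(default_factory=dict)  # 0-based
    allele0: dict[str, str] = field(default_factory=dict)
    allele1: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.snp_ids):
            raise ValueError("matrix shape inconsistent with snp_ids")
        if not np.all((self.matrix == 0) | (self.matrix == 1)):
            raise ValueError("haplotype entries must be 0/1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in panel")

    @property
    def n_hap(self) -> int:
        return self.matrix.shape[0]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column(self, snp_id: str) -> np.ndarray:
        if snp_id not in self._index:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return self.matrix[:, self._index[snp_id]]

    def frequency(self, snp_id: str) -> float:
        """Frequency of the '1'-coded allele."""
        return float(self.column(snp_id).mean())

    def maf(self, snp_id: str) -> float:
        f = self.frequency(snp_id)
        return min(f, 1.0 - f)


@dataclass(frozen=True)
class EQTLRecord:
    snp_id: str
    gene_id: str
    study_id: str
    direction: str = "unknown"  # up / down / unknown

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "unknown"):
            raise ValueError(f"bad eQTL direction {self.direction!r}")


@dataclass(frozen=True)
class ConsensusEQTL:
    """An eQTL relation replicated in >= 2 independent studies whose markers
    are identical or strongly linked."""

    gene_id: str
    marker_cluster: frozenset[str]
    n_studies: int
    direction_conflict: bool = False

    def __post_init__(self) -> None:
        if self.n_studies < 2:
            raise ValueError("consensus requires >= 2 studies")


@dataclass(frozen=True)
class MissenseAnnotation:
    snp_id: str
    gene_id: str
    impact: str  # high / low

    def __post_init__(self) -> None:
        if self.impact not in ("high", "low"):
            raise ValueError(f"{self.snp_id}: impact must be 'high' or 'low'")


@dataclass(frozen=True)
class SpliceScoreRecord:
    """Precomputed splice-scorer score change for an AG/GT dinucleotide near
    a known splice site (|signed_distance| <= 80 nt; negative = exonic side)."""

    snp_id: str
    gene_id: str
    site_type: str  # donor / acceptor
    signed_distance: int
    score_change: float

    def __post_init__(self) -> None:
        if self.site_type not in ("donor", "acceptor"):
            raise ValueError(f"{self.snp_id}: bad site_type {self.site_type!r}")
        if abs(self.signed_distance) > 80:
            raise ValueError(f"{self.snp_id}: |signed_distance| > 80")


@dataclass(frozen=True)
class MechanismCall:
    locus_id: str
    gene_id: str
    snp_id: str
    mechanism: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


@dataclass
class CandidateSNP:
    """A panel SNP near a marker, with the odds ratio it would need at its
    own alleles to generate the marker's observed association."""

    id: str
    chrom: str
    pos: int
    maf: float
    hf_to_marker: "object" = None  # ld.HaplotypeFreqs
    implied_or: Optional[float] = None  # None = infeasible / no LD information
    r2: float = 0.0
    accepted: bool = False
    annotations: set = field(default_factory=set)
    risk_allele: str = ""


@dataclass
class Locus:
    locus_id: str
    disease: str
    marker: MarkerSNP
    candidates: list[CandidateSNP] = field(default_factory=list)
    extent: tuple[int, int] = (0, 0)
    is_mhc: bool = False

    @property
    def accepted(self) -> list[CandidateSNP]:
        return [c for c in self.candidates if c.accepted]


@dataclass
class LocusSummary:
    locus_id: str
    disease: str
    mechanisms_present: frozenset[str]
    n_mechanism_types: int
    category: str = "none"  # A / B / C / D / none

    def __post_init__(self) -> None:
        if {"missense_high", "missense_low"} <= set(self.mechanisms_present):
            raise ValueError("high and low impact missense are mutually "
                             "exclusive at locus level")
        if not (0 <= self.n_mechanism_types <= 4):
            raise ValueError("n_mechanism_types must be 0..4")


@dataclass
class ProteinRecord:
    gene_id: str
    disease: str
    relevance: str  # A / B / C / D
    known: bool
    mechanisms: set = field(default_factory=set)
    is_mhc: bool = False

    def __post_init__(self) -> None:
        if self.relevance not in ("A", "B", "C", "D"):
            raise ValueError(f"{self.gene_id}: bad relevance {self.relevance!r}")
        if (self.relevance == "D") != self.is_mhc:
            raise ValueError(f"{self.gene_id}: category D iff MHC-region gene")
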