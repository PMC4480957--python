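"""Pipeline configuration.

All numeric cutoffs used by the pipeline live here so that a run is fully
described by one config object plus one RNG seed.  Defaults reflect the
standard analysis settings: a +/-200 kb candidate window around each marker,
a 5% minor-allele-frequency floor, association p-value thresholds of
5.0e-7 for primary-scan markers and 1e-5 for catalog markers, eQTL/marker
matching within 0.05 centiMorgans, and an r^2 > 0.8 consensus-linkage rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = ["SpliceThreshold", "PipelineConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class SpliceThreshold:
    """Score-change threshold for one signed-distance interval around a splice site.

    ``lo``/``hi`` are inclusive signed distances in nucleotides from the
    splice site (negative = exonic side); ``threshold`` is the minimum score
    change that flags a variant as an auxiliary-splicing candidate.
    """

    lo: int
    hi: int
    threshold: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"interval lo {self.lo} > hi {self.hi}")

    def covers(self, signed_distance: int) -> bool:
        return self.lo <= signed_distance <= self.hi


# Placeholder defaults: a single full-range interval with threshold 0.0.
# Real analyses must supply calibrated per-interval thresholds (three around
# donors, four around acceptors is the usual layout).
_DEFAULT_DONOR = (SpliceThreshold(-80, 80, 0.0),)
_DEFAULT_ACCEPTOR = (SpliceThreshold(-80, 80, 0.0),)

# Conventional extended-MHC bounds on chromosome 6 (hg19); config-overridable.
_DEFAULT_MHC = ("6", 28_477_796, 33_448_354)


@dataclass
class PipelineConfig:
    """Every tunable cutoff of the mechanism-assignment pipeline.

    Attributes
    ----------
    window_bp
        Maximum distance (bp) from the representative marker for a SNP to be
        considered a candidate; boundary inclusive.
    maf_min
        Minor-allele-frequency floor for candidates (LD estimates below 5%
        are unreliable); boundary inclusive.
    p_threshold_primary, p_threshold_catalog
        Strict upper bounds on association p-values for marker intake, by
        marker source.
    eqtl_match_cm
        Maximum genetic distance (cM) for a disease marker and a consensus
        eQTL marker to represent the same underlying expression mechanism.
    eqtl_consensus_r2
        Strict lower bound on r^2 for two eQTL markers to be linked into one
        consensus cluster (identical ids always link).
    r2_floor
        Minimum r^2 between candidate and marker for acceptance; 0 disables
        the floor and reproduces the bare feasibility rule.
    splice_donor_thresholds, splice_acceptor_thresholds
        Interval-specific auxiliary-splicing score-change thresholds.
    mhc_interval
        (chrom, start, end), 0-based half-open; loci/genes inside are
        reported separately as category D.
    prevalence
        Disease prevalence used by the cohort simulator only (retrospective
        sampling; controls approximate the population under rarity).
    or_scale
        Declared scale of marker odds ratios; only "allelic" is interpreted,
        genotypic ORs are never converted.
    """

    window_bp: int = 200_000
    maf_min: float = 0.05
    p_threshold_primary: float = 5.0e-7
    p_threshold_catalog: float = 1.0e-5
    eqtl_match_cm: float = 0.05
    eqtl_consensus_r2: float = 0.8
    r2_floor: float = 0.2
    consensus_linkage: str = "single"  # or "complete"
    splice_donor_thresholds: Sequence[SpliceThreshold] = _DEFAULT_DONOR
    splice_acceptor_thresholds: Sequence[SpliceThreshold] = _DEFAULT_ACCEPTOR
    mhc_interval: tuple[str, int, int] = _DEFAULT_MHC
    prevalence: float = 0.01
    or_scale: str = "allelic"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_bp", "maf_min", "p_threshold_primary",
                     "p_threshold_catalog", "eqtl_match_cm",
                     "eqtl_consensus_r2", "prevalence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.r2_floor < 0:
            raise ValueError("r2_floor must be >= 0")
        if self.consensus_linkage not in ("single", "complete"):
            raise ValueError("consensus_linkage must be 'single' or 'complete'")
        if self.or_scale not in ("allelic", "genotypic"):
            raise ValueError("or_scale must be 'allelic' or 'genotypic'")
        for side in ("splice_donor_thresholds", "splice_acceptor_thresholds"):
            ivs = sorted(getattr(self, side), key=lambda t: t.lo)
            for a, b in zip(ivs, ivs[1:]):
                if b.lo <= a.hi:
                    raise ValueError(f"{side}: overlapping intervals")
            setattr(self, side, tuple(ivs))

    def thresholds_for(self, site_type: str) -> Sequence[SpliceThreshold]:
        if site_type == "donor":
            return self.splice_donor_thresholds
        if site_type == "acceptor":
            return self.splice_acceptor_thresholds
        raise ValueError(f"unknown site_type {site_type!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mhc_interval"] = list(self.mhc_interval)
        for side in ("splice_donor_thresholds", "splice_acceptor_thresholds"):
            d[side] = [[t.lo, t.hi, t.threshold] for t in getattr(self, side)]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "mhc_interval" in d:
            c, s, e = d["mhc_interval"]
            d["mhc_interval"] = (str(c), int(s), int(e))
        for side in ("splice_donor_thresholds", "splice_acceptor_thresholds"):
            if side in d:
                d[side] = tuple(
                    SpliceThreshold(int(lo), int(hi), float(t))
                    for lo, hi, t in d[side]
                )
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Read a YAML config file; absent keys take their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
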