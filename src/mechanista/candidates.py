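"""Marker intake and per-locus candidate SNP selection.

A SNP is a candidate for a locus if it lies within the window around the
representative marker, clears the minor-allele-frequency floor, and the
two-SNP LD relationship admits a finite implied odds ratio — i.e. there is
some case/control frequency shift at the SNP's own alleles that would
generate the marker's observed association.  The accepted candidates define
the locus extent.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .config import PipelineConfig
from .ld import (NoLDInformationError, haplotype_freqs_from_panel,
                 implied_candidate_or, ld_stats)
from .models import CandidateSNP, HaplotypePanel, Locus, MarkerSNP

__all__ = [
    "select_markers",
    "enumerate_candidates",
    "accept_candidate",
    "locus_extent",
    "build_loci",
]

log = logging.getLogger(__name__)


def select_markers(markers: Sequence[MarkerSNP],
                   config: PipelineConfig) -> list[MarkerSNP]:
    """Keep markers passing the source-specific strict p-value threshold."""
    thresholds = {"primary_scan": config.p_threshold_primary,
                  "catalog": config.p_threshold_catalog}
    kept = []
    for m in markers:
        if m.source not in thresholds:
            raise ValueError(f"{m.id}: unknown source {m.source!r}")
        if m.p_value < thresholds[m.source]:
            kept.append(m)
    log.info("select_markers: %d of %d markers pass", len(kept), len(markers))
    return kept


def enumerate_candidates(marker: MarkerSNP, panel: HaplotypePanel,
                         config: PipelineConfig) -> list[CandidateSNP]:
    """All panel SNPs within ``window_bp`` of the marker (inclusive) with
    MAF >= ``maf_min`` (inclusive), each with its joint haplotype
    frequencies to the marker.

    Candidate risk-allele orientation: the allele positively associated with
    the marker's risk allele (D >= 0) — the only orientation consistent with
    a shared risk mechanism.
    """
    if marker.id not in panel:
        raise KeyError(f"marker {marker.id!r} absent from panel")
    out = []
    for snp in panel.snp_ids:
        chrom = panel.chrom.get(snp)
        pos = panel.pos.get(snp)
        if chrom != marker.chrom or pos is None:
            continue
        if abs(pos - marker.pos) > config.window_bp:
            continue
        maf = panel.maf(snp)
        if maf < config.maf_min:
            continue
        hf = haplotype_freqs_from_panel(panel, snp, marker.id)
        risk_code = 1
        if hf.h_ab - hf.p_a * hf.p_b < 0:
            hf = hf.flipped_candidate()
            risk_code = 0
        allele = (panel.allele1 if risk_code == 1 else panel.allele0).get(snp, "")
        out.append(CandidateSNP(id=snp, chrom=chrom, pos=pos, maf=maf,
                                hf_to_marker=hf, risk_allele=allele))
    return out


def accept_candidate(candidate: CandidateSNP, marker: MarkerSNP,
                     config: PipelineConfig) -> CandidateSNP:
    """Set ``implied_or``/``accepted`` on a candidate.

    Accepted iff the implied odds ratio is feasible and r^2 to the marker is
    at least the configured floor (0 disables the floor).  A monomorphic or
    zero-D candidate is simply rejected.
    """
    hf = candidate.hf_to_marker
    if hf is None:
        raise ValueError(f"{candidate.id}: haplotype frequencies missing")
    try:
        stats = ld_stats(hf)
        result = implied_candidate_or(hf, marker.odds_ratio)
    except (NoLDInformationError, ValueError):
        candidate.accepted = False
        candidate.implied_or = None
        return candidate
    candidate.r2 = stats.r2
    if result.feasible and stats.r2 >= config.r2_floor:
        candidate.accepted = True
        candidate.implied_or = result.value
    else:
        candidate.accepted = False
        candidate.implied_or = result.value if result.feasible else None
    return candidate


def locus_extent(candidates: Sequence[CandidateSNP],
                 marker: MarkerSNP) -> tuple[int, int]:
    """[min, max] position over accepted candidates; a point interval at the
    marker when none are accepted."""
    accepted = [c.pos for c in candidates if c.accepted]
    if not accepted:
        return (marker.pos, marker.pos)
    return (min(accepted), max(accepted))


def _merge_markers(markers: Sequence[MarkerSNP],
                   window_bp: int) -> list[MarkerSNP]:
    """One representative marker per locus: markers within the window of a
    stronger (lower-p) marker on the same chromosome for the same disease
    are absorbed by it."""
    reps: list[MarkerSNP] = []
    for m in sorted(markers, key=lambda m: (m.p_value, m.id)):
        if any(r.disease == m.disease and r.chrom == m.chrom
               and abs(r.pos - m.pos) <= window_bp for r in reps):
            continue
        reps.append(m)
    return sorted(reps, key=lambda m: (m.disease, m.chrom, m.pos))


def _in_mhc(chrom: str, start: int, end: int,
            mhc: tuple[str, int, int]) -> bool:
    mchrom, mstart, mend = mhc
    return chrom == mchrom and start < mend and end > mstart


def build_loci(markers: Sequence[MarkerSNP], panel: HaplotypePanel,
               config: PipelineConfig) -> list[Locus]:
    """Full selection stage: filter markers, merge to representative
    markers, enumerate and accept candidates, set locus extents."""
    kept = select_markers(markers, config)
    reps = _merge_markers(kept, config.window_bp)
    loci = []
    for k, marker in enumerate(reps):
        cands = enumerate_candidates(marker, panel, config)
        cands = [accept_candidate(c, marker, config) for c in cands]
        extent = locus_extent(cands, marker)
        locus = Locus(locus_id=f"locus{k + 1:03d}", disease=marker.disease,
                      marker=marker, candidates=cands, extent=extent,
                      is_mhc=_in_mhc(marker.chrom, extent[0], extent[1] + 1,
                                     config.mhc_interval))
        loci.append(locus)
        log.info("locus %s (%s): %d candidates, %d accepted",
                 locus.locus_id, marker.id, len(cands), len(locus.accepted))
    return loci
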