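"""Consensus eQTLs and their matching to disease markers.

Single-study eQTL relations are treated as noise: a relation enters the
consensus set only when reported by at least two independent studies, with
identical marker SNPs or markers in strong LD (r^2 above the consensus
threshold).  A consensus eQTL and a disease marker are taken to represent
the same underlying expression mechanism when the marker is in the cluster
or within a small genetic distance (default 0.05 cM) of its nearest member.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

from .config import PipelineConfig
from .ld import MonomorphicError, haplotype_freqs_from_panel, ld_stats
from .models import (ConsensusEQTL, EQTLRecord, GeneticMap, HaplotypePanel,
                     MarkerSNP, MechanismCall)

__all__ = [
    "build_consensus_eqtls",
    "cm_position",
    "cm_distance",
    "match_disease_eqtl",
    "assign_expression_mechanisms",
]

log = logging.getLogger(__name__)


def _pair_linked(panel: HaplotypePanel, s1: str, s2: str,
                 r2_min: float) -> bool:
    if s1 == s2:
        return True
    if s1 not in panel or s2 not in panel:
        return False
    try:
        r2 = ld_stats(haplotype_freqs_from_panel(panel, s1, s2)).r2
    except MonomorphicError:
        return False
    return r2 > r2_min


def _cluster_markers(snps: list[str], panel: HaplotypePanel,
                     r2_min: float, linkage: str) -> list[set[str]]:
    """Cluster marker SNPs under {identical OR r^2 > r2_min}.

    ``single``: connected components of the pairwise-link graph.
    ``complete``: greedy merge (strongest pair first) requiring every cross
    pair to be linked; deterministic and order-invariant because pairs are
    processed in a canonical order.
    """
    snps = sorted(set(snps))
    linked = {frozenset(p) for p in combinations(snps, 2)
              if _pair_linked(panel, *sorted(p), r2_min=r2_min)}
    clusters = [{s} for s in snps]
    if linkage == "single":
        merged = True
        while merged:
            merged = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any(frozenset((a, b)) in linked
                           for a in clusters[i] for b in clusters[j]):
                        clusters[i] |= clusters.pop(j)
                        merged = True
                        break
                if merged:
                    break
    else:  # complete
        merged = True
        while merged:
            merged = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if all(frozenset((a, b)) in linked
                           for a in clusters[i] for b in clusters[j]):
                        clusters[i] |= clusters.pop(j)
                        merged = True
                        break
                if merged:
                    break
    return clusters


def build_consensus_eqtls(records: Sequence[EQTLRecord],
                          panel: HaplotypePanel,
                          config: PipelineConfig) -> list[ConsensusEQTL]:
    """Per gene, cluster reporting markers and keep clusters supported by at
    least two distinct studies.

    Markers not covered by the panel are non-linkable (warning counted) but
    can still reach consensus through identical ids.  Direction conflicts
    within a cluster are flagged, not discarded.
    """
    by_gene: dict[str, list[EQTLRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    n_uncovered = len({r.snp_id for r in records if r.snp_id not in panel})
    if n_uncovered:
        log.warning("%d eQTL marker SNPs not covered by panel "
                    "(treated as non-linkable)", n_uncovered)

    out = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        clusters = _cluster_markers([r.snp_id for r in recs], panel,
                                    config.eqtl_consensus_r2,
                                    config.consensus_linkage)
        for cluster in clusters:
            members = [r for r in recs if r.snp_id in cluster]
            studies = {r.study_id for r in members}
            if len(studies) < 2:
                continue
            dirs = {r.direction for r in members} - {"unknown"}
            out.append(ConsensusEQTL(
                gene_id=gene, marker_cluster=frozenset(cluster),
                n_studies=len(studies),
                direction_conflict=len(dirs) > 1))
    log.info("consensus eQTLs: %d from %d records", len(out), len(records))
    return out


def cm_position(pos: int, chrom: str, gmap: GeneticMap) -> float:
    """Genetic-map coordinate by piecewise-linear interpolation; positions
    beyond the outermost anchors are clamped (warning counted on the map)."""
    return gmap.cm_at(chrom, pos)


def cm_distance(pos1: int, pos2: int, chrom: str, gmap: GeneticMap,
                chrom2: str | None = None) -> float:
    """|cM(pos1) - cM(pos2)|; undefined (error) across chromosomes."""
    return gmap.cm_distance(chrom, pos1, chrom2 or chrom, pos2)


def match_disease_eqtl(marker: MarkerSNP, consensus: ConsensusEQTL,
                       gmap: GeneticMap,
                       snp_locations: Mapping[str, tuple[str, int]],
                       config: PipelineConfig) -> bool:
    """Same underlying expression mechanism?  True iff the disease marker is
    in the consensus cluster, or within ``eqtl_match_cm`` of the nearest
    cluster member on the same chromosome."""
    if marker.id in consensus.marker_cluster:
        return True
    for snp in sorted(consensus.marker_cluster):
        loc = snp_locations.get(snp)
        if loc is None:
            continue
        chrom, pos = loc
        if chrom != marker.chrom:
            continue
        if gmap.cm_distance(marker.chrom, marker.pos, chrom, pos) <= config.eqtl_match_cm:
            return True
    return False


def assign_expression_mechanisms(loci, consensus: Sequence[ConsensusEQTL],
                                 gmap: GeneticMap,
                                 snp_locations: Mapping[str, tuple[str, int]],
                                 config: PipelineConfig) -> list[MechanismCall]:
    """Expression calls: one per (locus, consensus eQTL) match."""
    calls = []
    for locus in loci:
        for ce in consensus:
            if match_disease_eqtl(locus.marker, ce, gmap, snp_locations, config):
                rep = (locus.marker.id if locus.marker.id in ce.marker_cluster
                       else sorted(ce.marker_cluster)[0])
                conflict = "; direction conflict" if ce.direction_conflict else ""
                calls.append(MechanismCall(
                    locus_id=locus.locus_id, gene_id=ce.gene_id,
                    snp_id=rep, mechanism="expression",
                    evidence=f"consensus eQTL in {ce.n_studies} studies"
                             f"{conflict}"))
    return calls
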