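"""Per-candidate mechanism calls.

Three routes from an accepted candidate SNP to a molecular mechanism:

* missense — high/low impact labels are inputs (from upstream predictors);
  at locus level a high-impact call takes precedence over low.
* direct splice-site hit — purely positional: the two intronic bases at
  each end of an intron, the first exonic base on the acceptor side and the
  last three exonic bases on the donor side, at internal junctions only,
  in transcription order (mirrored for minus-strand genes).
* auxiliary splicing — precomputed score changes near splice sites, flagged
  when the change meets the threshold of the signed-distance interval that
  contains it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .config import PipelineConfig
from .models import (GeneModel, Locus, MechanismCall, MissenseAnnotation,
                     SpliceScoreRecord)

__all__ = [
    "SpliceHit",
    "classify_missense_locus",
    "direct_splice_hit",
    "auxiliary_splice_flag",
    "assign_locus_mechanisms",
]

log = logging.getLogger(__name__)


def classify_missense_locus(impacts: Iterable[str]) -> str:
    """Collapse a locus's missense calls: 'high' dominates 'low'; high and
    low are mutually exclusive at locus level."""
    impacts = set(impacts)
    bad = impacts - {"high", "low"}
    if bad:
        raise ValueError(f"unknown missense impact labels: {sorted(bad)}")
    if "high" in impacts:
        return "high"
    if "low" in impacts:
        return "low"
    return "none"


@dataclass(frozen=True)
class SpliceHit:
    site_type: str   # donor / acceptor
    region: str      # intronic / exonic
    junction: int    # 0-based intron index in transcription order


def direct_splice_hit(pos: int, gene: GeneModel) -> Optional[SpliceHit]:
    """Does ``pos`` (0-based) fall on a direct splice-site base of ``gene``?

    Site definitions per internal junction, in transcription order: the
    first two intron bases (donor), the last two intron bases (acceptor),
    the first exon base (acceptor side), the last three exon bases (donor
    side).  Single-exon genes have no junctions.
    """
    exons = gene.exons
    n_introns = len(exons) - 1
    if n_introns == 0:
        return None
    plus = gene.strand == "+"
    for k in range(n_introns):
        left_end = exons[k][1]        # intron start, genomic
        right_start = exons[k + 1][0]  # intron end (exclusive of exon), genomic
        j = k if plus else n_introns - 1 - k
        if plus:
            donor_intron = (left_end, left_end + 1)
            acceptor_intron = (right_start - 2, right_start - 1)
            donor_exon = (left_end - 3, left_end - 2, left_end - 1)
            acceptor_exon = (right_start,)
        else:
            donor_intron = (right_start - 1, right_start - 2)
            acceptor_intron = (left_end + 1, left_end)
            donor_exon = (right_start, right_start + 1, right_start + 2)
            acceptor_exon = (left_end - 1,)
        if pos in donor_intron:
            return SpliceHit("donor", "intronic", j)
        if pos in acceptor_intron:
            return SpliceHit("acceptor", "intronic", j)
        if pos in donor_exon:
            return SpliceHit("donor", "exonic", j)
        if pos in acceptor_exon:
            return SpliceHit("acceptor", "exonic", j)
    return None


def auxiliary_splice_flag(record: SpliceScoreRecord,
                          config: PipelineConfig) -> bool:
    """Flag iff the score change meets (>=) the threshold of the interval
    containing the record's signed distance; a distance outside every
    configured interval is never flagged (callers count the warning via
    :func:`covering_interval` returning None)."""
    interval = covering_interval(record, config)
    if interval is None:
        return False
    return record.score_change >= interval.threshold


def covering_interval(record: SpliceScoreRecord, config: PipelineConfig):
    for iv in config.thresholds_for(record.site_type):
        if iv.covers(record.signed_distance):
            return iv
    return None


def assign_locus_mechanisms(locus: Locus, genes: Sequence[GeneModel],
                            missense: Sequence[MissenseAnnotation],
                            splice_records: Sequence[SpliceScoreRecord],
                            config: PipelineConfig) -> list[MechanismCall]:
    """Missense, direct-splice and auxiliary-splice calls for one locus.

    A SNP may yield several calls (e.g. both missense and auxiliary splice);
    calls are evidence, not a partition.  Expression calls are made
    separately from consensus eQTL matching (see :mod:`.expression`).
    """
    accepted = {c.id: c for c in locus.accepted}
    missense_by_snp: dict[str, list[MissenseAnnotation]] = {}
    for ann in missense:
        missense_by_snp.setdefault(ann.snp_id, []).append(ann)
    splice_by_snp: dict[str, list[SpliceScoreRecord]] = {}
    for rec in splice_records:
        splice_by_snp.setdefault(rec.snp_id, []).append(rec)
    genes_on_chrom = [g for g in genes if g.chrom == locus.marker.chrom]

    calls: list[MechanismCall] = []
    n_uncovered = 0
    for snp_id, cand in accepted.items():
        for ann in missense_by_snp.get(snp_id, []):
            calls.append(MechanismCall(
                locus_id=locus.locus_id, gene_id=ann.gene_id, snp_id=snp_id,
                mechanism=f"missense_{ann.impact}",
                evidence=f"input impact label {ann.impact}"))
        for gene in genes_on_chrom:
            hit = direct_splice_hit(cand.pos, gene)
            if hit is not None:
                calls.append(MechanismCall(
                    locus_id=locus.locus_id, gene_id=gene.gene_id,
                    snp_id=snp_id, mechanism="direct_splice",
                    evidence=f"{hit.region} {hit.site_type} base, "
                             f"intron {hit.junction}"))
        for rec in splice_by_snp.get(snp_id, []):
            iv = covering_interval(rec, config)
            if iv is None:
                n_uncovered += 1
                continue
            if rec.score_change >= iv.threshold:
                calls.append(MechanismCall(
                    locus_id=locus.locus_id, gene_id=rec.gene_id,
                    snp_id=snp_id, mechanism="aux_splice",
                    evidence=f"{rec.site_type} score change "
                             f"{rec.score_change:g} >= {iv.threshold:g} "
                             f"at {rec.signed_distance:+d} nt"))
    if n_uncovered:
        log.warning("locus %s: %d splice score records outside configured "
                    "intervals (not flagged)", locus.locus_id, n_uncovered)
    return calls
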