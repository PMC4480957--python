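"""Pipeline orchestration: the five stages, file-to-file and in-memory.

Stages: ``simulate`` writes a complete synthetic input bundle with ground
truth; ``select`` filters markers and accepts candidates per locus;
``assign`` makes mechanism calls; ``aggregate`` builds locus/protein
summaries and enrichment; ``report`` derives per-disease fraction tables.
Each stage writes its outputs plus a manifest (config + seed + record
counts) and is deterministic given both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io
from .aggregate import (enrichment_by_mechanism,
                        protein_records_with_mechanisms, summarize_loci)
from .candidates import build_loci
from .config import PipelineConfig
from .expression import assign_expression_mechanisms, build_consensus_eqtls
from .mechanisms import assign_locus_mechanisms
from .models import (Locus, LocusSummary, MarkerSNP, MechanismCall,
                     ProteinRecord)
from .simulate import ScenarioBundle, simulate_scenario

__all__ = ["PipelineResult", "run_pipeline", "stage_simulate", "stage_select",
           "stage_assign", "stage_aggregate", "stage_report"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    loci: list[Locus]
    calls: list[MechanismCall]
    summaries: list[LocusSummary]
    proteins: list[ProteinRecord]
    enrichment: pd.DataFrame
    consensus_eqtls: list = field(default_factory=list)


def run_pipeline(bundle: ScenarioBundle,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Select -> assign -> aggregate on an in-memory input bundle."""
    config = config or bundle.config
    loci = build_loci(bundle.markers, bundle.panel, config)

    calls: list[MechanismCall] = []
    for locus in loci:
        calls.extend(assign_locus_mechanisms(
            locus, bundle.genes, bundle.missense_annotations,
            bundle.splice_records, config))
    eqtl_records = [r for recs in bundle.eqtl_tables.values() for r in recs]
    consensus = build_consensus_eqtls(eqtl_records, bundle.panel, config)
    snp_locations = {s: (bundle.panel.chrom[s], bundle.panel.pos[s])
                     for s in bundle.panel.snp_ids}
    calls.extend(assign_expression_mechanisms(
        loci, consensus, bundle.genetic_map, snp_locations, config))
    calls.sort(key=lambda c: (c.locus_id, c.mechanism, c.gene_id, c.snp_id))

    relevance = {p.gene_id: p for p in bundle.protein_relevance}
    summaries = summarize_loci(loci, calls, relevance)
    proteins = protein_records_with_mechanisms(calls, relevance)
    enrichment = enrichment_by_mechanism(proteins)
    return PipelineResult(loci=loci, calls=calls, summaries=summaries,
                          proteins=proteins, enrichment=enrichment,
                          consensus_eqtls=consensus)


# ---------------------------------------------------------------------------
# file-based stages

def stage_simulate(config: PipelineConfig, outdir) -> ScenarioBundle:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_scenario(config)
    io.write_marker_table(bundle.markers, outdir / "markers.tsv")
    io.write_haplotype_panel_vcf(bundle.panel, outdir / "panel.vcf")
    io.write_gene_models_bed12(bundle.genes, outdir / "genes.bed")
    io.write_genetic_map(bundle.genetic_map, outdir / "genetic_map.tsv")
    for study in sorted(bundle.eqtl_tables):
        io.write_eqtl_table(bundle.eqtl_tables[study],
                            outdir / f"eqtl_{study}.tsv")
    io.write_missense_table(bundle.missense_annotations,
                            outdir / "missense.tsv")
    io.write_splice_score_table(bundle.splice_records,
                                outdir / "splice_scores.tsv")
    io.write_relevance_table(bundle.protein_relevance,
                             outdir / "relevance.tsv")
    bundle.ground_truth().to_csv(outdir / "ground_truth.tsv", sep="\t",
                                 index=False)
    bundle.eqtl_truth.to_csv(outdir / "eqtl_ground_truth.tsv", sep="\t",
                             index=False)
    io.write_manifest(config, outdir / "manifest.json",
                      markers=len(bundle.markers),
                      panel_snps=len(bundle.panel.snp_ids),
                      genes=len(bundle.genes))
    log.info("simulate: wrote %d loci to %s", len(bundle.markers), outdir)
    return bundle


def _load_bundle(config: PipelineConfig, indir) -> ScenarioBundle:
    indir = Path(indir)
    eqtl_paths = sorted(indir.glob("eqtl_s*.tsv"))
    records = io.read_eqtl_tables(eqtl_paths)
    tables: dict[str, list] = {}
    for rec in records:
        tables.setdefault(rec.study_id, []).append(rec)
    return ScenarioBundle(
        config=config,
        markers=io.read_marker_table(indir / "markers.tsv"),
        panel=io.read_haplotype_panel(indir / "panel.vcf"),
        genes=io.read_gene_models(indir / "genes.bed"),
        genetic_map=io.read_genetic_map(indir / "genetic_map.tsv"),
        eqtl_tables=tables,
        missense_annotations=io.read_missense_table(indir / "missense.tsv"),
        splice_records=io.read_splice_score_table(indir / "splice_scores.tsv"),
        protein_relevance=list(
            io.read_relevance_table(indir / "relevance.tsv").values()),
    )


def _loci_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus_id": lo.locus_id, "disease": lo.disease,
        "marker_id": lo.marker.id, "chrom": lo.marker.chrom,
        "marker_pos": lo.marker.pos + 1,
        "risk_allele": lo.marker.risk_allele,
        "other_allele": lo.marker.other_allele,
        "marker_or": repr(lo.marker.odds_ratio),
        "p_value": repr(lo.marker.p_value), "source": lo.marker.source,
        "extent_start": lo.extent[0] + 1, "extent_end": lo.extent[1] + 1,
        "is_mhc": lo.is_mhc, "n_candidates": len(lo.candidates),
        "n_accepted": len(lo.accepted),
    } for lo in loci])


def _candidates_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    rows = []
    for lo in loci:
        for c in lo.candidates:
            rows.append({
                "locus_id": lo.locus_id, "snp_id": c.id, "chrom": c.chrom,
                "pos": c.pos + 1, "maf": repr(c.maf), "r2": repr(c.r2),
                "implied_or": "" if c.implied_or is None else repr(c.implied_or),
                "accepted": c.accepted, "risk_allele": c.risk_allele,
            })
    return pd.DataFrame(rows)


def stage_select(config: PipelineConfig, indir, outdir) -> list[Locus]:
    outdir = Path(outdir)
    bundle = _load_bundle(config, indir)
    loci = build_loci(bundle.markers, bundle.panel, config)
    io.write_report({"loci": _loci_frame(loci),
                     "candidates": _candidates_frame(loci)}, outdir, config)
    return loci


def _reload_loci(config: PipelineConfig, indir, workdir) -> list[Locus]:
    # loci are a deterministic function of (inputs, config); re-derive rather
    # than round-tripping CandidateSNP haplotype frequencies through TSV
    bundle = _load_bundle(config, indir)
    return build_loci(bundle.markers, bundle.panel, config)


def stage_assign(config: PipelineConfig, indir, outdir) -> list[MechanismCall]:
    outdir = Path(outdir)
    bundle = _load_bundle(config, indir)
    result = run_pipeline(bundle, config)
    calls_df = pd.DataFrame([{
        "locus_id": c.locus_id, "gene_id": c.gene_id, "snp_id": c.snp_id,
        "mechanism": c.mechanism, "evidence": c.evidence,
    } for c in result.calls])
    io.write_report({"mechanism_calls": calls_df}, outdir, config)
    return result.calls


def stage_aggregate(config: PipelineConfig, indir, outdir) -> PipelineResult:
    outdir = Path(outdir)
    bundle = _load_bundle(config, indir)
    result = run_pipeline(bundle, config)
    summaries_df = pd.DataFrame([{
        "locus_id": s.locus_id, "disease": s.disease,
        "mechanisms": ",".join(sorted(s.mechanisms_present)),
        "n_mechanism_types": s.n_mechanism_types, "category": s.category,
    } for s in result.summaries])
    proteins_df = pd.DataFrame([{
        "gene_id": p.gene_id, "disease": p.disease, "relevance": p.relevance,
        "known": p.known, "is_mhc": p.is_mhc,
        "mechanisms": ",".join(sorted(p.mechanisms)),
    } for p in result.proteins])
    io.write_report({"locus_summaries": summaries_df,
                     "protein_mechanisms": proteins_df,
                     "enrichment": result.enrichment}, outdir, config)
    return result


def fraction_tables(summaries: Sequence[LocusSummary]) -> dict[str, pd.DataFrame]:
    """Per-disease fractions: loci with each mechanism, with at least one
    mechanism, and the distribution of mechanism counts per locus."""
    from .models import MECHANISMS
    rows_mech, rows_count = [], []
    diseases = sorted({s.disease for s in summaries})
    for disease in diseases + ["all"]:
        subset = [s for s in summaries
                  if disease == "all" or s.disease == disease]
        n = len(subset)
        if n == 0:
            continue
        row = {"disease": disease, "n_loci": n}
        for mech in MECHANISMS:
            row[mech] = sum(mech in s.mechanisms_present for s in subset) / n
        row["any_mechanism"] = sum(
            s.n_mechanism_types > 0 for s in subset) / n
        rows_mech.append(row)
        crow = {"disease": disease, "n_loci": n}
        for k in range(5):
            crow[f"n_mech_{k}"] = sum(
                s.n_mechanism_types == k for s in subset) / n
        rows_count.append(crow)
    return {"fractions_by_mechanism": pd.DataFrame(rows_mech),
            "fractions_by_count": pd.DataFrame(rows_count)}


def stage_report(config: PipelineConfig, indir, outdir,
                 plots: bool = False) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    bundle = _load_bundle(config, indir)
    result = run_pipeline(bundle, config)
    tables = fraction_tables(result.summaries)
    io.write_report(tables, outdir, config)
    if plots:
        _plot_fractions(tables, outdir)
    return tables


def _plot_fractions(tables: dict[str, pd.DataFrame], outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .models import MECHANISMS
    df = tables["fractions_by_mechanism"]
    fig, ax = plt.subplots(figsize=(8, 4))
    df.set_index("disease")[list(MECHANISMS)].plot.bar(ax=ax)
    ax.set_ylabel("fraction of loci")
    fig.tight_layout()
    fig.savefig(outdir / "fractions_by_mechanism.png", dpi=120)
    plt.close(fig)
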