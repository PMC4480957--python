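"""Readers and writers for the pipeline's file formats.

Formats: markers/eQTL/annotation/relevance tables as TSV with documented
headers; phased haplotype panels as VCF (``GT`` must be phased) or a 0/1
haplotype-matrix TSV with an optional sites table; gene models as BED12 or
a restricted GFF3 (exon features, one transcript per gene); genetic maps as
three-column TSV (chrom, bp, cM) or PLINK MAP.

Coordinates are converted at this boundary only: VCF/GFF3/MAP/TSV positions
are 1-based in files, BED12 is 0-based half-open; everything in memory is
0-based half-open.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .config import PipelineConfig
from .models import (EQTLRecord, GeneModel, GeneticMap, HaplotypePanel,
                     MarkerSNP, MissenseAnnotation, ProteinRecord,
                     SpliceScoreRecord)

__all__ = [
    "read_marker_table", "write_marker_table",
    "read_haplotype_panel", "write_haplotype_panel_vcf",
    "write_haplotype_panel_tsv",
    "read_gene_models", "write_gene_models_bed12",
    "read_genetic_map", "write_genetic_map",
    "read_eqtl_tables", "write_eqtl_table",
    "read_missense_table", "write_missense_table",
    "read_splice_score_table", "write_splice_score_table",
    "read_relevance_table", "write_relevance_table",
    "write_report", "write_manifest",
]

log = logging.getLogger(__name__)

MARKER_COLUMNS = ["id", "chrom", "pos", "risk_allele", "other_allele",
                  "odds_ratio", "p_value", "source", "disease"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# marker tables

def read_marker_table(path) -> list[MarkerSNP]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, MARKER_COLUMNS, path)
    seen = set()
    out = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            marker = MarkerSNP(
                id=str(row["id"]), chrom=str(row["chrom"]),
                pos=int(row["pos"]) - 1,
                risk_allele=str(row["risk_allele"]),
                other_allele=str(row["other_allele"]),
                odds_ratio=float(row["odds_ratio"]),
                p_value=float(row["p_value"]),
                source=str(row["source"]), disease=str(row["disease"]))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
        if marker.id in seen:
            raise ValueError(f"{path}, line {line}: duplicate marker id "
                             f"{marker.id!r}")
        seen.add(marker.id)
        out.append(marker)
    log.info("read %d markers from %s", len(out), path)
    return out


def write_marker_table(markers: Sequence[MarkerSNP], path) -> None:
    df = pd.DataFrame([{
        "id": m.id, "chrom": m.chrom, "pos": m.pos + 1,
        "risk_allele": m.risk_allele, "other_allele": m.other_allele,
        "odds_ratio": repr(m.odds_ratio), "p_value": repr(m.p_value),
        "source": m.source, "disease": m.disease,
    } for m in markers], columns=MARKER_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# haplotype panels

def read_haplotype_panel(path, sites_path=None) -> HaplotypePanel:
    """Read a phased panel from VCF (``*.vcf``) or haplotype-matrix TSV.

    VCF: every genotype must be phased and diploid; each sample contributes
    two haplotypes.  TSV: rows are haplotypes, columns are SNPs, entries
    0/1; an optional sites table (columns snp_id, chrom, pos, allele0,
    allele1; pos 1-based) supplies coordinates.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_panel_vcf(path)
    return _read_panel_tsv(path, sites_path)


def _read_panel_vcf(path) -> HaplotypePanel:
    snp_ids, cols = [], []
    chrom, pos, a0, a1 = {}, {}, {}, {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            sid = rec.id or f"{rec.chrom}:{rec.pos}"
            alleles = []
            for sample in samples:
                call = rec.samples[sample]
                gt = call["GT"]
                if len(gt) != 2 or any(g is None for g in gt):
                    raise ValueError(f"{path}: {sid}: non-diploid or missing "
                                     f"genotype in sample {sample}")
                if not call.phased:
                    raise ValueError(f"{path}: {sid}: unphased genotype in "
                                     f"sample {sample}")
                alleles.extend(gt)
            snp_ids.append(sid)
            cols.append(np.array(alleles, dtype=np.uint8))
            chrom[sid] = str(rec.chrom)
            pos[sid] = rec.pos - 1  # pysam .pos is 1-based
            a0[sid] = rec.ref
            a1[sid] = rec.alts[0] if rec.alts else ""
    panel = HaplotypePanel(snp_ids=snp_ids, matrix=np.column_stack(cols),
                           chrom=chrom, pos=pos, allele0=a0, allele1=a1)
    log.info("read panel %s: %d haplotypes x %d SNPs", path,
             panel.n_hap, len(snp_ids))
    return panel


def _read_panel_tsv(path, sites_path) -> HaplotypePanel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}, line {lineno}: ragged row "
                                 f"({len(fields)} fields, expected {len(header)})")
            rows.append([int(v) for v in fields])
    panel = HaplotypePanel(snp_ids=header,
                           matrix=np.array(rows, dtype=np.uint8))
    if sites_path is not None:
        sites = pd.read_csv(sites_path, sep="\t", dtype=str)
        _require_columns(sites, ["snp_id", "chrom", "pos", "allele0",
                                 "allele1"], sites_path)
        for _, row in sites.iterrows():
            sid = row["snp_id"]
            panel.chrom[sid] = str(row["chrom"])
            panel.pos[sid] = int(row["pos"]) - 1
            panel.allele0[sid] = str(row["allele0"])
            panel.allele1[sid] = str(row["allele1"])
    return panel


def write_haplotype_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Write a phased VCF; requires an even number of haplotypes and per-SNP
    chrom/pos/allele metadata."""
    if panel.n_hap % 2:
        raise ValueError("VCF output needs an even number of haplotypes")
    n_samples = panel.n_hap // 2
    contigs = sorted({panel.chrom[s] for s in panel.snp_ids},
                     key=lambda c: (len(c), c))
    order = sorted(panel.snp_ids,
                   key=lambda s: ((len(panel.chrom[s]), panel.chrom[s]),
                                  panel.pos[s]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = [f"H{i}" for i in range(n_samples)]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for sid in order:
            col = panel.column(sid)
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}"
                            for i in range(n_samples))
            fh.write(f"{panel.chrom[sid]}\t{panel.pos[sid] + 1}\t{sid}\t"
                     f"{panel.allele0.get(sid, 'A')}\t"
                     f"{panel.allele1.get(sid, 'G')}\t.\t.\t.\tGT\t{gts}\n")


def write_haplotype_panel_tsv(panel: HaplotypePanel, path,
                              sites_path=None) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(panel.snp_ids) + "\n")
        for row in panel.matrix:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")
    if sites_path is not None:
        pd.DataFrame([{
            "snp_id": s, "chrom": panel.chrom.get(s, ""),
            "pos": panel.pos.get(s, -1) + 1,
            "allele0": panel.allele0.get(s, ""),
            "allele1": panel.allele1.get(s, ""),
        } for s in panel.snp_ids]).to_csv(sites_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models

def read_gene_models(path) -> list[GeneModel]:
    """BED12 (``*.bed``) or restricted GFF3 (exon features, one transcript
    per gene, gene identity from the Parent/gene_id attribute)."""
    path = Path(path)
    if path.suffix in (".gff", ".gff3"):
        return _read_gene_models_gff3(path)
    return _read_gene_models_bed12(path)


def _read_gene_models_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}, line {lineno}: BED12 needs 12 "
                                 f"columns, got {len(f)}")
            try:
                chrom, start = f[0], int(f[1])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(v) for v in f[10].rstrip(",").split(",")]
                starts = [int(v) for v in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}, line {lineno}: blockCount "
                                 f"mismatch")
            exons = tuple((start + s, start + s + z)
                          for s, z in zip(starts, sizes))
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand,
                                   exons=exons))
    log.info("read %d gene models from %s", len(genes), path)
    return genes


def _read_gene_models_gff3(path) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}, line {lineno}: GFF3 needs 9 columns")
            if f[2].lower() != "exon":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene = attrs.get("gene_id") or attrs.get("Parent")
            if gene is None:
                raise ValueError(f"{path}, line {lineno}: exon without "
                                 f"gene_id/Parent attribute")
            try:
                start, end = int(f[3]) - 1, int(f[4])  # 1-based incl -> half-open
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            exons.setdefault(gene, []).append((start, end))
            prev = meta.setdefault(gene, (f[0], f[6]))
            if prev != (f[0], f[6]):
                raise ValueError(f"{path}: gene {gene!r} spans chrom/strand "
                                 f"combinations (one transcript per gene required)")
    return [GeneModel(gene_id=g, chrom=meta[g][0], strand=meta[g][1],
                      exons=tuple(sorted(exons[g])))
            for g in sorted(exons)]


def write_gene_models_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.start, g.end
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, e in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, start, end, g.gene_id, 0, g.strand, start, end,
                "0,0,0", len(g.exons), sizes, starts])) + "\n")


# ---------------------------------------------------------------------------
# genetic maps

def read_genetic_map(path) -> GeneticMap:
    """Three-column TSV (chrom, pos, cm; pos 1-based, optional header) or
    4-column PLINK MAP (chrom, id, cm, bp)."""
    anchors: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            is_header = (not _is_number(f[3]) if len(f) >= 4
                         else not _is_number(f[1]))
            if lineno == 1 and is_header:
                continue
            try:
                if len(f) >= 4:
                    chrom, cm, bp = f[0], float(f[2]), int(f[3])
                elif len(f) == 3:
                    chrom, bp, cm = f[0], int(f[1]), float(f[2])
                else:
                    raise ValueError("need 3 (chrom pos cm) or 4 (PLINK) columns")
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            anchors.setdefault(chrom, []).append((bp - 1, cm))
    return GeneticMap(anchors)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tcm\n")
        for chrom in gmap.chroms:
            for pos, cm in gmap.anchors(chrom):
                fh.write(f"{chrom}\t{pos + 1}\t{cm!r}\n")


# ---------------------------------------------------------------------------
# eQTL / annotation / relevance tables

def read_eqtl_tables(paths: Sequence, study_ids: Sequence[str] | None = None,
                     ) -> list[EQTLRecord]:
    """Concatenate per-study TSVs (columns snp_id, gene_id, direction;
    study_id from the column if present, else from ``study_ids``/filename)."""
    out = []
    for k, path in enumerate(paths):
        df = pd.read_csv(path, sep="\t", dtype=str)
        _require_columns(df, ["snp_id", "gene_id"], path)
        default_study = (study_ids[k] if study_ids is not None
                         else Path(path).stem)
        for _, row in df.iterrows():
            out.append(EQTLRecord(
                snp_id=str(row["snp_id"]), gene_id=str(row["gene_id"]),
                study_id=str(row.get("study_id", default_study) or default_study),
                direction=str(row.get("direction", "unknown") or "unknown")))
    log.info("read %d eQTL records from %d tables", len(out), len(paths))
    return out


def write_eqtl_table(records: Sequence[EQTLRecord], path) -> None:
    pd.DataFrame([{
        "snp_id": r.snp_id, "gene_id": r.gene_id, "study_id": r.study_id,
        "direction": r.direction,
    } for r in records]).to_csv(path, sep="\t", index=False)


def read_missense_table(path) -> list[MissenseAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["snp_id", "gene_id", "impact"], path)
    return [MissenseAnnotation(snp_id=str(r["snp_id"]),
                               gene_id=str(r["gene_id"]),
                               impact=str(r["impact"]))
            for _, r in df.iterrows()]


def write_missense_table(records: Sequence[MissenseAnnotation], path) -> None:
    pd.DataFrame([{"snp_id": r.snp_id, "gene_id": r.gene_id,
                   "impact": r.impact} for r in records]
                 ).to_csv(path, sep="\t", index=False)


def read_splice_score_table(path) -> list[SpliceScoreRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["snp_id", "gene_id", "site_type",
                          "signed_distance", "score_change"], path)
    return [SpliceScoreRecord(
        snp_id=str(r["snp_id"]), gene_id=str(r["gene_id"]),
        site_type=str(r["site_type"]),
        signed_distance=int(r["signed_distance"]),
        score_change=float(r["score_change"])) for _, r in df.iterrows()]


def write_splice_score_table(records: Sequence[SpliceScoreRecord], path) -> None:
    pd.DataFrame([{
        "snp_id": r.snp_id, "gene_id": r.gene_id, "site_type": r.site_type,
        "signed_distance": r.signed_distance, "score_change": repr(r.score_change),
    } for r in records]).to_csv(path, sep="\t", index=False)


def read_relevance_table(path) -> dict[str, ProteinRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["gene_id", "disease", "relevance", "known",
                          "is_mhc"], path)
    out = {}
    for _, r in df.iterrows():
        rec = ProteinRecord(
            gene_id=str(r["gene_id"]), disease=str(r["disease"]),
            relevance=str(r["relevance"]),
            known=str(r["known"]).lower() in ("true", "1", "yes"),
            is_mhc=str(r["is_mhc"]).lower() in ("true", "1", "yes"))
        out[rec.gene_id] = rec
    return out


def write_relevance_table(records: Sequence[ProteinRecord], path) -> None:
    pd.DataFrame([{
        "gene_id": r.gene_id, "disease": r.disease, "relevance": r.relevance,
        "known": r.known, "is_mhc": r.is_mhc,
    } for r in records]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reports and manifests

def write_manifest(config: PipelineConfig, path, **counts) -> None:
    """Run manifest: full effective config, seed, and record counts.

    Deliberately contains nothing volatile (no timestamps, no paths) so that
    two runs with the same config and seed are byte-identical.
    """
    payload = {"config": config.to_dict(), "rng_seed": config.rng_seed,
               "counts": dict(sorted(counts.items()))}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report(results: dict[str, pd.DataFrame], outdir,
                 config: PipelineConfig) -> None:
    """Write each result table as ``<name>.tsv`` plus ``manifest.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name in sorted(results):
        results[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        counts[name] = len(results[name])
    write_manifest(config, outdir / "manifest.json", **counts)
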