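"""Synthetic input generation with known ground truth.

Every pipeline stage is exercised against data whose causal structure is
planted and recorded: a haplotype panel with controlled marker/causal LD, a
retrospectively sampled case/control cohort under a multiplicative per-allele
risk model, gene models with splice junctions, multi-study eQTL catalogs with
replicated and unreplicated relations, and missense/splice-score annotation
tables.  Generators are deterministic given their seed and always emit the
ground truth alongside the artifact.

LD construction is by symmetric allele flipping: the marker column is the
causal column with each haplotype's allele flipped with probability eps,
where eps is solved so that the expected squared correlation equals the
requested r^2.  This gives exact control of two-SNP LD without a coalescent
simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import PipelineConfig, SpliceThreshold
from .ld import (HaplotypeFreqs, case_frequency, forward_marker_or,
                 haplotype_freqs_from_panel, ld_stats)
from .models import (EQTLRecord, GeneModel, GeneticMap, HaplotypePanel,
                     MarkerSNP, MissenseAnnotation, ProteinRecord,
                     SpliceScoreRecord)

__all__ = [
    "PanelResult",
    "CohortResult",
    "PlantedEQTL",
    "PlantedLocus",
    "ScenarioBundle",
    "make_haplotype_panel",
    "plant_causal_cohort",
    "make_gene_models",
    "make_eqtl_catalogs",
    "make_missense_annotations",
    "make_genetic_map",
    "scenario_config",
    "simulate_scenario",
]

MECHANISM_CYCLE = ("missense_high", "missense_low", "expression",
                   "aux_splice", "direct_splice")


# ---------------------------------------------------------------------------
# haplotype panel

@dataclass
class PanelResult:
    panel: HaplotypePanel
    marker_id: str
    causal_id: str
    realized_r2: float
    freq_causal: float
    freq_marker: float


def _flip_rate_for_r2(p: float, target_r2: float) -> float:
    """Solve for the symmetric flip probability giving expected r^2.

    With marker = causal XOR Bern(eps):
      cov = p(1-p)(1-2 eps),  p_m = p(1-eps) + (1-p) eps,
      r = cov / sqrt(p(1-p) p_m (1-p_m)).
    r decreases monotonically from 1 (eps=0) to 0 (eps=1/2).
    """
    target_r = math.sqrt(target_r2)

    def f(eps: float) -> float:
        p_m = p * (1 - eps) + (1 - p) * eps
        cov = p * (1 - p) * (1 - 2 * eps)
        return cov / math.sqrt(p * (1 - p) * p_m * (1 - p_m)) - target_r

    if target_r2 >= 1.0:
        return 0.0
    return brentq(f, 0.0, 0.5 - 1e-12)


def make_haplotype_panel(n_hap: int, p_causal: float, target_r2: float,
                         n_neutral: int, seed: int, *,
                         chrom: str = "1", id_prefix: str = "snp",
                         marker_pos: int = 1_000_000,
                         causal_offset: int = 10_000,
                         neutral_span: int = 150_000,
                         n_far: int = 0,
                         far_offset: int = 250_000) -> PanelResult:
    """Phased panel with a causal SNP, a marker in controlled LD with it,
    ``n_neutral`` independent SNPs within ``neutral_span`` of the marker,
    and optionally ``n_far`` independent SNPs beyond the candidate window.
    """
    if n_hap < 100:
        raise ValueError("n_hap must be >= 100")
    if not (0.05 <= p_causal <= 0.5):
        raise ValueError("p_causal must be in [0.05, 0.5]")
    if not (0.0 < target_r2 <= 1.0):
        raise ValueError("target_r2 must be in (0, 1]")

    rng = np.random.default_rng(seed)
    causal = (rng.random(n_hap) < p_causal).astype(np.uint8)
    # guard against a monomorphic draw at small n
    if causal.sum() in (0, n_hap):
        causal[rng.integers(n_hap)] ^= 1

    eps = _flip_rate_for_r2(p_causal, target_r2)
    if eps == 0.0:
        marker = causal.copy()
    else:
        flips = rng.random(n_hap) < eps
        marker = causal ^ flips.astype(np.uint8)
        if marker.sum() in (0, n_hap):
            marker[rng.integers(n_hap)] ^= 1

    ids = [f"{id_prefix}_marker", f"{id_prefix}_causal"]
    pos = {ids[0]: marker_pos, ids[1]: marker_pos + causal_offset}
    cols = [marker, causal]
    taken = set(pos.values())

    def _fresh_pos(lo: int, hi: int) -> int:
        while True:
            p = int(rng.integers(lo, hi))
            if p not in taken:
                taken.add(p)
                return p

    for j in range(n_neutral):
        f = float(rng.uniform(0.1, 0.9))
        cols.append((rng.random(n_hap) < f).astype(np.uint8))
        sid = f"{id_prefix}_n{j}"
        ids.append(sid)
        pos[sid] = _fresh_pos(max(0, marker_pos - neutral_span),
                              marker_pos + neutral_span)
    for j in range(n_far):
        f = float(rng.uniform(0.1, 0.9))
        cols.append((rng.random(n_hap) < f).astype(np.uint8))
        sid = f"{id_prefix}_far{j}"
        ids.append(sid)
        offset = far_offset if j % 2 == 0 else -far_offset
        pos[sid] = marker_pos + offset + j

    matrix = np.column_stack(cols)
    panel = HaplotypePanel(
        snp_ids=ids, matrix=matrix,
        chrom={s: chrom for s in ids}, pos=pos,
        allele0={s: "A" for s in ids}, allele1={s: "G" for s in ids},
    )
    hf = haplotype_freqs_from_panel(panel, ids[1], ids[0])
    realized = ld_stats(hf).r2
    return PanelResult(panel=panel, marker_id=ids[0], causal_id=ids[1],
                       realized_r2=realized,
                       freq_causal=panel.frequency(ids[1]),
                       freq_marker=panel.frequency(ids[0]))


# ---------------------------------------------------------------------------
# case/control cohort

@dataclass
class CohortResult:
    snp_ids: list[str]
    case_hap: np.ndarray     # (2*n_case, n_snp) 0/1
    control_hap: np.ndarray  # (2*n_control, n_snp)
    causal_snp_id: str

    def genotypes(self) -> pd.DataFrame:
        """Per-individual genotype table (0/1/2) with a case/control label."""
        def collapse(hap: np.ndarray) -> np.ndarray:
            return hap[0::2] + hap[1::2]

        case = pd.DataFrame(collapse(self.case_hap), columns=self.snp_ids)
        case["status"] = "case"
        ctrl = pd.DataFrame(collapse(self.control_hap), columns=self.snp_ids)
        ctrl["status"] = "control"
        return pd.concat([case, ctrl], ignore_index=True)


def plant_causal_cohort(panel: HaplotypePanel, causal_snp_id: str,
                        causal_or: float, n_case: int, n_control: int,
                        seed: int,
                        snp_subset: Optional[Sequence[str]] = None) -> CohortResult:
    """Retrospective case/control sampling with a planted causal variant.

    Case haplotypes carry the causal risk allele at its case frequency under
    a multiplicative per-allele odds model; the rest of each haplotype is
    drawn from the panel conditional on the causal allele, so LD between the
    causal SNP and linked SNPs is preserved.  Controls are drawn from the
    panel directly (rare-disease approximation: controls ~ population).

    ``snp_subset`` restricts the emitted columns (the sampling itself is
    unaffected), which keeps large replicate sweeps cheap.
    """
    if causal_or <= 0:
        raise ValueError("causal_or must be > 0")
    col = panel.column(causal_snp_id)
    p = float(col.mean())
    if p in (0.0, 1.0):
        raise ValueError(f"{causal_snp_id}: degenerate frequency {p}")

    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(col == 1)
    idx0 = np.flatnonzero(col == 0)
    q = case_frequency(p, causal_or)

    n_case_hap = 2 * n_case
    alleles = rng.random(n_case_hap) < q
    chosen = np.empty(n_case_hap, dtype=np.int64)
    n1 = int(alleles.sum())
    chosen[alleles] = idx1[rng.integers(0, len(idx1), n1)]
    chosen[~alleles] = idx0[rng.integers(0, len(idx0), n_case_hap - n1)]

    ctrl_idx = rng.integers(0, panel.n_hap, 2 * n_control)

    if snp_subset is None:
        col_sel = slice(None)
        snp_ids = list(panel.snp_ids)
    else:
        index = {s: i for i, s in enumerate(panel.snp_ids)}
        col_sel = np.array([index[s] for s in snp_subset])
        snp_ids = list(snp_subset)

    return CohortResult(
        snp_ids=snp_ids,
        case_hap=panel.matrix[chosen][:, col_sel],
        control_hap=panel.matrix[ctrl_idx][:, col_sel],
        causal_snp_id=causal_snp_id,
    )


# ---------------------------------------------------------------------------
# gene models, eQTL catalogs, annotations, genetic map

def make_gene_models(n_genes: int, exons_per_gene: int, seed: int, *,
                     chrom: str = "1", start: int = 100_000,
                     id_prefix: str = "GENE") -> list[GeneModel]:
    """Random non-overlapping genes with ``exons_per_gene`` exons each."""
    if exons_per_gene < 1:
        raise ValueError("exons_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    genes = []
    cursor = start
    for g in range(n_genes):
        exons = []
        pos = cursor
        for e in range(exons_per_gene):
            length = int(rng.integers(80, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(400, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=f"{id_prefix}{g:03d}", chrom=chrom,
                               strand=strand, exons=tuple(exons)))
        cursor = exons[-1][1] + int(rng.integers(5_000, 20_000))
    return genes


@dataclass(frozen=True)
class PlantedEQTL:
    """Ground-truth eQTL relation: reported by ``n_studies`` studies, with
    identical reporting markers, or alternating with ``linked_snp_id``."""

    snp_id: str
    gene_id: str
    n_studies: int
    linked_snp_id: Optional[str] = None
    direction: str = "up"


def make_eqtl_catalogs(n_studies: int, planted_relations: Sequence[PlantedEQTL],
                       seed: int, *,
                       known_snps: Optional[set] = None,
                       known_genes: Optional[set] = None,
                       ) -> tuple[dict[str, list[EQTLRecord]], pd.DataFrame]:
    """Per-study eQTL tables realizing the planted relations.

    Returns (study_id -> records, ground-truth table).  Relations referencing
    SNPs or genes absent from the provided universes raise.
    """
    rng = np.random.default_rng(seed)
    studies = {f"s{k + 1}": [] for k in range(n_studies)}
    truth_rows = []
    for rel in planted_relations:
        if rel.n_studies < 1 or rel.n_studies > n_studies:
            raise ValueError(f"{rel.snp_id}/{rel.gene_id}: n_studies out of range")
        for sid in (rel.snp_id, rel.linked_snp_id):
            if sid is not None and known_snps is not None and sid not in known_snps:
                raise ValueError(f"planted relation references absent SNP {sid!r}")
        if known_genes is not None and rel.gene_id not in known_genes:
            raise ValueError(f"planted relation references absent gene {rel.gene_id!r}")
        study_ids = list(studies)
        rng.shuffle(study_ids)
        for k, study in enumerate(sorted(study_ids[:rel.n_studies])):
            snp = rel.snp_id
            if rel.linked_snp_id is not None and k % 2 == 1:
                snp = rel.linked_snp_id
            studies[study].append(EQTLRecord(snp_id=snp, gene_id=rel.gene_id,
                                             study_id=study,
                                             direction=rel.direction))
        truth_rows.append({"snp_id": rel.snp_id, "gene_id": rel.gene_id,
                           "n_studies": rel.n_studies,
                           "linked_snp_id": rel.linked_snp_id or "",
                           "replicated": rel.n_studies >= 2})
    return studies, pd.DataFrame(truth_rows)


def make_missense_annotations(candidates: Sequence[str],
                              planted_labels: dict[str, tuple[str, str]],
                              seed: int) -> list[MissenseAnnotation]:
    """Annotation table: ``planted_labels`` maps snp_id -> (gene_id, impact);
    only listed candidates are annotated."""
    rng = np.random.default_rng(seed)
    out = []
    for snp in candidates:
        if snp in planted_labels:
            gene, impact = planted_labels[snp]
            out.append(MissenseAnnotation(snp_id=snp, gene_id=gene, impact=impact))
    rng.shuffle(out)  # record order carries no information
    return out


def make_genetic_map(chrom_length: int, cm_per_mb: float, seed: int, *,
                     chrom: str = "1", n_anchors: int = 2) -> GeneticMap:
    """Linear genetic map: cM(pos) = pos * cm_per_mb / 1e6, sampled at
    ``n_anchors`` evenly spaced anchor points."""
    if n_anchors < 2:
        raise ValueError("need >= 2 anchors")
    pts = np.linspace(0, chrom_length, n_anchors)
    anchors = [(int(p), float(p) * cm_per_mb / 1e6) for p in pts]
    return GeneticMap({chrom: anchors})


# ---------------------------------------------------------------------------
# full scenario

@dataclass
class PlantedLocus:
    locus_id: str
    marker: MarkerSNP
    causal_snp_id: str
    causal_or: float
    mechanism_class: str
    target_r2: float
    realized_r2: float
    gene_id: str


@dataclass
class ScenarioBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: PipelineConfig
    markers: list[MarkerSNP]
    panel: HaplotypePanel
    genes: list[GeneModel]
    genetic_map: GeneticMap
    eqtl_tables: dict[str, list[EQTLRecord]]
    missense_annotations: list[MissenseAnnotation]
    splice_records: list[SpliceScoreRecord]
    protein_relevance: list[ProteinRecord]
    planted: list[PlantedLocus] = field(default_factory=list)
    eqtl_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "locus_id": pl.locus_id, "marker_id": pl.marker.id,
            "causal_snp_id": pl.causal_snp_id, "gene_id": pl.gene_id,
            "mechanism_class": pl.mechanism_class, "causal_or": pl.causal_or,
            "marker_or": pl.marker.odds_ratio, "target_r2": pl.target_r2,
            "realized_r2": pl.realized_r2,
        } for pl in self.planted])


def scenario_config(seed: int = 0) -> PipelineConfig:
    """Default study conditions for the synthetic scenario.

    Splice thresholds follow the usual layout of three donor and four
    acceptor signed-distance intervals; the numeric values are synthetic
    calibration for the generated score changes.
    """
    return PipelineConfig(
        rng_seed=seed,
        splice_donor_thresholds=(
            SpliceThreshold(-80, -1, 0.45),
            SpliceThreshold(0, 6, 0.40),
            SpliceThreshold(7, 80, 0.55),
        ),
        splice_acceptor_thresholds=(
            SpliceThreshold(-80, -21, 0.50),
            SpliceThreshold(-20, -3, 0.40),
            SpliceThreshold(-2, 2, 0.35),
            SpliceThreshold(3, 80, 0.55),
        ),
    )


def _gene_around(gene_id: str, chrom: str, causal_pos: int, strand: str,
                 direct_splice: bool) -> GeneModel:
    """Three-exon gene containing the causal SNP.

    For ``direct_splice`` the causal position is the first base (in
    transcription order) of the first intron, i.e. an intronic donor hit;
    otherwise it sits mid-exon, >= 50 bases from any junction.
    """
    c = causal_pos
    if direct_splice:
        if strand == "+":
            # exon1 ends at c; intron starts at c (first intron base = donor)
            exons = ((c - 200, c), (c + 300, c + 500), (c + 800, c + 1000))
        else:
            # transcription right->left: first intron base after the
            # genomically-rightmost exon is the base just left of it
            exons = ((c - 1000, c - 800), (c - 500, c - 300), (c + 1, c + 201))
    else:
        exons = ((c - 500, c - 300), (c - 100, c + 100), (c + 300, c + 500))
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)


def simulate_scenario(config: PipelineConfig, *, n_loci: int = 20,
                      n_hap: int = 1000, causal_or: float = 1.8,
                      target_r2: float = 0.8, n_neutral: int = 30,
                      n_eqtl_studies: int = 4) -> ScenarioBundle:
    """Default end-to-end scenario: ``n_loci`` independent loci, one planted
    mechanism each (cycling through the five classes), noise-free labels.

    Each locus sits on its own chromosome.  Negative controls are planted so
    that recovery is only exact if the filters work: a single-study eQTL on
    every missense_high locus, and a sub-threshold splice score record on
    every missense_low locus.
    """
    rng = np.random.default_rng(config.rng_seed)
    markers: list[MarkerSNP] = []
    genes: list[GeneModel] = []
    planted: list[PlantedLocus] = []
    missense_labels: dict[str, tuple[str, str]] = {}
    splice_records: list[SpliceScoreRecord] = []
    eqtl_relations: list[PlantedEQTL] = []
    relevance: list[ProteinRecord] = []
    map_anchors: dict[str, list[tuple[int, float]]] = {}

    all_ids: list[str] = []
    all_cols: list[np.ndarray] = []
    chrom_of: dict[str, str] = {}
    pos_of: dict[str, int] = {}

    diseases = ("diseaseA", "diseaseB")
    for i in range(n_loci):
        locus_id = f"L{i + 1:02d}"
        chrom = str(i + 1)
        mech = MECHANISM_CYCLE[i % len(MECHANISM_CYCLE)]
        p_causal = float(rng.uniform(0.15, 0.45))
        pr = make_haplotype_panel(
            n_hap, p_causal, target_r2, n_neutral,
            seed=int(rng.integers(2**31)),
            chrom=chrom, id_prefix=locus_id, n_far=2)
        hf = haplotype_freqs_from_panel(pr.panel, pr.causal_id, pr.marker_id)
        or_m = forward_marker_or(hf, causal_or)
        marker = MarkerSNP(
            id=pr.marker_id, chrom=chrom, pos=pr.panel.pos[pr.marker_id],
            risk_allele="G", other_allele="A", odds_ratio=or_m,
            p_value=1e-8, source="catalog", disease=diseases[i % 2])
        markers.append(marker)

        gene_id = f"GENE{i + 1:02d}"
        strand = "+" if mech == "direct_splice" else ("+" if i % 2 == 0 else "-")
        gene = _gene_around(gene_id, chrom, pr.panel.pos[pr.causal_id],
                            strand, direct_splice=(mech == "direct_splice"))
        genes.append(gene)

        if mech in ("missense_high", "missense_low"):
            missense_labels[pr.causal_id] = (gene_id, mech.split("_")[1])
        if mech == "missense_high":
            # negative control: unreplicated eQTL must never surface
            eqtl_relations.append(PlantedEQTL(snp_id=marker.id,
                                              gene_id=gene_id, n_studies=1))
        if mech == "missense_low":
            # negative control: sub-threshold splice score must not flag
            splice_records.append(SpliceScoreRecord(
                snp_id=pr.causal_id, gene_id=gene_id, site_type="donor",
                signed_distance=5, score_change=0.05))
        if mech == "expression":
            eqtl_relations.append(PlantedEQTL(snp_id=marker.id,
                                              gene_id=gene_id, n_studies=2))
        if mech == "aux_splice":
            splice_records.append(SpliceScoreRecord(
                snp_id=pr.causal_id, gene_id=gene_id, site_type="donor",
                signed_distance=5, score_change=0.80))

        rel = ("A", "B", "C", "C")[i % 4]
        relevance.append(ProteinRecord(gene_id=gene_id,
                                       disease=marker.disease,
                                       relevance=rel, known=rel in ("A", "B"),
                                       is_mhc=False))
        map_anchors[chrom] = [(0, 0.0), (2_000_000, 2.0)]

        all_ids.extend(pr.panel.snp_ids)
        all_cols.append(pr.panel.matrix)
        chrom_of.update(pr.panel.chrom)
        pos_of.update(pr.panel.pos)
        planted.append(PlantedLocus(
            locus_id=locus_id, marker=marker, causal_snp_id=pr.causal_id,
            causal_or=causal_or, mechanism_class=mech, target_r2=target_r2,
            realized_r2=pr.realized_r2, gene_id=gene_id))

    panel = HaplotypePanel(
        snp_ids=all_ids, matrix=np.hstack(all_cols),
        chrom=chrom_of, pos=pos_of,
        allele0={s: "A" for s in all_ids}, allele1={s: "G" for s in all_ids})

    known_snps = set(all_ids)
    known_genes = {g.gene_id for g in genes}
    eqtl_tables, eqtl_truth = make_eqtl_catalogs(
        n_eqtl_studies, eqtl_relations, seed=int(rng.integers(2**31)),
        known_snps=known_snps, known_genes=known_genes)
    missense = make_missense_annotations(
        all_ids, missense_labels, seed=int(rng.integers(2**31)))

    return ScenarioBundle(
        config=config, markers=markers, panel=panel, genes=genes,
        genetic_map=GeneticMap(map_anchors), eqtl_tables=eqtl_tables,
        missense_annotations=missense, splice_records=splice_records,
        protein_relevance=relevance, planted=planted, eqtl_truth=eqtl_truth)
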