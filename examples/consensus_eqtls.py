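"""Consensus eQTLs and matching to disease markers in centiMorgans.

An eQTL relation counts as consensus only when reported by at least two
independent studies with identical markers or markers in LD at r^2 > 0.8.
A consensus eQTL explains a disease marker when the two are identical or
within 0.05 cM.
"""

from mechanista import (EQTLRecord, GeneticMap, MarkerSNP, PipelineConfig,
                        build_consensus_eqtls, make_haplotype_panel,
                        match_disease_eqtl)

cfg = PipelineConfig()

# a panel where the two eQTL markers are in strong LD (r^2 ~ 0.95)
pr = make_haplotype_panel(4000, 0.3, 0.95, 0, seed=5)
records = [
    EQTLRecord(pr.marker_id, "GENE1", "study1", "up"),
    EQTLRecord(pr.causal_id, "GENE1", "study2", "up"),   # linked marker
    EQTLRecord("rs_lonely", "GENE2", "study1", "down"),  # single study
]
consensus = build_consensus_eqtls(records, pr.panel, cfg)
for ce in consensus:
    print(f"consensus eQTL for {ce.gene_id}: markers "
          f"{sorted(ce.marker_cluster)}, {ce.n_studies} studies")
print(f"GENE2 single-study relation filtered out: "
      f"{all(ce.gene_id != 'GENE2' for ce in consensus)}")

# matching by genetic distance on a 1 cM/Mb map: 40 kb = 0.04 cM matches,
# 60 kb = 0.06 cM does not
gmap = GeneticMap({"1": [(0, 0.0), (2_000_000, 2.0)]})
locations = {s: ("1", pr.panel.pos[s]) for s in pr.panel.snp_ids}
for offset in (40_000, 60_000):
    marker = MarkerSNP(id="gwas_hit", chrom="1",
                       pos=pr.panel.pos[pr.marker_id] + offset,
                       risk_allele="G", other_allele="A", odds_ratio=1.4,
                       p_value=1e-8, source="catalog", disease="d")
    hit = match_disease_eqtl(marker, consensus[0], gmap, locations, cfg)
    print(f"marker {offset / 1000:.0f} kb away ({offset / 1e6:.2f} cM): "
          f"match = {hit}")
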