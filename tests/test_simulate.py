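"""Synthetic-data generators: LD control, cohort sampling, catalogs, maps."""

import numpy as np
import pytest

from mechanista import (PlantedEQTL, forward_marker_or,
                        haplotype_freqs_from_panel, ld_stats,
                        make_eqtl_catalogs, make_gene_models,
                        make_genetic_map, make_haplotype_panel,
                        make_missense_annotations, plant_causal_cohort)
from mechanista.ld import estimate_allelic_or


class TestHaplotypePanel:
    def test_target_r2_one_gives_identical_columns(self):
        pr = make_haplotype_panel(200, 0.3, 1.0, 2, seed=1)
        assert np.array_equal(pr.panel.column(pr.marker_id),
                              pr.panel.column(pr.causal_id))
        assert pr.realized_r2 == pytest.approx(1.0)

    def test_realized_r2_close_to_target_at_large_n(self):
        pr = make_haplotype_panel(10_000, 0.3, 0.5, 0, seed=42)
        assert abs(pr.realized_r2 - 0.5) < 0.05

    def test_neutral_columns_uncorrelated_with_causal(self):
        pr = make_haplotype_panel(10_000, 0.3, 0.8, 20, seed=7)
        r2s = []
        for j in range(20):
            hf = haplotype_freqs_from_panel(pr.panel, f"snp_n{j}",
                                            pr.causal_id)
            r2s.append(ld_stats(hf).r2)
        assert np.mean(r2s) < 0.01

    def test_deterministic_given_seed(self):
        a = make_haplotype_panel(500, 0.25, 0.7, 5, seed=3)
        b = make_haplotype_panel(500, 0.25, 0.7, 5, seed=3)
        assert np.array_equal(a.panel.matrix, b.panel.matrix)
        assert a.panel.pos == b.panel.pos

    @pytest.mark.parametrize("n_hap,p,r2", [
        (50, 0.3, 0.5),      # too few haplotypes
        (200, 0.01, 0.5),    # frequency out of range
        (200, 0.3, 0.0),     # r2 out of range
        (200, 0.3, 1.5),
    ])
    def test_invalid_inputs_raise(self, n_hap, p, r2):
        with pytest.raises(ValueError):
            make_haplotype_panel(n_hap, p, r2, 0, seed=0)

    def test_far_snps_lie_outside_candidate_window(self):
        pr = make_haplotype_panel(200, 0.3, 0.8, 0, seed=1, n_far=2,
                                  marker_pos=1_000_000, far_offset=250_000)
        for sid in ("snp_far0", "snp_far1"):
            assert abs(pr.panel.pos[sid] - 1_000_000) > 200_000


class TestPlantedCohort:
    def test_null_or_gives_equal_frequencies(self):
        pr = make_haplotype_panel(1000, 0.3, 0.8, 0, seed=2)
        coh = plant_causal_cohort(pr.panel, pr.causal_id, 1.0, 20_000,
                                  20_000, seed=9)
        j = coh.snp_ids.index(pr.causal_id)
        f_case = coh.case_hap[:, j].mean()
        f_ctrl = coh.control_hap[:, j].mean()
        assert abs(f_case - f_ctrl) < 0.01

    def test_realized_causal_or_converges(self):
        pr = make_haplotype_panel(2000, 0.3, 0.8, 0, seed=4)
        coh = plant_causal_cohort(pr.panel, pr.causal_id, 3.0, 50_000,
                                  50_000, seed=10,
                                  snp_subset=[pr.causal_id])
        est, _, _ = estimate_allelic_or(coh.case_hap[:, 0],
                                        coh.control_hap[:, 0])
        assert 2.8 <= est <= 3.2

    def test_marker_or_matches_forward_model_prediction(self):
        pr = make_haplotype_panel(2000, 0.3, 0.7, 0, seed=6)
        hf = haplotype_freqs_from_panel(pr.panel, pr.causal_id, pr.marker_id)
        predicted = forward_marker_or(hf, 2.0)
        coh = plant_causal_cohort(pr.panel, pr.causal_id, 2.0, 50_000,
                                  50_000, seed=12,
                                  snp_subset=[pr.marker_id])
        _, lo, hi = estimate_allelic_or(coh.case_hap[:, 0],
                                        coh.control_hap[:, 0])
        assert lo <= predicted <= hi

    def test_degenerate_causal_frequency_raises(self):
        pr = make_haplotype_panel(200, 0.3, 0.8, 1, seed=2)
        pr.panel.matrix[:, 1] = 1  # causal column fixed
        with pytest.raises(ValueError, match="degenerate"):
            plant_causal_cohort(pr.panel, pr.causal_id, 2.0, 10, 10, seed=0)

    def test_genotype_table_shape_and_labels(self):
        pr = make_haplotype_panel(200, 0.3, 0.8, 1, seed=8)
        coh = plant_causal_cohort(pr.panel, pr.causal_id, 1.5, 50, 60, seed=1)
        df = coh.genotypes()
        assert len(df) == 110
        assert (df["status"] == "case").sum() == 50
        geno = df[coh.snp_ids].to_numpy()
        assert set(np.unique(geno)) <= {0, 1, 2}


class TestEQTLCatalogs:
    def test_two_study_relation_appears_in_two_tables(self):
        tables, truth = make_eqtl_catalogs(
            3, [PlantedEQTL("rs1", "G1", n_studies=2)], seed=0)
        hits = [s for s, recs in tables.items()
                if any(r.snp_id == "rs1" for r in recs)]
        assert len(hits) == 2
        assert truth.loc[0, "replicated"]

    def test_single_study_relation_appears_once(self):
        tables, truth = make_eqtl_catalogs(
            3, [PlantedEQTL("rs2", "G2", n_studies=1)], seed=0)
        total = sum(len(recs) for recs in tables.values())
        assert total == 1
        assert not truth.loc[0, "replicated"]

    def test_linked_marker_alternation(self):
        tables, _ = make_eqtl_catalogs(
            4, [PlantedEQTL("rs3", "G3", n_studies=2, linked_snp_id="rs4")],
            seed=0)
        snps = sorted(r.snp_id for recs in tables.values() for r in recs)
        assert snps == ["rs3", "rs4"]

    def test_absent_snp_or_gene_rejected(self):
        with pytest.raises(ValueError, match="absent SNP"):
            make_eqtl_catalogs(2, [PlantedEQTL("rsX", "G1", 2)], seed=0,
                               known_snps={"rs1"}, known_genes={"G1"})
        with pytest.raises(ValueError, match="absent gene"):
            make_eqtl_catalogs(2, [PlantedEQTL("rs1", "GX", 2)], seed=0,
                               known_snps={"rs1"}, known_genes={"G1"})


class TestOtherGenerators:
    def test_linear_map_is_exact(self):
        gmap = make_genetic_map(2_000_000, 1.0, seed=0)
        for pos in (0, 500_000, 1_234_567, 2_000_000):
            assert gmap.cm_at("1", pos) == pytest.approx(pos / 1e6)

    def test_gene_models_are_disjoint_and_well_formed(self):
        genes = make_gene_models(5, 3, seed=1)
        for g in genes:
            assert len(g.exons) == 3
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_missense_annotations_only_for_planted_candidates(self):
        anns = make_missense_annotations(
            ["rs1", "rs2", "rs3"],
            {"rs1": ("G1", "high"), "rs9": ("G9", "low")}, seed=0)
        assert len(anns) == 1
        assert anns[0].snp_id == "rs1" and anns[0].impact == "high"
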