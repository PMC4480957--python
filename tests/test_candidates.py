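"""Marker intake, candidate enumeration/acceptance, locus extent."""

import numpy as np
import pytest

from mechanista import (CandidateSNP, HaplotypeFreqs, HaplotypePanel,
                        MarkerSNP, PipelineConfig, accept_candidate,
                        enumerate_candidates, locus_extent, select_markers)
from mechanista.candidates import _merge_markers


def _marker(**kw):
    defaults = dict(id="m1", chrom="1", pos=1_000_000, risk_allele="G",
                    other_allele="A", odds_ratio=1.5, p_value=1e-8,
                    source="catalog", disease="d")
    defaults.update(kw)
    return MarkerSNP(**defaults)


class TestSelectMarkers:
    def test_catalog_threshold_keeps_2e6(self):
        kept = select_markers([_marker(p_value=2e-6)], PipelineConfig())
        assert len(kept) == 1

    def test_primary_scan_threshold_drops_2e6(self):
        m = _marker(source="primary_scan", p_value=2e-6)
        assert select_markers([m], PipelineConfig()) == []

    def test_exact_threshold_is_dropped(self):
        m = _marker(p_value=1e-5)
        assert select_markers([m], PipelineConfig()) == []
        m2 = _marker(source="primary_scan", p_value=5.0e-7)
        assert select_markers([m2], PipelineConfig()) == []

    def test_unknown_source_tag_rejected(self):
        m = _marker()
        object.__setattr__(m, "source", "mystery")
        with pytest.raises(ValueError, match="unknown source"):
            select_markers([m], PipelineConfig())

    def test_merge_keeps_lowest_p_representative(self):
        strong = _marker(id="strong", pos=1_000_000, p_value=1e-9)
        shadow = _marker(id="shadow", pos=1_050_000, p_value=1e-7)
        far = _marker(id="far", pos=1_500_000, p_value=1e-7)
        reps = _merge_markers([shadow, strong, far], window_bp=200_000)
        assert {m.id for m in reps} == {"strong", "far"}


def _tiny_panel():
    """Panel built by hand: marker plus SNPs probing each filter."""
    rng = np.random.default_rng(0)
    n = 100
    marker = rng.integers(0, 2, n).astype(np.uint8)
    inside = marker.copy()           # perfect LD, within window
    edge = marker.copy()             # at exactly +window_bp
    rare = np.zeros(n, dtype=np.uint8)
    rare[:4] = 1                     # maf 0.04 -> excluded
    border_maf = np.zeros(n, dtype=np.uint8)
    border_maf[:5] = 1               # maf 0.05 exactly -> included
    outside = marker.copy()          # beyond window
    ids = ["m1", "in", "edge", "rare", "mafb", "out"]
    pos = {"m1": 1_000_000, "in": 1_010_000, "edge": 1_200_000,
           "rare": 1_020_000, "mafb": 1_030_000, "out": 1_250_000}
    return HaplotypePanel(
        snp_ids=ids,
        matrix=np.column_stack([marker, inside, edge, rare, border_maf,
                                outside]),
        chrom={s: "1" for s in ids}, pos=pos,
        allele0={s: "A" for s in ids}, allele1={s: "G" for s in ids})


class TestEnumerateCandidates:
    def test_window_and_maf_filters(self):
        cands = enumerate_candidates(_marker(), _tiny_panel(),
                                     PipelineConfig())
        ids = {c.id for c in cands}
        assert "out" not in ids      # 250 kb away
        assert "rare" not in ids     # maf 0.04
        assert "edge" in ids         # exactly 200 kb: inclusive
        assert "mafb" in ids         # maf exactly 0.05: inclusive
        assert "in" in ids

    def test_marker_absent_from_panel_raises(self):
        with pytest.raises(KeyError):
            enumerate_candidates(_marker(id="nope"), _tiny_panel(),
                                 PipelineConfig())

    def test_risk_orientation_gives_nonnegative_d(self):
        cands = enumerate_candidates(_marker(), _tiny_panel(),
                                     PipelineConfig())
        for c in cands:
            hf = c.hf_to_marker
            assert hf.h_ab - hf.p_a * hf.p_b >= 0


def _cand(hf):
    return CandidateSNP(id="c", chrom="1", pos=1_010_000, maf=0.3,
                        hf_to_marker=hf)


class TestAcceptCandidate:
    def test_perfect_ld_accepted_with_marker_or(self):
        hf = HaplotypeFreqs(0.7, 0.0, 0.0, 0.3)
        c = accept_candidate(_cand(hf), _marker(odds_ratio=1.5),
                             PipelineConfig())
        assert c.accepted
        assert c.implied_or == pytest.approx(1.5)

    def test_hand_instance_implies_three(self):
        hf = HaplotypeFreqs(0.5, 0.2, 0.1, 0.2)
        c = accept_candidate(_cand(hf), _marker(odds_ratio=1.5),
                             PipelineConfig(r2_floor=0.1))
        assert c.accepted
        assert c.implied_or == pytest.approx(3.0)

    def test_zero_d_rejected_without_error(self):
        hf = HaplotypeFreqs(0.7 * 0.6, 0.7 * 0.4, 0.3 * 0.6, 0.3 * 0.4)
        c = accept_candidate(_cand(hf), _marker(), PipelineConfig())
        assert not c.accepted and c.implied_or is None

    def test_r2_floor_rejects_weak_ld(self):
        hf = HaplotypeFreqs(0.48, 0.21, 0.2, 0.11)  # r2 ~ 0.0025
        c = accept_candidate(_cand(hf), _marker(odds_ratio=1.05),
                             PipelineConfig(r2_floor=0.2))
        assert not c.accepted
        # floor disabled: the bare feasibility rule applies
        c2 = accept_candidate(_cand(hf), _marker(odds_ratio=1.05),
                              PipelineConfig(r2_floor=0.0))
        assert c2.accepted

    def test_acceptance_monotone_in_r2(self):
        # fixed allele frequencies, D swept upward: once accepted, stays
        p_a, p_b = 0.3, 0.4
        cfg = PipelineConfig()
        marker = _marker(odds_ratio=1.3)
        accepted_flags = []
        for d in np.linspace(0.005, min(p_a * (1 - p_b), (1 - p_a) * p_b) - 1e-3, 25):
            h_ab = p_a * p_b + d
            hf = HaplotypeFreqs(1 - p_a - p_b + h_ab, p_b - h_ab,
                                p_a - h_ab, h_ab)
            accepted_flags.append(
                accept_candidate(_cand(hf), marker, cfg).accepted)
        first_true = accepted_flags.index(True)
        assert all(accepted_flags[first_true:])


class TestLocusExtent:
    def _accepted(self, pos):
        return CandidateSNP(id=f"c{pos}", chrom="1", pos=pos, maf=0.3,
                            accepted=True)

    def test_min_max_over_accepted(self):
        cands = [self._accepted(p) for p in (100_000, 250_000, 380_000)]
        assert locus_extent(cands, _marker()) == (100_000, 380_000)

    def test_no_accepted_gives_point_at_marker(self):
        m = _marker(pos=1_000_000)
        assert locus_extent([], m) == (1_000_000, 1_000_000)

    def test_single_accepted_is_point(self):
        assert locus_extent([self._accepted(150_000)], _marker()) == \
            (150_000, 150_000)


class TestPlantedRecovery:
    def test_planted_causal_snp_always_accepted(self, bundle, result):
        truth = {pl.marker.id: pl for pl in bundle.planted}
        for locus in result.loci:
            pl = truth[locus.marker.id]
            accepted = {c.id for c in locus.accepted}
            assert pl.causal_snp_id in accepted
            cand = next(c for c in locus.accepted if c.id == pl.causal_snp_id)
            assert cand.implied_or == pytest.approx(pl.causal_or, rel=1e-6)
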