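"""Locus/protein aggregation, enrichment testing, and the sensitivity model.

The sensitivity model links a variant's molecular impact to its phenotypic
effect: a variant changes the in-vivo activity of gene product i by a
fraction dA_i, and the phenotype parameter q responds linearly,

    dP_q = sum_i S_iq * dA_i,

where S_iq is a dimensionless sensitivity coefficient (the local derivative
of phenotype with respect to activity).  dP relates to an odds ratio via
dP = OR - 1; an n-fold loss of activity gives dA = 1/n - 1.  Selection on a
variant with selection coefficient s is effectively neutral when
|s| < 1/(2*Ne) with Ne the effective population size.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .mechanisms import classify_missense_locus
from .models import (MECHANISMS, Locus, LocusSummary, MechanismCall,
                     ProteinRecord)

__all__ = [
    "locus_mechanism_profile",
    "locus_category",
    "overlap_fraction",
    "delta_a_from_fold",
    "fold_from_delta_a",
    "delta_p_from_or",
    "sensitivity_coefficient",
    "linear_phenotype",
    "selection_threshold",
    "fisher_two_tailed",
    "enrichment_by_mechanism",
    "summarize_loci",
    "protein_records_with_mechanisms",
]


# ---------------------------------------------------------------------------
# per-locus profiles and relevance categories

def locus_mechanism_profile(locus_id: str, disease: str,
                            calls: Sequence[MechanismCall]) -> LocusSummary:
    """Mechanism profile of one locus.

    Missense collapses to a single slot (high dominates low), so at most
    four mechanism types can be present: missense, expression, auxiliary
    splicing, direct splice hit.
    """
    mechs = {c.mechanism for c in calls if c.locus_id == locus_id}
    impacts = [m.split("_")[1] for m in mechs
               if m in ("missense_high", "missense_low")]
    present = set(mechs) - {"missense_high", "missense_low"}
    missense = classify_missense_locus(impacts)
    if missense != "none":
        present.add(f"missense_{missense}")
    slots = sum((
        missense != "none",
        "expression" in present,
        "aux_splice" in present,
        "direct_splice" in present,
    ))
    return LocusSummary(locus_id=locus_id, disease=disease,
                        mechanisms_present=frozenset(present),
                        n_mechanism_types=slots)


def locus_category(proteins: Iterable[ProteinRecord]) -> str:
    """Relevance category of a locus from its proteins' labels: A takes
    precedence over B, B over C; MHC (D) loci are reported separately."""
    labels = {p.relevance for p in proteins}
    for cat in ("A", "B", "C"):
        if cat in labels:
            return cat
    if "D" in labels:
        return "D"
    return "none"


def overlap_fraction(proteins: Sequence[ProteinRecord], mech1: str,
                     mech2: str) -> Optional[float]:
    """Of the proteins carrying ``mech1``, the fraction also carrying
    ``mech2``; None when no protein carries ``mech1``."""
    with1 = [p for p in proteins if mech1 in p.mechanisms]
    if not with1:
        return None
    both = [p for p in with1 if mech2 in p.mechanisms]
    return len(both) / len(with1)


# ---------------------------------------------------------------------------
# sensitivity model

def delta_a_from_fold(fold: float, gain: bool = False) -> float:
    """Fractional activity change from an n-fold effect.

    Loss: dA = 1/fold - 1 (five-fold loss -> -0.8); gain: dA = fold - 1.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    return fold - 1.0 if gain else 1.0 / fold - 1.0


def fold_from_delta_a(delta_a: float) -> float:
    """Inverse of :func:`delta_a_from_fold` (loss for dA < 0, gain for >= 0)."""
    if delta_a < -1:
        raise ValueError("delta_a must be >= -1")
    return delta_a + 1.0 if delta_a >= 0 else 1.0 / (delta_a + 1.0)


def delta_p_from_or(odds_ratio: float) -> float:
    """Fractional phenotype (risk) change from an odds ratio: dP = OR - 1."""
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    return odds_ratio - 1.0


def sensitivity_coefficient(delta_p: float, delta_a: float,
                            use_magnitude: bool = True) -> float:
    """S = dP/|dA| (magnitude convention, the worked-example form) or the
    signed ratio dP/dA."""
    if delta_a == 0:
        raise ValueError("delta_a must be nonzero")
    return delta_p / abs(delta_a) if use_magnitude else delta_p / delta_a


def linear_phenotype(s_list: Sequence[float],
                     delta_a_list: Sequence[float]) -> float:
    """Linear phenotype response: dP_q = sum_i S_iq * dA_i."""
    if len(s_list) != len(delta_a_list):
        raise ValueError("s_list and delta_a_list must have equal length")
    return float(sum(s * da for s, da in zip(s_list, delta_a_list)))


def selection_threshold(n_e: float) -> float:
    """Minimum |s| at which selection is operative: 1/(2*Ne)."""
    if n_e < 1:
        raise ValueError("n_e must be >= 1")
    return 1.0 / (2.0 * n_e)


# ---------------------------------------------------------------------------
# enrichment

def fisher_two_tailed(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p for the 2x2 table [[a, b], [c, d]].

    Two-sided by the probability-mass criterion: sum of hypergeometric
    probabilities (margins fixed) of every table at most as probable as the
    observed one.  All arithmetic is exact integer/rational — the support
    shares the denominator C(N, r1), so probabilities compare and sum as
    integer numerators.
    """
    for v in (a, b, c, d):
        if not isinstance(v, int) or v < 0:
            raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if 0 in (r1, c1, n - r1, n - c1):
        raise ValueError("all table margins must be positive")
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    numerators = [comb(c1, x) * comb(n - c1, r1 - x) for x in range(lo, hi + 1)]
    observed = numerators[a - lo]
    return Fraction(sum(m for m in numerators if m <= observed), comb(n, r1))


def enrichment_by_mechanism(proteins: Sequence[ProteinRecord],
                            mechanisms: Sequence[str] = MECHANISMS,
                            ) -> pd.DataFrame:
    """Per mechanism: is it enriched among known disease-relevant proteins?

    Builds the 2x2 table {has mechanism x known} over all eligible (non-MHC)
    proteins and applies the two-tailed Fisher test.  Raw p-values, no
    multiplicity adjustment.  Degenerate margins (e.g. a single protein, or
    a mechanism carried by none) report p = 1.
    """
    eligible = [p for p in proteins if not p.is_mhc]
    if not eligible:
        raise ValueError("no eligible proteins")
    rows = []
    for mech in mechanisms:
        a = sum(1 for p in eligible if mech in p.mechanisms and p.known)
        b = sum(1 for p in eligible if mech in p.mechanisms and not p.known)
        c = sum(1 for p in eligible if mech not in p.mechanisms and p.known)
        d = sum(1 for p in eligible
                if mech not in p.mechanisms and not p.known)
        try:
            p_val = float(fisher_two_tailed(a, b, c, d))
        except ValueError:
            p_val = 1.0
        rows.append({"mechanism": mech, "known_with": a, "unknown_with": b,
                     "known_without": c, "unknown_without": d, "p_value": p_val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline-level aggregation helpers

def summarize_loci(loci: Sequence[Locus], calls: Sequence[MechanismCall],
                   relevance: Mapping[str, ProteinRecord]) -> list[LocusSummary]:
    """Mechanism profile plus relevance category for every locus.

    ``relevance`` maps gene_id -> ProteinRecord (input labels); the locus
    category is taken over the genes its calls implicate.
    """
    by_locus: dict[str, list[MechanismCall]] = {}
    for call in calls:
        by_locus.setdefault(call.locus_id, []).append(call)
    out = []
    for locus in loci:
        locus_calls = by_locus.get(locus.locus_id, [])
        summary = locus_mechanism_profile(locus.locus_id, locus.disease,
                                          locus_calls)
        genes = {c.gene_id for c in locus_calls}
        recs = [relevance[g] for g in sorted(genes) if g in relevance]
        if locus.is_mhc:
            summary.category = "D"
        elif recs:
            summary.category = locus_category(recs)
        out.append(summary)
    return out


def protein_records_with_mechanisms(calls: Sequence[MechanismCall],
                                    relevance: Mapping[str, ProteinRecord],
                                    ) -> list[ProteinRecord]:
    """Attach the called mechanism sets to the input relevance records."""
    mechs: dict[str, set] = {}
    for call in calls:
        mechs.setdefault(call.gene_id, set()).add(call.mechanism)
    out = []
    for gene_id in sorted(relevance):
        rec = relevance[gene_id]
        out.append(ProteinRecord(gene_id=rec.gene_id, disease=rec.disease,
                                 relevance=rec.relevance, known=rec.known,
                                 mechanisms=mechs.get(gene_id, set()),
                                 is_mhc=rec.is_mhc))
    return out
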