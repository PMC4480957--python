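"""Two-SNP linkage-disequilibrium algebra and the implied odds ratio.

The central question: given a disease marker with observed case/control odds
ratio ``or_m``, what odds ratio would a nearby SNP need at its *own* alleles
for its involvement in mechanism to generate the marker's observed
case/control frequency difference?  Under a multiplicative per-allele risk
model with controls approximating the population, case haplotypes preserve
the candidate->marker allele conditionals, so marker and candidate case
frequencies are linked through the joint haplotype distribution.  Forward
propagation (candidate OR -> marker OR) is closed-form, and so is its
inverse; the inverse may land outside (0, 1) in candidate case frequency,
which is a regular "not a candidate" outcome, not an error.

Allele labelling follows the risk orientation: ``a`` is the candidate's
putative risk allele, ``b`` the marker's risk allele; ``h_ab`` is the
frequency of the haplotype carrying both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HaplotypeFreqs",
    "LDStats",
    "ImpliedOR",
    "MonomorphicError",
    "NoLDInformationError",
    "ld_stats",
    "forward_marker_or",
    "implied_candidate_or",
    "haplotype_freqs_from_panel",
]

_SUM_TOL = 1e-9


class MonomorphicError(ValueError):
    """One of the two SNPs is fixed; LD statistics are undefined."""


class NoLDInformationError(ValueError):
    """D = 0: the marker carries no information about the candidate."""


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Joint two-SNP haplotype frequencies.

    Uppercase = non-risk allele, lowercase = risk allele; first letter is the
    candidate SNP, second the marker.
    """

    h_AB: float
    h_Ab: float
    h_aB: float
    h_ab: float

    def __post_init__(self) -> None:
        vals = (self.h_AB, self.h_Ab, self.h_aB, self.h_ab)
        if any(v < -_SUM_TOL or v > 1 + _SUM_TOL for v in vals):
            raise ValueError(f"haplotype frequencies out of [0,1]: {vals}")
        if abs(sum(vals) - 1.0) > _SUM_TOL:
            raise ValueError(f"haplotype frequencies sum to {sum(vals)}, not 1")

    @property
    def p_a(self) -> float:
        """Candidate risk-allele frequency."""
        return self.h_aB + self.h_ab

    @property
    def p_b(self) -> float:
        """Marker risk-allele frequency."""
        return self.h_Ab + self.h_ab

    def flipped_candidate(self) -> "HaplotypeFreqs":
        """Swap which candidate allele is labelled as risk."""
        return HaplotypeFreqs(h_AB=self.h_aB, h_Ab=self.h_ab,
                              h_aB=self.h_AB, h_ab=self.h_Ab)


@dataclass(frozen=True)
class LDStats:
    D: float
    D_prime: float
    r2: float


@dataclass(frozen=True)
class ImpliedOR:
    """Outcome of inverting the forward model at a candidate SNP."""

    feasible: bool
    value: float | None  # None iff infeasible
    q_a: float  # implied candidate risk-allele case frequency (may be outside (0,1))


def _check_polymorphic(hf: HaplotypeFreqs) -> None:
    if not (0.0 < hf.p_a < 1.0) or not (0.0 < hf.p_b < 1.0):
        raise MonomorphicError(
            f"monomorphic SNP: p_a={hf.p_a}, p_b={hf.p_b}")


def ld_stats(hf: HaplotypeFreqs) -> LDStats:
    """D, D' and r^2 from joint haplotype frequencies.

    D = h_ab - p_a*p_b (covariance of the two risk-allele indicators);
    D' normalizes D by its frequency-constrained extreme; r^2 is the squared
    allelic correlation.
    """
    _check_polymorphic(hf)
    p_a, p_b = hf.p_a, hf.p_b
    D = hf.h_ab - p_a * p_b
    if D > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    D_prime = 0.0 if D == 0 else D / d_max
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDStats(D=D, D_prime=D_prime, r2=r2)


def case_frequency(p: float, odds_ratio: float) -> float:
    """Case allele frequency under a multiplicative per-allele odds model
    with controls at the population frequency ``p``."""
    return odds_ratio * p / (1.0 - p + odds_ratio * p)


def _odds_ratio(q: float, p: float) -> float:
    return (q * (1.0 - p)) / ((1.0 - q) * p)


def forward_marker_or(hf: HaplotypeFreqs, or_c: float) -> float:
    """Marker odds ratio generated by a candidate with allelic odds ratio
    ``or_c``, given the joint haplotype structure.

    The candidate's case frequency is lifted to the marker through the
    haplotype conditionals P(b|a) = h_ab/p_a and P(b|A) = h_Ab/(1-p_a),
    which are unchanged in cases when the candidate is the sole risk source.
    """
    if or_c <= 0:
        raise ValueError("or_c must be > 0")
    _check_polymorphic(hf)
    p_a, p_b = hf.p_a, hf.p_b
    q_a = case_frequency(p_a, or_c)
    q_b = q_a * (hf.h_ab / p_a) + (1.0 - q_a) * (hf.h_Ab / (1.0 - p_a))
    return _odds_ratio(q_b, p_b)


def implied_candidate_or(hf: HaplotypeFreqs, or_m: float) -> ImpliedOR:
    """Invert the forward model: the odds ratio the candidate would need to
    generate the observed marker odds ratio ``or_m``.

    Feasible iff the implied candidate case frequency q_a lies strictly in
    (0, 1); infeasibility ("not a candidate") is returned, not raised.
    Raises :class:`NoLDInformationError` when D = 0.
    """
    if or_m <= 0:
        raise ValueError("or_m must be > 0")
    _check_polymorphic(hf)
    p_a, p_b = hf.p_a, hf.p_b
    cond_b_given_a = hf.h_ab / p_a
    cond_b_given_A = hf.h_Ab / (1.0 - p_a)
    denom = cond_b_given_a - cond_b_given_A
    if abs(denom) < 1e-12:
        raise NoLDInformationError("D = 0: candidate uninformative for marker")
    q_b = case_frequency(p_b, or_m)
    q_a = (q_b - cond_b_given_A) / denom
    if not (0.0 < q_a < 1.0):
        return ImpliedOR(feasible=False, value=None, q_a=q_a)
    return ImpliedOR(feasible=True, value=_odds_ratio(q_a, p_a), q_a=q_a)


def haplotype_freqs_from_panel(panel, snp_candidate: str, snp_marker: str,
                               risk_allele_candidate: int = 1,
                               risk_allele_marker: int = 1) -> HaplotypeFreqs:
    """Joint haplotype frequencies by direct counting over a phased panel.

    ``risk_allele_*`` select which 0/1 panel code is the risk ("lowercase")
    allele for each SNP.
    """
    col_a = panel.column(snp_candidate)
    col_b = panel.column(snp_marker)
    a = col_a == risk_allele_candidate
    b = col_b == risk_allele_marker
    n = float(len(a))
    return HaplotypeFreqs(
        h_AB=float(np.sum(~a & ~b)) / n,
        h_Ab=float(np.sum(~a & b)) / n,
        h_aB=float(np.sum(a & ~b)) / n,
        h_ab=float(np.sum(a & b)) / n,
    )


def estimate_allelic_or(case_alleles: np.ndarray,
                        control_alleles: np.ndarray) -> tuple[float, float, float]:
    """Allelic odds ratio from 0/1 allele arrays with a Woolf 95% CI.

    Returns (or_hat, ci_low, ci_high); adds 0.5 to each cell if any is zero.
    """
    a = float(np.sum(case_alleles == 1))
    b = float(np.sum(case_alleles == 0))
    c = float(np.sum(control_alleles == 1))
    d = float(np.sum(control_alleles == 0))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_hat = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (or_hat, or_hat * math.exp(-1.959963984540054 * se),
            or_hat * math.exp(1.959963984540054 * se))
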