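"""Implied odds ratio at a candidate SNP from a marker's association.

A GWAS marker is usually not the mechanism variant; it tags one through
linkage disequilibrium.  Given the two-SNP haplotype frequencies and the
marker's observed case/control odds ratio, the engine computes the odds
ratio the candidate would need at its own alleles to generate that marker
association — the acceptance criterion for candidate SNPs.
"""

from mechanista import (HaplotypeFreqs, forward_marker_or,
                        implied_candidate_or, ld_stats)

# joint haplotype frequencies: h_AB, h_Ab, h_aB, h_ab
# (lowercase = risk alleles; first letter candidate, second marker)
hf = HaplotypeFreqs(0.5, 0.2, 0.1, 0.2)
stats = ld_stats(hf)
print(f"candidate risk-allele frequency p_a = {hf.p_a:.2f}, "
      f"marker p_b = {hf.p_b:.2f}")
print(f"D = {stats.D:.3f}, D' = {stats.D_prime:.4f}, r^2 = {stats.r2:.4f}")

# forward: a candidate with allelic OR 3.0 produces this marker OR
or_m = forward_marker_or(hf, 3.0)
print(f"candidate OR 3.0 -> marker OR {or_m:.3f}")

# inverse: observing marker OR 1.5, the candidate would need OR 3.0
res = implied_candidate_or(hf, 1.5)
print(f"marker OR 1.5 -> implied candidate OR {res.value:.3f} "
      f"(feasible={res.feasible})")

# weak LD cannot explain a strong marker signal: infeasible, not an error
weak = HaplotypeFreqs(0.48, 0.21, 0.20, 0.11)
res = implied_candidate_or(weak, 5.0)
print(f"weak LD (r^2 = {ld_stats(weak).r2:.4f}), marker OR 5.0 -> "
      f"feasible={res.feasible} (implied case frequency {res.q_a:.2f} "
      "is impossible)")

# The attenuation direction: incomplete LD dilutes signal, so the implied
# candidate OR is always at least the marker OR.
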