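"""The linear sensitivity model linking protein activity to phenotype.

A variant changes the in-vivo activity of gene product i by a fraction
dA_i; the phenotype parameter q responds as dP_q = sum_i S_iq * dA_i,
with S_iq a dimensionless sensitivity coefficient.  Worked numbers: the
MSP missense variant associated with Crohn's disease reduces interaction
with the RON receptor about five fold, and the homozygous-genotype disease
odds ratio at the locus is 1.84.
"""

from mechanista import (delta_a_from_fold, delta_p_from_or, linear_phenotype,
                        selection_threshold, sensitivity_coefficient)

delta_a = delta_a_from_fold(5, gain=False)
delta_p = delta_p_from_or(1.84)
s = sensitivity_coefficient(delta_p, delta_a)
print(f"five-fold loss of activity      -> dA = {delta_a:+.2f}")
print(f"genotype odds ratio 1.84        -> dP = {delta_p:+.2f}")
print(f"sensitivity coefficient S       =  dP/|dA| = {s:.3f}  (~1: risk "
      "tracks activity one-to-one)")

# several perturbed genes combine linearly
combined = linear_phenotype([s, 0.5], [delta_a, -0.2])
print(f"two perturbed genes             -> dP_total = {combined:+.3f}")

# drift dominates selection below 1/(2 Ne)
thr = selection_threshold(10_000)
print(f"selection threshold at Ne=10^4  -> |s| > {thr:g} to be operative")
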