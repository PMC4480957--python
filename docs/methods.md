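# Methods

## Scope and model

The pipeline assigns local molecular mechanisms to GWAS disease loci.  Its
unit of inference is the *locus*: a representative marker SNP plus the set
of nearby SNPs whose LD relationship to the marker is compatible with the
observed association.  Mechanism evidence (missense impact labels, splice
score changes, eQTL study tables) is attached to candidates, never
inferred from sequence: the impact predictors and the splice scorer are
upstream tools whose outputs are inputs here, and literature-derived
relevance categories (A/B/C/D) are input labels.  The pipeline's own
contributions are the LD algebra, the filters, the aggregation rules and
the enrichment test.

### Implied odds ratio

All LD computation is two-SNP.  Haplotype frequencies are counted directly
from a phased panel, with the candidate risk allele oriented so that
D = h_ab − p_a·p_b ≥ 0 (the allele positively associated with the marker
risk allele; the only orientation consistent with a shared risk
mechanism).  The forward model assumes a multiplicative per-allele odds
model at the candidate, controls approximating the population (rare
disease), and case haplotypes preserving the candidate→marker allele
conditionals; under these assumptions both directions of the
candidate↔marker odds-ratio map are closed-form, and the inverse is exact
(round-trip identity holds to 1e−9 over randomized feasible instances).
Infeasibility of the inverse (implied candidate case frequency outside
(0, 1)) is a regular rejection outcome.  Odds ratios are treated as
allelic throughout; genotypic ORs are never converted, only declared via
the `or_scale` config field so misuse is explicit.  D = 0 and monomorphic
SNPs raise typed errors.

### Filters and aggregation

Marker intake uses strict p-value thresholds by source (5.0e−7 for the
primary scan, 1e−5 for catalog markers); boundary values are dropped.
Candidate enumeration is boundary-inclusive at ±200 kb and MAF 0.05.
Several markers within one window merge into a single locus keyed by the
lowest-p marker.  Accepted candidates define the locus extent; a locus
with no accepted candidate is a point at the marker.

An r² floor (default 0.2) augments the bare feasibility rule: without it,
very weak LD admits candidates with wildly amplified implied ORs.  Setting
the floor to 0 restores the literal feasibility-only rule.

Missense high/low collapse at locus level with high taking precedence, so
a locus carries at most four mechanism types (missense, expression,
auxiliary splice, direct splice).  A SNP that is both missense and an
auxiliary-splice candidate yields two calls: calls are evidence, not a
partition.  Locus relevance categories follow precedence A > B > C;
MHC-region loci are reported separately as category D (default interval:
the conventional extended-MHC bounds chr6:28,477,797–33,448,354,
config-overridable).

### Splice rules

Direct splice-site hits are purely positional and applied at internal
junctions only, in transcription order (mirrored on the minus strand):
the first two and last two intron bases, the last three exon bases on the
donor side and the first exon base on the acceptor side.  Terminal exon
edges (no flanking intron) are deliberately not sites.  Auxiliary-splice
flags compare an input score change against the threshold of the
signed-distance interval containing the record (≥ at equality flags;
distances outside every configured interval are counted as warnings and
never flagged).  The shipped default is a single full-range interval at
threshold 0.0 — a placeholder that must be replaced with calibrated
values for real use; the synthetic scenario sets its own three-donor /
four-acceptor interval layout (0.35–0.55) as synthetic calibration.

### Consensus eQTLs

Per gene, reporting markers are clustered under the relation {identical
OR r² > 0.8}; clusters supported by ≥ 2 distinct studies become consensus
eQTLs.  Single-linkage clustering is the default because the pairwise
wording of the linkage rule is ambiguous for three or more markers; a
complete-linkage mode is a config switch.  Direction conflicts between
studies flag but do not disqualify a consensus.  Matching to a disease
marker is by identity or nearest-member genetic distance ≤ 0.05 cM,
piecewise-linearly interpolated from the genetic map (out-of-range
positions clamp to the end anchors, counted as warnings; cross-chromosome
distances are errors).

### Enrichment

The two-sided Fisher test uses the probability-mass criterion (sum of
hypergeometric probabilities ≤ that of the observed table), computed in
exact integer arithmetic over the common denominator C(N, r1) and
returned as a `fractions.Fraction`, so results are reproducible
bit-for-bit and free of cancellation for any realistic table size.  No
multiple-testing correction is applied to the per-mechanism p-values.

### Sensitivity model

δP = OR − 1; an n-fold loss gives δA = 1/n − 1 (gain: n − 1); S = δP/|δA|
by default (the worked-example convention), with a signed mode available;
multi-gene effects combine linearly as δP_q = Σ S_iq δA_i.  The linear
form is a local approximation: curvature and epistatic terms are outside
scope.  The drift threshold is 1/(2Nₑ).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not human genetics:

* **LD construction** is by symmetric allele flipping: the marker column
  is the causal column flipped with probability ε, solved (Brent's
  method) so the expected r² equals the target.  This controls two-SNP LD
  exactly but produces no haplotype blocks, no allele-frequency spectrum,
  and no recombination-map structure.
* **Cohorts** are sampled retrospectively (case/control-conditional), the
  GWAS design: case causal alleles at the case frequency implied by the
  per-allele odds model, remaining haplotypes drawn conditional on the
  causal allele, controls straight from the panel (prevalence, default
  0.01, matters only if control correction is enabled in future work).
* **Default scenario** (the study conditions for recovery checks):
  20 loci on separate chromosomes, one planted mechanism each, cycling
  the five classes; n_hap = 1000; causal frequency ~ U(0.15, 0.45);
  target r²(marker, causal) = 0.8; causal allelic OR 1.8; 30 neutral SNPs
  within ±150 kb plus two beyond ±200 kb (window negative controls); one
  three-exon gene per locus; linear 1 cM/Mb map; four eQTL studies.
  Negative controls are planted so recovery is only exact if the filters
  work: an unreplicated eQTL on each high-missense locus and a
  sub-threshold splice record on each low-missense locus.

Passing recovery tests on this scenario shows the machinery is correct
under its own assumptions; it says nothing about performance on real
panels with extended haplotype structure, allelic heterogeneity, multiple
causal signals per locus, or noisy annotation labels — none of which are
modelled.

## Numerical choices

* Coordinates are 0-based half-open in memory; file readers/writers are
  the only conversion point (VCF/GFF3/MAP/marker-TSV 1-based, BED12 native
  0-based half-open).
* Haplotype frequency vectors must sum to 1 within 1e−9; implied-OR
  inversion treats |Δconditionals| < 1e−12 as D = 0.
* Determinism: every generator takes an explicit seed; manifests contain
  the full config and seed and nothing volatile, and equal manifests give
  byte-identical outputs (enforced by test).
* Problem sizes in tests (panel sizes 100–10,000 haplotypes, cohorts up
  to 50,000/50,000, 200 simulation replicates, exhaustive Fisher sweep to
  N = 60) were chosen as the smallest scales at which the targeted
  stochastic properties are stable.

## Known limitations

* Two-SNP LD only: no imputation, no multi-SNP haplotypes, no conditional
  dissection of loci with several independent signals.
* Genotypic↔allelic OR conversion is intentionally not attempted.
* One transcript per gene; transcript selection is the caller's problem.
* Trans/remote expression effects, tissue specificity, epigenetics and
  environmental terms are out of scope.
* The upper tail of implied ORs is unbounded: no plausibility cap is
  applied beyond the r² floor.
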