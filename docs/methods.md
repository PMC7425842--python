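# Methods

## Population model and simulation

Each STR marker carries a population allele-frequency distribution.
Founders are drawn under Hardy–Weinberg equilibrium (two independent
allele draws per locus); children receive one uniformly chosen allele
from each parent.  Loci are treated as unlinked and statistically
independent — the standard assumption for CODIS-era autosomal kinship
calculation, and adequate for these panels, whose markers sit on
different chromosomes or far apart.  Scenarios are gene-dropped from
the minimal pedigree (e.g. first cousins descend from one shared
grandparental couple) and only the individuals tested in casework are
retained.  The trio "related" scenario assumes the mother and father
are themselves unrelated founders; related-parent trios, wrongly stated
relationships, X/Y markers, linkage, silent alleles and genotyping
error (dropout) are out of scope, though any simulated truth can be
paired with any tested hypothesis via the `tested=` argument of the
samplers.

## Likelihood ratios

Pairwise LRs condition on the IBD state with coefficients
(k₀, k₁, k₂); the one-IBD term conditions on which allele of the first
genotype is the IBD copy (probability ½ each) and requires the other
allele of the second genotype to be a population draw.  Trio paternity
indices enumerate maternal/paternal assignments of the child's alleles
consistent with the mother; the numerator uses Mendelian transmission
from the alleged father, the denominator a population draw for the
paternal allele.  If the mother is incompatible with the child at a
locus (possible only under mutation or when testing arbitrary
genotypes), that locus falls back to the motherless parent–child duo
LR between child and alleged father rather than contributing a
spurious zero through the untested maternal link.

Per-locus LRs are multiplied in log10 space; a combined LR of exactly 0
(any locus excluded) is tracked with a separate mask so thresholds and
histograms treat it correctly.  All LR kernels exist twice: a scalar
reference implementation and a vectorised numpy version used for
Monte-Carlo runs; the test suite asserts their equality to 1e-12 on
exhaustive genotype grids, and both against an independent
brute-force enumeration over ordered allele draws.

One analytic note: the trio PI does *not* reduce to the motherless duo
LR merely because the mother is uninformative-looking (mother aa,
child ab gives PI = T_AF(b)/p_b, while the duo LR averages over which
child allele is paternal, (T_AF(a)/p_a + T_AF(b)/p_b)/2).  The two
coincide only in symmetric configurations; the tests pin the exact
closed forms.

## Mutation

Two independent switches, both off by default:

* **LR side** (`MutationPolicy.mode`): `STRICT_ZERO` treats any
  Mendelian incompatibility as a hard exclusion (locus LR 0).
  `RATE_FLOOR` replaces a zero transmission probability with an
  aggregate per-meiosis rate μ (default 0.002, the order of observed
  STR mutation rates), applied to trio transmissions and the one-IBD
  term of pairwise LRs; the two-IBD identity term is not floored (a
  double-mutation event, below μ² and below this model's resolution).
* **Simulation side** (`simulate_mutations`): each transmitted allele
  mutates with probability μ by one step on the marker's numerically
  sorted allele ladder, up or down with equal probability, reflecting
  at the ladder ends.  This requires numeric allele labels (repeat
  counts, including intermediates like 9.3 — a "step" is to the
  neighbouring ladder allele).

The default (both off) is the most parsimonious reading of
threshold-based error-rate studies; the switches exist for sensitivity
analysis.

## Synthetic allele frequencies

Published forensic frequency tables are inputs (CSV
`marker,allele,frequency`; per-marker sums in [0.99, 1.01] are
renormalised, matching tables rounded to 3–4 decimals).  Because no
population table ships with the package, the generator draws, per
marker, an allele count uniform in [5, 15] and frequencies from a
symmetric Dirichlet with concentration 1.0.  For Dirichlet(α) with K
alleles the expected homozygosity is (α+1)/(Kα+1), so these defaults
give expected heterozygosities of about 0.67–0.88 (mean ≈ 0.79 over a
15-marker panel), matching real CODIS-era panels.  What the generator
does **not** emulate: the skewed, ladder-shaped frequency profiles of
specific real loci, population substructure (θ = 0 throughout; no
Balding–Nichols correction), and intermediate alleles.  Consequently
absolute error rates on synthetic frequencies differ from published
per-kit values — our synthetic 15-marker panel is somewhat more
informative than the real kit (e.g. a lower parent–child false negative
rate at LR ≥ 100) — and only the qualitative structure transfers:
ordering of error rates by relatedness, threshold trade-offs, the
effect of panel size, and the binary/ternary comparison.  Those are
what the acceptance tests assert; published per-cell rates enter the
caseload projection as printed inputs.

## Decision policies and rates

Inclusion at LR ≥ t_incl; ternary exclusion at LR ≤ t_excl with the
open interval in between inconclusive (an inconclusive range stated as
0.01 < LR < 100 makes boundary LRs decisions, not inconclusives).
Binary false negatives count every related case not called inclusion;
ternary false negatives count only related cases called exclusion —
the two conventions bracket the possible readings of survey-style
policies.  False positives are unrelated cases called inclusion in
either mode.  Rates carry binomial standard errors √(p(1−p)/n) so
scaled-down runs are interpretable.  LR histograms use decades of LR
from 10⁻¹⁰ to 10¹⁰ with open tails and a dedicated LR = 0 bin.

Monte-Carlo runs stream in batches (memory independent of `n_sims`)
with independent seeded RNG streams per arm.  Default study size in
the tests and the acceptance script is 10⁵ replicates per arm (chosen
as the point where binomial SEs are small against every asserted
effect); the generating study this package models used 10⁷.  The exact
oracle enumerates all joint genotype configurations (pairwise
relationships, panels with ≤ 10⁷ joint outcomes), weighting each by
its probability under the IBD-state mixture and under unrelatedness.

## Caseload projection

Expected false interpretations per (case type, arm, threshold) cell:
`total_cases × casetype share × related (or unrelated) fraction ×
laboratory share × false rate`, rounded half away from zero — the
convention that reproduces every cell of the published worldwide table
(e.g. 9.555 → 10, 1.47 → 1, 7.7 → 8).  The 72%/28% related/unrelated
split is applied uniformly across case types, mirroring the published
model's simplification even though true exclusion rates surely differ
by type.  Full-sibling laboratories without a threshold (80%) report
an LR only and contribute no decision cells.  The grand total is
reported both as the rounded sum of unrounded cells (62,408 for the
15-marker preset) and as the sum of the rounded rows (62,409); both
exceed 60,000.  A 21-marker projection is the same machinery with a
different rates input.

## Numerical and design notes

* Genotypes are stored in canonical order (numeric-aware label sort);
  all LR formulas are symmetric in allele order.
* Threshold comparisons in the vectorised path are done in log10; at
  LR exactly on a threshold this agrees with the linear comparison
  whenever log10(t) is exactly representable (t = 100, 1000, …).
* Dirichlet draws are floored at 1e-8 and renormalised so no allele
  has zero mass.
* Observed limitation: at a fixed absolute threshold, adding markers
  widens the null log-LR distribution faster than it shifts its mean
  for weak hypotheses, so the half-sibling *false positive* rate can
  rise slightly from 15 to 21 markers even as every false negative
  rate falls; the panel-size improvement asserted in the tests is for
  the trio / parent–child / full-sibling case types, where both rates
  improve.
* Imputing decisions for no-threshold laboratories was considered and
  rejected: they render no decision, so they contribute no expected
  false interpretations.
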