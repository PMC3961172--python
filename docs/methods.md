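# Methods

## Problem and estimand

For an affected proband, define the *inter-lineage relative risk* at
ancestor depth *g* as the disease risk in the maternal-line ancestor
(mother at *g* = 1, maternal grandmother at *g* = 2, ...), normalized to the
population risk for that sex, divided by the corresponding quantity for the
sex-matched paternal-side ancestor. Grandmother comparisons (MM vs FM) are
sex-matched, so they need no population normalizer; mother-vs-father
comparisons do.

With family-history data, the estimator is the matched-pair odds ratio from
*discordant* families — those where exactly one of the two sex-matched
grandparents is affected. If `a` families are maternal-only and `b`
paternal-only, `OR = a/b`, the 95% CI is Wald on the log scale with
`SE = sqrt(1/a + 1/b)`, and the p-value is the exact binomial probability of
`a` in `a+b` trials at ½, doubled smaller tail, capped at 1. Concordant
families (neither/both affected) carry no information about asymmetry and
enter only descriptive rates. The doubling rule is deliberately simple and
conservative; with `a = 2727`, `b = 2320` it gives p ≈ 1.1e-8 and the CI
(1.112, 1.242), matching the published values after rounding.

The packaged fixture reproduces the published stratified counts exactly.
Note the source abstract quotes 5,091 discordant families while the
published table's discordant columns sum to 5,047 (2,727 + 2,320); this
package reproduces the table-based count and makes no attempt to reconcile
the abstract's figure.

## Genotype algebra

All analytic results assume a rare outcome, one di-allelic autosomal locus,
random mating, Mendelian inheritance and HWE, no linkage disequilibrium
with other risk loci. Genotypes are variant-allele counts ordered (0, 1, 2).

The transmission matrix

```
V(q) = [ 1-q      q      0
        (1-q)/2   1/2    q/2
         0        1-q    q  ]
```

is the conditional genotype distribution of a parent — equivalently, of an
offspring — of an index person with the row's allele count, valid whenever
that relative's genotype is not itself risk-relevant to the conditioning
event. One of the relative's alleles is a uniformly chosen copy of the
index person's two; the other is a population draw at frequency q. `V` has
eigenvalues (1, ½, 0), so the HWE vector is stationary and any departure
from HWE halves per generation from the first step onward. That spectral
fact yields two exact laws used as test oracles:

- **halving law**: `RR_{g+1} − 1 = (RR_g − 1)/2` for maternal-effect models,
  any penetrance vector (log-additive or dominant), any q;
- **overlay law**: the imprinting parent curve coincides with the
  maternal-effect grandparent curve at equal effect size and q.

`V` is computed in closed form; the test suite re-derives it by brute-force
enumeration of the nine HWE mating types at several q, to 1e-12. Input
distributions are validated to 1e-9 and renormalized silently within that
tolerance (guarding drift under repeated propagation); the degenerate
frequencies q ∈ {0, 1} keep the stated closed forms so curve generation is
total.

## Mechanism models

Risk enters only as relative multipliers of an unspecified baseline
lifetime risk; under the rare-disease assumption the baseline cancels from
every ratio, so it appears nowhere in the analytic layer.

**Maternal effect** (q, S1, S2; default S2 = S1², the log-additive model).
The mother of a case has genotype distribution ∝ HWE(q) ∘ (1, S1, S2).
Her depth-g maternal-line ancestor's own risk is driven by *that ancestor's
mother's* genotype — one extra V-propagation beyond the ancestor — so

```
RR_g = E[S under md·V^g] / E[S under HWE(q)],   md = mother-given-affected.
```

Both causative (S1 > 1) and protective (S1 < 1) alleles push the
maternal-lineage RR above 1: whichever allele raises risk is the one
enriched in the maternal line.

**Imprinting** (q, I, expressed copy; maternal is the worked case). A
child's expected multiplier given the mother's genotype is
(1, (1+I)/2, I). The depth-g ancestor's own maternally inherited allele is
the variant with probability π_g = p1/2 + p2 of her genotype distribution
(md propagated g−1 steps); her relative risk is
`[(1−π_g) + π_g·I] / [(1−q) + q·I]`. The probability ½ that a
heterozygote's variant copy is maternal is independent of conditioning on
descendants' disease (single locus, random mating) — verified by the
simulator. A paternally expressed locus is the mirror image: the
maternal/paternal RR is the reciprocal of the maternal-case value.

**Mitochondrial** (R, carrier frequency). Along an unbroken female line
every ancestor shares the proband's mitochondria, so the excess does not
attenuate with generation; any ancestor reached through a male returns to
the population risk. The quoted inter-lineage RR (`interlineage_rr` returns
R) is the matriline risk ratio *in families whose case lineage carries the
variant*, exact in the rare-haplogroup limit; at carrier frequency c the
exact conditional value is `R / (1 + c(R−1))` (`matriline_carrier_or`).
An important caveat the exact algebra makes visible: *without* conditioning
on carriage, the population-level grandmother OR induced by a mitochondrial
variant is only `1 + c(R−1)²/(1 + c(R−1))²` — about 1.01 for R = 1.3 at
c = 0.1 — because affection only weakly certifies carriage. A mitochondrial
variant of modest effect therefore cannot, by itself, produce a
population-level family-history OR of 1.2–1.3; the mechanism's signature is
the *non-attenuation* of whatever excess is present along female lines, and
the simulator's mitochondrial checks condition on the case matriline
carrying the variant accordingly.

**Sibling recurrence** (maternal effect only). Full siblings and maternal
half-siblings share the risk-relevant mother: RR = E[S²]/E[S]² over her HWE
genotype. Paternal half-siblings have independent mothers: RR = 1. At
q = 0.07, S1 = 4 (log-additive) the full-sister RR is 1.9605 — the familiar
two-fold sister risk.

**Inversion.** `invert` solves effect size from a target RR by Brent's
method on [1, 1e6]; the map is strictly increasing there (below 1 it folds
back, so inversion is restricted to targets ≥ 1). Imprinting RRs are
bounded above in I (e.g. < 2 at q = 0.2 for grandparents), so unreachable
targets raise a clear error rather than returning the bracket edge.

**A reference-point discrepancy.** The exact algebra gives a grandparent RR
of 1.2396 for a maternal effect with S1 = 4 at allele frequency 0.10
(S1 ≈ 4.5 would be needed for 1.30), while 1.28 obtains at frequency 0.20.
Published prose quoting "about 4.0" for an asymmetry of "about 1.3" at
frequency 10% appears to mix these reference points; the package exposes
both computations and treats neither as privileged.

## Synthetic cohorts

`famasym.simulate` generates four-generation families: eight
great-grandparent founders, four grandparents, two parents, and
`n_sisters` (default 2) full sisters. Defaults define the study conditions:
baseline lifetime risk f = 0.01 (a rare outcome, keeping the rare-disease
algebra accurate), allele frequency per scenario, mitochondrial haplogroup
frequency 0.1 (a typical common-haplogroup frequency), sister-matched
ascertainment, no paternity errors. Two sisters is the smallest sibship
satisfying ascertainment and sidesteps the family-size ascertainment bias
that larger sibships would introduce (deliberately out of scope).

Choices that matter:

- **Founder risk under a maternal effect** uses a latent mother genotype
  drawn from the V-row conditional on the founder's own genotype, making
  founder risk consistent with an infinite HWE ancestry.
- **Paternity errors** replace the transmitted paternal allele with a
  random population male's draw, per child; the recorded pedigree is
  unchanged. Because the maternal-effect, maternal-imprinting and
  mitochondrial signals travel entirely through maternal links,
  misattributed paternity does *not* attenuate their grandmother OR — the
  attenuation property is exercised with a paternally expressed imprinted
  locus, where the signal crosses the father link.
- **Disease is a lifetime indicator**; no age structure is simulated, so
  simulated strata are a single label and the stratified age pattern of the
  real data has no synthetic counterpart.
- **Randomness**: one seeded numpy generator, drawing member-by-member in a
  fixed order, so runs are exactly reproducible for a given
  (seed, configuration); the cohort is stored as per-role arrays and
  materialized into `Pedigree` objects lazily.
- **Result verification on independent cohorts**: retrospective (looking up
  from cases) and prospective (looking down from affected progenitors)
  estimates share normalizers when computed on one cohort, which would make
  their equality partly tautological; the equality checks therefore compare
  estimates from independently seeded cohorts.

What passing simulation tests do show: the analytic RRs are the correct
large-sample limits of the ascertained discordant-pair ORs under the
mechanism models. What they do not show: robustness to reporting bias,
differential knowledge of maternal vs paternal relatives, estrangement,
family-size-dependent ascertainment, age structure, heteroplasmy or
multi-locus effects — all absent from the generator by design.

## Problem sizes and tolerances

Unit simulation checks use 2×10⁵–4×10⁵ families; the acceptance-level
simulation checks use 5×10⁵ families per mechanism and assert agreement
within 3 Monte Carlo standard errors computed from realized discordant
counts (`sqrt(1/a + 1/b)` on the log OR). At f = 0.01 these bands are wide
(a few hundred discordant pairs per 5×10⁵ families); the acceptance script
tightens them by accumulating discordant counts over chunked cohorts of
6×10⁶ families per nuclear mechanism and 3×10⁷ for the mitochondrial
comparison, whose carrier-conditioned pairs are sparsest. Algebraic laws are asserted to
1e-9–1e-12; inversion round-trips to 1e-6; exact-rational results
(1.28125, 1.1975…) to 1e-9. Zero discordant cells report an undefined CI
with an explicit flag unless the Haldane–Anscombe +½ correction is
requested; nothing is silently imputed. Families contributing two
discordant grandparent pairs (possible when both sexes are informative) are
handled by within-cluster resampling: one pair per family per resample, the
estimate is the mean log-OR, and the variance is the mean within-resample
Wald variance minus the between-resample variance.
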