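# Methods

This note records the statistical model behind each stage, the defaults and
why they are what they are, what the synthetic-data generator does and does
not emulate, and the numerical choices that would otherwise be invisible.

## Exact 2×2 inference

All variant-, gene- and pathway-level tests reduce to a 2×2 table
(exposed/unexposed × case/control) with exposure counted at allele level for
variant tests and at carrier level for collapsed tests.

**Two-sided p-value.** `fisher_two_tailed` implements the point-probability
rule: conditioning on the margins, the p-value is the sum of hypergeometric
point masses of all tables whose probability does not exceed that of the
observed table. Ties are detected with a 1e-12 relative tolerance on
log-probabilities; for the table sizes tested against the rational-arithmetic
oracle (margins ≤ 30) the minimum relative gap between two *distinct* point
masses is orders of magnitude larger, so the rule is effectively exact. When
every table is included the value is returned as exactly 1.0.

**Odds ratio.** The point estimate is the conditional MLE: the ψ solving
E<sub>ψ</sub>[X] = a under Fisher's noncentral hypergeometric distribution
with the observed margins. Confidence limits invert the exact conditional
test, putting (1 − level)/2 in each tail. Degenerate cells give one-sided
results: ψ̂ = ∞ when no control is exposed (lower bound finite, upper ∞) and
ψ̂ = 0 in the mirror case. Both are computed through
`scipy.stats.contingency.odds_ratio`; an independent noncentral-
hypergeometric inversion (bisection on the log-ψ scale) serves as the test
oracle. Root-finding is carried to near machine precision; statistical
software that inverts the same tails with loose root tolerances can disagree
in the third significant figure on extreme upper bounds (e.g. a table
(3, 235; 1, 2673) has exact upper 95% limit 1792.0; a solver with a ~1e-4
tolerance on the 1/ψ scale reports ≈1770), which matters for none of the
quantities this package asserts.

**Interval convention.** Intervals default to two-sided 95% (2.5% per tail);
the level is a parameter. Where legacy outputs label intervals "5–95%", the
printed bounds are consistent with the 95% two-sided convention, which is
why it is the default.

## Variant prioritization

Four stages in order: QC/manual-review flags (consumed as booleans, never
computed), recurrence (≥2 case carriers; variants with exactly one case
carrier are retained as singletons for gene-level tests only), rarity
(MAF < 1% in the local control cohort *and* the reference panel, each
comparison skipped when the frequency is missing — a variant with zero
frequency in all controls must survive, so absence of a panel record cannot
disqualify), predicted pathogenicity (nonsynonymous SNV with CADD phred
strictly > 20, or any of frameshift-indel / stop-gain / stop-loss /
start-loss regardless of score), and known-cancer-gene membership (≥2 of the
supplied source lists; comparisons strict). The three per-variant predicates
commute (property-tested); recurrence must run first only because it
consumes the genotype matrix. The cascade is idempotent.

## Dual-cohort association

Allele-level tables are built from case allele counts (2n = 238 at the
default discovery size) against (a) local control counts and (b) panel
counts. Panel-absent variants are assumed to have allele count zero with an
allele number linearly interpolated from the flanking valid panel sites when
the nearer one is within 300 nt (one-sided: that site's AN; interpolated
values rounded to the nearest even integer so they remain valid diploid
allele numbers; no site within 300 nt → untestable, excluded from that BH
family with a warning). BH adjustment is applied per comparison over the
variants actually tested in it. The shortlist takes variants with adjusted
p < q (default 0.10) *and* case frequency above control frequency in both
comparisons. The validation re-test re-runs the same machinery on the
shortlist only and reports raw p-values: a fixed hypothesis set forms no new
testing family.

## Gene burden

Collapsing is CMC-style: an individual is a gene carrier iff they carry ≥1
qualifying variant in the gene (qualifying = the cascade minus recurrence,
so singletons and control-only variants count). The carrier 2×2 table gets
the exact test above; the reported effect is the log carrier odds ratio with
a 0.5 Haldane–Anscombe correction when any cell is zero (the exact p needs
no correction). The effect is deliberately *not* a mixed-model coefficient:
kinship-adjusted score tests need the cohort's genotype-level relatedness,
which is outside this package's inputs, so the exact carrier test is the
engine and carrier counts are the comparable surface; mixed-model p-values
from other engines are not comparable and are not asserted anywhere.

**Depth control.** Cohorts sequenced on different platforms differ in
coverage; sites covered well in only one cohort produce one-sided carrier
artifacts. `depth_filter` removes variants below a per-cohort mean-depth
cutoff (default configuration filters only the control cohort, whose
platform differs from the cases'). `select_depth_cutoff` runs the burden
scan at each candidate cutoff, scores calibration by the squared Pearson
correlation between sorted observed −log₁₀ p and the uniform order-statistic
quantiles −log₁₀((i − 0.5)/m), and picks the *smallest* cutoff within a
tolerance (default 0.01) of the best R² — data are only sacrificed when
they demonstrably buy calibration. With fewer than 3 testable genes or a
constant p-vector the scan is degenerate; the orchestrator then falls back
to the most permissive candidate with a warning.

## Pathway analysis

Enrichment is the hypergeometric upper tail P(X ≥ k) for k significant
burden genes (raw p < 0.05 — an FDR-threshold would admit almost none)
falling in a pathway of K genes out of a universe of N. N is a required
parameter because it belongs to whatever knowledge base supplied the gene
sets; enrichment p-values are therefore only comparable within one universe
choice. The carrier odds ratio per pathway — individuals with ≥1 qualifying
variant in ≥1 pathway gene, tested with the exact 2×2 machinery — does not
depend on any universe and is the reproducible quantity.

## Co-segregation

Classification is a deterministic rule on genotyped members: *segregates*
iff all affected are carriers and no unaffected is; *contradicts* iff no
affected is a carrier or all unaffected are; *partial* otherwise;
*uninformative* without at least one genotyped member of each status.
Ungenotyped members are excluded and flagged. No penetrance model, LOD score
or phasing: with the small fully-genotyped sibships this targets, the rule
is the whole analysis.

## Synthetic cohorts

Defaults are the reference study conditions: 119 cases vs 1337 local
controls, 156 vs 9770 validation, panel of 9626 individuals. Per variant,
the control-population MAF is log-uniform on [1e-4, 5e-2]; control genotypes
are Binomial(2, MAF) (Hardy–Weinberg). Planted effects are parameterized by
the **carrier** odds ratio — the quantity both the variant shortlist and
the burden test act on — with case carrier probability
q₁ = OR·q₀ / (1 − q₀ + OR·q₀) for control carrier probability
q₀ = 1 − (1 − m)²; carriers are homozygous with the HWE conditional
probability m/(2 − m). Allele-level tables then follow from HWE within each
group. Panel allele counts are Binomial(AN, m) with AN jittered ±10% around
2·n_panel (rounded even); 5% of variants are withheld from the panel to
exercise the interpolation rule. CADD scores are two-component —
deleterious ~ N(25, 3), benign ~ N(8, 4), truncated at 0 — so the >20
threshold is informative but imperfect; 10% of variants are loss-of-function,
10% synonymous, and 30% of the remaining nonsynonymous variants are
deleterious. Per-variant mean depth is N(80, 15) in the case cohort and
N(55, 12) in the control cohort, truncated at 0 (distinct platforms,
control slightly shallower). Families are two ungenotyped parents plus
genotyped siblings; the planted variant is transmitted from a heterozygous
parent with probability 1/2 per child, optionally overridden to force or
break co-segregation. Default 200 variants in 40 genes keep replicated
experiments desk-sized while leaving every filter with work to do.

Not modelled: linkage disequilibrium, population structure or admixture,
relatedness beyond explicit pedigrees, sequencing error, genotype
missingness, and gene length variation. Passing tests on these cohorts
demonstrate that the machinery is wired and calibrated as designed — they
say nothing about confounding present in real cohorts (stratification,
batch effects, relatedness), which this pipeline controls only through the
depth cutoff and its input QC flags.

## Operating characteristics

`evaluation.null_false_discovery_proportion` simulates all-null cohorts
(defaults: 200 cases, 2000 controls, 500 variants, 50 replicates) and
reports the mean shortlist false-discovery proportion at q = 0.10; since
every rejection is false under the null, each cohort contributes 1 when
anything is shortlisted. The dual-comparison + direction requirement makes
the rule conservative (measured ≈0.02). `evaluation.planted_recovery_power`
measures end-to-end recovery (cascade → dual association → shortlist) of a
planted carrier-OR-10, MAF-0.005 variant at the discovery cohort sizes over
100 replicates (measured ≈0.88, acceptance bound ≥0.5). These sizes keep
each experiment under a minute on one CPU; both scale linearly if larger
replicate counts are wanted.

## Known limitations

- No mixed-model burden engine (see above); no SKAT-style weighted tests.
- No multi-allelic normalization/left-alignment beyond splitting records.
- Gene symbols are matched literally (trimmed, case-sensitive); no alias
  resolution.
- The enrichment universe is the caller's responsibility; none is bundled.
- Missing genotypes become non-carriers (tallied); with substantial
  missingness the carrier tests would be biased toward the null.
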