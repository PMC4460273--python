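# Methods

## Data model and conventions

The unit of data is the aggregated 2×3 case-control genotype count table
for a biallelic autosomal SNP. Genotype order is fixed as
(GG, AG, AA) = (baseline homozygote, heterozygote, risk homozygote) in every
file and API, which removes strand/allele-order ambiguity. Individual-level
formats (VCF/PLINK) are out of scope; published candidate-gene studies of
this kind report only the aggregated counts or summary odds ratios.

Printed output rounds percentages to 1 decimal and odds ratios and CI
bounds to 2 decimals; all internal computation is double precision with
z₀.₉₇₅ fixed at 1.959964.

## Per-genotype odds ratios

Each genotype contrast g ∈ {AG, AA} versus GG is a 2×2 subtable. The
effect is carried as a log odds ratio β_g with Woolf standard error
se = √(1/a + 1/b + 1/c + 1/d). Confidence intervals are
exp(β ± z₀.₉₇₅·se) and p-values are two-sided Wald. When any of the four
cells is zero the Haldane-Anscombe correction adds 0.5 to all four cells of
that contrast (policy selectable; `"none"` raises instead). The bundled AMD
table has no zero cells; the correction matters only for simulated studies
with rare risk homozygotes.

The exact 2×3 association test enumerates the full 2-degree-of-freedom
lattice of tables sharing the observed margins and sums the
multivariate-hypergeometric probabilities of every table no more probable
than the observed one (ties counted within 1e-7 relative tolerance;
log-factorials for stability). On the bundled AMD table it gives
p = 0.24499, agreeing with R's `fisher.test` to seven digits. A
Monte-Carlo fallback samples the same null for margins whose lattice
exceeds the configurable cell budget.

Summary-only studies are converted to log-scale estimates by recovering the
standard error from a 95 % CI (se = (ln hi − ln lo)/(2·z₀.₉₇₅)) or, failing
that, from a two-sided Wald p-value (se = |ln OR|/z). This makes published
tables usable as meta-analysis inputs without the raw counts.

## Recessive-model inference

**Difference test.** The recessive hypothesis (risk confined to AA) is
tested one-sided via d = β_AA − β_AG with
var(d) = se²_AA + se²_AG − 2·cov. The two log-ORs share the GG baseline
cells, so with counts available cov = 1/case_GG + 1/control_GG. For
summary-only inputs the covariance is unknowable and defaults to 0 with a
logged warning; since the shared-baseline correlation is positive, this
overstates var(d) and is conservative. On the bundled records the
summary-based tests give one-sided p = 0.011 (AD) and 0.013 (AMD), and the
count-based test on the 350/3781 study gives p = 0.092.

**Combined evidence.** The hypothesis that a variant affects neither of two
diseases is tested by the inverse-variance weighted mean of the homozygote
log-ORs: z = β̄·√(Σw). Two-sided by default (one-sided available); the
sidedness convention is a deliberate conservative choice.

**Genotype-class R².** Concordance of per-genotype ORs across diseases is
summarised by a one-way variance decomposition on the OR scale: the ORs
(baseline excluded) are grouped by genotype class and
R² = SS_between / SS_total about the grand mean — a one-way eta-squared.
This convention is named explicitly in output ("genotype-class
eta-squared") because several R²-like conventions exist; this is the one
under which the published concordance values (0.673 before, 0.978 after the
AMD meta-analysis update) are exactly recovered from the published ORs. It
is invariant to adding a constant to every OR and to disease relabelling,
and lies in [0, 1]; with all ORs identical it returns 1 with a degeneracy
flag.

**Per-allele mapping.** For a purely recessive effect (heterozygotes at
baseline), OR_N = f_N·(OR_NN − 1) + 1 and its exact inverse
OR_NN = (OR_N − 1)/f_N + 1. The mapping explains why additive GWAS tests
perceive strong recessive effects as weak: the per-allele OR shrinks
linearly with allele frequency.

## Meta-analysis

Fixed-effect pooling is inverse-variance on the log-OR scale; the headline
two-study AMD pooling uses summary estimates with standard errors recovered
from printed p-values, because one study's raw counts were never published.
Mantel-Haenszel pooling from per-study 2×2 counts (with the
Robins-Breslow-Greenland variance) is provided for count-complete
collections and agrees with inverse-variance pooling to < 0.01 on the OR
scale for large-count two-study collections. Random effects are
DerSimonian-Laird: τ² = max(0, (Q − df)/C), C = Σw − Σw²/Σw, truncated at
zero, in which case the result coincides with the fixed-effect one exactly.
Heterogeneity is reported as Cochran's Q (χ² with k−1 df) and
I² = max(0, (Q − df)/Q). Both poolers are cross-checked in the test suite
against statsmodels (`combine_effects`, `StratifiedTable`), which serves as
an independent oracle only.

When a study supplies both counts and summaries, counts win; a discrepancy
beyond 1e-6 on the log-OR is logged.

## Synthetic data

The generator draws the conditions the analyses assume. Controls come from
a reference genotype distribution: either Hardy-Weinberg proportions
((1−f)², 2f(1−f), f²) at a chosen risk-allele frequency, or the observed
control proportions of a real table. Case probabilities are the control
probabilities tilted by per-genotype odds ratios and renormalised —
exactly the case genotype distribution implied by those ORs against the GG
baseline. A study is a pair of independent trinomial draws, which is
distributionally identical to allocating genotypes to individuals one at a
time but vectorizable. Child seeds for study collections are spawned from
the master seed via numpy's `SeedSequence`, so collections are reproducible
independent of iteration order, and identical (model, sizes, seed) produce
byte-identical output files.

The default power model uses the observed control proportions of the
bundled 3781-control sample (0.6808, 0.2888, 0.0304) tilted by the AD
effect sizes (OR_AG = 1.06, OR_AA = 1.73); an HWE-at-f alternative is one
flag away. The generator emulates sampling variation only: no linkage
disequilibrium, covariates, ascertainment bias or genotyping error. Tests
passing on these data therefore validate the statistical machinery under
its own assumptions, not robustness to the messiness of real cohorts.

## Monte-Carlo power

Each iteration draws a study, computes β_AA with its Woolf standard error
(Haldane correction when any relevant cell is zero — such iterations are
corrected rather than discarded, since discarding would bias power upward
at small n; their count is reported), and declares success when
|β_AA|/se > z₁₋α/₂. Power is the success fraction with Monte-Carlo error
√(p(1−p)/reps). Two-study meta-analysis power simulates both studies per
iteration and tests the inverse-variance pooled z. `reps` defaults to
10,000; the bundled reproduction and acceptance runs use 20,000 to halve
the Monte-Carlo error. All engines are vectorised, so even 20,000
iterations complete in well under a second.

**Analytic oracle.** A closed-form approximation
power ≈ Φ(|ln OR_AA|/se_exp − z₁₋α/₂), with se_exp the Woolf SE at the
expected cell counts, serves as an independent check and seeds the
sample-size search. Its measured accuracy: within 0.04 of the simulated
power whenever every expected 2×2 cell is ≥ ~14, but it can overshoot by
up to 0.08 when expected cells sit in the 5–15 range (the Woolf SE at
*expected* counts understates the average simulated SE because
E[1/X] > 1/E[X], and the log-OR distribution is skewed at small counts).
The approximation also ignores the opposite rejection tail, so at
OR_AA = 1 it returns α/2.

**Calibration.** Under the null the test holds its nominal two-sided size
in the asymptotic regime (empirical size 0.050 at 2000/2000, f = 0.175) and
is conservative, never anti-conservative, when the expected AA cells are
sparse (size 0.038 at 300/300). This conservatism is inherent to the Wald
log-OR test at small expected counts.

**Sample-size search.** `required_cases` inverts the analytic formula for
an initial bracket, then bisects on the simulated power curve using common
random numbers (the same seed at every candidate n) so the search is
deterministic and the curve monotone up to shared noise. A known caveat
follows from the oracle's bias: for the bundled AMD configuration
(3781 controls, OR_AA = 1.73, target 80 %) the analytic inversion gives
≈ 729 cases while the simulated crossing sits near 810, because the true
finite-sample power of the Wald test at 735 cases is ≈ 0.77, not 0.80. The
package reports the simulated crossing; users wanting the cheaper
approximation can call the analytic inversion through `power_analytic`.

## Numerical and design notes

* Hardy-Weinberg testing defaults to the 1-df Pearson χ² without continuity
  correction; an exact mid-p variant (enumeration over heterozygote counts
  conditional on the allele counts) is available via `method="midp"` for
  sparse tables. On the bundled control sample the two give p = 0.95 and
  p = 0.98 respectively.
* The Fisher 2×3 enumeration iterates the two free case cells within margin
  bounds; the brute-force multivariate-hypergeometric summation used as its
  test oracle is written independently of this path.
* Degenerate inputs raise informative errors rather than returning NaN:
  all-zero count vectors, zero GG baselines for the shared covariance,
  OR = 1 in p-value-based SE recovery, unattainable power targets (the
  control sample puts a floor on the variance and hence a ceiling on
  power).
* Sidedness conventions: the recessive difference test is one-sided (the
  alternative is specifically d > 0); Wald, combined-evidence and pooled
  p-values are two-sided.

## Known limitations

* Crude (unadjusted) odds ratios only; no covariate-adjusted logistic
  regression.
* No genotype-level model selection beyond the recessive difference test
  (no MAX3 or model-free statistics).
* The binomial GLMM meta-regression variant of random-effects pooling is
  not implemented: it requires per-study counts that are unavailable for
  the summary-only study.
* Exact (mid-p) confidence intervals for odds ratios are not provided.
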