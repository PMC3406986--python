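# Methods

## The statistical model

A CSS panel consists of inbred lines: a host strain, a donor strain,
and consomic/congenic lines each carrying one donor chromosome (or a
centromeric/telomeric segment of one) on the host background.  Animals
within a line are genetically identical, so the model for a measurement
of trait *t* on animal *k* of strain *s* is

    y_sk = mu_s(t) + e_sk,    e_sk ~ N(0, sigma_t^2)

with all genetic signal concentrated in the strain means `mu_s`.  Every
statistic in the pipeline consumes per-strain summaries (mean, sample
SD with the n−1 denominator, n, SEM = SD/√n); per-animal records are
touched only when summarizing.  Sexes are never pooled: each
(trait, sex) pair is an independent analysis unit, matching how panel
surveys report male and female traits separately.  Congenic pairs
(centromeric/telomeric lines for one chromosome) are distinct test
units; no chromosome-level aggregation is performed.

## QTL detection

Each CSS is compared with the host by a two-sided unpaired t-test on
summary statistics.  The default is the Welch (unequal-variance) form
with Welch–Satterthwaite degrees of freedom — the safer choice when
strain variances differ and per-strain n is small (4–12 in real
surveys); a pooled-variance Student variant is available via
`method="pooled"` for exact replication against analyses that used it.
Significance is declared at a Bonferroni-corrected threshold
`alpha / m`, where `m` is by default the number of CSS lines actually
tested for the trait (data availability varies by trait in repository
data); `bonferroni="per_panel"` switches to the fixed panel size.  The
correction is across strains only, never across traits: each trait is
an independent genome survey.  `alpha` defaults to 0.05.

Degenerate inputs are defined, not improvised: two zero-variance groups
with equal means give t = 0, p = 1; with unequal means they raise an
error rather than fabricate an infinite statistic; any group with n < 2
is refused.

A trait is *monogenic*, *digenic* or *multigenic* according to whether
1, 2 or ≥ 3 CSSs are significant.  Effect-size, epistasis and
directionality analyses are restricted to traits whose parental strains
also differ significantly (uncorrected alpha, single comparison),
because the host–donor difference is the normalizing denominator.

## Effect normalization and error propagation

Conventional variance-component effect sizes are precluded by the CSS
design (no segregating population), so effects are expressed relative
to observable anchors:

* `NormUnit = 100 · (T_CSS − T_host)/(T_donor − T_host)` — percent of
  the parental difference; 0 at the host, 100 at the donor, negative
  away from the donor.
* `Hi_Low = 100 · (T_CSS − T_host)/(max − min of all strain means)` —
  percent of the panel's full phenotypic range, signed from the host.

NormUnit is invariant under affine rescaling of trait units and equals
100·r, where r is the directionality ratio below.  Its SEM is obtained
by the delta method with the three strain means independent (different
animals): with D = T_donor − T_host and N = T_CSS − T_host,

    SEM² = (100/D)² · [ sem_CSS² + sem_host²·(1 − N/D)² + sem_donor²·(N/D)² ].

A Monte-Carlo test confirms this matches the empirical SD of NormUnit
within 5% whenever all SEMs are below |D|/10 (the first-order validity
region).  The panel-level "average phenotypic effect" is the mean of
|NormUnit| over significant CSS–trait pairs — a magnitude, so
opposite-signed shifts do not cancel.

## The cumulative-effect epistasis test

For each qualifying trait (multigenic, parents differ) the signed
NormUnit effects are summed over three subsets — significant CSSs,
non-significant CSSs, and all combined — and the trait is flagged
epistatic when `|Σ| − SEM > 100%`.  Under additivity each chromosome
contributes its share of the parental gap and the combined sum should
approach 100%; sums of several hundred percent mean the same phenotypic
shift is produced repeatedly by different chromosomes, which only
epistasis in the intact genomes can reconcile.  The non-significant
subset is tested because many small same-direction effects can be
jointly significant even when individually undetectable.

The default SEM is the simple quadrature `√(Σ SEM_i²)`, the convention
of published panel analyses.  It understates the true sampling error of
the sum: all effects for one trait share the same host and donor means,
and the shared host term is coherent across the panel (its partial
derivatives add, giving a contribution that scales with the number of
strains rather than its square root).  A `covariance_aware=True` option
implements the full first-order propagation including the shared-parent
terms; simulations in the test suite show it matches the replicate SD
of cumulative sums within ~15%, while the quadrature SEM is roughly
3-fold too small on a 20-line panel with equal per-strain n.

A consequence worth stating explicitly: when the true cumulative effect
is exactly 100% — the additive case — the estimate is centred on the
decision boundary, so the flag rate does not vanish with sample size.
With exact error propagation it converges to about 1 − Φ(1) ≈ 16%, and
it is higher under the quadrature convention (~30% in our simulations
at n = 50/strain).  The rule is conservative only for traits whose true
cumulative effect is below 100% by a margin; on strongly epistatic
architectures (several hundred percent) it is effectively always
triggered, and that is the regime it is meant for.  For the same reason
the package's recovery checks (e.g. a true 800% cumulative effect
recovered within 2 SEMs) use the covariance-aware SEM, which is
calibrated; the flagging rule itself keeps the conventional quadrature
default.  Combined-subset aggregates are computed from the two subset
aggregates so the linearity identities (sum and variance additivity)
hold exactly in floating point.

## Directionality and boundaries

`r = (T_host − T_CSS)/(T_host − T_donor)` classifies each CSS–trait
shift: towards the donor (r > 0), away (r < 0), more extreme than the
donor (r > 1).  r = 0 (CSS exactly at the host mean) gets its own
`at_host` category rather than a forced sign; with continuous data its
probability is zero.  Relabelling host and donor maps r to 1 − r.
Summaries report percentages rounded half-away-from-zero at one decimal
(table convention) or integer precision (running-text convention); the
`percent` helper does this in exact integer arithmetic so decimal ties
round identically regardless of float representation.

The boundary (ceiling/floor) analysis compares strain *means*: the
parents bound the panel above/below when the max/min CSS mean lies
within the parental means, ties counting as bounded.  Incomplete panels
are projected to a complete one by
`avg_QTLs_per_trait · total_chromosomes / chromosomes_represented`,
with 22 substitutable mouse chromosomes (19 autosomes + X + Y + MT) as
the default total.

## Input handling

Phenotypes arrive as tidy CSV (`strain,trait,sex,animal,value`);
the panel layout as schema-validated JSON.  Validation is strict:
unknown strains, duplicate animal records, non-finite values and traits
without host data are errors, named specifically.  An optional IQR
outlier filter (remove outside [Q1 − k·IQR, Q3 + k·IQR], k = 3,
quartiles by linear interpolation between order statistics) is
implemented but **off by default**: with 4–12 animals per strain,
quartile-based trimming is unreliable and panel surveys have avoided
it.  Zero-IQR groups (a majority of identical values) are never
filtered — any finite k would delete every non-modal value.

## The synthetic generator

`SynthConfig`/`generate_panel` emulate the survey's statistical layer:
strain means at `mu_host`, `mu_host + delta` (donor), and
`mu_host + fraction_i · delta` per CSS, with i.i.d. Gaussian noise.
Defaults — 20 CSS lines, 10 animals per strain, noise SD at 20% of the
parental difference, 5 truly affected chromosomes per trait — mirror a
typical consomic survey, where most traits are measured on 8–12 animals
and a handful of chromosomes carry detectable effects.  When fractions
are not given explicitly they are drawn with magnitudes uniform on
[0.2, 1.0], signs positive (towards the donor) with probability
`towards_bias` (default 0.9, the strong donor-ward bias real panels
show), then rescaled so the signed sum equals `cumulative_target`
exactly (100% = additive; larger values build in epistasis).  Sign
draws are repeated (deterministically) until the raw sum shares the
target's sign and is not near-cancelled, so rescaling neither flips
nor explodes individual effects — a mild conditioning that slightly
favours majority-sign configurations.

Randomness descends from one seed; each strain draws from its own
deterministic substream, so adding a strain never changes the values of
existing strains.  Identical configs give bit-identical datasets.

What the generator does **not** emulate: genotypes and congenic
breakpoints (phenotype level only), within-strain genetic variance
(inbred lines have none), non-Gaussian noise, shared-environment and
batch effects, and correlations between traits.  Passing recovery tests
therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to real-data pathologies such as
heavy-tailed measurement error or litter effects.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations at: 1,000
replicate panels (20 lines, n = 10) for the null family-wise error
rate; 100 replicate panels (20 lines, n = 50) for effect-estimate bias;
n = 100/strain for cumulative-effect recovery; 60 replicate panels for
directionality-bias recovery — sizes at which Monte-Carlo error is a
few percent and the whole suite completes in seconds.  p-values come
from scipy's t distribution; quartiles from numpy's linear-interpolation
percentile; table percentages from exact integer rounding as above.

## Known limitations

* The pipeline treats all strains identically regardless of per-strain
  n; surveys with very unequal sample sizes inherit unequal power
  across chromosomes.
* The quadrature SEM convention for cumulative effects is kept as the
  default for comparability, despite understating the sampling error
  (see above); sensitivity analyses should use `covariance_aware=True`.
* "Number of QTLs" is a minimum-estimate convention (one per
  significant CSS); linked QTLs on one chromosome are not resolved.
* No multiple-testing correction across traits is applied anywhere, by
  design: the survey convention treats each trait as its own study.
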