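# Methods

## Data model

The unit of analysis is the unique (host species, virus) pair with its
**discovery year** — the earliest calendar year the virus was reported in
that host. Raw association tables carry one row per report (host taxonomy,
host status wild/domestic/laboratory, virus name and its taxonomic
resolution, detection method serology/PCR/isolation, year, source).
Ingestion validates rows (rejects are counted and logged, never silently
dropped), applies the analysis filters and collapses reports to pairs.

Filter conventions:

- **Resolution**: only taxonomically resolved virus names (ICTV-ratified or
  PREDICT-resolved) count toward richness; unresolved strain names would
  inflate it.
- **Host status**: wild species only; historical sampling intensity on
  domestic and laboratory animals would otherwise confound effort trends.
- **Window**: records after 2018 are excluded (reporting and taxonomic lag
  make the most recent years artificially sparse). Records *before* the
  1930 window start are kept for discovery-year computation — an early
  first report must not resurface as a post-1930 "discovery" — and series
  construction clips to the window.
- **Strict evidence**: each pair also carries its earliest
  PCR-or-isolation year (`strict_year`, missing for serology-only pairs).
  The snapshot regressions use this, so strict-evidence richness at year
  `t` is computed from strict-evidence reports up to `t`, not from
  any-evidence discovery years.

Counting conventions: at species level a discovery is a new pair; at
family/order/all level it is the first detection of a distinct virus within
the taxon (a virus found in a second member species is not a new
order-level discovery). Name matching is whitespace-normalized and
case-insensitive; display forms and taxonomy keys resolve to the
lexicographic minimum across contributing records, making deduplication
idempotent and invariant to input order.

## Trend model

Annual counts `y_t` are fitted with a penalized B-spline regression on the
log scale, basis dimension 20 (clamped below the series length), penalty
weight chosen by AIC over a 25-point log-spaced grid from ~unpenalized to
effectively linear. AIC here plays the role of UBRE for known-scale count
families — the standard criterion for such smooths; the underlying GAM
machinery exposes no restricted-likelihood criterion, and its generalized
cross-validation statistic is computed on the working-response scale and
degenerates on count data (it decreases monotonically with the penalty), so
it cannot be used. For one-dimensional smooths the B-spline/difference
penalty basis is statistically equivalent to thin-plate bases; the contract
is the penalized-likelihood fit, not the basis name.

Family: Poisson by default; `auto` switches to negative binomial (NB2) when
the Pearson dispersion of the Poisson fit exceeds 1.5 — overdispersion is
expected for heavily surveilled taxa whose yearly counts mix quiet years
with campaign-driven spikes. The NB dispersion is estimated by an outer
method-of-moments iteration on the Pearson statistic (at most 5 rounds; the
penalty weight is re-selected on the first round and held fixed after,
since moment updates barely move it), with a fixed-dispersion override.

Derivative and classification: the first derivative of the linear predictor
is computed by central finite differences (step 0.1 year; one-sided at the
boundary years, where evaluation points are clipped to the observed range).
Its pointwise 95% interval is the 2.5/97.5 percentile band over 10 000
multivariate-normal draws from the penalized coefficient posterior, seeded
explicitly. A year is *increasing* when the interval lies above zero,
*decreasing* when below, *none* otherwise; maximal runs of equal class form
the reported periods. Sign classification is identical on the link and
response scales. Intervals are pointwise, not simultaneous: under a
constant rate, a few percent of years are expected to misclassify, and the
calibration test budgets [0, 10%] around the nominal 5% level.

In the forced high-penalty limit the smooth collapses onto the log-linear
Poisson GLM; fitted predictor, derivative and derivative CI then agree with
the closed-form delta-method GLM results to < 1e-3, which is tested.

## Rank stability

For a fixed universe of taxa — those with ≥ 1 virus by the reference year
(2018); zeros backfilled for years before a taxon's first sampling — the
stability curve is Spearman's ρ (mid-ranks for ties) between richness at
each historical year and at the reference. The fixed-universe convention
keeps `n` constant along a curve, matching how these curves are reported;
the alternative (only-sampled-taxa) is available via the `universe` /
`species_universe` arguments. A constant historical snapshot (typically all
zeros) has undefined ρ and is reported as missing, never coerced to 0 —
early-year sparsity should be visible as a gap, not a fake value.
Within-order species curves require ≥ 10 member species with reference
richness ≥ 1; below that, rank correlations are not meaningful. Ties are
consequential here (historical snapshots are zero-heavy), hence the
explicit mid-rank convention, cross-checked against a hand-rolled mid-rank
Pearson oracle to 1e-12.

At family/order level two metrics are supported: **total** richness
(distinct-virus union over member species) and **mean species-level**
richness (arithmetic mean of member species' totals over the fixed species
universe). The mean-species metric is much more effort-sensitive, since a
surveillance campaign on a few member species moves it immediately.

## Snapshot regressions

At each snapshot year: order-level viral richness (strict evidence, records
≤ year), cumulative citations ≤ year, and fixed described-species counts
per order. The model is NB2 `viral_richness ~ log(S) + log(1 + C)` with a
free citation coefficient ("adjusting for" effort, not offsetting it; an
offset would force a unit elasticity). Citations enter as `log(1 + C)`
because zero-citation orders occur in early snapshots. The dispersion is
estimated by maximum likelihood, started from the Poisson solution plus a
moment estimate (cold starts fail on roughly half of small-n datasets);
Newton, BFGS and Nelder–Mead are tried in turn, and the model falls back to
a Poisson GLM with a logged warning only if all fail. Only the log-S slope
needs a finite standard error — a constant citation column (legal input) is
collinear with the intercept and leaves its own SE undefined. Detection is
declared when the Wald 95% CI on the log-S coefficient lies above zero.
Sweep failures at individual years are logged and reported, never fatal to
the other years.

## Synthetic discovery process

Per species `s` and year `t`: effort
`e(s,t) = base(t) × order weight × active shock multipliers`; events ~
Poisson(e); each event discovers a uniformly chosen not-yet-found virus
from the species' pool with probability 0.3, otherwise re-detects a known
virus (emitting the duplicate records that exercise deduplication);
citations ~ Poisson(2·e). Detection methods and (per-virus, fixed) taxonomic
resolutions are drawn from configurable mixes. Each order owns a virus pool
whose size interpolates between the sum (sharing 0) and the maximum
(sharing 1) of member species' true richness, default 0.5; species pools
are uniform subsets, so taxon-level distinct-virus unions genuinely differ
from summed species richness. A single generator seeded once drives
everything; runs are byte-identical given the config.

**Default world** (`default_config`): the eight best-sampled orders with
wild species counts as in the real record (1252 species), NB true richness
mean 80 / dispersion 0.5, exponential base effort 0.01·e^(0.05·(t−1930)),
and a ×5 bat-targeted shock from 2003. The richness scale is set so only
~5–15% of a typical species' virome is described by 2018 — rarefaction
studies put the described fraction of even well-sampled species' viromes in
single digits, and an effort shock only destabilizes rankings if it hits an
incomplete inventory. Total discovered pairs land in the thousands,
matching the order of magnitude of the real wild-mammal record.

**Test regimes**: *proportional* (equal constant effort, no shocks —
rankings should be stable), *shock* (one order ×10 from 2000; large pools,
for the reason above), *saturating* (logistic effort, inflection 1995,
small pools — discovery rises, peaks and declines as inventories complete,
timed so the decline is in progress over the final 15 years where an
asymptote test must see it). A lightweight generator
(`simulate_order_snapshots`) produces 17-order snapshot tables with a known
species-richness slope for regression parameter-recovery tests.

What the simulator does **not** emulate: phylogenetic or geographic
structure, virus sharing across orders, reporting lag, detection-method
evolution over time, or any calibration to the real database's parameter
values. A green pipeline test therefore establishes correctness of the
computations and the qualitative effort-bias mechanisms, not quantitative
agreement with the real record's numbers.

## Numerical choices & degenerate inputs

- All-zero count series and series shorter than 10 years are rejected, as
  are smoothing steps ≤ 0 and derivative draw counts < 100.
- Posterior draws use a Cholesky factor with a 1e-12 diagonal jitter
  (high-penalty covariances are near-singular by construction).
- Spearman ρ of a constant vector is NaN, with an explicit pre-check.
- Snapshot GLMs require ≥ 6 orders, positive species richness, and
  non-constant viral richness.
- The year-validity envelope for records is [1900, 2100]; the analysis
  window defaults to [1930, 2018].

## Known limitations

- Derivative CIs are pointwise; whole-curve claims about a period's
  significance inherit the usual multiplicity caveat.
- AIC-based penalty selection can undersmooth very sparse series (few
  species, counts mostly 0–2), producing short spurious trend periods; the
  calibration test bounds the per-year false-classification rate, not the
  period count.
- The NB snapshot GLM at n ≈ 17 orders is fragile by nature; the Poisson
  fallback slightly narrows CIs when it triggers.
- `curve_summary` reports the most recent threshold crossing; for
  non-monotone curves earlier crossings are not enumerated.
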