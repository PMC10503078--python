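# Methods

This note documents the model implemented by `cherisk`, the choices made
where the published description leaves the design open, and the limits of
what the packaged inputs and synthetic data can show.

## The estimand

For a (country, service) pair, the quantity modeled is the **risk of
catastrophic health expenditure conditional on having the disease** the
service treats: the probability that a person with the condition ends up
paying, out of pocket, more than a threshold fraction τ ∈ {0.10, 0.25,
0.40} of their annual income.  Prevalence is deliberately out of scope —
every simulated individual has the condition — as are multi-episode and
multi-year accumulation, household composition, non-medical and indirect
costs, insurance design, and impoverishment metrics.

## Income model

Incomes are gamma distributed.  Two published country indicators pin the
distribution down uniquely:

* mean: GNI per capita in 2016 USD (`shape × scale = GNI`, exact by
  construction);
* inequality: the Gini index, using the closed form for a gamma
  distribution `G(k) = Γ(k + ½)/(Γ(k + 1)√π)`, which is strictly
  decreasing in the shape k.

Calibration inverts `G` by Brent root-finding on k ∈ [1e-3, 1e4]
(achievable Gini ≈ 0.006–0.9998) to |ΔG| ≤ 1e-10.  The test suite checks
the closed form against independent numerical integration of the gamma
Lorenz curve `L(p) = F_{k+1}(F_k^{-1}(p))` to 1e-6, and verifies on all 34
packaged countries that 10⁶ draws recover the target Gini within 0.005 and
the mean within 0.5%.

GNI per capita is treated as individual annual income: no household-size
equivalence adjustment is applied, and income stands in for consumption
expenditure.  Both are simplifications inherited from the data (only GNI
and Gini are available for all country-years).

Wealth quintiles are assigned by sorting incomes and splitting into fifths;
the individual at sorted index i (0-based, n incomes) falls in quintile
⌊5i/n⌋ + 1, ties keeping stable input order.  For n not divisible by 5
this floor rule makes quintile sizes differ by at most one (e.g. sizes
(2, 1, 2, 1, 1) at n = 7).

## Simulation engine

Per replicate: draw n = 1000 incomes, sort (which is the quintile
assignment), draw service use as independent Bernoulli(u_q) per individual,
charge utilizers `unit cost × OOP share`, and flag CHE where the payment
**strictly exceeds** τ × income ("exceeds" is read literally; boundary
equality is not catastrophic).  Risks are means over 1000 replicates;
`mc_stderr` is the standard deviation of per-replicate proportions divided
by √replicates.  Denominators always include non-utilizers: the risk is
conditional on disease, not on care-seeking.

Numerical implementation: because each replicate's incomes are sorted, the
CHE set at threshold τ is the first `#(income < payment/τ)` columns, so
per-quintile CHE counts reduce to cumulative-sum lookups of the utilization
mask — no per-threshold re-simulation.  This also guarantees *exact*
threshold monotonicity (risk at 40% ≤ 25% ≤ 10% in every cell) since all
thresholds share one set of draws.

Randomness is organized as named streams: every (country, service) cell
derives its generator from the root seed plus CRC-32 hashes of its
identifiers, so results are independent of iteration order and of which
subset of cells is run, and reruns are bit-identical.  By default one
income panel per (country, replicate) is shared across that country's
services (utilization is redrawn per service); the marginal distribution of
every cell is unchanged, and a config flag (`reuse_income_panel=False`)
switches to fully independent panels per cell.  Whether the original
analysis resampled incomes per service cannot be determined; both draws are
resampled across replicates here.

### Analytic oracle

`analytic_che_risk` computes the same estimand in closed form.  With
F the gamma CDF and c = payment/τ, quintile q occupies the probability band
[(q−1)/5, q/5], so its infinite-population risk is
`u_q × (min(F(c), q/5) − min(F(c), (q−1)/5)) × 5`.  At finite n this band
formula is biased wherever n·F(c) lies within a few √(n F(1−F)) of a
quintile edge: the count below c is B ~ Binomial(n, F), and its spread
smears individuals across the boundary (at n = 1000, F = 0.3935 the Q2
risk is 0.950, not the band value 0.967).  The oracle therefore also
offers the exact finite-population expectation,
`E[min(B, b)] − E[min(B, a)]` per position band, which is what the
equivalence tests compare the simulation against.  Comparisons are made on
the Monte-Carlo standard-error scale with a suite-level calibrated rule
(a handful of ~3 SE excursions among hundreds of comparisons is what
chance produces; systematic errors register at tens of SE).

## Input handling

* **Country table** (packaged): 34 countries with income group, region,
  NHA year, GNI per capita and Gini.  Gini is accepted on the percent
  (values ≥ 2, divided by 100) or fraction scale; 1 < value < 2 is
  rejected as ambiguous.  A missing Gini is filled with the unweighted
  regional average of the other study countries and flagged.
* **Service catalog** (packaged): 29 primary-care services, each with LI
  and LMI unit costs (2016 USD) and a disease-area mapping shipped as an
  editable CSV column (the mapping is many-to-one and user-overridable;
  each disease area belongs to exactly one broad group, which the loader
  enforces).
* **OOP shares and utilization**: loaded per (country, disease) and
  (country, service, quintile).  Pairs required by the catalog but absent
  from the tables are added as missing, then filled by unweighted
  same-region, same-key regional averages (imputation is idempotent and
  flagged with the donor region).  A utilization row known only as a flat
  rate is expanded with the country's average wealth-quintile gradient
  (mean-one normalized, clipped to [0, 1]); when a country has no
  empirical five-value row the gradient falls back region → global →
  uniform.
* **Currency**: packaged values are already 2016 USD; a converter is
  provided for other inputs (FX to USD first, then US-CPI deflation to
  2016).

## Aggregation and scenarios

Cell risks average **unweighted over all contributing country × service
cells** per disease, service or disease group ("pooled"); a two-stage
country-first mean is available (`mode="country_first"`) because the
original tables' weighting cannot be determined from their description —
the mode used is recorded in the run manifest.  Rendering rounds half-up
to one decimal on the percent scale, only at display time; the
`x.x (y.y)` cells parse back to the rounded fractions.

Financing scenarios override the OOP share of selected services and re-run
under the baseline seed, so per-cell reductions are exact differences (no
Monte-Carlo contamination) and scenario risk can never exceed baseline
when the share is reduced.

## Synthetic inputs

Country- and disease-specific OOP shares and quintile utilization proxies
have no published table, so `cherisk.synth` emulates their structure:

* OOP shares ~ Beta with disease-level means (defaults 0.10–0.60, ordered
  NCDs > infectious > childhood/reproductive; concentration 12).  The
  ordering is qualitative and illustrative — it reflects which disease
  groups are typically publicly subsidized — and is **not** fitted to any
  country's accounts.
* Utilization `u_q = expit(base + slope × (q − 3))` with per-service slope
  ≥ 0 drawn from [0, 0.6] and country-level logit noise (sd 0.75) around a
  base rate of expit(−1) ≈ 0.27: monotone non-decreasing wealth gradients
  by construction.  Real survey gradients need not be monotone;
  `nonmonotone_noise_sd` adds logit noise to emulate that.
* Optional synthetic country profiles stay inside the observed study
  ranges (GNI: LI $230–903, LMI $1081–3508; Gini 0.296–0.54).
* Missing cells are injected at a configurable rate to exercise the
  imputation path.

Consequently, pipeline runs on the fixture bundle demonstrate *structural*
properties — equity gradients, threshold monotonicity, scenario dominance,
determinism — not numeric reproduction of any published disease-level
aggregate, which would require the unpublished country inputs.  Headline
quantities that depend only on the packaged tables (the lowest-cost
services under upper-bound 100% share/utilization assumptions) are
recomputed by `scripts/acceptance.py` at the full 1000 × 1000 setting; the
test suite runs the same engine at reduced sizes (typically 500 × 120–150,
plus one full-size fixture run) to keep the default suite under a minute
apart from the full-scale checks.

## Known limitations

* The gamma family cannot represent bimodal or heavy-tailed (Pareto-like)
  income distributions; at high Gini (≥ 0.5) it places several percent of
  mass below a few dollars per year, which makes even sub-dollar payments
  register non-zero CHE risk in the poorest quintile under full
  utilization.
* One payment per person per year: chronic care requiring repeat visits is
  understated.
* OOP shares are national, disease-level aggregates applied equally to all
  quintiles; pro-poor exemption schemes would shift risk toward middle
  quintiles.
* Imputation by unweighted regional means ignores within-region
  heterogeneity and country size.
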