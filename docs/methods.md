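# Methods

## The surveillance model

`rarelens` compares two independent views of a rare-disease panel observed
over several calendar years:

* a **search system** — a stream of search-engine queries, from which the
  per-disease *search popularity* p_{d,y} = q_{d,y}/Q_y is computed
  (q_{d,y}: queries in year y containing one of disease d's keywords;
  Q_y: all queries that year), and projected to a *search-estimated patient
  count* N̂_{d,y} = p_{d,y}·P_y under the assumption that searchers are a
  random sample of the population P_y;
* a **case system** — a registry of confirmed cases C_{d,y} reported per
  disease and year.

Absolute patient numbers in the two systems carry different, year-varying
systemic biases, so they are not compared directly.  Instead each year's
diseases are ranked 1..D by patient count within each system (rank 1 =
largest), and the per-disease **ranking difference**

δ_{d,y} = r^S_{d,y} − r^C_{d,y}

is coded into a **ranking-difference group (RDG)** by a cutoff τ (default
20): group 0 for δ < −τ (the disease looms much larger in search than in
the registry), group 1 for |δ| ≤ τ (agreement to within τ positions),
group 2 for δ > τ.  Both interval endpoints belong to group 1.

Concordance between the systems is summarised by blocking diseases into
consecutive groups of `block_size` (default 20) by search rank, taking each
block's mean case rank, and correlating (Pearson) block mean search ranks
against block mean case ranks within each year.  Inter-year stability is
summarised by the adjacent-year intersections of each RDG's member set, by
top-k persistence (diseases in the top k of a system in *every* year), and
by a generalized linear model

RDG ~ C(year) + C(disease_group),

a Gaussian identity-link fit (ordinary least squares) on the numeric codes
of all D × Y disease-years.  The disease factor is collapsed to the three
RDG levels each disease occupied in a baseline year (default: the earliest),
both to match how the grouping is reported and to keep the design
well-conditioned.  Factors use **sum-to-zero (effects) coding**: each
level's coefficient is its deviation from the grand mean, the intercept is
the grand mean under balance, and the omitted contrast of each factor is
reconstructed as minus the sum of the others with its standard error taken
from the coefficient covariance (1ᵀΣ1), so every level is reported.
z = β/SE and p-values are two-sided normal tails.  Small year coefficients
relative to disease-group coefficients indicate that the relation between
the two rankings is stable over time.

Finally each disease is assigned one collapsed RDG code — by default the
majority code across years, ties resolved by the most recent tied year; a
baseline-year policy is available — and classified: **category 2** if the
collapsed code is 0 (high search rank, low registry rank: publicity
inflation and/or under-diagnosis suspected, searchers worth mining for
undiagnosed patients), **category 1** otherwise (the registry is considered
relatively comprehensive and can anchor predictive models).

## The synthetic scenario

Real query logs and registry extracts of this kind are proprietary, so the
package ships a seeded generator with the structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `n_diseases` | 120 | panel size |
| `years` | 2016–2019 | study window |
| `population` | ≈1.0e7/yr | persons at risk (a panel; see below) |
| `prevalence_logmu, _logsigma` | −11.51, 1.6 | log-normal prevalence (median ≈1e-5 cases/person, heavy cross-disease tail) |
| `search_rate` | 2.0 | expected queries per true patient per year |
| `publicity_spike_prob` | 0.10 | per disease-year chance of an attention spike |
| `publicity_spike_scale` | 6.0 | query inflation under a spike |
| `reporting_alpha, _beta` | 1.5, 3.5 | Beta law of per-disease reporting rate ρ (mean ≈0.3, wide spread) |
| `background_queries` | 100 000/yr | non-disease noise lines |

True patients are T_{d,y} = round(prevalence_d · P_y); expected queries
q̄_{d,y} = search_rate · T_{d,y} · π_{d,y} with publicity multiplier π = 1
except in spike disease-years; expected cases C̄_{d,y} = ρ_d · T_{d,y}.
Emitted files draw Poisson(q̄) matching log lines (each embedding exactly
one keyword of one disease in a short query template) and Binomial(T, ρ)
registry counts; background lines are screened against the lexicon so they
can never match.  Every random stream derives from the single scenario seed
through fixed `SeedSequence` spawn keys (prevalence 0, publicity 1,
reporting 2, lexicon 3, search_log 4, registry 5), so adding a stream never
perturbs the others, and identical configurations produce byte-identical
files.

The noise-free expectations are exposed as a ground-truth oracle: running
the ranking comparison on (q̄, C̄) defines `truth_rdg`, and applying the
classification rule to the first year's noise-free code defines
`truth_category`.  Tests verify that feeding the expected counts through
the live pipeline reproduces both exactly.

**Scale.** Popularity and ranks are invariant to rescaling all counts and
the population together, so the default scenario uses a ~10-million-person
panel rather than a national population; this keeps a full run (≈750 k log
lines) under ten seconds on one CPU while preserving the ranking structure.
The consequence is that absolute estimated-patient totals are illustrative,
not calibrated to any national figure.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: user-level structure (sessions, repeat searchers,
regional mix), genuine natural-language query variety (three fixed
templates per keyword), correlated reporting and publicity (drawn
independently here), secular trends in search behaviour, and search-engine
market-share effects.  The Poisson/Binomial count laws are stand-ins; the
real data's dispersion structure is unknown.

With these defaults, the per-disease log-scale distortions (Beta reporting
noise on the case side, occasional six-fold publicity spikes and Poisson
noise on the search side) are small against the 1.6-log-sd prevalence
spread, so most diseases move fewer than 20 rank positions between systems:
across seeds, 58–74 % of disease-years fall in RDG 1 with both tails
populated, the regime the analysis is designed for, while the grouped
Pearson correlations stay near 0.98.

## Numerical and design choices

* **Matching** is normalized substring containment: NFKC, casefold,
  whitespace collapse; a keyword matches anywhere inside the query.  Real
  queries append terms ("… symptoms"), so whole-query equality would
  discard most disease traffic; an `exact` mode exists for sensitivity
  analysis.  A query matching k diseases increments all k counts but the
  year total once; repeated identical queries count separately (the
  estimator is event-based).  The matcher pre-compiles a prefix-tree regex
  over all keywords as a rejection filter, keeping the per-line cost near
  linear; tallying is a single streaming pass with memory independent of
  log length.
* **Ties** in ranking are broken by ascending disease id after the
  descending value sort, so ranks are always strict permutations — required
  by exact blocks of 20 and set-valued RDG membership.  A final block
  smaller than `block_size` is retained, not merged.
* **Popularity** keeps N̂ as a real number internally; only reports round.
  A year with zero total queries raises an error naming the year.
* **GLM**: the design is checked for full column rank before fitting; a
  factor level with no members is dropped with a warning; a single-level
  factor contributes no contrasts.  With fewer than two blocks the Pearson
  correlation is reported as NaN with a warning rather than an error.
* **Problem sizes in tests**: oracle suites use 8 random instances with
  D ≤ 10 and 3–4 years; GLM parameter recovery uses 20 panels of 480
  observations; the end-to-end suite runs the full default scenario once
  and reuses it.

## Known limitations

The patient estimate inherits the random-sampling assumption wholesale: no
market-share, demographic or intent correction is applied, so N̂ is a
relative index, trustworthy only through ranks.  The classification
watches one tail (code 0); a disease the registry over-represents
relative to search lands in category 1 by design.  The GLM treats ordinal
RDG codes as numeric — adequate for effect-size comparison between year
and disease factors, not for probability statements about group
membership.  Chinese-language analysis is limited to NFKC-normalized
substring matching; no word segmentation or pinyin handling is attempted.
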