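# Methods

This note documents the generative model, the processing rules, the
permutation tests, and the numerical and design choices behind them.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time and units

All times are integer seconds from a study epoch (sunrise of day 1).
A 24-h cycle holds a 12-h day (in-roost) followed by a 12-h night
(foraging); day `d` is `[(d-1)·86400, (d-1)·86400 + 43200)` and night
`d` the remainder.  Nights are when foraging bouts happen.  Real sunset
and sunrise times are not needed for any of the inference, so the
day/night boundary is a config value rather than an astronomical one.

## The synthetic colony

The generator exists so that every downstream stage can be tested
against known ground truth; its defaults describe a 50-bat study
(27 never-captive controls, 17 previously captive adults, 6 captive-born
daughters) over 9 nights.

**Latent relationships.**  Dyadic cooperative-relationship weights are
`w_ij ~ Beta(mu*kappa, (1-mu)*kappa)` with mean `mu = 0.1` and
concentration `kappa = 1`.  One knob (`kappa`) controls social
differentiation — the quantity the differentiation test must detect;
`kappa -> inf` collapses all dyads to the mean (the no-differentiation
limit).  Grooming and food-sharing rates for the captive subset are
log-normal multiplicative distortions of `w` (sd 0.5 on the log scale),
i.e. noisy monotone transforms.  Kinship is 0.5 for each captive-born
daughter with her mother and zero elsewhere by default; it is an input,
not an estimated quantity.

**Departures and bouts.**  Bat `i` of type `T` departs on night `d` at
`m_T + drift·(d-1) + b_i + e_id` seconds after sunset, with
`b_i ~ N(0, sigma_b[T]^2)` and `e_id ~ N(0, sigma_w[T]^2)`.  Defaults:
`m_T` = 8.3 h for controls, 1.6 h earlier for previously captive bats,
2 h earlier for captive-born; `drift` = 840 s/night (departures about
14 minutes later each night).  Because *unadjusted* repeatability counts
the shared drift as within-individual variance (over 9 nights it adds
`(840 · sd(0..8))^2 ≈ 4.7e6 s^2`), the between-bat defaults are set from
the variance algebra to yield unadjusted ICCs of roughly 0.58 / 0.21 / 0
by type; simulation confirms means of about 0.54 / 0.18 / 0.06 (the
truncated-at-zero estimator has positive bias when the true value is 0).
Departures within a night are jittered apart by at least 6 s.  Bout
durations are normal per type around 2.5 h with their own two variance
components (targeting duration ICCs of roughly 0.54 / 0.35 / 0.15); a
configurable set of bats (all captive-born plus three previously captive
by default) leaves the roost for good after a mid-study night.

**Night reunions.**  For each clock hour in which two bats' bouts
overlap by at least 2 s, a foraging encounter occurs with probability
`p = 1 - exp(-lambda0 · exp(beta_r·w_ij + beta_k·k_ij))` — a
complementary-log-log link, chosen because it keeps probabilities valid
for any coefficients; the field data identify no particular link, so
any monotone one is admissible and this choice is recorded here.
Defaults `lambda0 = 0.02`, `beta_r = 4`, `beta_k = 1.5` put per-dyad
hourly co-foraging counts in the 0–15 range actually observed in field
data of this design, with strong pairs reuniting in a large fraction of
their shared hours.  Encounter durations are a mixture of a 1-s point
mass and a log-normal tail truncated at 30 minutes; kin dyads draw from
the tail more often, so their encounters run longer.  A small fraction
of reunions is generated at the roost entrance (a concurrent roost
base-station contact) or just after a departure, specifically to
exercise the exclusion rules; ground-truth context labels ride along in
a `true_context` column that processing code never reads.

**In-roost association.**  By day, a dyad meets with probability
`1 - exp(-(0.8 + 3·w_ij))` and, given a meeting, spends a
Gamma-distributed fraction of the day in association with mean
`0.02 + 0.25·w_ij`; a relationship-increasing fraction is re-emitted at
close-contact signal level.  By night, bats still inside the roost
associate with their neighbours in departure order (and, after
returning, in return order) — the roost cluster is whoever is currently
present.  This matters for detection: it produces the associate-count
collapse at each departure and the rise at each return.

**Captive co-feeding.**  Hourly feeder observations over 70 nights ×
15 h: each captive bat attends an hour with probability 0.3 (optionally
heterogeneous across bats on the logit scale — the confounding scenario
in which raw co-feeding counts reflect shared feeder time rather than
preference), and an attending dyad co-feeds with probability
`0.005 · exp(1.5·w_ij)` (set the exponent's coefficient to zero for the
identity-independent null).  Defaults give about 100–200 events with
per-dyad counts spanning 0–6.

**What the generator does not emulate.**  No spatial movement, no
acoustic behaviour, no prey or environmental covariates, no sensor
dropout or clock drift, and independence of hours given the bout
structure (real reunions may be serially dependent within a night).
Passing tests therefore demonstrate that the *inference machinery* is
correct and calibrated under a faithful opportunity structure — not that
any particular field dataset satisfies the generator's assumptions.

## Sensor processing

* **Durations**: encounters shorter than two successive 2-s beacons are
  recorded as 1 s; longer ones are rounded to whole seconds.
* **Proximity classes**: two nested signal thresholds define
  `association` (~50 cm) and `close_contact` (~2 cm).  Thresholds are
  inputs in raw signal units (sensor calibration is out of scope), and
  boundaries are inclusive so tie handling is deterministic.
* **Bout detection**: candidate bouts are gaps of at least 300 s in a
  bat's merged roost-station coverage, after dropping roost contacts
  shorter than 600 s (blips from passing the roost entrance must not
  split a bout — they are instead what the near-roost exclusion rule
  catches).  A departure is confirmed when the bat's distinct-associate
  count falls from at least `many` (default 4) to at most `few`
  (default 3) within the gap's first 300 s; returns are confirmed
  symmetrically.  The `many` reference level is evaluated in a 120-s
  trailing window with a 3600-s lookback fallback: the night's last
  departers have no tagged associates left within two minutes, yet their
  count did collapse from many — the lookback captures exactly that.
  A bat with no roost contact at all is flagged, never silently bouted.
  A trailing gap that never ends is a censored bout.
* **Context labels**: an encounter is `foraging` iff, for each bat
  separately, it starts more than 60 s after that bat's departure and
  ends more than 60 s before its return, and neither bat has a
  roost-station contact overlapping it.  The margin rule is applied
  before the roost-contact rule, mirroring the order in which the field
  filtering was described.  Everything not inside both bats' bouts is
  `roosting`.  The four labels partition the stream; context counts
  always sum to the input count.

## Networks

Roosting edges are rates: summed roosting-context association (or
close-contact) seconds divided by the dyad's co-presence seconds from
roost-station records, per day or aggregated (the aggregate equals the
co-presence-weighted mean of the daily rates by construction).  Only
daytime encounters enter these networks.  Dyads never co-present are
structurally missing, not zero, and are dropped from vectorized
regressions.  Foraging responses are total foraging seconds and the
number of distinct nights with an encounter.  Hourly co-foraging marks a
dyad at most once per clock hour (an encounter spanning a boundary
belongs to its start hour); a bat is "outside" in an hour if a bout
overlaps it by at least 1 s.  Degree centrality counts distinct partners
per period; a period with no encounters is missing, never zero, and a
bat's summary is the mean over non-missing periods.  Degree is
binary-partner by default (summed edge weight available behind a flag).

## Permutation inference

All tests share the add-one p-value convention
`p = (1 + #{tail exceedances}) / (1 + n_perm)`, so `p = 0` is impossible
and the floor is `1/(1+n_perm)`; two-sided p doubles the smaller tail,
capped at 1.  Identical seeds give identical null draws everywhere.

**Social differentiation.**  Statistic: CV (sample SD over mean) of
per-dyad co-foraging totals over every dyad with at least one shared
outside-hour.  Null: each marked (night, hour, dyad) record
independently has one randomly chosen member replaced by a uniformly
random *other* bat outside in that same night and hour (the kept member
is excluded; with fewer than three bats outside the record has no
freedom and stays put).  Rewritten records that collide on the same
(hour, dyad) collapse to one mark — the statistic is defined on
presence/absence per hour, and without the collapse the null CV is
systematically inflated.  Inference is one-tailed on the raw CV's rank;
the centered statistic (observed minus null median) is reported
alongside because the null's location is dataset-dependent.  Calibration
note: because the null keeps one member of every record, null draws are
positively correlated with the observed configuration, which makes the
test mildly *conservative* on very short studies where per-dyad
opportunity is heterogeneous (rejection ~0.02 at nominal 0.05 with
4-night colonies); at the 9-night design the measured type-I error is
~0.04.  The error never exceeds nominal in any regime we measured.

**Co-feeding.**  Within-hour identity permutation relabels, per hour and
per draw, the identities of the bats seen that hour; event counts follow
their labels.  The double permutation test subtracts each dyad's median
null count from its observed count (removing what shared feeder time
explains) and then tests the adjusted matrix against a predictor with
node-label permutations.  With sparse counts the median is a coarse
(integer-ish) location estimate, so under identity-independent
generation the adjusted values are centered near — not exactly at —
zero; the calibration test bounds the mean adjusted value by 10% of the
mean dyadic count, and the de-confounding test verifies that adjustment
collapses the spurious correlation with shared feeder time.

**QAP / MRQAP.**  Coefficients are OLS on the vectorized non-missing
dyads of the aggregate response.  The constrained null draws one
independent relabelling per period, uniform over the bats *present* in
that period (absent bats are fixed points, so no draw ever moves a bat
into a period it missed), applies it to that period's response layer,
re-aggregates, and refits; predictors are held fixed (the standard QAP
convention).  With an unstratified response this reduces to whole-matrix
node-label permutation.  For covariate-controlled runs on aggregate
matrices, double semi-partialling permutes the focal predictor's
residuals given the other predictors.  A condition-number guard
(>1e10) rejects collinear designs.

**Paired day-to-night regression.**  For each day, a simple QAP of that
night's foraging layer on that day's roosting layer over the bats
present in both; days with fewer than three shared bats are skipped and
reported.  The mean slope's uncertainty comes from a nonparametric
bootstrap resampling *days* as units (5,000 draws, percentile CI — no
CI method is canonical here, and the percentile method keeps the
day-level exchangeability assumption explicit).

**Centrality consistency.**  The slope of nightly foraging degree on
mean daytime roosting degree is estimated with night effects absorbed
(both variables centered within night).  Night-level centering was
chosen over bat-level intercepts deliberately: the predictor is constant
within bat, so within-bat centering would annihilate it exactly; within-
night centering matches the permutation strata and equals the
mixed-model fixed-effect slope in the small-random-intercept limit.
The null permutes foraging degrees among the bats observed each night.
The p-value is one-tailed with a *fixed* greater tail (the hypothesized
positive consistency), computed as a rank within the null distribution —
whose center is away from zero, because bats that are out longer meet
more partners in both contexts even under the null.  Choosing the tail
adaptively from the observed side would double the type-I error
(measured ~0.09 vs ~0.05) and is not done.

**Mantel test.**  Pearson correlation of vectorized non-missing dyads,
null from whole-matrix node-label permutations of the second matrix.

**Repeatability.**  Unadjusted ICC from one-way ANOVA method-of-moments
components with the between-group component truncated at zero, so
ICC = 0 is attainable; degenerate groupings (fewer than two groups, or
all singletons, or zero total variance) are rejected explicitly.  The
estimator agrees with pingouin's ICC(1,1) to machine precision.

## Problem sizes used by the test suite

The statistical acceptance tests run simulation studies sized so the
whole suite completes in a few minutes on one core: enumeration oracles
use 3–4 bats and 1–2 periods (where every constrained permutation can be
listed); type-I studies use 500 replicates of 12–15-bat colonies at 200
permutations (9 nights for the differentiation study, matching the field
design; 4 nights elsewhere); the power study uses 100 replicates of the
full 50-bat, 9-night default generator at 499 permutations; ICC recovery
uses 200 replicates of 30 bats × 9 nights.  `scripts/acceptance.py`
runs the complete chain once at the full default scale with 5,000
permutations per test.

## Known limitations

* The last bat to depart (and the first to return) on a night can fail
  the associate-count confirmation when no tagged bats remain in range
  even within the lookback; bout recall is high (~0.95 at default scale)
  but not 1.
* The differentiation test's conservatism on short, sparse studies is a
  property of the stream-permutation null (it conditions on, and partly
  preserves, the observed configuration), not of this implementation —
  the Monte-Carlo engine matches exhaustive enumeration on toys.
* Kinship is sparse by default (six mother-daughter dyads), so
  kinship-predictor regressions have limited power at default settings;
  the effect is embedded and detectable, but p-values for kinship are
  noisier than for the relationship predictor.
* The median-based co-feeding adjustment inherits a small positive
  offset when counts are sparse (median < mean for right-skewed nulls).
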