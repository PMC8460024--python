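# proxinet

Proximity-sensor encounter networks and constrained-permutation inference
for social-foraging studies.

## The problem

Animal-borne proximity sensors log when two tagged individuals meet, for
how long, and at what peak signal strength (a proxy for distance).  For a
colony of vampire bats this yields two very different social contexts
from one sensor stream: daytime association inside the roost, and brief
nightly reunions far outside it while the bats hunt.  The scientific
question is whether the long-term cooperative relationships visible in
the roost (association, social grooming, food sharing, kinship) also
structure who meets whom during foraging — or whether bats that happen
to be out at the same time simply bump into each other.

Answering that requires inference machinery that respects how the data
were collected.  Dyadic observations are not independent, individuals
enter and leave the study, and two bats can only meet in an hour when
both are outside.  Every test in this package therefore draws its null
distribution from permutations constrained to the observed opportunity
structure.

## What the package does

* **`synthetic`** — a generative colony model with known ground truth:
  latent relationship weights `w_ij ~ Beta(mu*kappa, (1-mu)*kappa)`;
  per-hour reunion probability with a complementary-log-log link,
  `p_ij = 1 - exp(-lambda0 * exp(beta_r w_ij + beta_k k_ij))`;
  departure times `t_id = m_type + drift*(d-1) + b_i + e_id` with
  per-type variance components; captive co-feeding with configurable
  attendance heterogeneity.
* **`sensors`** — the stream-processing rules: sub-2-s encounters get
  duration 1 s; nested association / close-contact signal thresholds;
  foraging-bout detection from roost base-station gaps confirmed by the
  collapse of the tagged-associate count; encounter context labels
  (`roosting`, `foraging`, `excluded_transition` within one minute of a
  departure/return, `excluded_near_roost` on concurrent roost contact).
* **`networks`** — roosting rate networks (association seconds over
  co-presence time, per day or aggregated), foraging-seconds and
  nights-with-encounter response networks, hourly co-foraging counts,
  bout-overlap covariate, and missing-if-absent degree centrality.
* **`inference`** — social differentiation (CV of co-foraging counts
  against hourly partner swaps), within-hour identity permutations and
  the double permutation test for co-feeding, QAP / MRQAP-DSP network
  regression with within-period constrained node-label permutations,
  paired day-to-night QAP with a bootstrap CI of the mean slope,
  centrality consistency with within-night permutations, Mantel tests,
  and unadjusted repeatability (one-way ANOVA ICC).
* **`pipeline` / CLI** — an end-to-end runner
  (`proxinet simulate|process|validate|run`) that is byte-reproducible
  under a master seed.

## Worked example

```python
import proxinet as px

truth = px.simulate_colony(px.ColonyParams(seed=11))
events, _, bouts = px.simulate_foraging_nights(truth)
foraging = events[events["true_context"] == "foraging"]

table = px.hourly_coforaging(foraging, bouts)
res = px.differentiation_test(table, n_perm=5000, seed=1)
print(f"{res.observed_stat:.3f} {res.centered_stat:.3f} {res.p_value:.4f}")

strat = px.nightly_foraging_networks(foraging, bouts, truth.ids, 9)
q = px.qap_regression(strat, {"relationship": truth.relationship},
                      n_perm=2000, seed=2)
print(f"{q.coefficients['relationship']:.1f} "
      f"{q.p_values['relationship']:.4f}")
```

prints

```
2.420 1.098 0.0002
35.8 0.0010
```

The observed social differentiation (CV of hourly co-foraging counts,
2.42) sits 1.10 above the median of its constrained null, with
p = 0.0002 — the smallest value attainable at 5,000 permutations — so
specific pairs reunite outside the roost far more often than random
meetings among co-active bats would produce.  The QAP slope of ~36
foraging-seconds per unit of latent relationship weight (p = 0.001)
recovers the relationship effect built into the generator.  The
`examples/` directory has one short script per capability; each prints
its numbers with a line on what they mean.

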