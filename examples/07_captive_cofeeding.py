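"""Captive co-feeding: Mantel tests, the double permutation test, and
departure-time repeatability.

Co-feeding counts are confounded by shared feeder time, so the double
permutation test first subtracts each dyad's median count under
within-hour identity permutations, then correlates the adjusted matrix
with a predictor under node-label permutations.
"""

import numpy as np

import proxinet as px

truth = px.simulate_colony(px.ColonyParams(seed=11))
feed = px.simulate_captive_feeding(truth)        # 70 nights x 15 hours
cap = truth.captive_ids()

counts = px.cofeeding_network(feed.events, cap)
print(f"co-feeding events: {len(feed.events)}; per-dyad counts "
      f"0..{counts.vectorize().max():.0f}")

mant = px.mantel_test(truth.grooming, truth.sharing, n_perm=2000, seed=6)
print(f"Mantel grooming ~ sharing: r = {mant.observed_stat:.3f}, "
      f"p = {mant.p_value:.4f}")

adj, dp = px.double_permutation_test(feed.events, feed.attendance,
                                     truth.grooming, n_perm=2000, seed=7)
print(f"double permutation, adjusted co-feeding ~ grooming: "
      f"r = {dp.observed_stat:.3f}, p = {dp.p_value:.4f}")

bouts = px.true_bouts(truth)
night0 = (bouts["night"] - 1) * 86400 + truth.params.day_s
after = bouts["depart_s"] - night0
for t in ("control", "previously_captive", "captive_born"):
    bats = [b for b in truth.ids if truth.types[b] == t]
    sub = bouts["bat"].isin(bats)
    icc = px.icc_unadjusted(after[sub], bouts["bat"][sub]).icc
    print(f"departure-time repeatability (ICC), {t}: {icc:.2f}")

# High ICC = a bat keeps its personal departure schedule night after
# night; previously captive and captive-born bats are less predictable.
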