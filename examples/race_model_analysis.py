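"""Race-model analysis of redundant-target reaction times.

Simulates a detection task in which a coactivation architecture speeds up
double-target responses 40 ms beyond the race-model bound, then runs the
full behavioral arm: hit/false-positive rates, redundancy gain, race-model
inequality violation areas, the cluster-based sign-flip permutation test
over the 5th–30th percentiles, Benjamini–Hochberg correction, and the
exponential-prior Bayesian test on the violation areas.
"""

from c1race import (
    RTSimConfig,
    bh_correct,
    cluster_permutation_test,
    exponential_null_test,
    performance_rates,
    redundancy_gain,
    simulate_rt_dataset,
    violation_profiles,
)
from c1race.bayes import ModelSpec

rts = simulate_rt_dataset(RTSimConfig(
    model="coactivation", coactivation_shift=40.0,
    n_participants=12, n_trials=100, seed=3))

perf = performance_rates(rts)
print(f"hit rate {100 * perf.hit_rate.mean():.1f}%, "
      f"false positives {100 * perf.false_positive_rate.mean():.2f}%")

gains = redundancy_gain(rts, scope="participant")
print(f"mean redundancy gain: {gains.gain_av_ms.mean():.1f} ms "
      "(double-target speedup beyond the fastest single-target class)")

profiles = violation_profiles(rts)
d_cols = [c for c in profiles.columns if c.startswith("d_p")]
print(f"mean violation area: {profiles.violation_area_ms.mean():.1f} ms")

pvals, labels = [], []
for cong, sub in profiles.groupby("congruence"):
    res = cluster_permutation_test(sub[d_cols].to_numpy(), n_perm=10_001,
                                   seed=0)
    pvals.append(res["min_p"])
    labels.append(cong)
    print(f"cluster permutation ({cong}): min p = {res['min_p']:.4f}")

reject, p_adj = bh_correct(pvals, q=0.05)
for lab, r, pa in zip(labels, reject, p_adj):
    print(f"BH-adjusted ({lab}): p_adj = {pa:.4f}, "
          f"{'violation' if r else 'no violation'}")

expo = exponential_null_test(profiles, ModelSpec(draws=8000, seed=0))
row = expo.summary.set_index("parameter").loc["intercept"]
print(f"\nexponential-null Bayes test: intercept "
      f"{row['mean']:.1f} ms [{row.hdi_low:.1f}, {row.hdi_high:.1f}], "
      f"BF_10 = {row.bf_10:.1f}")
print("Areas clearly above zero (BF_10 > 3, HDI outside the ROPE) indicate "
      "multisensory integration beyond what parallel-channel statistical "
      "facilitation can produce.")
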