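"""Combine replicate ΔG estimates with the Gaussian-weighted average.

Three replicas of one environment disagree: two sit near −5 kcal/mol and
one is an outlier at −7. The rule-of-thumb bandwidth downweights the
outlier; setting σ → ∞ recovers the plain arithmetic mean.
"""

from neqcycle import FreeEnergyEstimate, ReplicaSet, bandwidth, combine, weights

values = [-5.0, -5.1, -7.0]
ests = tuple(FreeEnergyEstimate(v, 0.2, "bar", 50, 50) for v in values)

sigma = bandwidth(values)
print(f"replica values : {values}")
print(f"bandwidth σ    : {sigma:.4f} kcal/mol (std · n^-1/5)")
print(f"raw weights ω  : {[round(float(w), 3) for w in weights(values, sigma)]}")

weighted = combine(ReplicaSet("protein", ests, sigma_mode="rule_of_thumb"))
equal = combine(ReplicaSet("protein", ests, sigma_mode="infinite"))
print(f"weighted mean  : {weighted.value:+.3f} ± {weighted.uncertainty:.3f} kcal/mol")
print(f"arithmetic mean: {equal.value:+.3f} ± {equal.uncertainty:.3f} kcal/mol")
print("\nThe outlier replica pulls the arithmetic mean down by ~0.2 kcal/mol "
      "more than the proximity-weighted combination.")
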