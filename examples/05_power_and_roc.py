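"""A-priori power analysis and the cumulative-cutoff ROC construction."""

from misinfosim import PowerSpec, power_n_per_group, roc_curve

# how many participants per cell to detect Cohen's f = 0.20
# (d = 0.40 for two groups) at alpha = .05 with 80% power?
n = power_n_per_group(PowerSpec(effect_f=0.20, alpha=0.05, power=0.80))
print(f"required n per group for f = 0.20: {n}")

# ROC from ordinal 0-10 belief ratings: each level is a cutoff; a true
# claim rated >= cutoff is a hit, a false claim rated >= cutoff a false alarm
true_ratings = [8, 7, 9, 6, 5, 7, 8, 4]
false_ratings = [3, 5, 2, 6, 4, 1, 3, 5]
curve = roc_curve(true_ratings, false_ratings)
print("\ncutoff  hit-rate  false-alarm-rate")
for c, h, f in zip(curve.cutoffs, curve.hit_rates, curve.false_alarm_rates):
    print(f"  >={c:2d}    {h:5.2f}       {f:5.2f}")
print(f"trapezoidal AUC = {curve.auc:.3f} "
      "(equals the probability a random true claim outranks a random false one)")
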