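"""Statistical validation at reduced scale: calibration and power.

Under a shared generating model every analysis step should reject at its
nominal alpha; a planted +0.25 anxiety self-transition boost should be
recovered with high power at realistic group sizes (40 vs 28).
"""

from emoseq.studies import effect_recovery, type_i_calibration

cal = type_i_calibration(n_cohorts=60, n_per_group=20, seed=7)
print("type-I rejection rates over 60 null cohorts:")
print(f"  replication  (nominal .014): {cal.overall_rate('replication'):.4f}")
print(f"  specificity  (nominal .014): {cal.overall_rate('specificity'):.4f}")
print(f"  exploratory  (nominal .005): {cal.overall_rate('exploratory'):.4f}")

rec = effect_recovery(n_cohorts=50, boost=0.25, n_boosted=40, n_control=28, seed=8)
print(f"\nrecovery of persistence(anxious) over {rec.n_cohorts} boosted cohorts:")
print(f"  flagged significant at alpha .014: {rec.flag_rate:.2f}")
print(f"  boosted group had highest mean ranked ARF: {rec.highest_rank_rate:.2f}")

# Rates near (or conservatively below) the nominal alphas show the rank tests
# hold their level despite the massive ties at ARF = 0; a flag rate near 1
# shows the pipeline reliably detects a moderate persistence effect.
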