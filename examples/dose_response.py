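"""Dose-response statistics on a synthetic five-interval population.

Generates 60 subjects per cooking-water fluoride interval (metrics-level
mode, fast), collapses teeth to subject level with the max rule, and runs
the full statistics battery: Spearman correlations with the TF score,
pairwise Mann-Whitney interval separation with Bonferroni correction, and
ROC analysis of dQ for the TF <= 2 vs >= 3 case definition.
"""
from fluoroquant import PopulationSpec, dose_response_report, make_population

df = make_population(PopulationSpec(n_per_interval=60, seed=17))
report = dose_response_report(df)

print("mean dQ_ch per water interval (dose response):")
print(report["descriptives"]["delta_q_ch_mean"].round(4).to_string())

print("\nSpearman rho vs TF score:")
print(report["correlations"].round(3).to_string(index=False))

sep = report["separation"]["delta_q_ch"]
print(f"\npairwise separation for dQ_ch (Levene p={sep['levene_p']:.3g} -> "
      f"{sep['path']} path), Bonferroni-adjusted p:")
print(sep["p_adjusted"].round(4).to_string())

roc = report["roc"]["delta_q_ch"]
thr, sens, spec = roc.operating_point
print(f"\nROC dQ_ch: AUC={roc.auc:.3f}; Youden point: threshold {thr:.4f}, "
      f"sensitivity {100 * sens:.1f}%, specificity {100 * spec:.1f}%")
print("""
Mean dQ_ch rising across intervals and small adjusted p for the extreme
pairs is the dose-response signature; adjacent low-fluoride intervals are
expected to stay unseparated.""")
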