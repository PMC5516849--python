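"""Dietary scenario comparison with the coupled PBPK / enterocyte model.

Runs the dose-matched scenarios (200 mg t.i.d. every 6 h, 18 h horizon,
0.1 h dynamic-FBA steps) and prints the area under the plasma curve above
the stage-1 efficacy threshold, relative to ante cibum dosing.  Takes about
a minute on one CPU (five coupled runs of 1260 linear programs each).
"""

from levogut import HYThresholds, build_scenario, load_config, run_and_compare

cfg = load_config(overrides={"regimen": {"amount_mg": 200.0}})
names = ("ac", "lpd_cystine", "lpd_ornithine", "prd", "serine_rich")
report = run_and_compare([build_scenario(n, cfg) for n in names],
                         HYThresholds(), cfg)

cols = ["cmax_mg_l", "auc_above_HY1", "rel_change_HY1_pct"]
print(report.table[cols].round(3).to_string())
print("\nCompeting meals (cystine worst, ornithine mildest) cut the exposure")
print("above the efficacy threshold; the protein-redistribution and")
print("serine-rich patterns raise it via basolateral trans-stimulation.")
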