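"""Run the whole pipeline end to end and write the comparison report.

Chains every stage on the packaged fixtures — response-surface fit + ANOVA +
optimum, neural surrogate, kinetic round-trips at all seven whey doses, and
the substrate-inhibition ranking — and writes report.json / report.md.
Equivalent to the shell command `whey2xanthin reproduce`.
"""

from whey2xanthin.workbench import RunConfig, reproduce_study

report = reproduce_study(RunConfig(seed=0, ann_seeds=10,
                                   out_dir="whey2xanthin_report"))

for stage, res in report["stages"].items():
    print(f"{stage}: {res['status']}")

rsm_stage = report["stages"]["rsm"]
pred = rsm_stage["predicted_at_reference_optimum"]
print(f"\nquadratic model at the optimum: {pred['bcrx_mg_l']:.2f} mg/l, "
      f"{pred['biomass_g_l']:.2f} g/l")
ann_stage = report["stages"]["ann"]
m = ann_stage["pred_at_optimum_mean"]
print(f"surrogate at the optimum:       {m['bcrx_mg_l']:.2f} mg/l, "
      f"{m['biomass_g_l']:.2f} g/l")
kin = report["stages"]["kinetics"]
print(f"worst kinetic round-trip error: {kin['worst_roundtrip_error_pct']:.4f}%")
inh = report["stages"]["inhibition"]
print(f"best inhibition model:          {inh['best_model']} "
      f"(R² {inh['han_levenspiel_r2']:.4f})")
print("\nfull report written to whey2xanthin_report/report.{json,md}")
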