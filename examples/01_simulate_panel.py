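"""Generate a small synthetic jurisdiction-year panel and describe it.

The generator mimics a national primary-care panel: 16 input rates
(infrastructure + staffing per 10,000 inhabitants), two outputs (diabetes
patients treated / controlled) produced by a known Cobb-Douglas frontier
with context-driven inefficiency, and 7 contextual covariates.
"""

from deapanel import SyntheticConfig, generate_panel

cfg = SyntheticConfig(n_jurisdictions=50, years=(2009, 2014), seed=7)
panel, truth = generate_panel(cfg)

print(f"panel: {len(panel)} jurisdiction-year rows, "
      f"{panel.jurisdiction_id.nunique()} jurisdictions")
p0 = panel[panel.year == 2009]
print(f"2009 means: GP rate {p0.general_practitioners.mean():.2f}/10k, "
      f"treated {p0.treated_patients.mean():.0f}, "
      f"controlled {p0.controlled_patients.mean():.0f}")
print("mean true efficiency by year (exp(-u), 1 = on the frontier):")
print(truth.groupby("year").true_efficiency.mean().round(3).to_string())
print("\nThe yearly means rise toward 2014 because the generator's "
      "inefficiency multiplier improves over the early years.")
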