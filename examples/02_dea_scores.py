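"""Score one cross-section with output-oriented VRS (BCC) DEA.

Each jurisdiction's Farrell distance theta >= 1 says by how much its two
outputs could be expanded jointly if it operated like the best peers with
no more inputs; the reported efficiency is 1/theta.
"""

from deapanel import SyntheticConfig, generate_panel, score_year
from deapanel.synthetic import INPUT_COLS, OUTPUT_COLS

cfg = SyntheticConfig(n_jurisdictions=60, years=(2009, 2009),
                      noise_scale=0.0, seed=3)
panel, truth = generate_panel(cfg)
scores = score_year(panel, INPUT_COLS, OUTPUT_COLS, year=2009)

merged = scores.merge(truth, on=["jurisdiction_id", "year"])
print(merged[["jurisdiction_id", "theta", "efficiency", "true_efficiency"]]
      .sort_values("efficiency").head(5).round(3).to_string(index=False))
print(f"\nfrontier units (efficiency = 1): {(scores.efficiency > 0.9999).sum()}"
      f" of {len(scores)}")
print("DEA efficiency exceeds the true efficiency because the frontier is "
      "estimated from the best observed peers, who are themselves "
      "somewhat inefficient - the bootstrap (example 03) corrects this.")
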