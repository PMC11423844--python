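# deapanel

Bootstrap-corrected efficiency analysis of health-jurisdiction panels:
output-oriented BCC data envelopment analysis (DEA), Simar–Wilson
smoothed-bootstrap bias correction, and a random-forest determinants
analysis, with a synthetic panel generator that makes every stage
testable against known ground truth.

The package is built for health-services and efficiency researchers who
ask questions like: *given the staff and infrastructure each health
jurisdiction has, how close does it come to treating and controlling as
many diabetes patients as the best-performing peers — and which
socioeconomic conditions explain the shortfall?*

## The methods

**DEA (BCC, output-oriented).** For each decision-making unit (DMU) *o*
with inputs `x_o` and outputs `y_o`, the Farrell output distance solves

    max θ   s.t.   Yᵀλ ≥ θ·y_o,   Xᵀλ ≤ x_o,   Σλ = 1,   λ ≥ 0

with θ ≥ 1; the reported technical-efficiency score is `1/θ ∈ (0, 1]`
(1 = on the estimated frontier). One frontier is estimated per calendar
year. Two independent geometric oracles (a concave-hull construction
for one input/one output, and brute-force vertex enumeration for small
instances) verify the LP to 1e−6.

**Bias correction.** DEA frontiers are estimated from the best
performers of a finite sample, so raw scores are biased upward. The
smoothed homogeneous bootstrap resamples the estimated distances with a
reflected kernel density (Silverman bandwidth on the reflected sample),
rebuilds pseudo data sets, re-solves the DEA B = 100 times, and
subtracts the estimated bias: `corrected = 2/θ̂ − mean_b(1/θ̂*_b)`, with
percentile confidence intervals.

**Determinants.** A random forest (500 trees, 5 candidates per split,
repeated 10×3 cross-validation) predicts the corrected scores from
seven contextual covariates plus the year. Variable importance is the
mean RMSE increase when a variable is permuted, over 50 bootstrap
subsamples with out-of-fold scoring; partial dependence curves give the
direction of each effect. The same analysis refits per socio-economic
region.

**Synthetic panels.** Because the original administrative panel is not
public, `deapanel.synthetic` generates jurisdiction-year panels with the
same schema and magnitudes — 16 input rates, two outputs produced by a
known Cobb–Douglas frontier with variable returns to scale, and
inefficiency driven by the contextual covariates through known signed
links — so frontier recovery, correction direction, importance rankings
and partial-dependence signs are all checkable offline. See
`docs/methods.md` for the full model.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_bootstrap_correction.py` (60 noise-free
jurisdictions, one frontier, B = 100) prints:

```
mean raw 0.738  mean corrected 0.597  mean true 0.463
MAE vs truth: raw 0.275, corrected 0.185
```

The raw DEA means overstate efficiency because the estimated frontier
hugs the best observed peers; the bootstrap correction moves every
score off the frontier and cuts the error against the generator's true
efficiencies by about a third. `python examples/04_rf_determinants.py`
then recovers the generator's determinant structure:

```
cross-validated fit: R2 = 0.92, RMSE = 0.048, MAD = 0.033

       variable  mean_delta_rmse  sd_delta_rmse  rank
marginalization           0.1055         0.0034     1
   phc_coverage           0.0443         0.0023     2
           year           0.0431         0.0021     3
 indigenous_pct           0.0393         0.0039     4
```

Marginalization — the generator's dominant inefficiency link — ranks
first, and the partial-dependence curve on marginalization falls
monotonically: poorer jurisdictions are systematically less efficient.

A thin CLI wraps the same pipeline for shell use:

```bash
deapanel run-all --seed 1 --outdir out --b 100 --years 2009-2020
```

writing the panel, per-DMU estimates, importance and partial-dependence
tables, yearly/regional summaries, and a JSON manifest with SHA-256
digests (two runs with the same seed are byte-identical).

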