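"""Forest-plot table: how each covariate moves steady-state exposure.

Each row perturbs one covariate away from the reference subject (BSA 1.66
m^2, TP 68.95 g/L, male, melanoma) and reports the AUC0-24,ss and Cmax,ss
ratios.  BSA is evaluated at the population 5th/95th percentiles; total
protein at its 95th percentile.
"""

from fcn159pk import FixedEffects, covariate_effects

tbl = covariate_effects(FixedEffects())
print(tbl.to_string(index=False))

low_bsa = tbl[(tbl.covariate == "bsa=1.42") & (tbl.metric == "auc24_ss")]
print(
    f"\nA small (1.42 m^2) subject clears drug more slowly, so AUC rises by "
    f"{low_bsa['pct_change'].iloc[0]}% -- the allometric CL/F exponent (1.11) "
    "acting alone.  TP and sex leave AUC untouched because neither enters CL/F."
)
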