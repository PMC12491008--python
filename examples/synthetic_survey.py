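"""Generate a survey-like synthetic consumption dataset and assess it.

The generator draws log-normal per-person daily consumption for every
sex x age-stratum x category cell, calibrated so the cell means and
medians match the magnitudes of the bundled national intake tables, then
runs the full pipeline: scoring the bundled composition tables, category
mean contents, intake estimation, and adequacy flags.
"""

import omega3diet as od

cfg = od.RunConfig(consumption="synthetic", n_synthetic=400, seed=11)
bundle = od.run_assessment(cfg)

ala = bundle.intake_ala
totals = ala[(ala.category == "all")]
print("Synthetic survey, ALA all-foods totals (g/day):")
print(
    totals[["sex", "age_low", "age_high", "mean", "p50", "p95", "mean_adequate", "p50_adequate"]]
    .to_string(index=False, float_format=lambda x: f"{x:.3f}")
)
print(
    "\nPattern to note: median (P50) intake sits far below the mean in every "
    "stratum — the right-skewed consumption the assessment assumes."
)
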