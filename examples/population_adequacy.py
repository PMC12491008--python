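"""Stratified population intake and adequacy from the bundled survey tables.

Intake per stratum and category is mean category content (g/g) times
consumption (g/day). Here the published category-level intake statistics
for women aged 19-65 are summed by the estimator and compared against the
NIH ALA reference (1.1 g/day) and the WHO EPA+DHA floor (0.25 g/day).
"""

from omega3diet.intake import (
    ConsumptionStats,
    ConsumptionStratum,
    assess_adequacy,
    estimate_intake,
    load_bundled_intake,
    reference_for_stratum,
)
from omega3diet.records import Category
from omega3diet.requirements import Authority, Nutrient, Sex

for nutrient, authority in ((Nutrient.ALA, Authority.NIH), (Nutrient.EPA_DHA, Authority.WHO)):
    df = load_bundled_intake(nutrient)
    cats = df[(df.sex == "female") & (df.age_low == 19) & (df.category != "all")]
    # feed the published per-category intakes through the estimator with
    # unit consumption, so totals are the estimator's own category sums
    contents = {Category(r.category): float(r.mean) for r in cats.itertuples(index=False)}
    p50s = {Category(r.category): float(r.p50) for r in cats.itertuples(index=False)}
    stratum = ConsumptionStratum(
        sex=Sex.FEMALE,
        age_low=19.0,
        age_high=65.0,
        consumption={c: ConsumptionStats(1.0, 1.0, 1.0) for c in contents},
    )
    est_mean = estimate_intake(stratum, contents, nutrient)
    est_p50 = estimate_intake(stratum, p50s, nutrient)
    ref = reference_for_stratum(stratum, nutrient, authority)
    mean_ok = assess_adequacy(est_mean, ref)["mean"]
    p50_ok = assess_adequacy(est_p50, ref)["mean"]
    print(f"\nwomen 19-65, {nutrient.value} vs {authority.value} {ref.amount_low} g/day:")
    print(f"  all-foods mean intake   {est_mean.totals['mean']:.3f} g/day -> "
          f"{'adequate' if mean_ok else 'inadequate'}")
    print(f"  all-foods median intake {est_p50.totals['mean']:.3f} g/day -> "
          f"{'adequate' if p50_ok else 'inadequate'}")
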