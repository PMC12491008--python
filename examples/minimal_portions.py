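"""Minimal daily portions to meet omega-3 recommendations.

The daily minimally required consumption (DMRC) of a food is
target / content, in g food per day. ALA targets come from the NIH
reference intakes (1.6 g/day adult men, 1.1 g/day adult women); EPA+DHA
scenarios use the 250 / 500 / 1000 mg/day tiers. ALA can substitute for
EPA+DHA through endogenous conversion at about 15%.
"""

import omega3diet as od
from omega3diet.requirements import (
    Authority,
    EPA_DHA_TIERS,
    Nutrient,
    Sex,
    ala_equivalent_epa_dha,
    lookup_reference,
    minimal_required_consumption,
)

tables = od.load_all_bundled()
scored = {c.food_id: c for t in tables.values() for c in od.score_table(t.records)}

male_ala = lookup_reference(Nutrient.ALA, Authority.NIH, Sex.MALE, 30.0).amount_low
print(f"ALA portions for the adult-male target ({male_ala} g/day):")
for fid in ("oil-01", "nut-01", "nut-02"):
    c = scored[fid]
    req = minimal_required_consumption(c, male_ala, Nutrient.ALA)
    print(f"  {c.name:<16} {req.grams_exact:6.2f} g/day (~{req.grams_rounded} g)")

print("\nEPA+DHA portions per scenario tier:")
for fid in ("fish-01", "fish-02", "cru-01", "mol-04"):
    c = scored[fid]
    portions = [
        minimal_required_consumption(c, tier, Nutrient.EPA_DHA).grams_rounded
        for tier in EPA_DHA_TIERS
    ]
    tiers = " / ".join(f"{int(t*1000)} mg: {g} g" for t, g in zip(EPA_DHA_TIERS, portions))
    print(f"  {c.name:<16} {tiers}")

soy = scored["oil-05"]
ala_from_55g = soy.content_exact * 55.0
equivalent = ala_equivalent_epa_dha(ala_from_55g)
print(
    f"\n55 g/day of {soy.name} provides {ala_from_55g:.3f} g ALA, "
    f"worth {equivalent:.3f} g EPA+DHA at 15% conversion "
    f"({'meets' if equivalent >= 0.25 else 'misses'} the 250 mg/day tier)."
)
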