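# omega3diet

Screening-level dietary exposure assessment for omega-3 fatty acids.

Nutrition surveillance needs to answer two practical questions: *which
foods are efficient omega-3 sources*, and *does a population's actual diet
deliver enough of them*? `omega3diet` implements the full assessment for
the plant omega-3 α-linolenic acid (ALA) and the long-chain marine pair
EPA + DHA, built for nutritional epidemiologists and food-safety analysts
who work with food composition databases and stratified consumption
surveys.

## The model

For a food with fatty-acid composition per 100 g (ALA, EPA, DHA, and the
SFA / MUFA / PUFA group totals) and fat fraction *f* (g fat / g food), the
omega-3 content is

```
share = (ALA + EPA + DHA) / (SFA + MUFA + PUFA)        # fraction of fat
content = share × f                                     # g omega-3 / g food
```

Contents are displayed at two decimals (half-up) and banded on the display
value: **low** < 0.01, **moderate** 0.01–0.02, **high** > 0.02 g/g. The
daily minimally required consumption (DMRC) of a food against a reference
intake *R* (g/day) is `DMRC = R / content` (g food/day). ALA substitutes
for EPA+DHA only through endogenous conversion, defaulting to a 15% mass
yield.

Population intake per stratum *s* (sex × age interval) and category *c*
is the deterministic concentration × consumption product

```
intake[s, c, stat] = mean_content[c] × consumption[s, c, stat]    stat ∈ {mean, P50, P95}
```

with 100% assumed bioavailability, plant categories (edible oils,
nuts/seeds) feeding the ALA estimate and aquatic categories (fish,
crustaceans, mollusks) feeding EPA+DHA. A stratum is flagged *adequate*
for a statistic when its all-category total meets the applicable reference
(NIH age/sex-specific values for ALA; the 250 mg/day floor of the WHO /
AHA / EFSA / DGA recommendations for EPA+DHA).

The composition tables of the Taiwan FDA nutrient-database survey (23
edible oils, 19 nuts and seeds, 48 fish, 21 crustaceans, 15 mollusks) and
the national sex × age intake tables are bundled as plain-text package
data. The consumption microdata behind those tables is not publicly
deposited, so the `synthetic` module generates survey-like right-skewed
(log-normal) consumption calibrated to the published statistics.

## Worked example

```python
import omega3diet as od
from omega3diet.requirements import Nutrient, minimal_required_consumption

oils = od.load_bundled("edible_oils")
scored = od.score_table(oils.records)
top = od.rank_by_content(scored, 1)[0]
req = minimal_required_consumption(top, 1.6, Nutrient.ALA)
print(top.name, top.content_display, req.grams_exact)
```

prints

```
Flaxseed oil 0.54 2.9881073328153946
```

i.e. flaxseed oil carries 0.54 g omega-3 per gram, so about 3 g/day meets
the adult-male ALA reference of 1.6 g/day. The scripts under `examples/`
extend this: `rank_top_sources.py` (rankings and bands per category, e.g.
mackerel 0.08 g/g, top fish), `minimal_portions.py` (DMRC at every EPA+DHA
tier and the ~15% ALA conversion check), `population_adequacy.py` (women
19–65: mean ALA intake 3.449 g/day adequate, median 0.548 g/day inadequate
against 1.1 g/day) and `synthetic_survey.py` (a fully synthetic survey run
end-to-end). A thin CLI mirrors the stages:
`omega3diet score | rank | dmrc | qc | intake | simulate | registry | report`.

## Quality control

Loading a table also recomputes every printed content from its share and
fat columns. Three fish rows of the bundled survey are internally
inconsistent (their printed g/g values cannot be reproduced from their own
share × fat), and the oils/nuts tables print one more row than the survey
text states; `validate_and_qc` surfaces all of these as findings rather
than silently correcting them.
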