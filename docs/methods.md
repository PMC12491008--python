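# Methods

## Scope and model

`omega3diet` is a deterministic, screening-level dietary exposure
assessment for omega-3 fatty acids. It treats two nutrients separately:
α-linolenic acid (ALA, 18:3 n-3), the essential plant omega-3, and the
long-chain marine pair EPA + DHA (20:5 / 22:6 n-3). The assessment has
three layers:

1. **Food scoring.** A food's omega-3 content is
   `share × fat_fraction`, where the share of fat is
   `(ALA + EPA + DHA) / (SFA + MUFA + PUFA)` — the omega-3 fraction of the
   identified fatty acids. The content is a point value per food; the
   underlying database carries single-entry records, so no within-food
   variance is modelled.
2. **Portion inversion.** The daily minimally required consumption of a
   food for a reference intake `R` is `R / content` (g food/day), the
   exact inverse of the supplied-amount check
   `supplied = content × grams`. ALA counts toward an EPA+DHA target only
   via endogenous conversion, modelled as a single linear mass-yield
   factor (default 0.15; human conversion is limited and variable, and a
   point factor is the convention for screening assessments).
3. **Population intake.** Intake per stratum (sex × age interval), food
   category and statistic (mean / P50 / P95 of consumption in g/day) is
   `category_mean_content × consumption`, with 100% bioavailability.
   Totals are the category sums per statistic; a stratum is *adequate* on
   a statistic when the total meets the lower bound of the applicable
   recommendation.

## Rounding and banding

Published composition tables print contents at two decimals. The package
rounds half-up (`decimal`-based, so 0.005 → 0.01 reliably) and classifies
**bands on the display value**: low < 0.01, moderate 0.01–0.02 inclusive,
high > 0.02 g/g. Banding on the displayed rather than the exact value is
the rule that reproduces the source tables' own classifications (foods at
0.0051–0.0094 g/g are printed and treated as 0.01-class moderate sources).
Where this promotion crosses a band boundary, QC emits an `info` finding
so the effect stays visible. DMRC values are reported exactly and, for
table output, half-up rounded to the nearest gram.

## Reference-intake registry

ALA uses the NIH age/sex references: 0.32 g/day (0–6 mo), 0.5 (7–12 mo),
0.7 (1–3 y), 0.9 (4–8 y), 1.2 / 1.0 for boys / girls 9–13 y, 1.6 / 1.1
for males / females 14 y and older, 1.4 when pregnant, 1.3 when
lactating. Age intervals are half-open and lower-inclusive on the printed
group labels ([9, 14), [14, 19), …), so a boundary age such as exactly 13
resolves to the younger group; pregnancy/lactation overrides the age–sex
lookup. EPA+DHA has no formal DRI; the registry carries WHO and AHA
250–500 mg/day (plus an AHA ≥ 1 g/day clinical tier behind a `condition`
key), EFSA 250 mg/day, and the ~250 mg/day implied by the US guideline of
8 oz of seafood per week (DGA). All three scenario tiers (0.25 / 0.5 /
1.0 g/day) are always computed. Adequacy is judged against the lower bound
of a range. Two gram-equivalences for the 1.1 oz daily fish portion
circulate (31.2 g and 34.2 g); the default is 31.2 g — the avoirdupois
value — with the alternative available by configuration. The registry is
YAML-serializable so recommendations can be revised without code changes.

## Bundled data and quality control

The five composition tables of the Taiwan FDA nutrient-database survey
(23 edible oils, 19 nuts/seeds, 48 fish, 21 crustaceans, 15 mollusks) are
bundled as tab-separated text with the printed share-of-fat (%), fat
content (%) and listed g/g content, including left-censored entries
("<0.01"; the single censored share, almond's "<0.05%", is used at its
bound and flagged). The national sex × age intake tables for ALA and
EPA+DHA, with their printed adequacy markers, are bundled likewise.

`validate_and_qc` recomputes every listed content and reports:

* **mismatch** — the printed g/g value cannot be recovered from the row's
  own share × fat at the printed precision. Three fish rows fail:
  silverfish (18.3% of 2.0% fat recomputes to 0.00, printed 0.02), yellow
  croaker (0.0025 → 0.00, printed 0.01) and runner (0.0109 → 0.01,
  printed 0.02). The other 45 fish rows and all 78 rows of the other four
  tables reproduce exactly.
* **info** — display rounding crossed a band boundary; a share was
  censored; or a table's stated item count differs from its printed rows
  (the survey text states 22 oils and 18 nuts/seeds but prints 23 and 19;
  all printed rows are kept).

QC never aborts and is order-deterministic. Internally every quantity is
a fraction in [0, 1]; percent→fraction conversion happens only at the
loader boundary, driven by a column-mapping dialect with a closed
five-category vocabulary (unknown category labels reject the row). When
duplicate food ids occur, the raw-preparation record wins, matching the
survey's raw-foods-only convention.

Published all-foods intake cells occasionally differ from their printed
category sums by 0.001 g/day (summation upstream preceded rounding). The
package always sums at full precision; the fixture tests assert exact
equality where the printed numbers permit it and a ≤ 0.001 residual
everywhere else.

## Intake conventions

* The P50 and P95 totals are sums of per-category percentile
  contributions. Summed percentiles overstate the true total's percentile
  (no person is a top consumer of every category at once); this
  upper-bound convention is retained because it is how the published
  tables are constructed, and it is conservative in the direction that
  matters for flagging *inadequacy* only at the mean.
* Nutrient-to-category map: ALA ← {edible oils, nuts/seeds};
  EPA+DHA ← {fish, crustaceans, mollusks}. Cross-contributions (ALA in
  fish, trace EPA+DHA precursors in oils) are excluded.
* Central scenario uses the category **mean** content; a median-content
  pathway (`category_median_content`) exists for sensitivity analysis.
  The high-intake scenario is the P95 consumption column.
* A survey stratum spanning several reference age groups (e.g. 0–3 y)
  maps to the oldest contained group (0–3 y → 0.7 g/day), a deterministic
  choice that is conservative for growth.
* Body weight is carried as stratum metadata only; no per-kg
  normalization is applied.

## Synthetic consumption and composition

The consumption microdata behind the published statistics is not publicly
deposited, so the `synthetic` module generates it. Per stratum × category
cell, individual daily consumption is iid log-normal — the simplest
family reproducing the published P50 ≪ mean < P95 skew — summarised by
the sample mean and nearest-rank empirical percentiles (rank
`ceil(q·n)`, chosen for cross-platform determinism). `taiwan_like_spec`
calibrates each of the 70 cells (7 age strata × 2 sexes × 5 categories)
from the published intake tables: implied median `m` and mean `M` of
consumption are the printed intake statistics divided by the bundled
category-mean content, giving `mu = ln m` and `sigma = sqrt(2 ln(M/m))`.
Cells where the printed mean equals the median come out degenerate. The
default cell size is 500 respondents, a plausible per-cell size for a
national recall survey; tests that verify distributional convergence use
100,000 draws in a single cell, where the closed-form log-normal median
and mean are recovered within 2%.

The composition generator draws a band per food from a requested band
mix, then a fat fraction from a category-plausible range and an exact
content safely inside the band (so display rounding cannot move it), and
constructs a fully consistent fatty-acid profile (95% of fat mass as
identified fatty acids; omega-3 all-ALA for plant categories, 5/45/50%
ALA/EPA/DHA for aquatic ones; the stored share is recomputed from the
profile so the construction identity is exact). A mix requesting a band
whose minimum content exceeds a category's fat cap is rejected up front.

What the synthetic data does *not* emulate: survey weights, within-person
day-to-day correlation, consumption zero-inflation (non-consumers), and
any dependence between categories. Pipeline tests passing on synthetic
data therefore demonstrate arithmetic and contract correctness, not that
real consumption is log-normal.

## Numerical choices and degenerate inputs

* Half-up rounding via `decimal` on the float's shortest repr; ties in
  ranking break by ascending food name for deterministic output.
* A zero fatty-acid sum makes the share undefined (error), zero fat
  yields content 0 (low band), and zero content makes any positive target
  unreachable (typed error rather than infinity).
* The guideline check uses a 1e-9 relative tolerance at the boundary so
  that consuming exactly `target / content` grams meets its own target
  despite float division round-trip error.
* All randomness flows through a single `numpy` generator seeded per run;
  identical seeds give byte-identical outputs.

## Limitations

Single-entry composition records (no variance), a fixed scalar ALA
conversion factor, 100% bioavailability, raw-food compositions (cooking
alters lipid totals and the EPA/DHA fraction), no supplements, and
percentile totals that are upper bounds. The assessment flags adequacy
against references; it makes no claims about health outcomes.
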