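# Methods

## The mass-balance model

The nutrient load a floating cage releases over one production cycle is
estimated as inputs minus retained outputs:

```
X_loss = (F·X_feed + J·X_fish) − (H·X_fish + M·X_fish),   X ∈ {C, N, P}
```

with F = feed supplied, J = stocked juveniles, H = harvest, M = dead fish
(all kg per cage per cycle) and X_feed, X_fish the measured nutrient mass
fractions. Assumptions worth stating explicitly:

- **One fish composition.** Juveniles, mortalities and harvested fish all
  carry the same C/N/P fractions; the underlying laboratory analysis
  measures a single fish sample, so no stage-specific values exist. A
  faeces composition is carried in the configuration and reports, but the
  loss equation does not use it — the balance attributes everything not in
  fish to the waterbody without partitioning it into uneaten feed, faeces
  and dissolved excretion.
- **Mass basis.** The composition fractions are measured on dry weight.
  The default `as_recorded` basis applies them directly to the recorded
  wet/as-fed masses; this is the accounting that reproduces the published
  per-cage budgets for this system (e.g. 1226 kg harvested × 0.1656 =
  203.0 kg C, matching the published harvest-C mean of 203.01). A
  `dry_matter` basis — masses first multiplied by (1 − moisture) — is
  provided as the literal dry-weight reading; its results are smaller by
  the moisture factor per component and are not the published accounting.
- **Negative losses warn, never error.** Real end-of-cycle bookkeeping can
  show more nutrient leaving in fish than entered (weighing errors,
  unrecorded feed); the analyst should see the cage flagged, not lose the
  run.
- Conservation is exact by construction: inputs − outputs − loss ≡ 0 to
  floating-point identity, and the loss is affine in the feed mass with
  slope equal to the feed nutrient fraction.

Default composition (percent of dry weight): feed C 20.23, N 6.02, P 0.71,
H₂O 8.75; fish C 16.56, N 3.01, P 0.40, H₂O 68.90; faeces C 14.21, N 1.20,
P 0.95, H₂O 72.29.

## Performance metrics

- **SGR** = 100·log(H/J)/days. The natural log is the default: with ~50 g
  juveniles grown to 225–290 g over 160–175 days it yields the reported
  0.87–1.04 %/day band, whereas base-10 gives ~0.38–0.45; base-10 remains
  available (`log_base="base10"`) for comparison with sources that use it.
- **Gross yield** = H/V. Some published statements of this formula carry a
  spurious ×100 which would put a 75 m³ cage at ~1600 kg/m³; the plain
  ratio is used.
- **FCR** = feed/H with the *harvest weight* (not the weight gain) in the
  denominator — the convention of this accounting tradition; 2023/1226 =
  1.65 reproduces the reported survey mean. FCE = 1/FCR, and 1 − FCE is
  the waste mass per kg of feed fed.
- **Feeding rate** has three readings because the field formula ("average
  weight gain per day in kg over mean harvest size in g, ×100") is
  dimensionally informal:
  - `total_gain` (default): cage-total gain per day (kg) over the mean
    harvested-fish size (g), ×100. This reading reproduces the reported
    1.24–3.47 %/day band across the survey's stocking/survival/size ranges
    and makes feeding level a direct linear correlate of net yield — the
    pattern such surveys report.
  - `mean_biomass`: feed per day over the mean standing biomass
    (J + H)/2, ×100 — the conventional ration-size measure. Under this
    system's conditions it spans only ~1.45–1.85 %/day.
  - `per_fish_gain`: per-fish daily gain (kg) over mean harvest size (g),
    ×100 — the strictly per-fish substitution; its values are three orders
    of magnitude smaller (~5·10⁻⁴ %) and it is kept purely for
    transparency about the formula's ambiguity.
- **Survival** = 100·harvested/stocked; with the enforced count identity
  (harvested + dead = stocked) it complements the mortality fraction
  exactly.

## Regression

Cross-cage relationships are ordinary least-squares lines with intercept,
reported as slope, intercept, r² and n — no p-values or intervals, matching
how such farm surveys are reported. r² is computed as 1 − SSres/SStot; a
constant-y design fits exactly (r² = 1 by the SSres = 0 convention), and a
constant-x design is rejected as degenerate. The fitting is delegated to
`scipy.stats.linregress`; the test suite checks it against an independent
hand-written normal-equation solution to 1e-9.

The seven default pairs: feed supply vs C, N and P loss; feed supply,
stocking density, cycle length and feeding rate vs net yield. A feed-supply
vs survival pair is available but not in the default report.

## The synthetic cohort generator

The generator emulates the *end-of-cycle records* of a 20-cage survey, not
the within-cycle dynamics. Per cage it draws, independently:

| quantity | distribution | default |
|---|---|---|
| stocking density | two-band uniform mixture | 70 % in 40–80, 30 % in 80–107 fish/m³ |
| cycle length | integer uniform | 160–175 days |
| survival | uniform | 86.33–95.27 % |
| harvest mean weight | uniform | 225–290 g |
| FCR | uniform | 1.60–1.75 |
| initial weight | normal, clipped ±3σ | 50 ± 2 g |

and derives the bookkeeping: stock count = round(density × volume),
harvest count = round(survival × stock count), harvest mass =
count × mean weight, **feed = FCR × harvest**, and dead fish booked at a
configurable fraction (default 0.5) of the harvest mean weight — deaths
occur throughout the cycle, so half the final size is a neutral default
for an unobserved quantity. Uniform draws are used because the emulated
survey reports only ranges, never distributional shape.

Deriving feed from the drawn FCR (rather than drawing it independently) is
the one deliberate coupling: on real farms feed drives growth, but in
end-of-cycle records the observable coupling *is* the conversion ratio,
and this construction makes the tight feed–loss and feed–yield linearity
of real surveys emerge structurally. Measured on a 2000-cage cohort, the
generator's population r² values are ≈0.99 (feed vs each loss), ≈0.93
(feeding rate vs net yield), ≈0.87 (stocking density vs net yield) and
≈0.000 (cycle length vs net yield); individual 20-cage draws scatter
around these (the feeding-rate r², for instance, ranges roughly 0.86–0.97
across seeds), which is why cohort-level tests either average over seeded
cohorts or use larger cohorts.

What the generator does **not** emulate — so what passing tests cannot
show: within-cycle growth and feeding schedules (generated feeding rates
under the `mean_biomass` reading are narrower than daily-log-based ones);
density-dependent growth (density and harvest size are independent, so the
stocking–yield r² is slightly below what a survey with density-dependent
management shows); and any real covariance between mortality timing and
dead-fish weight. Every draw is retained in a ground-truth table, and the
performance metrics recover the drawn FCR exactly (feed is defined through
it) and survival/density up to count rounding — the generator's primary
correctness check.

## Numerical and design choices

- All arithmetic is double precision scalar/ndarray; no tolerance tuning is
  needed anywhere in the computation itself.
- Records are validated on construction (pydantic): the count identity is a
  hard error; a >1 % mismatch between recorded stock weight and
  count × mean weight warns only, because both numbers are recorded
  independently in the field.
- Composition files declare their unit (`percent` default, or `fraction`);
  fractions outside [0, 1] after normalisation are rejected, as is
  C + N + P > 1.
- Aggregation uses the sample SD (n−1); a single-cage aggregate reports
  SD 0 with a warning rather than NaN.
- The pipeline computes everything before writing anything, so a failed run
  leaves no partial report bundle; report CSV/JSON files carry full
  precision, with 2-decimal rounding applied only at display time.
- Test and acceptance problem sizes — 20-cage cohorts for survey-scale
  statistics, 1000-cage cohorts for invariant sweeps and range-coverage
  checks, 10 seeded cohorts for the r²-pattern test — were chosen as the
  smallest sizes at which the checked quantities are stable; the full
  suite runs in a few seconds.

## Known limitations

- The balance does not partition the loss into dissolved vs particulate or
  uneaten-feed vs faecal fractions; it is a whole-cage budget.
- No economic metrics, no water-quality modelling, and no
  carrying-capacity or stocking-recommendation calculations.
- The `as_recorded` basis ties this package to the published accounting of
  the system it emulates; comparisons against studies using true dry-matter
  budgets should use the `dry_matter` basis and expect systematically
  smaller numbers.
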