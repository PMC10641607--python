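# admark

A tested, reusable pipeline for analysing the TV food advertising that child
audiences see: audience-exposure metrics from rating points, nutrient-profile
("high-in") classification of the advertised products, emotional/rational
appeal-variety scoring, intercoder reliability, and stratified statistical
comparisons. Because instance-level TV ratings data are proprietary, the
package ships a first-class seeded synthetic-data generator so every stage is
testable end to end without any download.

## What it computes

1. **Exposure** (`exposure_metrics`) — airing instances are deduplicated into
   unique ads (duration variants merged, the longest version marked as the
   one used for content coding). Average weekly impressions per stratum are
   `(avg_rating / 100) × population × n_instances / 52` (rating points are
   percentages of the stratum audience; the divisor is fixed at 52). The top
   `floor(fraction × N)` ads by weekly impressions are selected (ties broken
   by ascending ad id), then sample filters remove ads whose products are all
   alcoholic beverages / cooking ingredients, are unavailable for purchase,
   or lack nutrition records — with full exclusion bookkeeping.
2. **Nutrient profiling** (`nutrient_profiling`) — processed and
   ultra-processed products are flagged *high-in* when any of six inclusive
   criteria is met: ≥ 10 % of energy from free sugars, ≥ 30 % from total fat,
   ≥ 10 % from saturated fat, ≥ 1 % from trans fat, ≥ 1 mg sodium per kcal,
   or any non-caloric sweetener. Energy conversion uses Atwater factors
   (4 kcal/g sugars, 9 kcal/g fats); zero-energy products with a positive
   problematic nutrient fire the criterion by convention.
3. **Appeal scoring** (`appeal_scoring`) — presence/absence flags per appeal
   type (default codebook: 5 emotional + 5 rational types) are reduced to
   ordinal 0–4 *variety* scores per strategy (distinct flagged types, capped
   at 4), broadcast from ads to the products they promote.
4. **Reliability** (`reliability`) — percent agreement and Cohen's kappa per
   code on a seeded subsample (default 10 %, floor 59 ads); kappa is reported
   as undefined (NaN) when expected agreement is 1.
5. **Comparisons** (`group_comparisons`) — Wilcoxon signed-rank (emotional vs
   rational variety), Mann–Whitney U (variety by high-in status), and paired
   t-tests on per-ad weekly impressions between demographic strata, gridded
   by strategy × variety level. Rank tests use mid-ranks, tie-corrected
   normal approximations, and exact small-sample distributions; both are
   verified against enumeration oracles in the test suite.
6. **Synthetic data** (`synthetic_data`) — seeded generator of airing logs
   (heavy-tailed instance counts, gender/SES exposure gradients), nutrition
   tables (target high-in fraction, verified through the real classifier, not
   a shortcut label), and two-coder appeal codings (prevalence conditional on
   the ad promoting a high-in product; coder 2 = coder 1 plus symmetric flip
   noise).

## CLI

```bash
admark simulate --out data/ --seed 1            # synthetic airings/nutrition/codings
admark exposure --airings data/airings.csv --populations data/populations.json \
    --fraction 0.2 --stratum overall --out out/
admark classify --nutrition data/nutrition.csv --out verdicts.csv
admark appeals --codings data/codings.csv --out varieties.csv
admark reliability --coder1 c1.csv --coder2 c2.csv --subsample 0.1 --seed 0
admark compare --airings ... --nutrition ... --codings ... --populations ... --out out/
admark run-all --config config.yaml --out out/  # simulate + full analysis
```

Exit codes: 0 success, 1 validation error, 2 runtime error. A `config.yaml`
for `run-all` may set any `SimConfig` field under `sim:` plus `top_fraction`,
`stratum`, `holm_adjust` and `subsample_fraction`.

## Data formats

* **airings.csv** — `ad_id, version_id, timestamp, duration_s, channel,
  program, product_ids` (`;`-separated), plus `rating_<stratum>` for strata
  `overall, female, male, ses_low, ses_mid, ses_high`.
* **nutrition.csv** — `product_id, energy_kcal, free_sugars_g, total_fat_g,
  saturated_fat_g, trans_fat_g, sodium_mg, has_noncaloric_sweetener,
  processing_category` plus optional `category`, `available_for_purchase`
  and an auto-detected `energy_unit` column (kJ converted at 4.184 kJ/kcal).
  An empty `energy_kcal` marks a product without a nutrition record.
* **codings.csv** — `ad_id, coder_id` plus one 0/1 column per appeal type.
* **populations.json** — child-population counts per stratum
  (female + male must equal overall).
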