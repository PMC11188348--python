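# Methods

This note documents the modelling choices behind `urbanhealth`: what each
component computes, which parameters matter, what the synthetic generator
does and does not emulate, and where the genuinely open design decisions
were made.

## Index formulas

**Pollutant sub-index.** The sub-index is the standard piecewise-linear
interpolation of a concentration between graded breakpoints. The shipped
breakpoint tables and secondary standards (`data/breakpoints.yaml`) are
modeled on the Chinese ambient air quality grading scheme (24-h averaging,
8-h for O₃; S_p standards 60/40/70/35 µg/m³ for SO₂/NO₂/PM10/PM2.5, 4 mg/m³
daily for CO, 160 µg/m³ 8-h for O₃). They are data, not code: any table
with contiguous, sorted rows validates and can be substituted. A
concentration above the top row raises an above-scale error carrying the
scale maximum rather than being silently capped; the CLI and the batch
pipeline cap with a warning because monitoring feeds do contain excursions.
Aggregation across pollutants is the maximum of sub-indices, the universal
AQI convention; the per-pollutant interpolation is the primitive.

**Thermal comfort.** The adopted reading of the comfort formula treats wind
speed as a correction to the temperature term and humidity as a separate
additive term:

    TCI = (T − 14.3) / (1 + 0.0216·V·(T − 14.3)) + (1 − 0.01·|70.5 − RH|).

The defining expression admits a second, purely additive grouping; both are
implemented and selected by `tci_form={"ratio","additive"}` with `ratio` as
the default, because the prose description of the formula's three terms
("wind speed corrects the temperature term") fits the ratio form best.
Neither reading is asserted as uniquely correct. The ratio form has a pole
where `1 + 0.0216·V·(T − 14.3) = 0` (possible only for cold, windy inputs);
inputs within ε = 1e−9 of the pole raise a degenerate-input error rather
than returning an arbitrarily large value.

**Noise and composite indices.** NPI is the contribution-weighted mean
decibel level and is invariant to rescaling of the contribution rates.
I_sum sums concentration/standard ratios over whichever pollutants are
present; it is linear in each concentration and additive across pollutants.

## The fuzzy engine

Membership function families: sigmoid `1/(1+exp(−c(x−a)/b))` (with `b`
defaulting to 1 so `c` alone sets steepness), Gaussian
`exp(−(y−b)²/2σ²)`, triangular, and difference-of-sigmoids (the classic
`dsigmf` bump). Sigmoid evaluation is clamped to the open interval (0, 1)
so saturated inputs never produce exact 0/1 that would annihilate
product-AND rule firing.

Inference is conjunctive only: rule strength is the product (default) or
minimum of antecedent degrees, times the rule weight. Defuzzification is
the weighted average of crisp consequent levels — a zero-order
Takagi–Sugeno reading in which each output linguistic label maps to a
representative crisp level, by default the center of the label's output
membership function. Consequently the output is always a convex combination
of consequent levels, which is what bounds the risk index to [0, 1] without
any post-hoc clipping. Centroid-of-area defuzzification, fuzzy OR/NOT, and
any learning or optimisation of membership parameters are out of scope;
parameters come from configuration.

Inputs outside a variable's declared universe are clamped with a logged
warning by default (strict mode raises), since monitoring data contain
excursions.

## The default FIS tree

The hierarchical decomposition — four per-medium leaf systems feeding a
root system over the sub-scores — keeps the rule count tractable (a flat
ten-input grid would need 3¹⁰ rules) and mirrors how practitioners reason
about media separately. No published rule base exists for this setting, so
the shipped default is an explicit stand-in with three properties chosen up
front:

1. **Partition of unity.** Each variable carries low/medium/high terms
   (decreasing sigmoid, difference-of-sigmoids bump, increasing sigmoid)
   with centers at 35% and 65% of the universe and steepness 8 per span, so
   the three degrees sum to exactly 1 everywhere.
2. **Single-antecedent rules.** Each term maps directly to a risk level
   (0.1/0.5/0.9). With the partition of unity, the defuzzified node output
   is then an exact average of per-variable severities `0.1 + 0.4·(u + w)`
   (u, w the two sigmoid values), each strictly increasing — so the tree is
   provably monotone: a worse environment never lowers the risk.
3. **Direction encoding.** Dissolved oxygen has its consequents flipped
   (low oxygen → high risk). pH uses acidic/neutral/alkaline terms
   (sigmoid pair at 6.5 and 8.5, steepness 3 per pH unit) with
   acidic→high, neutral→low, alkaline→high: a V-shaped contribution around
   the neutral band.

Default universes (clamped at the edges): PM2.5 0–100 µg/m³, NO₂ 0–80,
PM10 0–150, O₃ 0–200, heavy metal 0–0.1 mg/L, dissolved oxygen 0–14 mg/L,
pH 0–14, soil organic matter 0–10%, soil N/P 0–2000 mg/kg, noise 30–90 dB;
sub-scores and risk live on [0, 1]. With these choices an all-benign record
scores ≈ 0.17, an all-extreme record ≈ 0.84, and the all-midpoint record
≈ 0.48.

Missing values are a batch-level policy: hard error by default, or
per-variable median imputation from the batch with a log flag
(`missing="impute"`).

## Evaluation protocol

**Credibility.** Percentile bootstrap of the mean risk (n_boot ≥ 200,
default 2000): resample with replacement, take the (α/2, 1−α/2) empirical
quantiles. Chosen as the assumption-light default; BCa is available behind
`method="bca"`. The sample is sorted before resampling so the interval is
invariant to input ordering under a fixed seed; a constant sample yields a
valid zero-width interval.

**Significance.** A permutation test of the Pearson association between an
index series and the risk output, statistic |r|, with add-one smoothing:
p = (1 + #{permuted |r| ≥ observed |r|}) / (n_permutations + 1). The
p-value is never zero and has resolution 1/(n_permutations+1); at the
default 999 permutations the α = 0.05 test is exact (verified at type-I
error 0.03–0.07 in simulation). Pairs are canonically sorted before the
permutation stream is drawn, again for order invariance. The three index
p-values are reported raw, with Holm-adjusted companions labelled
separately. Note one structural fact: the thermal fields do not enter the
risk tree (the ten monitoring variables do), so TCI is expected to test
null against the default tree's output; IAQI and NPI share variables with
the tree and test significant.

**Applicability.** RMSE, R² = 1 − SS_res/SS_tot, and the mean absolute
residual (the scalar "residual term"; the mean signed residual is also
emitted for transparency). What the risk output should be compared against
is an explicit user input: the pipeline defaults to the synthetic
generator's planted latent risk. Because the default rule base is a
hand-specified stand-in, not a model fitted to that latent risk, absolute
agreement is modest (R² can even be negative when the mean levels differ)
while the rank association is strong; the applicability section measures
exactly this, and should be read accordingly when the observed series comes
from an independent source.

## Synthetic city archetypes

The generator emulates three archetypes anchored to composite air-quality
indices 3.92 (city_B, most polluted), 3.04 (city_W, moderate) and 2.3
(city_K, cleanest). Pollutant means are chosen so that Σ mean_p/S_p equals
the target exactly (e.g. city_B: PM2.5 49, NO₂ 36, PM10 70, O₃ 99.2 µg/m³ →
1.4 + 0.9 + 1.0 + 0.62 = 3.92); the realized batch index then falls within
±15% of the target for n ≥ 200 with large margin (≈ ±2% at n = 500), and a
calibration warning fires otherwise.

Marginals are Normals truncated at zero. Air pollutants use a coefficient
of variation of 0.30 (month-scale variability); water and soil nuisance
variables use 0.15 so that the planted signal is not swamped by media that
carry no planted structure; noise is Normal(city mean, 6 dB). PM2.5 and
PM10 are coupled through a Gaussian copula at ρ = 0.8 (co-emitted
particulates); all other variables are independent — a deliberate
simplification, so passing tests say nothing about real cross-media
dependence, seasonality or spatial autocorrelation, none of which are
modelled.

The latent risk is `expit(w_pm·z_pm25 + w_noise·z_noise + ε)` with
standardized drivers and ε ~ Normal(0, 0.25). The logistic link keeps the
latent risk in (0, 1) and monotone in both drivers, which is what makes the
recovery tests well-posed. Loadings per archetype: city_B (0.8, 0.5) —
particulate-driven; city_W (0.62, 0.7) and city_K (0.45, 0.55) —
noise-driven, mirroring the qualitative city orderings the archetypes are
meant to span. With these settings the default tree's risk output
correlates with the planted latent risk at r ≈ 0.7 on batches of 500.

Noise-source decompositions use Dirichlet(2,2,2) contribution rates over
traffic/construction/ambient sources with decibels scattered (σ = 2 dB)
around the record's level at offsets +2/−1/−5 dB. Thermal fields are
city-level seasonal Normals placing TCI in a comfortable-to-hot range.

Default batch size in examples and the acceptance script is n = 500 per
city, enough to make the calibration and recovery properties stable across
seeds while keeping the full pipeline fast on one CPU.

## Numerical and degenerate-input conventions

- Sigmoid outputs clamped to (0, 1) open bounds; exponent arguments clipped
  at ±700 before `exp`.
- Above-scale concentrations: error object in the library, cap-with-warning
  in the pipeline.
- All firing strengths zero: `NoRuleFiredError` (callers may catch and
  substitute a neutral output; the default tree cannot trigger it because
  its partitions sum to one).
- Zero-variance inputs: zero-width credibility interval (valid), undefined
  R² (error), constant correlation factor (flagged, not raised), constant
  significance series (degenerate-test error).
- Bootstrap/permutation reproducibility: single integer seeds, numpy
  `default_rng`, canonical input sorting before any resampling.

## Known limitations

- The default rule base encodes generic monotone expert judgement, not a
  fitted model; absolute risk levels are only meaningful relative to the
  declared universes and consequent levels.
- The generator's independence assumptions make it unsuitable for studying
  cross-media confounding; it exists to give the pipeline a controllable
  ground truth.
- No spatial interpolation between sites, no temporal forecasting, no
  individual-level exposure modelling, no unit inference (units are fixed
  per pollutant in configuration and validated at load).
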