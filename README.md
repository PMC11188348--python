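# urbanhealth

Fuzzy-inference health risk assessment from urban multi-media environmental
monitoring data.

Urban environmental health studies routinely collect monitoring data across
several media at once — air quality (PM2.5, NO₂, PM10, O₃), water quality
(heavy metals, dissolved oxygen, pH), soil quality (organic matter, N/P
content) and noise levels — and need to condense them into a single,
interpretable health risk indicator per site and time point, together with
an honest statistical account of how stable and how well-founded that
indicator is. `urbanhealth` is a toolkit for exactly that workflow, aimed at
environmental epidemiologists and urban-planning analysts.

## The model

**Classical indices.** Four formula-defined scalars summarise the raw
variables:

- per-pollutant air-quality sub-index by linear breakpoint interpolation,
  `IAQI = I_lo + (I_hi − I_lo)·(C − C_lo)/(C_hi − C_lo)`, aggregated across
  pollutants as the maximum sub-index;
- thermal comfort index
  `TCI = (T − 14.3)/(1 + 0.0216·V·(T − 14.3)) + (1 − 0.01·|70.5 − RH|)`
  (higher = more comfortable; a purely additive variant is available);
- noise pollution index `NPI = Σ pᵢdᵢ / Σ pᵢ`, the contribution-weighted
  average decibel level over noise sources;
- composite air-quality index `I_sum = Σ_p C_p/S_p`, concentrations
  normalised by regulatory secondary standards (larger = heavier pollution).

**The FIS tree.** A hierarchical fuzzy inference system maps the ten
monitoring variables to a comprehensive health risk index in [0, 1]. Each
medium (air, water, soil, noise) has a leaf fuzzy system: inputs carry
low/medium/high linguistic terms built from sigmoid memberships
`μ(x) = 1/(1 + exp(−c(x − a)/b))` arranged as an exact partition of unity,
rules fire by product-AND (min optional) scaled by rule weights, and the
crisp sub-score is the weighted average of rule consequent levels,
`Output = Σ wᵢ·Outputᵢ / Σ wᵢ` (a zero-order Takagi–Sugeno reading). The
four sub-scores feed a root system of the same form that emits the final
risk. The shipped default rule base is monotone by construction: raising
any harmful variable never lowers the risk, raising dissolved oxygen never
raises it, and pH contributes V-shaped risk around the neutral 6.5–8.5
band. Every pipeline function takes the tree as a parameter, so the default
is a documented starting point, not a fixed oracle.

**Evaluation protocol.** For a batch of assessments the package computes
bootstrap percentile credibility intervals (90%/95%) of the mean risk,
Pearson correlations of every factor with the risk index, permutation
significance tests of the association between each classical index and the
risk (add-one-smoothed p-values, never zero), and applicability metrics
(RMSE, R², mean absolute residual) against an observed risk series.

**Synthetic city archetypes.** Because real campaigns of this kind are not
deposited, a generator ships three calibrated city archetypes spanning
composite indices 3.92 / 3.04 / 2.3 (most polluted → cleanest) with a
planted latent health risk, so the entire pipeline is testable end to end
against a known ground truth.

## Worked example

```python
import numpy as np
from urbanhealth import (
    assess_batch, build_default_tree, builtin_profiles,
    default_breakpoints, evaluate_city, generate_city,
)

batch = generate_city(builtin_profiles()["B"], 500, seed=7)
tree, tables = build_default_tree(), default_breakpoints()
assessments, summary = assess_batch(list(batch.records), tree, tables)

a = assessments[0]
print(a.indices)     # {'iaqi': 67.53, 'tci': 8.01, 'npi': 58.18, 'i_sum': 3.48}
print(a.risk)        # 0.413
print(a.sub_scores)  # {'air': 0.395, 'water': 0.416, 'soil': 0.368, 'noise': 0.512}

report = evaluate_city(assessments, batch.latent_risk, seed=7)
```

For this batch the mean risk is 0.4393 with a 90% credibility interval of
(0.4365, 0.4422) and a 95% interval of (0.4361, 0.4427) — the wider band at
the higher confidence level reflects the extra uncertainty absorbed. The
permutation p-values are 0.001 for IAQI and NPI (both feed the tree through
their underlying variables, so the association is real and the p-value sits
at the 1/1000 resolution floor) and 0.116 for TCI (the thermal fields do
not enter the risk tree, so no association is expected). The model risk
recovers the planted latent risk at Pearson r = 0.73, and the planted
factor correlations (PM2.5: 0.78, noise: 0.49 against the latent risk)
reproduce the archetype's intended ordering.

The same pipeline is available from the shell:

```bash
urbanhealth synth --profile B -n 500 --seed 7 --out records.csv \
    --noise-out noise.csv --latent-out latent.csv
urbanhealth assess --records records.csv --noise noise.csv --out assessments.csv
urbanhealth evaluate --assessments assessments.csv --observed latent.csv \
    --records records.csv --out report.json --seed 42
urbanhealth run --out-dir demo_run --profile B -n 500 --seed 7
```

## Layout

- `src/urbanhealth/indices.py` — breakpoint tables, IAQI/TCI/NPI/I_sum
- `src/urbanhealth/fis.py` — membership functions, rule bases, inference
- `src/urbanhealth/assessment.py` — FIS tree, default rule base, batch assessment
- `src/urbanhealth/evaluation.py` — credibility/correlation/significance/applicability
- `src/urbanhealth/synthetic.py` — city archetypes and the planted-risk generator
- `src/urbanhealth/io.py`, `cli.py` — CSV/YAML/JSON IO and the `urbanhealth` CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
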