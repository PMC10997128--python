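# nutrilink

Joint analysis of child undernutrition and anemia for epidemiologists and
biostatisticians working with DHS-style child-level survey data.

Undernutrition (stunting, underweight, wasting) and anemia frequently
co-occur in the same under-five children, and analysing them with two
separate logistic regressions discards exactly the quantity of interest —
their dependence. `nutrilink` implements the joint workflow end to end:

1. **Composite undernutrition index.** The three anthropometric z-scores
   (HAZ, WAZ, WHZ) are summarised by the first principal component of their
   correlation matrix; the PC1-weighted sum `l1·HAZ + l2·WAZ + l3·WHZ` is
   dichotomised at −2 into nourished / undernourished.
2. **Exploratory tables.** Outcome and covariate frequency tables,
   Pearson chi-square screening of each covariate against each outcome, and
   the joint/marginal 2×2 table of the two outcomes with its odds ratio.
3. **Bivariate binary logistic regression.** Two marginal logits

   logit P(Y₁=1|x) = xᵀβ₁ (anemia),  logit P(Y₂=1|x) = xᵀβ₂ (undernutrition)

   are linked by a single global odds ratio ψ = p₁₁p₀₀/(p₁₀p₀₁), constant
   across covariate patterns. The four joint cell probabilities are the
   Plackett construction — p₁₁ solves a quadratic in (π₁, π₂, ψ) — and
   (β₁, β₂, log ψ) is estimated by maximising the joint likelihood with a
   Newton-type ascent. Output is a table of adjusted odds ratios exp(β̂)
   with 95% Wald intervals, plus ψ̂ and its interval.
4. **Goodness of fit** via the correct classification rate (CCR), with an
   argmax-over-joint-cells rule and a marginal-threshold rule.

Because the DHS Kid Record microdata are access-restricted, the package
ships a seeded synthetic generator (`nutrilink.synthdata`) that emulates
the published Rwanda 2019/20 study conditions: n = 3206 children, z-score
correlations (0.42, 0.44, 0.62), covariate marginals from the published
frequency table, outcome models built from the published adjusted odds
ratios, and dependence ψ = 1.729. The published summary tables themselves
live in `nutrilink.reference`.

## Worked example

```python
import numpy as np
from nutrilink import synthdata, build_composite_index, DesignMatrix, fit
from nutrilink.tables import joint_marginal_table

cfg = synthdata.default_config(seed=1)
children = synthdata.generate_dataset(cfg)          # 3206 synthetic records

index = build_composite_index(children)
print("PC1 proportion: %.3f" % index.proportion_explained[0])
print("PC1 loadings:  ", np.round(index.loadings[:, 0], 3))

jt = joint_marginal_table(children[["anemia", "undernutrition"]])
print("joint OR (counts): %.3f" % jt.or_from_counts)

design = DesignMatrix.from_dataframe(
    children,
    covariates=[name for name, _, _ in cfg.covariate_spec],
    reference_levels={n: l[0] for n, l, _ in cfg.covariate_spec},
    weight_column="weight",
)
res = fit(design, children[["anemia", "undernutrition"]])
print("fitted psi: %.3f  (log psi SE %.3f)" % (res.psi, res.se()[-1]))
print(res.aor_table.query("term == 'residence=urban'")
      [["outcome", "term", "aor", "ci_low", "ci_high", "p_value"]]
      .round(3).to_string(index=False))
```

prints

```
PC1 proportion: 0.657
PC1 loadings:   [0.517 0.599 0.611]
joint OR (counts): 1.669
fitted psi: 1.628  (log psi SE 0.091)
       outcome            term   aor  ci_low  ci_high  p_value
        anemia residence=urban 0.705   0.582    0.855      0.0
undernutrition residence=urban 0.626   0.483    0.812      0.0
```

The first principal component carries about two thirds of the variance of
the three z-scores, so a single composite index is a defensible summary.
The empirical 2×2 odds ratio (1.669) and the model's ψ̂ (1.628) both sit
within sampling error of the generating dependence ψ = 1.729: anemic
children have noticeably higher odds of also being undernourished. The
urban adjusted odds ratios below 1 recover the protective urban effects the
generator embeds for both outcomes.

The same pipeline runs from the shell:

```sh
nutrilink simulate --seed 1 --out children.csv
nutrilink run --seed 1 --out results_dir     # all stages + manifest
```

`nutrilink run` writes one JSON (and text) artifact per stage —
composite-index eigenstructure, frequencies, chi-square screen, joint
table, fit report, CCR — plus a manifest with the config hash and seed;
reruns with the same config are byte-identical.

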