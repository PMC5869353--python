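# countcompare

Biologists analysing count data (species per quadrat, offspring per
female, collisions per year) face a long-running methodological split:
transform the counts and run an ordinary linear model, or reform the
model with a generalized linear model (GLM) that carries a log link and
a Poisson or negative-binomial error structure. The two camps agree
reasonably well on *p*-values but can disagree badly on what the
coefficients mean once they are returned to the count scale.

`countcompare` makes that disagreement measurable. Every dataset is
analysed three ways:

1. **sqrt_lm** — OLS on √(y + c), c ∈ {0, ½, ⅜};
2. **log_lm** — OLS on log(y + 1) (base e by default, base 10 optional);
3. **glm** — log-link GLM fitted by iteratively reweighted least
   squares (IRLS), Poisson or negative binomial
   (Var(y) = μ + μ²/θ), the family chosen by the Pearson dispersion
   statistic χ²/df of the Poisson fit.

Each route's coefficients are then returned to the count scale with the
conventions the comparison is about:

| route   | one-way group mean        | regression slope            |
|---------|---------------------------|-----------------------------|
| sqrt_lm | (β₀ + β_level)², sign kept | β₁² with the sign of β₁ kept |
| log_lm  | e^(β₀+β_level) − 1         | e^β₁ − 1                    |
| glm     | e^(β₀+β_level)             | e^β₁ − 1 (proportional change per unit) |

On top of the per-dataset comparison (decision agreement at a fixed α,
% difference of LM estimates relative to the GLM, residual-vs-fit
diagnostics with a lowess smooth and a Spearman "fan index"), the
package ships Monte-Carlo studies of type-I error and coefficient
recovery, and a synthetic generator with known ground truth so none of
this requires external data.

## Worked example

```python
from countcompare import GeneratorConfig, generate
generate(GeneratorConfig("oneway", n=30, group_means=(3.0, 7.0), seed=11)).write("horseshoe.csv")
```

```sh
countcompare compare --data horseshoe.csv --kind oneway --out report.csv
```

```
INFO route sqrt_lm: family=gaussian iterations=1 converged=True p=2.9093e-10 decision=reject
INFO route log_lm: family=gaussian iterations=1 converged=True p=2.81133e-10 decision=reject
INFO route glm: family=poisson iterations=5 converged=True p=1.87939e-15 decision=reject
INFO decisions agree across routes: True
```

The report (abridged, two groups of 30 counts drawn at means 3 and 7):

| route   | mean[a] | mean[b] | p-value  | % diff vs GLM (a) |
|---------|---------|---------|----------|-------------------|
| sqrt_lm | 1.879   | 6.437   | 2.9e-10  | −20.6             |
| log_lm  | 1.940   | 6.295   | 2.8e-10  | −18.0             |
| glm     | 2.367   | 6.633   | 1.9e-15  | —                 |

All three routes reject the null of equal means, yet the
back-transformed group means differ by up to 20%: the GLM means equal
the sample means exactly (the log-link one-way GLM is saturated in the
group factor), while the concave √ and log transforms pull their
back-transformed means below the sample means (Jensen's inequality).
That gap — decisions agree, coefficients don't — is the phenomenon the
package quantifies.

Other entry points: `countcompare simulate --scenario s.yaml --study
type1 --reps 2000 --seed 1` for rejection rates under the null, and
`countcompare generate --config g.yaml` for synthetic datasets. The
same functionality is available as a library (`compare_dataset`,
`run_case_suite`, `type1_error_study`, `recovery_study`).

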