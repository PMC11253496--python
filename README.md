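# minpverse

**minP multiplicity adjustment for researcher degrees of freedom.**

When analysts face one research question but many defensible analysis
pipelines — impute or drop the missing values? random forest or penalized
regression for the surrogate model? mean or median aggregation? logistic
regression on the continuous exposure or an exact test on a clinically
dichotomized one? — running several *specifications* and reporting the
smallest p-value p<sub>(1)</sub> silently performs multiple tests. Even
under the global null, P(p<sub>(1)</sub> ≤ α) can be several times α.

`minpverse` makes the selection honest. It executes a declared
specification grid (the canonical grid crosses five decision axes into
2·2·2·2·3 = 48 strategies for the motivating question, *does
intra-operative paO2 affect post-operative complications?*), approximates
the null distribution of the minimal p-value by permuting the outcome, and
reports the single-step **minP**-adjusted p-value

&nbsp;&nbsp;&nbsp;&nbsp;p̃<sub>i</sub> = P( min<sub>1≤ℓ≤m</sub> P<sub>ℓ</sub> ≤ p<sub>i</sub> | ∩<sub>i</sub> H<sub>0</sub><sup>i</sup> )
&nbsp;≈&nbsp; #{ b : min<sub>ℓ</sub> p<sub>b,ℓ</sub> ≤ p<sub>i</sub> } ⁄ B,

alongside Bonferroni (min(m·p<sub>i</sub>, 1)) and Holm. Because the
permutation null inherits the dependence between the strategies, minP
retains far more power than Bonferroni while controlling the family-wise
error rate in the weak sense — the relevant sense when all m hypotheses
formalize the same vague research claim. The package is aimed at
biostatisticians and meta-researchers who want to report the most
convincing specification *with* a valid error guarantee, and ships a
synthetic generator for the clinical data structure (sparsely observed
paO2 filled in from proxy vitals by a surrogate model, one binary outcome
per surgery) plus the two standard simulation studies. See
`docs/methods.md` for the model, defaults, and design decisions.

## Worked example

Generate a synthetic dataset with a planted exposure effect and analyze it
with the full 48-strategy grid and 500 outcome permutations:

```bash
printf 'n: 300\nbeta1: 1.0\n' > effect.yaml
minpverse generate --config effect.yaml --seed 3 --out-dir data
minpverse analyze --measurements data/measurements.csv \
                  --outcomes data/outcomes.csv \
                  -B 500 --seed 3 --out-dir results
```

which prints:

```
Smallest raw p-value: 0.001035 (strategy 'imp-glm-def-med-f200', 48/48 strategies produced p-values)
  H0: complication rates are equal below and above 200 mmHg aggregated paO2 (Fisher's exact test); ...
Significance level alpha = 0.05
        minP-adjusted p_(1) = 0.008 -> significant
  Bonferroni-adjusted p_(1) = 0.04969 -> significant
        Holm-adjusted p_(1) = 0.04969 -> significant
  (Holm necessarily agrees with Bonferroni on the smallest p-value, so it adds no power for selective reporting.)
```

Reading: the best-looking of the 48 specifications achieved p = 0.001035.
That number alone is not publishable evidence — 48 tries were made. Only 4
of 500 permuted (null) datasets produced a minimum that small, so the
selection-corrected p-value is 0.008: the effect survives the adjustment.
Bonferroni, blind to the strong dependence among the 48 tests, multiplies
by 48 and lands at 0.0497 — here it still (barely) rejects, but it gives
up most of the margin that minP preserves. Per-strategy raw and adjusted
p-values are written to `results/adjusted_pvalues.csv`, the report to
`results/report.{json,txt}`, and a reproducibility manifest to
`results/manifest.json`.

The same machinery is available as a library:

```python
import minpverse as mv

data = mv.generate_part1_null(100, seed=0)          # global-null dataset
grid = mv.default_grid()                            # the 48 strategies
raw  = mv.run_grid(data, grid, seed=0)              # 48 raw p-values
null = mv.build_null(data, grid, B=1000, seed=0)    # permutation null
res  = mv.adjust_minp(raw, null)
print(res.selected_raw, res.selected_adjusted)
```

## Simulation studies

`minpverse simulate-fwer` estimates the family-wise error rate of the
unadjusted / minP / Bonferroni analyses on global-null datasets (outcome
i.i.d. Bernoulli(0.5)) with Newcombe confidence intervals;
`minpverse simulate-power` estimates the mean fraction of the 48
specifications significant at the 1/5/10% levels under a planted effect.
Both are deterministic given `--seed` and write tidy CSVs (`--plot` adds
the standard figures).

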