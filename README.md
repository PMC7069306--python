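# mgsalloc

Mating-group-size and sex-allocation analysis for spatially clustered
simultaneous hermaphrodites — built for acorn barnacles, where mating is
constrained by penis reach.

## The problem

Sex-allocation theory predicts that a simultaneous hermaphrodite should
shift investment toward its male function as its mating group grows
(local sperm competition weakens in larger groups). For sessile animals
like barnacles the mating group is set by geometry: an individual can
only inseminate neighbours within reach of its penis. Because penis
length varies among individuals, the mating group is *directional* — the
group an animal can reach as a sperm donor (male role) differs from the
group that can reach it as a recipient (female role).

`mgsalloc` turns individual-level field records — planar position on a
substrate shell, penis length, and dry weights of the reproductive
organs — into that directed analysis:

1. **Reach graph.** Per shell, a directed edge *i → j* exists iff the
   gap between *i* and *j* is at most *i*'s penis reach, taken as
   1.82 × resting penis length (the elongation rate measured in a
   congener). Mating group size in the male role is
   MGSm = out-degree + 1; in the female role MGSf = in-degree + 1.
2. **Allocation.** The ovary is the female variable cost, testis +
   seminal vesicles the male variable cost, and the penis the male fixed
   cost (all dry weights, mg). Sex allocation is
   *a* = testis+SV / (testis+SV + ovary) ∈ [0, 1]; the penis is excluded
   from the index and tracked separately (e.g. as its percentage of total
   male output).
3. **Inference.** Each response *y* (testis+SV, penis, ovary, sex
   allocation) is fitted as a random-intercept linear mixed model

   *y* = β₀ + β₁·MGSm + β₂·MGSf + β₃·body + u(shell) + ε,

   with operculum dry weight as the body-size index and shell identity
   as the random factor. Collinearity between MGSm and MGSf is checked
   with variance inflation factors, and the contribution of MGSf is
   tested with a likelihood-ratio comparison of ML refits with and
   without it.

A synthetic-population generator reproduces the study design (42 shells
of 2–7 barnacles, truncated-normal penis lengths 1.67–4.46 cm with mean
2.77 and SD 0.53, log-normal operculum weights spanning 245–1,807 mg)
with known generating coefficients, so every stage is testable with no
field data.

## Worked example

```python
import warnings
from mgsalloc import (GeneratorConfig, StudyConfig, generate_population,
                      build_mating_graph, compute_mgs, build_analysis_table,
                      fit_lmm, vif, marginal_line)
from mgsalloc.inference import lrt_drop_predictor

gen = GeneratorConfig(n_shells=400, mode="allocation_level", seed=42)
records, truth = generate_population(gen)
cfg = StudyConfig()
graph = build_mating_graph(records, cfg)
table = build_analysis_table(records, compute_mgs(graph), cfg)
print(f"{len(records)} individuals, {graph.n_edges} directed edges, "
      f"{len(table)} analyzed")
fit = fit_lmm(table, "sex_allocation")
for term in ("intercept", "mgs_m", "mgs_f", "body_weight"):
    print(f"{term:12s} {fit.params[term]: .6f}  (SE {fit.bse[term]:.6f})")
chi2, df, p = lrt_drop_predictor(table, "sex_allocation", "mgs_f")
print(f"LRT drop MGSf: chi2={chi2:.3f}, df={df}, p={p:.4f}")
line = marginal_line(fit, "mgs_m",
                     {"mgs_f": 3, "body_weight": table["body_weight"].mean()})
print(f"marginal line vs MGSm: y = {line.slope:.4f}x + {line.intercept:.4f}")
```

prints

```
1758 individuals, 2254 directed edges, 1351 analyzed
intercept     0.108935  (SE 0.002380)
mgs_m         0.008660  (SE 0.000667)
mgs_f        -0.008988  (SE 0.000743)
body_weight  -0.000018  (SE 0.000002)
LRT drop MGSf: chi2=138.765, df=1, p=0.0000
marginal line vs MGSm: y = 0.0087x + 0.0685
```

The population was generated with sex allocation following
0.1084 + 0.0089·MGSm − 0.0083·MGSf − 0.00002·body (plus shell and
residual noise); the fitted coefficients recover those values within
their standard errors — sex allocation rises with the group an
individual can reach as a male and falls with the group that can reach
it as a female. The marginal line holds MGSf at 3 partners and body
weight at its sample mean.

Individuals that are isolated in both roles (MGSm = MGSf = 1) or missing
an organ weight are excluded from the table — but never from the
geometry, so their neighbours' group sizes are unaffected.

## Command line

```sh
mgsalloc simulate --seed 3 --out sim/ --n-shells 42   # individuals.csv + truth.json
mgsalloc analyze sim/individuals.csv --out run/       # tables, model report, log
mgsalloc recover --replicates 100 --n-shells 42       # bias/coverage summary
```

`analyze` writes the analysis table, per-individual MGS values with
exclusion reasons, the directed edge list, a model-report CSV (one row
per response × term), marginal-line data and a stage-stamped run log.

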