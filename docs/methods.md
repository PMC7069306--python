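# Methods

## Model and assumptions

The analysis treats a barnacle population as a set of independent
substrate shells; individuals on different shells never interact (the
study design spaced shells to guarantee this), so all geometry is
per-shell 2-D Cartesian, in centimetres.

**Reach graph.** For an ordered within-shell pair (i, j), i can
inseminate j iff gap(i, j) ≤ reach(i), with

* reach(i) = `elongation_factor` × penis length of i. The default
  factor, 1.82, is the penis elongation rate measured in a closely
  related congener on a wave-protected shore; it is a config knob
  because that transfer is an assumption, not a measurement on this
  species.
* gap: by default the Euclidean distance between operculum centres
  (`center` mode); with radius data, `operculum_edge` mode subtracts
  both operculum radii and floors at 0 for touching/overlapping animals,
  approximating the minimum distance between the opercula.
* The threshold is inclusive: a partner exactly at full extension counts
  as reachable.

MGSm = out-degree + 1 and MGSf = in-degree + 1 (the focal animal counts
itself). The graph is always built on *all* individuals; exclusion from
the statistical analysis is a table event, never a removal from the
geometry, so neighbours' counts reflect the real population.

**Inclusion filter.** An individual is excluded when the isolation rule
fires or any of the three organ weights is missing. The default rule
`both_roles_isolated` reads "no potential mating partner" as no partner
in either role (MGSm = MGSf = 1); the stricter `either_role_isolated`
variant is selectable because the source description does not resolve
the one-sided case. Neither is asserted as the original study's choice.

**Allocation.** Sex allocation a = (testis+SV)/(testis+SV+ovary), a
dimensionless fraction on [0, 1] with meaningful endpoints (0 pure
female, 1 pure male). The penis, a maintained structure rather than
gamete investment, is excluded from a; it enters only its own response
model and the descriptive statistic
100 × penis/(penis + testis+SV) ("penis share of total male output"),
reported as the mean of per-individual percentages. Dry weight is a
relative currency: no energetic conversion is attempted.

**Mixed models.** Every response is fitted as
y = β₀ + β₁·MGSm + β₂·MGSf + β₃·body + u(shell) + ε, u ~ N(0, σ²ₛ),
ε ~ N(0, σ²), with no interactions and sex allocation modelled
untransformed. Fitting uses statsmodels `MixedLM`. Coefficient tables
use REML (the conventional default of mixed-model software);
likelihood-ratio tests refit both nested models by plain ML, as REML
log-likelihoods of models with different fixed effects are not
comparable. The criterion used is recorded on every fit. p-values for
coefficients are Wald z-based; other software's small-sample df
approximations (e.g. Satterthwaite) will differ slightly, which is why
coefficient estimates, not p-values, are the quantities to compare
across implementations. One test cross-checks the REML fixed effects
against R `lme4` on the same table (agreement ~1e-7 relative).

**Collinearity.** VIF_j = 1/(1 − R²_j) from an OLS regression (with
intercept) of predictor j on the others; VIF > 10 is the conventional
harm flag, and perfect collinearity is reported as infinite. A
sign-stability diagnostic (single- vs multi-predictor fits) is provided
as a secondary check.

## Synthetic-population generator

The generator emulates the study conditions and nothing more:

* 42 shells by default, each with 2–7 barnacles placed uniformly on a
  7.5 cm-radius disc with a 0.5 cm minimum separation (rejection
  sampling; the source gives no layout detail, so uniform-on-disc is a
  modeling choice).
* Penis lengths from a truncated normal on [1.67, 4.46] cm whose
  *truncated* mean and SD are 2.77 and 0.53 cm — field summaries
  describe the observed, bounded sample, so the parent normal is solved
  numerically (root-finding on the truncated moments) rather than used
  directly; using parent moments would shift the sample mean ≈0.02 cm
  upward.
* Operculum weights log-normal with 1st–99th percentiles at
  [244.98, 1807.32] mg; the shape is a modeling choice, only the range
  is anchored.
* True MGSm/MGSf are computed from the generated geometry by the same
  reach-graph code the analysis uses (never re-implemented).
* Responses from the linear-model structure above. The default
  generating coefficient sets are the published estimates for the four
  responses. Shell-intercept and residual SDs are free knobs (the source
  reports neither); defaults — (10, 20) mg for testis+SV, (0.15, 0.3) mg
  for penis, (75, 150) mg for ovary, (0.01, 0.02) for allocation — were
  chosen once so simulated response ranges bracket the observed field
  ranges.
* `organ_level` mode draws the three organ weights (floored at 0.01 mg;
  floor events counted) and lets allocation be implied; at the published
  ovary coefficients the linear predictor can go negative for small,
  high-MGSf animals, so a run typically floors a few percent of ovary
  draws — the generator warns above 1% because flooring distorts
  organ-level coefficient recovery. `allocation_level` mode draws
  allocation directly (clipped to [0, 1], clip events counted — at
  default noise fewer than 1/1000 draws clip) and back-fills organ
  weights (ovary from its own model, testis+SV = a/(1−a)·ovary) purely
  for file-format completeness; recovery experiments in this mode target
  the allocation model alone.

**What passing simulation tests does and does not show.** The generator
matches the *assumed* data-generating process exactly: linear effects,
Gaussian shell and residual noise, correct reach geometry. Parameter
recovery on it validates the estimation machinery, not the biological
model; real data can violate linearity, homoscedasticity (organ weights
plausibly scale multiplicatively), the 1.82 reach transfer, and the flat
substrate. No gonad cycle, settlement, growth or penis plasticity is
simulated.

## Numerical choices

* **Exactly-linear responses.** With zero generator noise the mixed
  model's likelihood is degenerate (both variance components → 0).
  `fit_lmm` detects a response whose OLS residual sum of squares is
  below 1e-10 of its total sum of squares and returns the exact
  least-squares solution (`method="exact"`, zero variances, SEs 0,
  p-values NaN), which is the common ML/REML limit. The LRT accepts
  `exact` wherever ML is required.
* **CSV round-trip.** Individuals files are written with Python's
  shortest-roundtrip float repr and parsed with pandas'
  `float_precision="round_trip"`, so write → read is the identity at
  full precision; missing organ weights stay empty cells, never 0.
* **Determinism.** All randomness flows from one integer seed through
  `numpy.random.Generator`; identical config + seed gives byte-identical
  CSV output. Replicated recovery uses master-seed + replicate-index
  streams.
* **Degenerate inputs.** Duplicate ids, non-positive penis lengths and
  negative weights are hard errors naming the row; an all-excluded table
  is a hard error carrying the exclusion counts; a single shell is a
  hard error (random intercept unidentifiable); LRT on non-nested or
  differently-fit models is a hard error, and a negative LRT statistic
  is floored at 0 with a warning.

## Problem sizes

Unit and property tests run on populations of ≤ 30 shells plus random
instances up to ~100 individuals checked against a brute-force O(n²)
recount. The recovery acceptance run uses a 1,000-shell
allocation-level population (~4,500 individuals, seconds to fit); the
Monte-Carlo unbiasedness test uses 400 replicates at the 42-shell study
scale. These sizes give Monte-Carlo standard errors comfortably inside
the tolerances tested while keeping the full suite under a minute of
compute for everything except the replicated recovery test.

## Known limitations

* Sex allocation is modelled on the raw [0, 1] scale with Gaussian
  errors; no beta/logit variant is provided, matching the analysis this
  package mirrors. Predictions can leave [0, 1] for extreme covariates.
* Wald p-values lack small-sample df corrections; for small shell counts
  they are anti-conservative relative to Satterthwaite/Kenward-Roger.
* The reach rule is isotropic and planar; curved substrates and penis
  anchor-point geometry are ignored.
* `operculum_edge` mode approximates opercular extent by a disc.
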