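# Methods

## Diet panel

Diets are defined by integer molar AA:C ratio pairs (kept un-divided so ids
like `1:250` stay exact) at a fixed sucrose molarity, 0.5 mol/L by default.
Total AA molarity is `sucrose_molarity × ratio_aa / ratio_c`; the per-AA
breakdown multiplies that total by a named mix of proportions summing to 1.
The built-in mix is equimolar over the ten essential amino acids used in
bumble-bee liquid-diet work; pollen-style blends are user configuration (a
two-column table), since assayed pollen proportions are
composition-specific. Total solute (AA + C) deliberately varies across the
panel — the design holds sucrose, not total solute, constant — and no
normalization is applied.

## Consumption accounting

Daily cage consumption = (Δtube1 + Δtube2) − mean daily control loss for the
same diet. Negative corrected values can arise from weighing noise; they are
retained (subtracting them would bias intake upward) and flagged with a
warning; a `floor_at_zero` switch exists for sensitivity checks. Mass is
converted to volume with a single density, 1.06 g/ml (a parameter), scaled
per bee alive during the preceding 24 h *before* summing over days, then
converted with ml × mol/L = mmol. Cage-days with zero bees contribute
nothing and are logged. The record-wise and vectorized DataFrame paths are
tested to agree to 1e−12.

## Rule geometry and array statistics

All geometry is in cumulative mmol-per-bee coordinates without axis
rescaling; the equal-distance rule is unit-dependent by construction, which
is the field's convention when both axes are molar. Projections are closed
form (see README). The intake-array slope is OLS of the per-diet *means*
(one point per diet, not per-cage replicates), with the slope SE from
residual variance on n − 2 df — `scipy.stats.linregress` provides exactly
this fit. Slope hypothesis tests are two-tailed; an exact fit (SE = 0)
reports p = 1 when the slopes agree and p = 0 otherwise, flagged.

`classify_rule` operationalizes the visual comparison of arrays with rule
predictions: for each rule it finds the target minimizing the SSE between
observed means and predicted rail points, via a 200×200 log-spaced target
grid spanning 0.25×–4× the observed intake range, refined by Nelder–Mead in
log-target space. Rules are ranked by minimized SSE with deterministic
tie-breaking (equal_distance, closest_distance, no_interaction_aa,
no_interaction_c). Two identifiability limits are inherent, not defects:

- under equal distance, predictions depend on T only through T_aa + T_c, so
  the target is identified only up to that sum;
- under no-interaction, only the regulated coordinate of T is identified,
  and the rule is undefined on rails lacking the regulated nutrient (the
  sucrose-only rail for AA regulation); such rails are excluded from that
  rule's SSE with a logged note, so its SSE has fewer terms than the others.

## Shape characterization

The array is read as a response curve: cumulative carbohydrate intake (mmol
per bee) against diet AA molarity (mol/L; an alternative x such as mean AA
intake may be supplied). Smoothing is a cubic smoothing spline with the
penalty chosen by generalized cross-validation (`lam=None`); `lam=0` gives
the interpolating limit used by the exactness tests. GCV needs ≥5 points;
with exactly 4 an interpolating natural cubic is used, and <4 raises. On a
1000-point grid refined by bounded local optimization:

- **peak/height**: argmax/max; boundary maxima allowed and flagged; flat
  curves tie-break to the leftmost x.
- **tolerance**: width of the superlevel set `f ≥ height × (1 −
  drop_fraction)` — the connected component containing the peak, edges
  sharpened by root finding, truncation at domain ends flagged. Default
  drop_fraction 1/3.
- **strength**: `1 − mean(f)/height` with a trapezoid mean; 0 for a flat
  curve, → 1 for a needle peak, and invariant to rescaling y.

These are fixed operational definitions of the four preference-function
summaries; tools in the mate-preference tradition expose many smoothing
choices, so users comparing against them should calibrate `lam` and
`drop_fraction`.

## Synthetic trials

The generator exists for invertibility: every pipeline stage is validated by
parameter recovery. Defaults are the study conditions: micro-colonies of 5
bees, 7 days, the seven-ratio panel at 0.5 mol/L sucrose, 5 cages per diet.
An agent's cumulative per-bee intake is its rule's projection of the target
onto the diet rail; feeding is at a constant daily rate (no within-week
dynamics are modelled). Each cage-day both tubes jointly lose intake ×
density × n_alive grams, split 50:50, plus a truncated-Gaussian evaporation
draw (mean 0.05 g/day, sd 0.01 g — plausible for open feeder tubes; only the
diet-level mean matters downstream) and independent Gaussian weighing noise
per tube (sd 0.02 g, the resolution-limited error of repeated balance
readings). Controls are 7 independent evaporation draws per diet. Deaths are
Bernoulli per bee per day (default 0.01/day, the low background mortality of
fed workers); dead bees stop feeding the following day, and `n_alive`
records bees alive during the preceding 24 h, matching the accounting
convention. The default target (0.025 mmol AA, 3.0 mmol C per bee over the
trial) sits in the intake range such trials report. Rules undefined on a
rail are simulated under closest distance with a logged substitution, or the
rail is excluded, per configuration.

What passing recovery tests shows: the accounting, geometry and statistics
are mutually consistent and invert the stated generative model exactly at
zero noise. What they do not show: real bees feed at constant rates, have
Gaussian weighing errors, or obey any single rule — the generator emulates
the measurement process, not bee physiology.

## Problem sizes and numerics

The bundled studies use 20–50 replicate trials of 7 diets × 30 cages for
noisy recovery and single trials at the design's 5 or 15 cages per diet
elsewhere; these sizes give stable Monte-Carlo rates while keeping each
driver in seconds. On carbohydrate-dominated rails (AA molarity ≤ 0.05
vs sucrose 0.5) the closest-distance and carbohydrate-only rules produce
nearly identical arrays, so rule discrimination there reflects small SSE
margins; the recovery driver prints this caveat with its rates. Floating
point: on-rail checks use a 1e−9 cross-product tolerance; exact assertions
(noiseless inversion, conservation) hold to 1e−12.
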