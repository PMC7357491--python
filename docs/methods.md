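# Methods

`rhizorank` implements a quantitative screening framework for plant
growth-promoting rhizobacteria (PGPR): phenotype assays are reduced to
per-strain *performance values* with linear and linear mixed models, the
performance values are homogenised to 0–1 *scores* with exponential
single-attribute value functions, and the scores are aggregated into one
ranking per *scenario* of criterion weights. A calibrated synthetic-data
generator supplies assay tables with the statistical structure the
estimators assume, so the full pipeline is testable without wet-lab data.

## Statistical models per assay

All halo-type responses (solubilization, swimming, spreading and
peroxide-inhibition halos) are quantified as a rectangle area `A = r1·r2`
from two perpendicular half-diameters and transformed with the natural
`log(x + 1)` before fitting, to stabilise variances; fitted means are
back-transformed with `expm1` so performance values live on the
measurement scale. Readers accept full diameters (`d1_cm`/`d2_cm`) and
halve them.

| assay | model | extracted estimand |
|---|---|---|
| NBRIP agar halos | per P source: LM `log1p(area) ~ strain × time` | strain means at 48 h (`Pca`, `Pfe`, `Prk`) |
| NBRIP broth | per medium: LM `concentration ~ strain` | strain means (`PMY`, `PMN`, `PGN`, `PSN`, `PFN`) |
| CAS assay | mean blank-zeroed absorbance per strain | ×100 → percent siderophore units (`Sph`) |
| swimming | LM `log1p(area) ~ strain × time` | strain means at 48 h (`Sw`) |
| surface spreading | LMM `log1p(area) ~ strain × time_h + (1 \| plate)` | strain means at the mean time (`Ss`) |
| H₂O₂ sensitivity | LM `log1p(area) ~ strain + concentration` | strain means at the mean concentration (`ros`) |
| biofilm | LM `absorbance ~ strain × condition` | cell means (`BfM`, `BfpH`, `BfT`, `Bfrk`) |
| EcoPlate | per strain × substrate: OD-on-time slope with plate intercepts | gated degradation velocity, one attribute per substrate |

*Marginal means.* Estimated (adjusted) marginal means are model
predictions averaged over a balanced reference grid: every level of the
other factors with equal weight, continuous covariates at their data
means, with optional pinning of a factor level (e.g. the 48-h reading).
Standard errors come from the coefficient covariance.

*Pairwise comparisons.* All-pairs Tukey tests use the studentized-range
distribution with `q = √2·|diff|/se` and the fit's residual degrees of
freedom, summarised as a compact letter display built by the
insertion-and-absorption algorithm (deterministic; ties broken by level
order). With two groups the procedure reduces exactly to the pooled
two-sample t-test. α defaults to 0.05 throughout.

*Mixed models.* Random-intercept models are fitted by REML (statsmodels
MixedLM). Degrees of freedom use a residual approximation
(`n − k_fixed − (n_groups − 1)`) rather than Kenward-Roger; at three
replicates per cell this does not move any 0.05 decision. A mixed fit
that cannot converge (e.g. zero residual variance in noiseless data)
falls back to OLS for the fixed effects with a warning — for the balanced
designs generated here the fixed-effect estimates coincide.

*Degradation velocities.* Per (strain, substrate) the OD-vs-time slope is
estimated with a free intercept per plate (within-plate centering). For
balanced plate × time layouts this equals the REML random-intercept
fixed-slope estimate, is exact on noiseless data, and is fast enough for
the repeated-simulation suites. A velocity is reported only when the
slope is statistically significant (two-sided t-test, p < α) *and*
positive; otherwise the cell is gated to zero and flagged. Cells need at
least three distinct time points.

*Siderophore units.* The literal protocol rule is ×100 of the
blank-zeroed 630-nm absorbance, clipped at 100 with a warning — the
spectrophotometer is zeroed on CAS-treated uninoculated medium, so a
reading can exceed 1 only through noise. The conventional
reference-normalised CAS formula `(Ar − As)/Ar × 100` is provided as
`cas_reference_percent` for users whose readings are not blank-zeroed;
the pipeline default is the literal rule.

## Value functions, weights and ranking

Each attribute has elicited anchors `v_min < v_mid < v_max` on its
measurement scale and a preference direction. Scores come from the
exponential single-attribute value function

```
v(x) = (1 − e^{−(x − v_min)/ρ}) / (1 − e^{−(v_max − v_min)/ρ})
```

with the curvature ρ solved by bisection (signed normalised curvature
`c = range/ρ` in `[1e−6, 1e6]`, tolerance 1e−10) so that `v(v_mid) = 0.5`.
A central midpoint yields the linear ramp (`ρ = ∞`). Decreasing-preference
attributes (the peroxide-sensitivity halo: a smaller halo means a more
resistant strain) evaluate the function at the reflected argument
`v_min + v_max − x`, with the midpoint reflected accordingly so the
midpoint still scores 0.5. Performance values outside the anchors are
clamped (score 0 or 1) and the clamp is recorded per cell — anchors are
elicited bounds and extrapolation beyond them is undefined.

The 38 declared attributes split into three criteria: plant growth (3
agar + 5 broth phosphate attributes + siderophore units), colonization
(swimming, spreading, peroxide resistance, control-condition biofilm) and
persistence (3 stress-condition biofilms + 22 carbon sources). Scenario
weights are normalised to sum to one and split equally across a
criterion's attributes (explicit per-attribute weights can be supplied
instead); the total score per strain is the linear weighted sum of
attribute scores, reported together with per-criterion subtotals. Ranks
are by descending total, ties broken lexicographically by strain id and
flagged. Rankings are invariant to any positive rescaling of the raw
weights. No hierarchical aggregation, attribute interactions or
sensitivity analysis are provided.

Default scenarios: scenario 1 = (0.5, 0.25, 0.25) (growth-dominated),
scenario 2 = (0.4, 0.4, 0.2) (growth + colonization), scenario 3 = equal
thirds. The true elicitation table behind the published analysis is in
supplementary material that is not reproduced here, so anchors and
numeric weights are declared package defaults satisfying the published
ordering constraints, fully overridable via the YAML config.

## Synthetic data generator

The generator emulates the published three-strain campaign (B02, L3,
Sp20; three replicates per experiment) with additive Gaussian noise on
the analysis scale — log1p for halo areas, raw for absorbances, ODs and
concentrations — truncated at physical bounds, and plate-level random
intercepts where the models expect repeated measures. Each assay table
draws from its own PCG64 stream seeded by (master seed, CRC32 of the
assay id), so outputs are byte-identical for a fixed config and adding an
assay never perturbs another.

Calibration. Printed values are used wherever the study reports them:
48-h halo means 1.5/2.03/2.09 cm² and source profile 2.39/0.53/0.43 cm²;
B02's 72.6 mg/L on mannitol + ammonium; CAS absorbances
0.861/0.884/0.594; the biofilm mean ± SE table (replicate SD taken as
SE·√3); 17/15/13 usable substrates for L3/B02/Sp20 with 13 substrates
unusable by all (the amines and polymers among them); OD readings at 12-h
intervals to 72 h plus 84 h. Unreported dispersions and per-strain means
are declared assumptions chosen once so that the fixture reproduces the
published qualitative structure with margins well above estimation noise:
B02 leads the plant-growth criterion (broth series 72.6/65/60/55 mg/L and
the highest peroxide resistance), L3 leads colonization spreading
(3.2 cm² at 60 h vs 1.5/1.2) and persistence (utilisation slope
0.015 OD/h vs 0.009/0.008, 17 usable substrates). Under the default
scenarios this yields B02 first in scenarios 1–2 and L3 first under equal
weights in ≈100% of seeds.

Two generator details matter for inference. First, every EcoPlate well
carries a small negative drift (−0.0002 OD/h, evaporation/settling over
the 84-h incubation), so unused wells have a weakly negative true slope
rather than an exact zero; without it, any size-α significance gate would
admit false-positive "usable" substrates at ~α/2 per null well and the
recovered counts would fluctuate around the true pattern. Second, the
four substrates the study singles out as most easily assimilated
(D-mannitol, N-acetyl-D-glucosamine, D-xylose, L-asparagine) get a 1.5×
slope multiplier.

What the generator does *not* emulate: mechanistic growth kinetics
(logistic/Monod curves — OD is linear in time over the fitted window),
heteroscedasticity across conditions, plate-position or batch effects,
non-Gaussian measurement error, and correlations between assays of the
same strain. Passing tests therefore demonstrate that the estimators and
the decision layer recover truths under the models' own assumptions, not
that those assumptions hold for any particular laboratory's data.

## Numerical and design choices

- Natural logarithm for the log(x+1) transform; '.' decimal separator and
  UTF-8 fixed, no locale inference; long CSV is the canonical interchange
  format (plate grids exist only for EcoPlate import).
- OLS designs are checked for rank deficiency via pivoted QR and rejected
  with the aliased terms named.
- Zero residual variance (exact fits) is handled explicitly: standard
  errors of 0 give p = 0 for a nonzero difference and p = 1 otherwise.
- The bisection solver caps |range/ρ| at 1e6; midpoints within tolerance
  of the centre (or beyond the cap on the near-linear side) return the
  exact linear limit.
- Problem sizes in the verification suites — 200 simulated EcoPlate cells
  for coverage, 200 seeded campaigns for the rank-reversal frequency —
  were chosen to bound the Monte-Carlo error of the reported rates at
  about ±2–3 percentage points.

## Known limitations

- Kenward-Roger degrees of freedom are not implemented; mixed-model df
  are approximate (documented above).
- The compact letter display is deterministic but not guaranteed minimal
  in the number of letters for pathological significance graphs.
- `PerformanceMatrix.from_csv` cannot recover per-attribute provenance
  (source assay, units); the JSON export preserves it.
- The MAUT layer assumes preferential independence between attributes, as
  does any linear weighted sum.
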