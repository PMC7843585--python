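# Methods

## Density-response model

The package models the *final* morphology of a maize canopy at full
expansion — no thermal-time kinetics, no phenology. The state variable is
a profile of six organ dimensions (LL, LW, SL, SW, IL, ID; cm) per
phytomer rank 6–18. Ranks 1–5 drop off before full expansion; they are
valid identities but carry no modelled morphology. Total initiated leaf
number is fixed at 18.

The percent change *Y* of a dimension relative to its reference-density
(4.5 plants m⁻²) size is

* ranks 6–11 and 13–18: `Y = A·ln(x) + B·PP + C` (separate coefficient
  sets for the two groups),
* rank 12 (ear position): `Y = D·x + E`,

applied multiplicatively, `size = base·(1 + Y/100)`, floored at 0.

**Regressor choice.** The source material is internally ambiguous about
whether the logarithm takes the absolute density or the increase over the
reference. The default is the *increment* `x = PD − 4.5` (the framing in
which the relationships were plotted and fitted); `regressor_mode =
"absolute"` selects the other reading. Refitting round-trips are
mode-agnostic. Under increment mode the equations are undefined at the
reference density itself, so density exactly 4.5 bypasses them and
returns the base profile unchanged (`Y = 0` by contract).

**Domain.** Densities between the trial levels are allowed — the model is
continuous in x. Densities above 15 plants m⁻² extrapolate beyond the
calibration and emit a log warning. Densities below the reference are
rejected: the response was characterized for increased competition only.

**Default coefficients** are the published calibration for the hybrid
Zhengdan 958 (six organs × {lower, ear, upper}); they are constants of
the package and are never re-derived at run time. R² of the original fits
is ≥ 0.8 except internode length (0.65 lower group).

## Fitting

`fit_group` is plain unweighted OLS on the design `[ln x, rank, 1]`
(grouped) or `[x, 1]` (ear), solved by `numpy.linalg.lstsq`; no
regularization. `R² = 1 − SSE/SST`; when SST = 0 (constant response) R²
is 1 if the residuals vanish and −∞ otherwise. Preconditions are enforced
fail-fast: the grouped model needs ≥ 3 points spanning ≥ 2 distinct x and
≥ 2 distinct ranks with x > 0; the ear model needs ≥ 2 distinct x.
`standard_errors` returns classical homoskedastic SEs,
`s²·(XᵀX)⁻¹` with `s² = SSE/(n − p)`.

`percent_changes` turns a long-form measurement table into fit-ready
(x, rank, y) triples: replicates are averaged per (density, rank, organ)
and each elevated-density mean is expressed as percent change against the
reference. Two referencing modes exist: against the table's own
reference-density means (field-data situation), or against a separately
known calibration profile (`reference_profile=`). The distinction
matters statistically: with a *sampled* reference, its noise enters every
change at the same rank as a shared offset, correlating residuals across
densities and making iid OLS standard errors anti-conservative. The
stochastic recovery suite therefore uses the known-profile mode. A
related caveat: the ear-position fit has only as many points as elevated
densities (4 in the trial design), so any ±k·ŜE interval there has the
coverage of a t statistic with 2 degrees of freedom (≈ 90 % at k = 3),
regardless of implementation; coverage checks are meaningful only for the
grouped fits (24 points each).

## Synthetic data

True reference-density organ sizes of the studied hybrid are available
only graphically, so the generator stands in for them with bell-shaped
rank profiles, `size(rank) = peak·exp(−(rank − peak_rank)²/(2·width²))`:

| organ | peak (cm) | peak rank | width (ranks) |
|-------|-----------|-----------|---------------|
| LL    | 80        | 12        | 4 |
| LW    | 10        | 13        | 5 |
| SL    | 18        | 10        | 5 |
| SW    | 3         | 10        | 6 |
| IL    | 14        | 14        | 5 |
| ID    | 2.2       | 8         | 8 |

Peaks and positions are plausible for a modern dent hybrid at low
density; they are *not* calibrated to any measured plant. Observation
tables mirror the trial structure — 3 replicates × densities
{4.5, 6, 7.5, 9, 15} — with multiplicative Gaussian noise
`value = prediction·(1 + ε)`, `ε ~ N(0, sd)`, default sd 2 %, truncated
at zero (truncations logged; they do not occur below ~10 % noise with the
default profiles). Noise is multiplicative because organ-size measurement
error scales with size and sizes are positive. One master seed spawns one
child stream per density, so adding a density level leaves the other
levels' draws unchanged.

What passing tests on these data do and do not show: they verify the
estimator (round-trip identifiability, error propagation, NRMSE
behaviour), not the biology — real canopies have rank-profile asymmetry,
between-plant covariance, within-plot gradients and year effects that the
generator deliberately omits.

## Geometry

* Intra-row spacing is the exact reciprocal `1/(row_spacing·density)`
  with 0.6 m rows; a reporting helper rounds to 2 cm precision. The field
  notes' 0.38 m at 4.5 plants m⁻² differs from the reciprocal 0.37 m; the
  reciprocal is used everywhere and the discrepancy is only documented.
* Leaf insertion height LIH(r) is the cumulative internode length from
  rank 6 up, plus a configurable basal offset (default 0 cm) for the
  senesced ranks.
* Leaf area LA = 0.75·LL·LW — the conventional maize blade shape factor;
  configurable in (0, 1].
* Insertion angles: measured anchors 18°/22°/10° at ear−1/ear/ear+1;
  other ranks by linear inter-/extrapolation in rank, clamped to
  [5°, 40°]; an explicit per-rank override table wins. Angles are held at
  their reference-density values across densities (the measured ear-zone
  angles were stable under density; the one reported reduction at ear−1
  has no published magnitude, so it is left to the override hook).
* Midribs are quadratic Béziers: the tangent leaves the stem at the
  insertion angle and the tip direction is tilted a further
  `droop·90°` downward (droop default 0.3, no published curvature model).
  Droop 0 with angle 0 degenerates to a vertical straight midrib of the
  full lamina length. Blade width along the midrib follows
  `LW·sin(π·s^0.8)` (zero at collar and tip, maximum LW past midleaf).
* Phyllotaxis is alternate-distichous: azimuths alternate 180° per rank
  plus uniform jitter of ±15°, drawn from a per-plant seed; geometry is
  bit-reproducible per seed, and plant height is seed-invariant.
* Scenes use meters, z-up, soil at z = 0; organ space is cm, converted at
  export. OBJ export writes one named object per organ
  (`plantNNN/leaf_r12`, …) plus a 100 cm reference bar. The OBJ loader
  used for round-trip checks merges objects, so group presence is checked
  on the file text while vertex counts and bounds are checked on the
  re-imported mesh.

## Validation statistic

`NRMSE = 100·sqrt(Σ(SIMᵢ−OBSᵢ)²/n)/mean(OBS)` — note the radical: the
printed form of this statistic in the source literature omits it, but
"root mean square error" semantics and the hand-checked example
(sim (3,3,3) vs obs (1,2,3) → 64.55 %) require it. Replicates are
averaged per rank *before* pairing with the simulation. Quality bands use
≤ at the edges: 10 % is excellent, 20 % good, 30 % fair. LA and LIH are
validated alongside the six measured dimensions whenever LL and LW
(respectively a contiguous IL series from rank 6) are available on both
sides; otherwise they are skipped with a log note. The closed-form
identities tested — scale invariance, constant-bias `NRMSE = 100·|e|/ō`,
and the uniform +10 % perturbation giving 100/11 ≈ 9.09 % — hold exactly
for rank-constant series; for non-constant series the perturbation
identity becomes a lower bound (rms/mean ≥ 1).

## Heatmaps

Two change framings are deliberately distinct: the canopy-overview
heatmap shows *successive* transitions (4.5→6, 6→7.5, 7.5→9, 9→15; a
13 × 4 matrix per organ), while the regression model is fitted in the
*reference* framing (everything vs 4.5); `reference_change_matrix`
provides the latter. Rows are ordered top-of-canopy first (rank 18 at
the top) by default. Rendering uses matplotlib's RdYlGn diverging map
with color limits fixed at −16…+10 % (values clamped); a zero
denominator yields a flagged NaN cell, not an error. Exact color
interpolation is not contractual, only the limits.

## Problem sizes

The test suite and the acceptance script run on desk-scale inputs by
design: 13 ranks × 6 organs × 5 densities × 3 replicates (1 170 rows per
table), 200 seeded trials for the stochastic coverage suite, and scenes
of one to a few dozen plants for mesh checks (a full 9 m × 5 m plot at
15 plants m⁻² is supported but unnecessary for verification). The whole
suite completes in well under a minute.

## Known limitations

* The base profile is synthetic; absolute simulated sizes are
  illustrative until a measured calibration profile is supplied.
* Only final morphology is modelled — no organ extension dynamics,
  phenology, light interception or photosynthesis.
* Sheaths are rendered as simple cylinders (no wrapping geometry); no
  tassel/ear geometry; no collision avoidance.
* The density response of leaf angles is not modelled beyond the
  override hook; the published anchors cover only the three ear-zone
  leaves.
* Published NRMSE values against the second field season are not
  reproducible here (those observations are unpublished); the validation
  machinery is instead verified against closed forms and synthetic data.
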