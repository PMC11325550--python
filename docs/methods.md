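# Methods

## Problem setting

Mobile monitoring campaigns (instrumented cars logging 1-Hz geolocated
NO₂ / ultrafine-particle readings) yield hyperlocal annual concentration
estimates on ~50 m road segments, but covering a new city takes months of
driving. This package transfers LUR models fitted on mobile campaigns in
monitored *source* cities to an unmonitored *target* city, using only the
target's GIS predictor table — no target measurements enter model fitting.

## Preprocessing model

Raw 1-Hz readings pass through, in order: plausibility range filters
(NO₂ kept in [0, 500] μg/m³, UFP in [250, 500 000] particles/cm³, bounds
inclusive), campaign-wide winsorizing at the 2.5th/97.5th percentiles
(linear interpolation between order statistics; applied per pollutant per
city on the raw value distribution, before any spatial assignment),
additive temporal correction against an hourly reference site (NO₂ only:
`value − (ref[hour] − mean(ref))`; configurable `additive | none`),
nearest-segment snapping (default threshold 35 m ≈ half a segment plus
GPS error; ties to the smallest segment id), and "mean-of-means"
aggregation: the mean over drive-day means, so frequently driven days do
not dominate the annual estimate. Drive pass = number of distinct
calendar days a segment was measured.

Winsorizing and temporal correction are one-shot stages of a fixed
pipeline: winsorizing is only approximately idempotent (re-clamping moves
values by at most the inter-order-statistic gap at the cut points) and
re-applying the reference correction would subtract the hourly deviations
twice, so the pipeline applies each exactly once.

## CORAL + ridge

Stage 1 computes `A = C_S^{-1/2} C_T^{1/2}` from the column-centred
sample covariances (denominator n−1) of the two cities' feature tables,
each regularised by `lambda_reg·I`. Matrix square roots use symmetric
eigendecomposition with eigenvalues floored at `lambda_reg` — buffer
feature tables are routinely rank-deficient (many all-zero or nested
columns), and the symmetric route is deterministic and sign-stable where
a Cholesky factorisation is not. `lambda_reg` defaults to 1e-5 of the
mean pooled covariance diagonal (relative regularisation, so tables in
m² and veh/day units behave alike). Stage 2 standardises the transformed
source features and fits ridge regression (`alpha = 1.0` by default;
`"cv"` selects it by 5-fold CV on the source). Prediction applies the
stored centring/scaling to the raw target features — the source was
transformed *toward* the target, so target features already live in the
aligned space.

Both domains are mean-centred by their own column means before
alignment: the alignment objective is a pure covariance statement, and
per-domain centring also removes the mean component of covariate shift.
The consequence — predictions are anchored at the source's mean response
— is an assumption, not a bug: absent target labels, the method cannot
know the target's city-wide background, and this is precisely the
residual error the distance-weighted fusion addresses. Conditional
shifts are deliberately not corrected; no target labels exist to
estimate them from.

## Stepwise LUR baseline

The supervised baseline is the forward-stepwise procedure standard in the
LUR literature: add the predictor maximising adjusted R², accepting a step
only if the gain is ≥ 0.01, the new coefficient matches its a-priori sign
(traffic / road length / industry / port / transportation / population
"+", natural / urban-green / agricultural "−", others free), previously
accepted signs are preserved, and no variance-inflation factor exceeds 3;
afterwards predictors with p > 0.10 are dropped (worst first). Ties on
gain break alphabetically, making the fit invariant to column order. All
thresholds are configurable; the defaults are the convention, not values
fitted to any dataset.

## Inverse-distance fusion

Per-source models are combined with weights `w_i ∝ d_i^{-p}` (p = 1,
configurable), `d_i` the great-circle distance between declared city
centroids (explicit straight-line distances can override). Weights are
constant across target segments because conditional shift is a
city-level, not segment-level, phenomenon. The layer is model-agnostic:
it wraps CORAL members (IDW_Coral) or directly applied stepwise members
(IDW_SLR) identically. A zero distance is rejected — a source at the
target needs no transfer.

## Evaluation

R² is the **squared Pearson correlation** of predictions vs observations
(not 1 − SSE/SST; the two differ under bias). Lin's concordance
correlation coefficient uses population (1/n) moments:
`CCC = 2ρσxσy / (σx² + σy² + (μx−μy)²)`. Fixed validation sites are
matched to their nearest segment within 20 m (distinct from the 35 m
reading-snap threshold). Zero-variance inputs yield NaN correlation
metrics with a warning rather than an arbitrary number.

## Synthetic multi-city generator

The generator produces the statistical structure the method is designed
for, at desk scale. Three cities mirror the motivating geometry: target
"AMS" with sources "RTM" (~58 km) and "CPH" (~620 km).

**Features.** 14 predictors with realistic units and magnitudes (nearest
-road and in-buffer traffic, road length, buffer areas of industry /
port / transportation / residential / natural / urban-green / water,
population). Rows are multivariate normal, rectified at 0; with several
means below one sd this reproduces the zero inflation of sparse land-use
classes. The correlation structure is strongly blocked (nested traffic
buffers at ρ ≈ 0.7–0.88, urban-fabric block ρ ≈ 0.45, green block
negatively tied to traffic) — the collinearity that makes stepwise
selection rely on proxy variables.

**Covariate shift** (target vs sources): traffic-related means up by
0.5–0.7 sd with scales ×1.4–1.5, port/industry down, green and water up,
and off-diagonal correlations damped to 55 % of the source values —
a different urban fabric in which source-learned proxy relationships
break. The implied city-mean response difference is ≈ +2 μg/m³.

**Conditional shift** with distance decay: each city's coefficients are
`β_general + β_city`, with β_city drawn per predictor from a zero-mean
spatial process over city centroids, covariance
`(0.5·|β_j|)² · exp(−d/ℓ)`, ℓ = 150 km, plus an exponentially correlated
city-wide background offset (sd 2.5 μg/m³). At ℓ = 150 km the near pair
shares ~68 % of its perturbation variance, the far pair ~2 % — the
structure inverse-distance fusion exploits.

**Campaigns.** Per collection day a Bernoulli subset of segments is
driven (revisit rate = requested mean drive passes / days); each visit
yields 5 readings `Y + day_effect + obs_noise` with σ_day = 3 and
σ_obs = 9 μg/m³, and the day effect doubles as the reference-site signal
for temporal correction. Defaults mirror the emulated study conditions:
sources 30 days at ~1.8 mean passes, target 160 days at ~6.8; 2 000
segments per city; 82 validation sites carrying true long-term values;
true surfaces include σ = 1 μg/m³ of micro-scale variation GIS
predictors cannot explain. Everything is reproducible from (params,
seed); derived seeds stay below 2³¹.

Scenario presets: `no_shift`, `covariate_shift_only`,
`conditional_shift_only`, `both_shifts_tobler`.

**What the generator does not emulate:** physical dispersion, street-
canyon geometry, meteorology-driven spatial noise correlation, on-road
vs roadside bias, instrument drift, and any nonlinearity of the true
concentration surface in the predictors. Because the truth is linear in
the observed features, a correctly specified full linear model with
abundant, low-noise training data would transfer perfectly; the transfer
problem here arises — as in practice — from collinearity-driven variable
selection, noisy short campaigns, and the shifted feature geometry.
Passing tests therefore show the machinery and its comparative orderings
under these mechanisms, not real-world accuracy levels.

## Numerical and design choices

- Buffers are centred on segment midpoints (not whole-line buffers) for
  speed and determinism; circular buffers use 64 quadrant segments
  (relative area error ~1e-4, reflected in test tolerances).
- In-buffer traffic intensity features are length-weighted sums
  (intensity × in-buffer road length), the common LUR convention.
- "Major road" is an input attribute of the network, never inferred from
  intensity; a network without major roads yields zeroed nearest-major
  features with a logged warning.
- GeoJSON is stored in WGS84 lon/lat and projected to a local
  equirectangular metric plane on read; at city extents (~20 km) the
  distortion is far below GPS error. Great-circle distances use the
  haversine formula.
- Snapping/matching ties break on the smallest segment id; degenerate
  inputs (empty segment sets, zero distances, n < 2 covariance rows,
  non-symmetric covariance inputs, unknown pollutants or scenario names)
  raise informative errors rather than propagating NaNs.
- Acceptance-style simulation checks use 20 replicates and desk-scale
  problem sizes (2 000 segments per city; 600 target segments for the
  160-day learning curve), chosen as the package's own balance between
  Monte-Carlo stability and quick iteration.

## Known limitations

- The alignment transform is unregularised beyond the eigenvalue floor;
  with many more features than segments a stronger `lambda_reg` is
  advisable.
- The fusion weights are fixed inverse distances; dispersion-informed or
  learned weights are out of scope.
- The stepwise thresholds (gain 0.01, p 0.10, VIF 3) follow the field's
  convention and are not tuned per dataset.
- UFP lacks a reference-site correction (none exists routinely), so its
  temporal variation inflates aggregate noise.
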