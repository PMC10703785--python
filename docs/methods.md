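# Methods

`spudlca` models the nutritional and environmental consequences of how a
household stores and cooks potatoes. A *pathway* couples a processing
method (raw RW, boiled BL, baked BK, fried FR) with a storage condition
(unstored US, refrigerator FG, ideal high-humidity chamber ID, cupboard
CP) and a storage duration (the nominal "2 week" and "5 week" arms are 17
and 33 calendar days). All quantities are expressed per functional unit:
1 kg of processed, ready-to-eat potato.

## Nutrient change

Mineral composition is carried for ten elements (Ca, P, K, Na, Al, Cu,
Fe, Mg, Mn, S) in ppm, alongside an energy density in Cal/g air-dry
basis. The nutrient-change statistic for a pathway against the
raw-unstored reference is the unweighted arithmetic mean of the
per-mineral signed percent changes,

    aggregate = (1/|M|) Σ_{m∈M} 100 · (c_m − r_m) / r_m ,

negative meaning loss. This aggregation reproduces the reported ~24.8%
and ~24.7% average losses for the baked/ideal and baked/cupboard 2-week
pathways to within 0.25 points. Below-detection cells ("<x") are kept as
censored entries carrying the detection bound; by default they are
excluded from the mean, and a switch substitutes bound/2 instead
(left-censored data have no unbiased point substitute; half-bound is the
common pragmatic choice). Calories never enter the mineral aggregate;
they are a separate decision criterion.

Known inconsistency: the reported "~26% increase" for the baked/ideal
5-week pathway is not recoverable under this (or any obvious)
aggregation — the composition table gives ≈ +12.9%. The package does not
tune toward that sentence.

## Cooking and storage energy

Cooking energy uses a two-stage model. The heating stage is sensible
heat Q = Σ m_i·Cp_i·ΔT (Cp water 4.18, potato 3.39 kJ/kg·K) delivered
through an electric burner at 39% efficiency; the maintenance stage
loses heat by free convection, q = h·A·(T_s − T_∞), with h = 15 W/m²·K
(free-air range 5–25), a 0.0314 m² pot surface (0.2 m saucepan), a 95 °C
simmer surface and 25 °C ambient, giving 32.97 W. Efficiency applies to
the heating stage only: 1427.8 kJ / 0.39 = 3661.0 kJ plus 900 s of
maintenance gives ≈ 3690.7 kJ for a boiling batch, matching the
published chain to under 1 kJ; dividing the maintenance term by the
efficiency would not.

The boiling heating requirement is carried as the configured constant
1427.8 kJ. Recomputing it from the stated 1.9 kg of water plus 0.93 kg
of potato over 75 K yields 832 kJ — the constant is only consistent with
roughly 3.8 kg of water. The worked-example value is treated as
canonical and the discrepancy is documented here rather than silently
resolved.

Frying (8784 kJ = 2.44 kWh) and baking (3888 kJ = 1.08 kWh) totals are
configuration overrides: the oil mass, oven duty cycle and effective
heat-transfer parameters needed to re-derive them are not independently
specified. Where source temperature statements conflict between
sections, the values attached to the published energy totals are used.

Refrigerated storage draws `daily kWh × allocation share × days`. The
allocation share is the product 6.4% (fresh-vegetable share of food
expenditure) × 50% (fraction refrigerated) × 5% (potato share) = 0.16%
of refrigerator space. The refrigerator condition runs at the medium
setting (1.5 kWh/day); the ideal chamber is modelled as a refrigerator
at the low setting (1.1 kWh/day) holding a salt solution with no extra
burden, since no separate figure exists for it. Cupboard storage is
free.

## Inventory and mass balance

Potato purchased per FU is 1 / ((1 − peel)·(1 + δ)), with 10% of the
post-storage mass peeled to biowaste and δ the cooking mass-change
fraction. Defaults are midpoints of the observed ranges: frying −42.5%
(2 wk) / −59% (5 wk), baking −30% / −43%, boiling +4% / +15%. Boiling
uses 1.9 kg tap water per batch; frying uses 0.5 kg vegetable oil per
batch — a realistic household deep-frying quantity chosen once because
no oil mass is independently specified (it affects only synthetic
end-to-end runs, never the published-value checks). All flows scale
linearly with functional-unit mass.

## Impact characterization

Midpoint scores are the linear map score_c = Σ_f amount_f·CF_{f,c} over
18 categories (FPM, FRS, FEW, FET, GW, HCT, HNCT, IR, LU, ME, MET, MRS,
OFHH, OFTE, SOD, TAD, TET, WC); normalization divides by per-person
reference values; endpoint translation is a second linear map onto human
health (DALY), ecosystem quality (species·yr) and resource availability
(USD2013). Real characterization-factor databases are proprietary and
are **not** shipped: the published midpoint/endpoint values are carried
as fixtures for ratio- and CV-level checks, and the synthetic generator
supplies full factor matrices (log-uniform over a configurable decade
span; endpoint factors at the magnitudes conventional for DALY,
species·yr and USD coefficients) so every stage can run end to end.
Consequently absolute impact magnitudes from synthetic runs are not
comparable to published ones — only structural properties (linearity,
ordering invariance, contribution shares) and the fixture-derived
statistics are.

Contribution analysis reports per-flow shares of each category score;
flows under the 0.1% cutoff are pooled into "other".

## Uncertainty

Each foreground flow carries pedigree scores (reliability, completeness,
temporal, geographic, technological; 1 best – 5 worst) mapped through
the classic ecoinvent-style indicator factor table to uncertainty
factors U_i, combined with a basic geometric SD U_b as

    gsd = exp( sqrt( Σ ln(U_i)² + ln(U_b)² ) ).

The factor table is configuration, not physics, and can be replaced.
Monte Carlo iterations (default n = 1000) perturb every flow amount with
an independent median-preserving lognormal draw (deterministic value =
geometric mean, spread = gsd) and re-characterize; flows are mutually
independent because no correlation structure is specified. Summaries
report mean, SD, CV = 100·sd/mean and 5th/95th percentile bounds with
linear interpolation between order statistics (quantile definitions
differ between tools, so this is stated explicitly). The sampled mean
converges to the deterministic score times exp(ln(gsd)²/2), the
lognormal mean identity, which the tests verify. Only foreground flows
are perturbed — background-database exchanges are out of scope.

One-at-a-time sensitivity perturbs a named scenario parameter by ±10%
and reports the percent response of the five highest normalized
categories, flagging any response of 10% or more.

## Trade-off model

Pathways are ranked by TOPSIS on five criteria in two groups:
environment — human health damage, resource depletion, ecosystem damage
(all minimized) — and nutrition — aggregate mineral gain/loss and
calories (both maximized). Group weights encode consumer priority:
[0.8, 0.2] environment-first, [0.2, 0.8] nutrition-first (mirror of the
stated environment weighting, which is the natural reading of "vice
versa"), [0.5, 0.5] equal. Each group's weight is split equally among
its criteria because only group-level preferences are stated. The
formulation is the canonical one: columns divided by their Euclidean
norm, weighted, ideal/anti-ideal at column extrema respecting direction,
Euclidean distances D⁺/D⁻ and closeness C = D⁻/(D⁺+D⁻). Closeness is
invariant to positive rescaling of any criterion column.

Practical equivalence applies a ±1% band to score differences of
adjacent alternatives, chained transitively into classes. The band is
interpreted on the **absolute** closeness difference by default (the
published usage is ambiguous between absolute and relative differences —
0.875 vs 0.861 is called insignificant at 1% while a 1.6% relative gap
is elsewhere called significant); a relative variant is available.

## Synthetic data

The generator emulates the study arm: tuber-level mineral profiles are
base concentrations (the raw-unstored column) times per-condition
storage and processing multipliers times median-preserving lognormal
noise at a configurable inter-tuber CV (default 10%, of the order of the
tuber-to-tuber spreads reported for macrominerals). Multiplicative
noise keeps ppm values positive and matches the right-skewed duplicate
spreads of the measured tables. What it does not emulate: intra-tuber
spatial gradients, sprouting biology, storage-time nonlinearity and
mineral-specific covariance — so passing generator-based tests
demonstrates correct statistical machinery, not biological fidelity.
The boiled-pathway composition table was published only as
supplementary material; the shipped `tableS_boiled_synthetic.csv` is a
deterministic generator product (raw rows times boiling leaching
factors, K and Na leaching most) and is flagged `synthetic` in the
data manifest. All fixture files are sha256-checked on load.

## Problem sizes and numerics

Default runs use the 2-week arm (16 pathways), n = 1000 Monte Carlo
iterations per pathway and seeds recorded in the run log; the package's
own test suite uses n up to 10⁵ for distribution-identity checks and
n = 100–1000 elsewhere, sizes at which the vectorized sampler completes
in seconds. Aggregates are recomputable to 1e-9; TOPSIS agrees with a
naive step-by-step implementation to 1e-10 on random matrices.
Degenerate inputs fail loudly: zero normalization references,
nonpositive lognormal medians, all-zero criterion columns, single-
alternative TOPSIS and >100% mass loss all raise with named context.

## Known limitations

- Absolute midpoint/endpoint magnitudes require proprietary background
  data and are fixtures, not outputs; synthetic end-to-end runs are
  structurally faithful but numerically arbitrary.
- The published closeness scores cannot be reproduced exactly because
  the full per-pathway decision inputs are not published; ranking tests
  on synthetic data are qualitative.
- Storage effects on minerals are treated as multiplicative and
  time-separable; the measured tables show nonlinear, sometimes
  non-monotone behaviour that the generator does not attempt to fit.
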