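# Methods

## The analysis problem

Beak increment profiles give one δ13C, δ15N and C:N measurement per crest
subsection, with per-individual metadata (species, capture year and location,
time series). Interpreting such values across a century requires removing
two nuisance signals at the base of the food web: the spatial structure of
the phytoplankton δ15N baseline (which otherwise masquerades as trophic
differences) and the temporal decline of baseline δ13C under anthropogenic
CO2 (the Suess effect plus increased phytoplankton fractionation). The
package corrects for both, then quantifies trophic position, individual
specialization, isotopic niches, and temporal/ontogenetic trends.

## Baseline surrogate (isoscape)

The original baseline fields come from a global isotope-enabled ocean
biogeochemistry hindcast. Running such a model is far outside desk scale, so
the package ships a parametric surrogate on the same 1.8° × 3.6° grid,
constrained to reproduce the hindcast's printed regional aggregates exactly:

- δ13C correction: `A_total · (r(year) − r(2023)) · g(lat)` with
  `A_total = 0.78 (Suess) + 2.3 (fractionation) + 0.12 (residual) = 3.2 ‰`.
  The published Suess and fractionation components sum to 3.08 ‰ against a
  stated 3.2 ‰ total; the residual component (labelled "other/circulation")
  closes the budget so all three numbers hold simultaneously. `g ≡ 1` by
  default (no longitudinal structure is documented), so the aggregates hold
  cell-wise, not only on average.
- Temporal ramp `r`: a logistic in year (midpoint 1975, steepness 0.06 yr⁻¹)
  normalised so r(1850) = 0 and r(2023) = 1 — monotone, mimicking
  accelerating fossil-fuel emissions. Any monotone normalised ramp would
  serve; the calibration targets are ramp-independent.
- Reference year 2023 (the most recent sample): corrections are 0 in 2023 and
  negative for earlier years, so "corrected" δ13C is expressed on the 2023
  baseline. The normalisation year is a free convention; within-individual
  and between-group contrasts are invariant to it.
- δ15N baseline: piecewise-linear in latitude — flat south of ~35°N, a
  2.2 ‰ decrease to the nitrate maximum near 60°N, a 0.5 ‰ rebound toward
  75°N (the rebound magnitude is a free choice; only its existence is
  documented), flat beyond; longitude-invariant; level anchor 5.0 ‰ at 35°N
  (typical North Atlantic phytoplankton values). A +0.05 ‰ transient drift
  follows the same ramp. The latitude knots sit at the grid-cell centers
  containing 35/60/75°N, so the 2.2 ‰ gradient between snapped cells is
  exact rather than attenuated by cell-center offsets.
- Grid cells are anchored at (−90°, −180°) with half-open edges (a point on
  an edge belongs to the cell to its north/east); the anchoring convention is
  not documented for the original grid and is fixed here for determinism.
- Fields represent the euphotic-zone (0–130 m) average directly; there is no
  depth argument. Real gridded correction files can replace the surrogate by
  writing them through the same `IsoscapeValue` interface.

## Corrections and trophic position

Subsections with C:N outside the inclusive window [2.90, 3.99] are flagged
and excluded from all downstream statistics (the bounds are retained because
observed kept data include both endpoints). No fixation correction is
applied. δ13C is corrected additively; because one baseline/correction pair
is used per specimen (capture year and snapped location — back-dating early
subsections to earlier years would require growth-rate and movement
assumptions the data do not support), within-individual contrasts are exactly
correction-invariant. The chitin offset (+4.8 ‰) enters only the TP
computation; the reported muscle-equivalent δ15N keeps its provenance. TP
uses a species→region TEF policy (3.8 ‰ Arctic, 3.4 ‰ North Atlantic
classical), configurable for other taxa.

## Specialization index

`s = Var_within / (Var_among + Var_within)` per individual and metric, on
corrected values only. "Among individuals" is implemented as the variance of
per-individual means (the between-individual component of the classical
within/total niche-width decomposition), matching the interpretation of s = 1
as complete overlap between individual and population; the pooled-variance
alternative is available via `among="pooled"`. Sample variances use n − 1
throughout because time series contain as few as 2 individuals. Note the
estimator's within-variance includes ontogenetic trend variation (it is the
raw variance along the crest); the generator's closed-form
`s_true = σ_w²/(σ_b² + σ_w²)` refers to the detrended components, so recovery
checks use flat-trend populations.

## Niche model

Sequential subsections of one beak are not independent samples, which is why
the niche is summarised through posterior uncertainty of a bivariate normal
rather than small-sample ellipse statistics: `Σ ~ IW(n−1, (n−1)S)`,
`μ|Σ ~ N(x̄, Σ/n)` (noninformative conjugate limit), default 1000 draws and
α = 0.95, with TP on the y-axis (not raw δ15N) to keep axes comparable
across years and regions. Niche size is `π · χ²₂(α) · √det Σ` per draw.
Directional overlap a→b is the Monte-Carlo probability that a point from
draw-wise `N(μ_a, Σ_a)` falls inside b's α-ellipse, averaged over paired
draws (`n_mc` points per draw, default 1000). Categories follow the printed
bins after half-up rounding to two decimals (the printed bins leave gaps at
(0.29, 0.30) and (0.60, 0.61)); only "large" is significant.

Period segmentation operates on the symmetrized categorical matrix of
ordered per-subsection niches: the main stable period is the longest terminal
all-large run; the initial period is the longest leading internally-large run
isolated (no large overlap) from everything after it; the first stable period
is the next internally all-large run of length ≥ 2; change is the remainder.
The verbal description this formalises does not fix every corner case; the
two clarifications (initial runs must be internally coherent, and a stable
period needs at least two subsections) are this package's choices, and empty
periods are reported as absent rather than forced.

## Trend statistics

Smoothers are penalized regression splines: a B-spline basis of dimension k
(cubic for k ≥ 4, quadratic at k = 3) with interior knots at quantiles, a
second-difference coefficient penalty, and a sum-to-zero constraint on the
smooth. The smoothing parameter minimises GCV on a fixed logarithmic grid
(10⁻⁸–10¹⁰, 91 points) via a Demmler–Reinsch decomposition, with near-ties
resolved toward the larger λ (this makes noise-free polynomial data collapse
to the penalty null space, edf → 1, instead of an arbitrary point on the flat
GCV ridge). k is selected from candidates {3…10} (restricted to admissible
designs) by AICc with the effective parameter count edf + intercept + scale.
Significance of the smooth is a seeded permutation test on deviance explained
(default 999 permutations; λ re-selected for every permutation so observed
and permuted statistics are exchangeable); p ≥ 1/(B+1) by construction. The
repeated-measures variant adds fixed per-individual intercepts (reported as
offsets about their mean), not random effects, matching "individual as a
factor". Permutation of y in the grouped fit also breaks the group
structure; for the pipeline's use (testing the smooth against a null of no
ontogenetic trend) this is conservative in the common case of group effects
inflating permuted deviance.

Rank tests: Mann–Whitney uses exact enumeration for total n ≤ 16 without
ties, and otherwise the tie-corrected normal approximation *without*
continuity correction (so identical samples give p = 1 exactly).
Kruskal–Wallis is scipy's tie-corrected H (all-identical inputs short-circuit
to H = 0, p = 1); Dunn's pairwise Z uses the pooled-rank variance with tie
correction and Holm adjustment by default (the multiplicity adjustment is not
documented in the source analysis; Holm is uniformly valid). The
Skillings–Mack statistic uses the adjusted rank-sum vector with its
design-based covariance and a pseudo-inverse quadratic form (χ² with
rank(Σ) df); it reduces exactly to Friedman's χ² on complete balanced
designs, which is the independent oracle in the tests. Ties are handled by
average ranks only. The Nemenyi post hoc (studentized-range reference) is
computed on blocks observed for every treatment. Spearman's ρ uses exact
permutation enumeration for n ≤ 9 without ties, the t-approximation
otherwise. All tests are two-tailed.

## Synthetic generator

Defaults are set to the observed magnitudes of the study system: anterior
δ13C increase ≈ 0.33 ‰/subsection over subsections 1–4 then a slight
decline, TP increase ≈ 0.25/subsection over 1–5 then ≈ 0.04; δ13C level
near −18 ‰ and TP near 3.3 at subsection 1; variance components giving
detrended s ≈ 0.4 for δ13C and ≈ 0.94 for TP; C:N centred at 3.45 (SD 0.12,
truncated to the acceptance window) with a 5 % outlier fraction outside it;
8–23 subsections per beak; the default scenario pack mirrors the two-species
sampling design (six time series 1900–2017 for the Arctic species, four
1844–2018 for the boreal one, 4–13 individuals each). Raw values embed the
baseline fields exactly (see module docstring), so correction correctness is
a machine-precision round trip, and a constant-ecology population generated
across 1850–2023 must show no corrected-δ13C temporal trend — both are
tested. The generator does not emulate predator-stomach degradation beyond a
posterior-trim flag, lifetime movement (one location per individual),
laboratory measurement drift, or non-normal noise; passing tests therefore
validate the estimators under the stated model, not robustness to those
real-data features.

Allometries in the generator are synthetic power laws chosen for realistic
size ranges (the published coefficient sources are external to this package);
analyses of real data should supply published coefficients through
`AllometryCoefficients`.

## Problem sizes and numerical choices

The test suite uses deliberately small problem sizes chosen as the smallest
that make each property sharp: 50 replicates of 10 × 12 populations for
specialization recovery (±0.10), 100 replicates with 199 permutations for the
detrending null (≥ 90 % of p > 0.05), 10⁴ Monte-Carlo points per draw for the
self-overlap ≈ α check (±0.02), 400 simulations for type-I-error calibration
of the rank tests (±0.03). Degenerate inputs error explicitly (fewer than 2
individuals/subsections for s, zero total variance, singular niche scatter,
n < 3 niches, non-SPD covariances, out-of-range probabilities) rather than
returning NaN. All randomness flows through `numpy.random.default_rng`
seeded at the interface.

## Known limitations

- The isoscape surrogate reproduces regional aggregates, not the hindcast's
  spatial patterns; per-cell values are smooth interpolations.
- One baseline per specimen ignores within-life movement and back-dating of
  early subsections.
- The smoother family is Gaussian-response only; no tensor smooths or
  alternative links.
- Niches are strictly bivariate normal; no ≥ 3-dimensional niches or
  standard-ellipse (SEA) estimators.
- Exact small-sample Spearman enumeration is O(n!) and is restricted to
  n ≤ 9.
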