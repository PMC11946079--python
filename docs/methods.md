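# Methods

## The design and its analysis

The trial structure is a four-factor, three-level orthogonal array
L9(3⁴): irrigation amount IA (50 / 75 / 100% of ET_c, realized as
seasonal volumes of 1525 / 2287.5 / 3050 m³ ha⁻¹ in season one and
1475 / 2212.5 / 2950 m³ ha⁻¹ in season two) and stage fertilizer rates
FI, FII, FIII (562.5 / 750 / 937.5 kg ha⁻¹ each). The array is pinned
to the packaged treatment table (`data/table1_treatments.csv`): row T1
has every factor at level 1, T5 is (2, 2, 3, 1), and so on. The
constructor re-validates column balance (each level exactly three times
per column) and pairwise orthogonality (all nine ordered level pairs in
every column pair) as exact integer checks, so a corrupted array cannot
propagate. Two useful consequences of the array's strength-2 structure
are used elsewhere: any two distinct runs agree in exactly one column,
and level means of an unrelated factor are forced equal under a purely
additive response.

Irrigation "level" deliberately has two representations: the ET_c
fraction (what the design varies) and the metered seasonal volume (what
enters efficiency metrics and savings arithmetic). Savings percentages
are computed per year from the volumes; by construction of the table
the two years give identical percentages, and the published volumes
reproduce the 75% and 50% fractions exactly.

**Range analysis.** For each factor j and level l, k̄(j, l) is the mean
response over the three runs with factor j at level l; R_j = max k̄ −
min k̄ ranks factor influence, and the optimal level is the argmax
(benefit indicator) or argmin (cost indicator) of the level means, ties
resolving to the lower level index. Because the design is balanced, the
mean of each factor's three level means equals the grand mean — the
suite asserts this identity on random responses. Replicates must be
averaged before range analysis (the function takes exactly nine
values); significance testing of factor effects is out of scope and is
left to standard ANOVA tooling.

**Input-reduction note.** Relative to full irrigation (T7), the
mild-deficit optimum T5 uses 25% less water in both seasons; its
fertilizer total (2250 kg ha⁻¹) is 20.0% below the maximum-rate
treatment T3 (2812.5 kg ha⁻¹) and equal to T7's. The package reports
whatever the table arithmetic gives for the requested pair and
hard-codes no headline percentage.

## Efficiency metrics

WUE = Y/IA (kg m⁻³) and PFP = Y/F (kg kg⁻¹), with Y the fruit yield
(kg ha⁻¹), IA the seasonal irrigation volume (m³ ha⁻¹) and F the season
fertilizer total across the three stages — per-stage productivity is
not defined. Records are computed per replicate with the year's own IA,
then averaged within year and across years; this "per-year then
average" convention is the default because efficiency in a given season
should be judged against that season's water.

## Entropy weighting

Indicators are first benefit-oriented: cost indicators (by default
fruit hardness Hd, titratable acidity TA and nitrate NA) are replaced
by x' = max(x) − x + min(x), which flips direction while preserving
non-negativity (a plain max − x complement would zero the worst
alternative and distort shares more than necessary). Columns are then
normalized to proportional shares y_ij = x_ij / Σᵢ x_ij and the scaled
Shannon entropy per indicator is E = −(1/ln n) Σ y ln y with the
0·ln 0 = 0 convention, so E ∈ [0, 1] with E = 1 for a uniform column
and E = 0 for a one-hot column.

Two weight schemes share this entropy:

* classical: H_i = (1 − E_i)/Σ(1 − E_i), undefined when every E = 1;
* exponential form:
  H_x = [exp(k(ΣE − E_x + 1)) − exp(k E_x)] / Σ_l [exp(k(ΣE − E_l + 1)) − exp(k E_l)].

For entropies in [0, 1] the exponential numerator is positive and
strictly decreasing in E_x, so weights are non-negative, sum to one and
never reward a less-informative indicator; equal entropies give exactly
uniform weights. The coefficient k (default 1, exposed everywhere)
controls dispersion: smaller k pulls the weights toward uniform. In the
high-entropy regime that proportional shares of nine alternatives
actually produce (all E ≳ 0.97 in practice; the property suite tests
E ∈ [0.6, 0.99]) the exponential scheme's weight spread never exceeds
the classical scheme's — that compression is its purpose, since
classical weights explode on near-one entropy differences (e.g.
E = (0.8, 0.9) gives classical weights (2/3, 1/3) but exponential
weights (0.554, 0.446)). The compression guarantee does **not** extend
to low entropies, where the inequality can reverse; this is a property
of the formula, not an implementation artifact.

A shift of +0.01 is applied to the normalized shares to remove zeros,
and the shifted matrix is what composite scores are computed on
(S_a = Σ_i H_i z_ai). Entropy itself is computed on the unshifted
shares by default — the shift exists to protect the score aggregation
from zero cells, and shifting before the entropy would perturb E for
every indicator whether or not zeros occur. The alternative (entropy on
the renormalized shifted shares) is available behind the
`entropy_on_shifted` flag. The shift is affine and is not renormalized;
scores are therefore comparable within a run, not across differently
sized alternative sets.

Weights are computed per evaluation dimension — yield, quality,
efficiency — so each dimension's block sums to one (a dimension with a
single indicator takes weight 1), and also globally across all included
indicators; the global block is the default source of TOPSIS weights.

## Virtual-ideal TOPSIS

After cost inversion, columns are normalized by their Euclidean norm
(z = x/√Σx², the TOPSIS standard; min-max normalization is available
behind a flag, and no z-scoring is applied by default). The real ideals
Z± are the column-wise max/min; the virtual ideals extrapolate them:
V⁺ = 2Z⁺ − Z⁻ and V⁻ = 2Z⁻ − Z⁺. Virtual coordinates may be negative;
distances are unaffected and nothing is clipped. All distances are
root-weighted-Euclidean √(Σ w_j(ref_j − z_j)²) — a no-root variant was
rejected because it is dimensionally inconsistent with blending the
real and virtual distances linearly and breaks the closed-form checks
below. The blends S± = αD± + βF± use α = 0.9, β = 0.1 by default, and
C = S⁻/(S⁺ + S⁻).

Closed forms anchor the implementation: with d the weighted distance
between Z⁺ and Z⁻, an alternative sitting exactly at Z⁺ has
(D⁺, D⁻, F⁺, F⁻) = (0, d, d, 2d), hence C = (α + 2β)/(α + 3β) = 11/12
at the defaults, and symmetrically 1/12 at Z⁻; the two always sum to 1.
With β > 0, C never reaches 0 or 1, which is exactly the discrimination
the virtual ideals buy near the boundary. At α = 1, β = 0 the method
collapses to classical TOPSIS, and the suite checks exact agreement
with an independently written textbook implementation. A variance-gain
claim (virtual blending always spreads C more than classical) is not
asserted — it is not true in general.

Ranking is by descending C with ties broken by input (treatment id)
order, deterministically. If all alternatives are identical, S⁺ = S⁻ =
0 and the closeness is refused with an explicit error rather than an
arbitrary 0.5.

## Synthetic trials

The generator emulates the study conditions: two seasons, nine
treatments on the L9 array, three replicate plots (27 plots per year),
twelve indicators. Additive indicators follow

    value = (baseline + Σ_j effect_j(level_j) + year_offset) · (1 + CV·ε)

with ε standard normal from a single seeded stream. Effects are
additive on the natural scale and the noise multiplicative (CV,
default 5%), which keeps strictly positive quantities positive at
plausible CVs; the rare non-positive draw is resampled (up to 100
attempts, then a hard error — reachable only with unrealistic CVs).
The year effect is a fixed shared offset (±1% of baseline by default),
a stand-in for a random season effect; full mixed-model simulation,
spatial plot correlation and mechanistic crop growth are out of scope.

WUE and PFP are not generated independently: each replicate's values
are derived from its generated yield and the treatment's irrigation
volume and fertilizer total, so the efficiency definitions hold
identically downstream. Their ground-truth optimal levels are obtained
by exact enumeration of noiseless level means on the design (no
sampling involved). For additive indicators the truth is read directly
off the configured effects.

The default panel (yield; Hd, VC, SP, LC, TA, SS, NA, SSC, MC; WUE,
PFP) uses magnitudes plausible for greenhouse tomato — e.g. yield
5.5×10⁴ kg ha⁻¹, vitamin C 24 mg 100 g⁻¹, nitrate 140 mg kg⁻¹ — with
irrigation as the dominant factor and stage fertilizer secondary,
mirroring how deficit-fertigation trials qualitatively behave. The
magnitudes are deliberately **not** calibrated to any measured dataset:
passing recovery tests shows the pipeline recovers what the generator
planted under additive-plus-noise conditions, not that real greenhouse
data satisfy those conditions.

`make_dominant_scenario` rewrites the effects so a chosen treatment is
strictly best on every indicator: each factor contributes 0 at the
target's level and ∓10% of baseline elsewhere (enlarged if needed to
keep the margin at three noise standard deviations). Since two distinct
L9 runs disagree in exactly three columns, the target's margin over any
rival is three effect units. Derived indicators are switched to
additive in this scenario, because WUE dominance cannot be guaranteed
through the yield/volume quotient alone.

## Verification study sizes

The recovery studies run at the sizes the suite and acceptance script
report: 50 random noiseless configurations for exhaustive
optimal-level recovery (every factor × indicator must match the truth);
200 seeded trials at 5% CV and 10%-of-baseline effects for dominant
treatment recovery (required ≥ 95%, observed 100%); 1000 random 9×12
matrices for the classical-TOPSIS equivalence (max |ΔC| ≤ 10⁻¹²); 1000
random entropy vectors for the weight-simplex and monotonicity
properties. The full chain on one trial is well under a second, so
these sizes run in seconds.

## Known limitations

* The evaluation is as objective as entropy weighting makes it — which
  is to say, driven entirely by dispersion; an indicator that varies
  little gets little weight regardless of agronomic importance.
* Indicator screening is advisory and config-driven (user-supplied
  stability flags, e.g. a fruit-shape index known to be unstable); no
  correlation-strength threshold is imposed, and removing a whole
  evaluation dimension is refused.
* Spearman correlation significance for n = 9 alternatives has little
  power; the matrix is reported for inspection, not inference.
* Composite scores and closeness coefficients are ordinal tools:
  differences between adjacent ranks should not be over-interpreted,
  especially under the 0.01 shift's (documented, unrenormalized)
  affine distortion.
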