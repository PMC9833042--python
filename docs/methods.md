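# Methods

`rubiscotherm` models how the growth temperature of a C3 plant (here,
Arabidopsis grown at 10 °C vs 30 °C air temperature) reshapes Rubisco's
kinetic constants, and how those biochemical shifts propagate to leaf-level
CO2 assimilation. It implements the desk half of such a study end to end:
temperature scaling of in vitro kinetics, forward photosynthesis modelling,
and inverse estimation from gas-exchange curves, with a seeded generator
standing in for raw instrument logs.

## Temperature responses of kinetic constants

Each constant (carboxylation turnover `kcat_co2`, s⁻¹; specificity factor
`s_co`, M M⁻¹; Michaelis constants `k_c`, `k_o`, dissolved µM) carries a
value at 25 °C and an activation energy `Ea` (kJ mol⁻¹) in the Celsius
Arrhenius form

    P(T) = P(25) · exp[(T − 25)·Ea·10³ / (298·R·(273 + T))],  R = 8.314 J K⁻¹ mol⁻¹.

This single-anchor form is exact at 25 °C, monotone in T for fixed-sign Ea,
and is used both for evaluation and for nonlinear least-squares fitting of
assay series (`fit_arrhenius`; the start point comes from the log-linear
transform, so fitting is deterministic and noiseless data round-trip to
solver precision). `Ea` of the specificity factor is negative
(≈ −20 to −24 kJ mol⁻¹): specificity declines with warming. Temperatures
are restricted to −10..60 °C; thermal deactivation above ~40 °C is
deliberately out of scope, so extrapolations near the upper bound should be
read as "no-deactivation" projections.

The bundled reference table (`data/reference_kinetics.csv`) holds the measured
means for the 10/20/30 °C growth treatments. The key contrast it encodes:
cold-grown Rubisco has Ea(K_C) ≈ 54.8 against 40.4 kJ mol⁻¹ for warm-grown,
so the cold enzyme's K_C overtakes the warm enzyme's by ~25% at 35 °C even
though the 25 °C values are indistinguishable.

## Derived quantities and units

Two derived quantities feed the leaf model:

* apparent Michaelis constant at 21 % O2, `K_C21%O2 = K_C·(1 + O/K_O)`;
* CO2 compensation point without day respiration, `Γ* = 0.5·O/S_C/O`
  (one CO2 released per two oxygenations). The source study does not print
  its Γ* formula; this standard definition is the package's choice.

Both start in dissolved µM. Gas exchange lives in mole fractions
(µmol mol⁻¹), so the package bridges units with a Henry-law solubility
table (µM per µbar partial pressure, 0–40 °C in 5 °C steps, linear
interpolation; CO2 from standard Henry constants — 0.0339 mol L⁻¹ atm⁻¹ at
25 °C, cf. Carroll, Slupsky & Mather 1991 — and O2 from Benson & Krause
1984). The table ships as data (`data/solubility.csv`) and is replaceable.
All conversions use the cuvette-reported *leaf* temperature (8.8 / 19.2 /
27.4 °C for air setpoints of 10 / 20 / 30 °C), not air temperature. The O2
mole fraction used for `K_C21%O2` and Γ* is a configuration value
(default 210 000 µmol mol⁻¹); piecewise-linear interpolation is adequate at
the table's ≤5 °C spacing.

## Forward FvCB model

Net assimilation is the minimum-limb Farquhar–von Caemmerer–Berry model.
The limitation is decided on potential carboxylation rates

    W_c = V_cmax·C_c/(C_c + K_m),    W_j = J_max·C_c/(4·C_c + 8·Γ*),

and the net rate of the limiting limb is `A = (1 − Γ*/C_c)·W − R_d`, i.e.

    A_c = V_cmax (C_c − Γ*)/(C_c + K_m) − R_d
    A_j = J_max (C_c − Γ*)/(4 C_c + 8 Γ*) − R_d.

Above Γ* this is identical to taking the smaller net rate; below Γ* it
keeps the low-CO2 region Rubisco-limited (taking the smaller *net* rate
there would flip the tag to the regeneration limb, whose expression is
merely more negative — carboxylation, not RuBP supply, is what runs out at
low CO2). The electron-transport limb uses the NADPH-basis denominator
`4C_c + 8Γ*` with J = J_max, because the reference measurements were taken
at saturating light and J_max is fitted directly; no light response is
modelled. The min rule is applied pointwise with a hard transition (no
hyperbolic smoothing), matching how the transition point is later
estimated. Ties at the crossover are tagged Rubisco-limited; both limbs
equal −R_d exactly at C_c = Γ*, so the composite curve is continuous.

With finite mesophyll conductance, `C_c = C_i − A/g_m` turns each limb into
a quadratic in A (the Ethier–Livingston substitution):

    A² − A·[g_m(C_i + kd) + vm − R_d] + g_m·[vm(C_i − Γ*) − R_d(C_i + kd)] = 0,

with `(vm, kd) = (V_cmax, K_m)` or `(J_max/4, 2Γ*)`. The physically
admissible branch is the lower root; for positive parameters the
discriminant equals `(g_m(C_i+kd) − vm + R_d)² + 4 g_m vm (kd + Γ*) ≥ 0`,
so a negative discriminant only ever signals inconsistent parameters. The
lower root is evaluated as `2c/(b + √disc)` when `b > 0` to avoid
cancellation at very large g_m. `g_m = math.inf` is the sentinel for
C_c = C_i. Correctness of root selection is established against an
independent bracketed fixed-point solve of `A = A_cc(C_i − A/g_m)` in the
test suite (agreement ≤ 1e−8 over a seeded parameter sweep), not trusted by
formula. Note the exact gap between the `g_m = 10⁶` solution and the
C_c = C_i model is first-order `|A|·(dA/dC_c)/g_m` (a few 1e−6 at this
parameter scale) — a model difference, not numerical error — and shrinks
as 1/g_m.

## Inverse estimation (A–C_i fitting)

`fit_aci_ethier` estimates (V_cmax, J_max, g_m) per curve with R_d fixed to
the dark-measured value — respiration is never fitted. Candidate
transitions are the observed splits of the C_i-sorted records (an
exhaustive, deterministic grid; with ≤14 points a continuous search buys
nothing). For each split, (V_cmax, g_m) are fitted on the low limb and
(J_max, g_m) on the high limb by uniform-weight least squares on the limb
quadratics; the chosen transition minimises |g_m(rubisco) −
g_m(regeneration)| and the reported g_m is the mean of the two limb
estimates (the criterion defines the transition, not the final estimator;
both limb values are always reported). Start values are deterministic: a
closed-form infinite-g_m linear estimate for V_cmax (and J_max), and
g_m = 0.15 mol m⁻² s⁻¹, midrange of the reference fits.

The minimum number of points per limb defaults to **2** — the number of
free parameters per limb — not 3. This matters: with the reference
cold-grown/30 °C parameters (J_max/V_cmax = 1.76, gas-phase
K_m ≈ 850 µmol mol⁻¹) the limb crossover sits near C_i ≈ 670, so the
printed 13-step protocol contains only two genuinely regeneration-limited
steps (C_a = 1200 and 1800). Forcing three points into that limb drags a
Rubisco-limited point across, biasing the limb's g_m by tens of percent
even on noiseless data; with two points the noiseless round trip is exact
for all four design cells. Callers wanting the more conservative behaviour
pass `min_points_per_limb=3`.

`fit_mm_kc21` regresses gross assimilation `A_N + R_d` against
`vmax·(C_c − Γ*)/(C_c + K)` with Γ* fixed, giving the operational in vivo
`K_C21%O2`; `C_c` comes from the fitted g_m. An optional mask restricts the
records used. The CLI fits the whole inferred A–C_c curve (all C_c > 0):
the Rubisco-limited portion alone barely saturates, leaving K nearly
unidentified under noise, whereas the whole-curve regression is the
operational in vivo constant the reference study reports.
`normalise_by_sites` divides the vmax term by the leaf's Rubisco site
content to report an in vivo kcat per site; both that flag and the gross
(A+R_d) convention are explicit because the printed form of the source
equation is ambiguous on both points. `initial_slope` is a plain OLS slope
of A_N on C_c below a threshold, for carboxylation-efficiency comparisons,
and `percent_difference` reproduces the reduction/excess contrasts used to
compare growth treatments.

## Synthetic data generator

The generator defines the study conditions every recovery test runs under:

* design: 2 growth treatments × 2 measurement temperatures (leaf 8.8 and
  27.4 °C), 4–7 replicate curves per cell in the reference study (default
  5 here);
* C_a protocol: 400, 200, 150, 100, 75, 50, 300, 400, 400, 500, 750, 1200
  (+1800 at 30 °C only), duplicates included;
* truth: the bundled reference means (`data/reference_photosynthesis.csv`)
  for V_cmax, J_max, R_d, g_m, g_s and Rubisco sites per cell, with Γ*/K_m
  derived from the bundled kinetics at leaf temperature;
* C_i from C_a by a constant draw-down ratio 0.7 with per-step Gaussian
  jitter (sd 0.02, clipped to 0.40–0.95) standing in for stomatal dynamics
  — only C_i is consumed downstream, so no stomatal model is fitted;
* noise: additive Gaussian on A_N (default σ = 0.2 µmol m⁻² s⁻¹, the order
  of the reference replicate SEs) and mean-one multiplicative lognormal
  noise on in vitro assay rates (default CV = 5 %). A single noise tier:
  plant-to-plant and within-curve variance are not separated, because the
  reference study reports only group SEs.

Everything is a pure function of (truth, cell, replicate): seeds derive
from `numpy.random.default_rng([seed, cell_index, replicate])`, so datasets
are byte-reproducible and zero-noise datasets make every downstream fit an
exact round trip. What the generator does *not* emulate — instrument
drift, leaks, stomatal patchiness, light gradients, temperature drift
within a curve — bounds what passing recovery tests show: they validate the
estimators under the stated noise model, not the instruments.

## Problem sizes and numerical choices

The recovery studies run at deliberately desk-scale sizes: 50 seeded
replicates per design cell for the σ = 0.2 study (medians of V_cmax and
J_max land within 10 %, g_m within 20 % of truth), a 30-replicate
σ ∈ {0.4, 0.2, 0.1, 0} sweep for the monotone-error check, 100 seeds for
the assay-Ea recovery, and a 100-point sweep for the fixed-point oracle.
Optimiser: SciPy `curve_fit` (TRF with bounds g_m ∈ [1e−3, 5] mol m⁻² s⁻¹,
rates positive), `maxfev = 20000`; non-convergent splits are skipped and
reported, and a fit error lists per-split diagnostics if none converge.
Ties in the transition criterion resolve to the first (lowest-C_i) minimal
split. Degenerate inputs (all C_c at Γ*, zero signal) raise typed errors
rather than returning numbers.

## Known limitations

* No triose-phosphate-utilisation limitation, light/temperature response of
  J_max, Rubisco activation state, CO2/HCO3⁻ equilibria, or energy-balance
  leaf temperature.
* The in vivo K_C21%O2 from whole-curve regression is an operational
  constant; it mixes limitation states and is not comparable 1:1 with the
  in vitro K_C21%O2 (the reference study's own in vivo values differ from
  in vitro ones severalfold).
* Group comparisons are means/SE and percent differences only; no ANOVA or
  post-hoc inference is provided.
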