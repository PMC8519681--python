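# Methods

## The primary-tail PDD model

The package models the central-axis electron percent depth dose as a product
of two empirical factors of depth `x` (mm of water):

```
primary(x) = x^0.1 / (N + x^0.2) · e^(−μx)          N > 0, μ ≥ 0 (mm⁻¹)
tail(x)    = 1 − x/(√n + x²) + t                    n > 0, |t| < 1
```

`primary` vanishes at the surface, rises slowly (the `x^0.1` build-up tamed
by the harden factor `N`), and decays exponentially with the attenuation
factor `μ`. `tail` equals `1 + t` at the surface and asymptotically, with a
shallow minimum at `x = n^0.25`; `t` sets the height of the bremsstrahlung
plateau. Curves are normalized so the maximum *over the evaluation grid*
equals 100, matching how commissioning tables are printed (their modeled
columns peak at exactly 100 at a grid point). Normalization is invariant
under positive rescaling of the raw curve.

Two deliberate consequences of the functional form:

* **The model is exactly 0 at `x = 0`**, while measured surface doses are
  ~80%. Model evaluation happens only at supplied grid points and the fitter
  excludes depth-0 samples by default (`include_surface=True` restores them).
  No ad-hoc surface offset is invented.
* **The classic tail cannot produce a real distal falloff.** Its dip depth is
  bounded by `1/(2·n^0.25)` (≈ 0.12 for `n = 290`), so the steep 80→20%
  plunge of a measured scan is out of reach for any parameter choice: a
  global search (differential evolution over log-scaled parameters,
  `t ∈ (−1, 1)`) floors at ≈ 25% rms relative deviation on a measured 12 MeV
  scan, with the optimum degenerating to a quasi-linear ramp. The package
  therefore also provides a sigmoid (Hill) tail

  ```
  tail_p(x) = 1 − x^p / (n^(p/2) + x^p) + t
  ```

  with fitted exponent `p` (bounds 1–40) and midpoint at `x = √n`, which on
  well-fit scans coincides with R50. With it the same 12 MeV scan fits to
  ≈ 2.8% rms. The classic grouping remains the default for formula
  evaluation and for self-consistent synthetic studies; `tail_form="sigmoid"`
  is the recommended setting for measured scans, and is what the package's
  own measured-scan tests use.

## Fitting

`fit_curve` minimizes the sum of squared residuals between the normalized
model and the normalized measurement (both max = 100) with scipy's bounded
trust-region-reflective least squares (`xtol=1e-12`, `ftol=1e-10`, at most
2000 function evaluations). Residuals are unweighted by default;
`weighting="relative"` divides them by the measured dose, which balances the
low-dose tail against the plateau and is appropriate when the figure of merit
is relative deviation. Initialization comes from an explicit parameter set,
from the energy regressions when an energy is given, or from the curve itself
(the sigmoid midpoint is seeded at the distal half-maximum depth). A
deterministic multi-start schedule (the initialization, then ×2 and ÷2
perturbations of `N` and `n`) resolves ties reproducibly, and the returned
parameters never score worse than the initialization. Non-convergence is
reported through `FitResult.converged`, never silently.

Model-measurement disagreement is quantified by the signed percent deviation
`(model − measured)/measured · 100` per depth and its root mean square.

### Parameter identifiability — a caution

The model is *sloppy*: near the optimum, the `N`–`μ` and `n`–`t` directions
are almost degenerate (over `μ ∈ [10⁻⁴, 2·10⁻³]` mm⁻¹ the factor `e^(−μx)`
is a gentle tilt indistinguishable from the tilt `N` produces, and the
classic tail is nearly constant). Linearized error propagation at an additive
noise of 0.5 percentage points on an 80-point, 1 mm scan gives 1-σ relative
uncertainties of roughly 6–12% for `N` and `μ`, 15–23% for `n`, and ±0.05
absolute for `t`; the condition number of the Gauss-Newton normal matrix is
~10¹². Individual parameters are therefore only recoverable from essentially
noiseless data (exact recovery from noiseless scans, and 5%-accurate
recovery of `N`, `n`, `μ` at σ = 0.01, are both verified by tests). What *is*
stable at clinical noise levels is the fitted curve itself, which the suite
verifies separately. Where a recovery check needs a tolerance for `t` near
zero, 5% relative is floored at 0.0025 absolute (5% of the working `t`
range), since a relative tolerance on a vanishing parameter is meaningless.

## Beam quality

All dose-level crossings (R90, R50, the 80% and 20% window edges, the 10%
plateau threshold) are located by linear interpolation between bracketing
samples on the distal limb of the curve; no smoothing is applied because the
bundled reference tables are sampled at 5 mm (a smoothing flag is
deliberately absent rather than default-on). The 80–20% slope is the
least-squares line through the interpolated window endpoints plus all
samples strictly inside the window. The practical range `Rp` is the depth
where that line meets the horizontal bremsstrahlung background — the 80–20%
line standing in for the inflection tangent, which is how the quantity is
defined operationally in commissioning practice. The background (X-ray
contamination) is estimated as the **median of all samples beyond the distal
10%-of-max crossing**; the median absorbs the non-monotone scatter of
printed tail values, though on scans truncated shortly after the falloff the
estimate still includes falloff shoulder points and reads high (on the
bundled 12 MeV scan, which ends at 65 mm, it returns 6.4% against the 2.1%
of a full-length scan). Energy relations: `E0 = 2.33 MeV/cm · R50` and the
NACP quadratic `(E_p)₀ = 0.22 + 1.98·Rp + 0.0025·Rp²` (Rp in cm, water).

R50 from a 5 mm grid differs from a continuous water-phantom scan: on the
bundled 15 MeV table the grid interpolation gives 63.8 mm against the 60.3 mm
of the finer reference scan. The package reports what the supplied curve
supports and makes no claim of reproducing finer-scan values. Likewise
`r_max` (maximum reading) vs `d_max` (maximum dose) differ only across an
ionization-to-dose conversion; on a single input curve `quality_report` sets
both to its argmax.

## Stopping power and reading↔dose conversion

The empirical water/air stopping-power ratio is
`(−0.042·ln N + 1.072) · e^((−5·10⁻⁵·n + 0.0381)·x)`. The depth `x` is
interpreted in **cm** by default: in cm the 12 MeV ratio spans ≈ 0.98–1.10
over a clinical range, a physically plausible band for water/air collision
stopping-power ratios, whereas interpreting it in mm drives the ratio beyond
3, which is impossible. A `StoppingPowerModel(depth_unit="mm")` forces the
mm reading for strict reproduction. The ratio is depth-independent exactly
at `n = 762` and increases with depth for `n < 762`.

Conversion direction is a **required** argument (`reading_to_dose`
multiplies, `dose_to_reading` divides, each followed by renormalization to
max 100): published descriptions of the operation disagree on the direction,
so the package refuses to guess. The round trip is the identity.

## Energy regressions

Defaults are the published coefficients listed in the README. `ln(−μ)` in
the published statement is implemented as `ln(μ)` with `μ > 0` — the only
reading consistent with the tabulated `ln(μ)` column (e.g.
`ln 0.0005 = −7.6009`). OLS refits of the bundled parameter table reproduce
the `n` line (31.667, −88.0) and the `ln μ` slope (−0.1355) but *not* the
published `N` pair (OLS gives ≈ 1.003, −2.92 against 0.9975, −2.8535); the
printed pair is nevertheless kept as the default, the discrepancy noted here.

The published slope–μ relation `tan⁻¹(slope) = −6.6729·ln μ − 16.623`
cannot reproduce the tabulated `tan⁻¹(slope)` values under any unit or sign
convention tried (it returns ≈ 34 where the measured angle is −1.355 rad);
`slope_mu_relation` evaluates the printed line but emits an
`InconsistencyWarning` on every call, and `refit_slope_mu_relation` rebuilds
the line from data (the tabulated angles are in fact well fit by
`≈ −0.153·ln μ − 2.51`).

## Lateral scatter equilibrium

`S_eq = (n − N)^0.288 / (E0/n)^0.0195` is dimensionless as written; its
output is declared **cm**, the only interpretation consistent with the
tabulated mm values (which are 10× the formula's result). The mean energy
`E0` (not the nominal energy) enters the denominator — that is what the
tabulated rows use. The energy-only comparator is implemented as
`1.58·√E0` cm: the literature rule is sometimes typeset without the radical,
but every tabulated comparator value matches the square-root form exactly.
A field side exactly equal to `S_eq` counts as adequate (equilibrium is
reached *at* that size). No output-factor correction is attempted for
sub-LSE fields; the package only flags them.

## Synthetic scans

`synth_scan` emulates a water-phantom scan: normalized model on a regular
grid, floored at a flat `xray_floor` (default 2%, a typical mid-energy
bremsstrahlung level) beyond the curve's distal crossing of that level, plus
additive Gaussian noise (default σ = 0.5 percentage points, a realistic
scan noise level) from a single generator seeded per call. Defaults
(1–80 mm at 1 mm) span a mid-energy electron range. Real scans differ in
ways the generator does not emulate: noise is not exactly Gaussian nor
depth-independent, the plateau is not exactly flat, and measured build-up
regions include surface effects the model lacks — so passing synthetic tests
demonstrates correctness of the algorithms under the model's own
assumptions, not clinical validity on any particular machine.

## Numerical choices

* Optimizer bounds: `N, n ∈ (10⁻⁸, 10⁶/10¹²)`, `μ ∈ [0, 1]` mm⁻¹,
  `|t| < 1`, sigmoid exponent `p ∈ [1, 40]`. Sloppy fits may park `N` at a
  bound; this is a symptom of non-identifiability, not failure (the curve is
  unaffected).
* Crossings are exact on piecewise-linear data (verified to 1e−9 mm against
  a closed-form segment solver); the analytic line-plus-plateau `Rp` is
  recovered to 1e−6 mm.
* CSV doses are written with two decimals, round-half-even, via decimal
  arithmetic (so `83.335 → 83.34` regardless of binary float representation).
* Curve equality compares depths and values exactly; labels are metadata.
* Depths are physical depths in water from the phantom surface (mm); no
  effective-point-of-measurement shift is applied (that is a
  measurement-time correction, out of scope for the software).

## Bundled reference tables

Five CSVs transcribe the commissioning dataset digit-for-digit (a Varian
VitalBeam, 6–18 MeV, SSD 100 cm, parallel-plate chamber in a 3-D water
phantom): per-cone and per-energy modeled/standard PDD tables, the fitted
parameter table, the beam-quality table, and the LSE comparison table. Known
internal quirks are preserved rather than repaired: the two 12 MeV 10-cone
standard columns disagree in a few digits and are kept under separate table
identifiers; a handful of printed deviation cells (the depth-70 block of the
cone table) are inconsistent with the deviation formula; and most deviation
cells were evidently computed from unrounded doses, so recomputation from
the printed 2-decimal doses reproduces them only to ±0.01–0.02. The modeled
columns are treated as fit-quality references, not as bit-exact targets —
the tail offset `t` used to produce them is not recorded in the parameter
table, and they are not reproducible from it.

## Known limitations

* 1-D central-axis curves only: no profiles, no 2-D/3-D dose, no pencil-beam
  or Monte Carlo transport, no film-dosimetry workflow, no output factors.
* The classic tail form is retained for compatibility but is unsuitable for
  fitting measured falloffs (see above).
* Parameter values from fits are machine-comparable only through the fitted
  curves, not individually (sloppiness).
* The empirical stopping-power model is not a substitute for ICRU/NIST
  tables; it is the package's only reading↔dose mechanism by design.
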