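# Methods

## The steady-state growth-zone model

The simulator and all estimators share one kinematic picture of the root
apex. Position *x* (µm) runs from the quiescent centre shootward; all
rates are per hour. The tissue velocity field is the integral of a
piecewise strain-rate (REGR) field:

* **meristem** `[0, Lm]`: constant strain rate `r_m` and constant cell
  length `l0`. Divisions are not modelled individually; they are implied
  by the rising cell flux `F(x) = v(x)/l0 = r_m·x/l0`.
* **elongation zone** `[Lm, Lg]`, `Lg = Lm + Le`: a strain-rate bump with
  integral `A_e` (µm h⁻¹). Default shape is a raised cosine
  `(A_e/Le)·(1 − cos 2π(x−Lm)/Le)` — smooth and unimodal, like measured
  REGR profiles; a rectangular bump is kept because every quantity then
  has an elementary closed form.
* **mature zone** `x > Lg`: no growth, `v = V`.

Derived steady-state quantities: final velocity `V = r_m·Lm + A_e`, cell
production `P = r_m·Lm/l0`, mature cell length `l_mature = V/P` (flux
conservation `v/l = P` for `x ≥ Lm`), meristem cell number `N = Lm/l0`,
cell-cycle duration `Tc = ln2·N/P` (exponential doubling of the
proliferating population — a classical kinematic identity, not printed in
every paper that uses it), elongation-zone transit time
`te = ∫_{Lm}^{Lg} dx/v(x)`.

The model is time-invariant. Real roots drift on multi-hour scales; the
analysis assumes the observation interval (≈1 h) is short enough that the
steady-state picture holds.

### Parameters of the reference world

| parameter | symbol | default | unit |
|---|---|---|---|
| meristem length | `Lm` | 500 | µm |
| meristem cell length | `l0` | 10 | µm |
| meristem strain rate | `r_m` | 0.04 | h⁻¹ |
| elongation zone length | `Le` | 400 | µm |
| elongation strain integral | `A_e` | 280 | µm h⁻¹ |
| domain extent | `X_max` | `Lg + 6·l_mature` | µm |

giving `V = 300 µm h⁻¹`, `P = 2 cells h⁻¹`, `l_mature = 150 µm`,
`N = 50`, `Tc ≈ 17.3 h`, `te ≈ 5.98 h` — a realistic fast-growing
*Arabidopsis* primary root around one week after germination. The
contrast cohort (`Lm=375, A_e=255`) keeps `Tc` fixed while lowering `P`
to 1.5 and raising `l_mature` to 180 µm: reduced cell production
partially compensated by post-mitotic cell enlargement.

## What the simulators emulate (and what they do not)

**Particles** (`simulate_particles`): start positions uniform on
`[0, X_max − V·dt]`; end positions by classical RK4 on `dx/dt = v(x)`
with step `dt/100` (verified against the exponential closed form in the
constant-strain meristem and the linear-velocity rectangular bump to
1e-4). Gaussian noise of sd `position_noise_sd` (default 5 µm,
instrument-scale) is added independently to both recorded positions, so
the displacement noise sd is `√2·position_noise_sd`; records with
displacements more negative than 3 sd of that combined noise are
physically impossible and dropped (counted in `n_discarded`).

**Cell files** (`simulate_cell_file`): cells tile the axis from the QC;
cell *k* with proximal boundary `x_k` gets length `l(x_k)·exp(ε)`,
`ε ~ N(0, ln(1+cv²))` truncated at ±3σ — multiplicative lognormal noise,
because biological length variation scales with size. Default CV 5 %.
Generation stops after six cells lie wholly beyond `Lg`.

**Ploidy** (`simulate_ploidy`): nuclei drawn from the stated class
proportions; intensity `anchor·2^k·exp(η)` with lognormal spread
(default CV 5 %, stain/instrument variation). Default 10 000 nuclei and
six samples per genotype — the usual flow-cytometry sampling design.

Deliberately **not** emulated: individual division events (so meristem
cell lengths carry no division-cycle variation — see the segmentation
caveat below), debris/doublets in cytometry, non-steady growth, image
formation. A green test on synthetic data therefore establishes estimator
correctness under the stated noise, not robustness to every artefact of
real micrographs or FCS files.

All simulators take one integer seed; cohorts derive per-root sub-streams
deterministically (`SeedSequence.spawn`), so identical seeds reproduce
byte-identical observation tables.

## Kinematic estimation

Raw velocity points: `(x_end−x_start)/dt` at the displacement midpoint.
With `dt = 1 h` a plateau particle moves ~300 µm, so the secant reading
smears the field by up to ~12 % of `V` where the velocity profile is
curved; this is a property of the measurement interval, and closed-form
estimator checks in the test suite use `dt = 0.1 h` to isolate estimator
error from it.

**Velocity fit**: local quadratic regression with tricube weights,
half-width `bandwidth` (default 50 µm), evaluated on a uniform 1 µm grid
over the occupied positions, then projected onto non-decreasing profiles
(pool-adjacent-violators) and clamped at zero. With `min_points` set,
each window is widened to the distance of the `min_points`-th nearest
raw point; the cohort-analysis default is 16, chosen so that per-root
fits from ~40 particles are stable (a fixed 50 µm window then often
holds fewer than 3 points, which is an error by contract when
`min_points=None`). On dense data the floor is inactive.

**Zone boundaries** (95 %-plateau rule): the boundary is the first grid
point whose value reaches 95 % of the mean of the strictly distal points
(candidate excluded; configurable), the scan restricted to the growth
zone (where `v̂ < 0.99·max v̂`, plus one plateau point). The meristem
boundary `L̂m` applies the rule to the flux `v̂/ℓ̂`, the growth-zone
boundary `L̂g` to `v̂` itself. Note the rule's intrinsic fixed point:
on a smooth profile it fires where the curve reaches ~95 % of its
plateau, i.e. `L̂m ≈ 0.95·Lm` on a linear flux ramp — a systematic ~5 %
underestimate that is part of the method, inherited by every analysis
that uses this rule on densely sampled profiles.

**Cell-length field**: lengths attached at proximal cell boundaries and
linearly interpolated (midpoint attachment lags the steady-state length
field by half a cell and breaks flux conservation by ~10 %). Grid points
outside the file's coverage are excluded.

**Scalars**: `V̂` = mean fitted velocity at and beyond `L̂g`;
`ℓ̂m` = mean of the first five cells wholly beyond `L̂g`;
`P̂ = V̂/ℓ̂m`; `N̂` from the doubling-rule segmentation of the paired
cell file when it succeeds, else `L̂m` / median meristem cell length;
`T̂c = ln2·N̂/P̂`; `r̂ = dv̂/dx` by central differences, clamped ≥ 0;
`t̂e = ∫_{L̂m}^{L̂g} dx/v̂` integrated segment-exactly on the piecewise
linear profile (log form on sloped segments).

Recovery at the reference world (10 roots × 40 particles, 1 h interval,
5 µm position noise, 5 % length CV; cohort means, median over 50 seeds):
`P`, `V`, `ℓ_mature` within ~0.5 %; `Lm`, `Tc` within ~6 %; `te` within
~10 % — computed by `tests/test_acceptance.py`.

## Static segmentation: scope of validity

The two scan rules are field rules applied to raw lengths (no smoothing
by default; an optional 3-cell median pre-filter affects detection only):

* elongation onset: first cell ≥ 2× its predecessor with a longer
  successor (the successor condition skips recently divided cells);
* maturation onset: first later cell whose successor is within
  `1 + tol` (default 5 %) of it, with five cells left for the mature
  average.

Under steady-state flux conservation, successive simulated cell lengths
grow by the factor `1 + r(x)/P`. Doubling therefore requires
`r(x) ≥ P` — true in steep growth zones but **not** in the reference
world (max `r` = 1.4 h⁻¹ < `P` = 2 h⁻¹), where the rule correctly
reports a segmentation failure on noiseless profiles and the kinematic
pipeline falls back to the length-based meristem count. On real roots
the rule works because division keeps meristem lengths fluctuating while
the first post-mitotic cells double relative to freshly divided
neighbours — precisely the variation the minimal simulator omits.
Similarly, the maturation rule returns at best the cell straddling `Lg`
(its length is already within tolerance of mature), and in smooth-bump
worlds the gentle start of elongation can satisfy the rule immediately
after the meristem. Segmentation-rule correctness is therefore verified
against brute-force oracles on arbitrary sequences and against ground
truth in steep-bump worlds where the rules' premises hold.

Indices are 1-based in all user-facing output (cell 1 = first cell after
the cortex/endodermis initial); the meristem length includes the declared
`qc_offset` (default 0) between the QC and cell 1.

## Ploidy classification

Manual instrument gating is replaced by a deterministic rule: with 2C
anchor `a`, class index `k = round(log2(I/a))` clipped to [0, 4]
(classes 2C…32C). The anchor is the lowest mode of a Gaussian KDE on
log2 intensity whose density exceeds 10 % of the global maximum, or a
user-supplied value. Classification is scale-invariant and classifies
every nucleus; at CV ≤ 0.10 the ladder separation (1.0 on the log2 axis
vs noise sd ≈ 0.14) keeps misclassification below 1 %. Debris/doublet
exclusion is out of scope; min/max intensity filters are exposed for
real data. Genotype contrasts are per-class Welch *t*-tests on
per-sample proportions; raw p-values by default, Benjamini–Hochberg
opt-in.

## Group statistics

*t*-tests are Welch (unequal variance, Satterthwaite df), two-sided; the
zero-variance/equal-means degenerate case returns p = 1 by convention.
Multi-group designs use one-way ANOVA plus all-pairs Tukey HSD from the
studentized-range distribution (scipy implementations; cross-checked
against statsmodels in the tests to 6 significant digits). No cross-metric
multiple-testing correction is applied by default, matching common
practice in per-figure reporting; a BH column is available.

## Numerical choices

* grid step 1 µm; boundaries reported at grid resolution ("first point
  where"), no sub-grid interpolation;
* quadratures: strain-rate integral by trapezoid on the grid; transit
  time segment-exact on the linear interpolant; the simulator's
  ground-truth transit time by adaptive quadrature (rtol 1e-10);
* the local-regression normal equations are solved in the scaled
  coordinate `u = (x−x₀)/h` with a 1e-10 ridge to survive coincident
  midpoints;
* degenerate roots (too few particles, no plateau, no cell-file overlap)
  raise typed errors; cohort drivers collect them per root and continue.

## Known limitations

* The 95 %-plateau rule's ~5 % boundary bias propagates into `Tc` (via
  `N̂`) and especially `te` (the meristem tail is slow, so small boundary
  shifts change `∫dx/v` noticeably).
* With 1 h displacement intervals the velocity readings near the
  elongation-zone shoulders are smeared; sub-hour intervals remove this
  if the imaging allows.
* The doubling rule is undefined for smooth steady-state profiles
  without division-cycle length variation (see above).
* Ploidy classes are capped at 32C; S-phase deconvolution and
  endoreplication indices beyond class proportions are not implemented.
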