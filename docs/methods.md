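# Methods

## Models

### CMC shift under host–guest complexation

An amphiphilic guest G micellizes at its critical micelle concentration
CMC₀ (µM), a characteristic of the compound at a given pH, temperature
and ionic strength. A cyclodextrin host C binds monomeric guest:

- 1:1: `G + C ⇌ GC`, `Kc = [GC]/([G][C])`;
- sequential 1:2: `G + C ⇌ GC` (`K1`) then `GC + C ⇌ GC₂` (`K2`).

Because micellization is pinned to the free-monomer activity, the
monomer concentration at the micellization threshold can be replaced by
the apparent CMC, giving the closed forms used throughout:

```
CMC([C]) = CMC0 · (1 + Kc·[C])                       (1:1)
CMC([C]) = CMC0 · (1 + K1·[C] + K1·K2·[C]²)          (1:2)
```

`[C]` is the **total added CD**, not free CD: micellar diagrams are
plotted against the added host concentration, and the estimator is
defined against that axis. The free-CD correction (closing the ternary
mass balance over host) is deliberately not applied; `species_fractions`
therefore also takes free CD as an explicit argument. When CD is in
large excess over guest the distinction is small; at comparable
concentrations the fitted constants are *operational* constants tied to
this plotting convention.

Units: CMC in µM, `[C]` in mol/L, all constants in M⁻¹. Files carry CD
in mM (bench convention); conversion happens only at the I/O boundary.

### Species fractions

For free-CD level c, the stepwise mass-action laws give
`f_free = 1/(1 + K1·c + K1·K2·c²)`, `f_1:1 = K1·c·f_free`,
`f_1:2 = K1·K2·c²·f_free`; they sum to one by construction and the
implementation guarantees 1e−12 closure.

## CMC estimation (two-line intersection)

Each titration is modelled as two straight lines: a pre-micellar
baseline (free slope by default; an option pins it to zero) and a
post-micellar trend. The estimator:

1. enumerates every partition of the distinct concentration levels with
   at least 3 levels per segment (replicates stay together and are
   fitted jointly — no pre-averaging, preserving degrees of freedom);
2. fits ordinary least squares to each segment and keeps the partition
   with minimal total SSE;
3. reports the **analytic intersection** of the two selected lines as
   the CMC (not the split-point abscissa). If the intersection falls
   outside the closed interval between the last pre- and first
   post-micellar level, a warning is attached but the fit is returned.

Degenerate inputs are rejected explicitly: a constant signal ("flat
signal"), fewer than 6 points or 6 distinct levels, and the absence of a
break — declared when the post−pre slope difference does not exceed 3
pooled standard errors of that difference ("no micellization
detected"). The 3σ rule costs nothing on noise-free data (the standard
errors vanish) and blocks spurious breaks on pure-noise curves.

**Axis choice.** Fitting is on linear concentration unless the sampled
positive concentrations span more than two decades, in which case both
lines are fitted in log₁₀ concentration and the intersection is
back-transformed. A straight line across 3–4 decades of concentration is
meaningless; the sub-µM (nanomolar-CMC) regime of the most hydrophobic
conjugates requires log-spaced designs, and slopes there are read as %
per decade. The estimator is affine-invariant in the signal (blank
subtraction and normalization upstream do not matter) and scale- and
offset-equivariant on each axis; both properties are under test.

## Micellar-diagram fitting

A diagram needs ≥3 CD levels including 0. CMC₀ is **fixed to the
measured zero-CD value by default** (`cmc0="measured"`): it is a
characteristic constant of the compound/condition and measuring it
anchors the intercept; `cmc0="fitted"` frees it. With CMC₀ fixed the 1:1
fit is closed-form non-negative least squares for Kc; the 1:2 fit is
bounded nonlinear least squares over (K1, K2) ≥ 0 (trust-region
reflective, SSE-relative tolerance 1e−14, residuals scaled by the mean
CMC for conditioning), multistarted from the linear-fit slope for K1 and
K2 ∈ {0, 0.1, 1, 10} M⁻¹, keeping the lowest-SSE solution. Weighting is
unweighted by default, inverse-variance when per-level standard errors
are present. A significantly negative 1:1 slope is clamped to Kc = 0
with a warning (the only post-hoc clamp; elsewhere non-negativity is
enforced by bounds).

### Stoichiometry selection

The visual rule "linear ⇒ 1:1, curved ⇒ 1:2" is made reproducible as:

1. **Curvature test.** Free-intercept linear and quadratic polynomials
   in `[C]` are fitted by weighted least squares with weights
   `1/ŷ²` from a preliminary linear fit — a constant-CV error model,
   which is how replicate scatter of CMC estimates behaves. The
   extra-sum-of-squares statistic for the quadratic term is referred
   one-sidedly to Student's t (the signed square root of the nested F):
   since `K1·K2 ≥ 0`, only *upward* curvature is evidence for 1:2
   binding. A two-sided F-test with K2 on its boundary would run at
   roughly half its nominal level; the one-sided version is calibrated,
   and the package verifies this by simulation (false 1:2 rate ≈ 0.05 at
   α = 0.05 under linear truth with 5% CV noise).
2. **Curvature floor.** A rejection only selects 1:2 when the fitted
   quadratic contribution is chemically non-negligible:
   `K1·K2·cd_max² > 0.01·K1·cd_max` (i.e. `K2·cd_max > 0.01`). This
   keeps statistically detectable but trivial curvature from flipping
   the model.

The returned fit carries the test statistic, one-sided p-value, an AICc
difference between the two models, and the rival model's fit.

### Bootstrap uncertainty

CD levels are designed, not sampled, so **residuals** (not pairs) are
resampled: residuals from the point fit are drawn with replacement,
added back to the fitted values, and the model is refitted (1:2 refits
warm-start from the point estimate). Percentile intervals at 95% are
reported; a fixed seed makes them deterministic, and all-zero residuals
collapse the intervals to the point estimate with a warning. On the
short 6-level designs used here the intervals are mildly conservative
(empirical coverage ≈ 0.95–1.0 at nominal 0.95 in the package's own
simulations); the test suite asserts coverage ≥ 0.90.

### Identifiability caveat: K2 in shallow-curvature regimes

With K1 = 17 M⁻¹, K2 = 0.18 M⁻¹ and CD up to 0.1 M, the quadratic term
contributes at most `K2·cd_max ≈ 2%` of the linear term. K1 is then
well identified (median error ~2–3% at 1% CV noise) but **K2 is weakly
identified**: even 1% noise produces order-100% median error in K2.
Noise-free data recover both constants to 1e−4 relative; real-data K2
values in such regimes should be read as order-of-magnitude estimates.

## Ligand efficiency

`LE = ΔG_bind / N_heavy`, with N_heavy the non-hydrogen atom count
parsed from the molecular formula (H, D, T excluded; charges and
isotope labels out of scope — the medicinal-chemistry standard). The
division is done in decimal arithmetic and summaries round
half-away-from-zero to 3 decimals, so printed values are reproduced
exactly. The bundled six-guest reference set pairs each compound with
its published MM-GBSA energy toward hydroxypropyl-β-cyclodextrin;
computing those energies (docking, MD) is out of scope — they are
inputs. Note that the published LE discussion ranks the four amphiphile
guests; over all six fixtures the small rigid aromatics (the probe and
the parent polyphenol) have the best per-atom efficiency.

## Synthetic data

The generator is the package's stand-in for raw plate-reader data and
defines the conditions every statistical claim is made under:

- **Titrations**: piecewise-linear response with a continuous join at
  the breakpoint — baseline level 5%, baseline slope 0, post slope
  8 %/µM by default, the minimal shape consistent with two-line
  analysis. Sigmoidal smoothing at the join is deliberately omitted;
  the estimator assumes lines, and smoothing would inject a model
  mismatch of unquantified size. The breakpoint is the forward-model
  evaluation at the curve's CD level. Grids default to 12 levels,
  linear on CMC/4…2.5·CMC, switching to log-spaced (CMC/30…30·CMC,
  response linear in log₁₀ c, slopes %/decade) for breakpoints below
  1 µM. Noise is additive Gaussian on the fluorescence (default sd 2%
  absolute), 3 replicates per level.
- **Diagrams**: CMC values are model evaluations × (1 + ε),
  ε ~ N(0, CV) — multiplicative noise, since CMC estimation errors
  scale with the CMC. Default CV 5%. With replicates, per-level means
  and standard errors are returned.
- **Presets**: the published condition grid (two conjugates and the two
  parent fatty acids; pH 2.0/7.0, 15/25/35 °C, PBS vs MilliQ water)
  with the reported CMC₀/Kc/K1/K2 as ground truth for simulation.

No instrument noise model was published, so both noise magnitudes are
user parameters with the defaults above. What passing tests show is
that the *inference chain* is correct and calibrated under these
generative assumptions; they cannot show robustness to features the
generator lacks — probe-partitioning photophysics, competitive
displacement of the probe by the host, drift, heteroscedastic
plate effects, or a genuinely gradual micellization transition.

## Simulation sizes and numerical conventions

Recovery experiments use 200 replicate diagrams; selection calibration
uses 1000 replicates per scenario (binomial 95% half-width ±1.4
percentage points at rate 0.05); bootstrap defaults to B = 1000, with
B = 200–400 in fast tests. The acceptance script derives every stream
from the single `--seed` argument with fixed offsets. Fold-change
arithmetic rounds half-away-from-zero in decimal arithmetic at the
stated number of decimals. Reports serialize with sorted keys and no
timestamps, so identical inputs and seed give byte-identical documents.

## Known limitations

- Operational constants: total-CD convention (above) — constants are
  conditional on the diagram axis, as published.
- The breakpoint search is O(levels) exhaustive, intended for dozens of
  levels, not thousands.
- The curvature test assumes independent errors across CD levels; CMC
  estimates sharing a plate/run may be correlated.
- No competitive-binding correction for the fluorescent probe, which
  itself binds the host; the probe is assumed to report micelle onset
  passively.
- 2:1 (two guests per host) and higher-order stoichiometries are not
  modelled.
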