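# Methods

`conespect` decomposes the massed cone photoreceptor response of the
zebrafish retina — the PIII component of the electroretinogram, isolated
pharmacologically by blocking transmission to second-order neurons — into
the contributions of the four cone classes (red/LWS, green/RH2, blue/SWS2,
UV/SWS1).  This note describes the model, the numerical procedures, the
design choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## The four-cone saturation model

The trough-to-peak PIII amplitude evoked by a flash of quantal irradiance
*I* (quanta·μm⁻²·s⁻¹) at wavelength λ is modelled as a sum of four
hyperbolic saturation functions (Naka–Rushton form with exponent 1):

    V(I, λ) = Σ_x  V_x · I / (I + k_x · A(λ_x, λ)),   x ∈ {r, g, b, u}

Each cone class contributes three parameters:

| parameter | meaning | units | bounds |
|---|---|---|---|
| V_x  | saturation amplitude ("fractional contribution") | dataset-peak units | [0, 1.5] |
| log k_x | semi-saturation irradiance at the pigment peak | log(quanta·μm⁻²·s⁻¹) | [1, 6] |
| λ_x  | wavelength of peak sensitivity | nm | class window |

Amplitudes are dimensionless throughout the modelling layer because fits
are performed on pooled data in which every eye's 70 amplitudes have been
divided by that eye's maximum; microvolts exist only upstream in the trace
pipeline.  A consequence worth stating explicitly: the fitted V_x are
fractions of the maximal PIII response, and their sum may exceed 1, since
no single stimulus saturates all four cones at once.

## Nomogram spectral coupling

A(λ_x, λ) couples each cone's irradiance response to wavelength through a
visual-pigment absorbance template: order-8 polynomials P(x) in the
normalized reciprocal wavelength x = λ_x/λ, returning log₁₀ relative
quantal sensitivity, one polynomial for r/g/b pigments and a slightly
narrower one for UV pigments (coefficients shipped as package data in
`src/conespect/data/nomogram_coefficients.csv`).  Both templates are
peak-normalized: the coefficient sums are 0.005 (r/g/b) and 0.002 (UV), so
P(1) ≈ 0.  The model consumes A ≡ 10^(−P): A = 1 at the pigment peak and
grows off-peak, so k_x·A is the effective semi-saturation at wavelength λ
and the fitted k_x is automatically referred to the pigment's peak.  The
raw polynomial cannot be the weight itself — it evaluates to ≈0 at the
peak, which would zero the denominator.

**Validity windows.**  Polynomials of this order cannot be extrapolated.
P is clamped to its boundary value outside a per-family window of x:
[0.5, 1.25] for r/g/b and [0.5, 1.15] for UV.  The window edges were
chosen from the polynomial shapes: on the long-wavelength side (small x)
both polynomials fall smoothly and monotonically at least to x = 0.5
(−18 and −320 log units respectively), and this depth matters — a red-
cone-less retina must stay silent at bright 650-nm flashes, which requires
the green/blue/UV templates to be suppressed by much more than the ~2.4
log units a clamp at x = 0.8 would allow.  On the short-wavelength side
the r/g/b template levels off in a β-band-like plateau (≈ −0.8 log units
for x ∈ 1.25–1.9), which is physically reasonable; the UV template instead
turns upward above x ≈ 1.15 (it would predict off-peak hypersensitivity)
and is clamped there.  The argument convention x = λ_x/λ is the default;
λ/λ_x is available for sensitivity analyses and differs little near the
peak because P is nearly symmetric about 1.

## Trace preprocessing

Raw sweeps are digitized at 2000 Hz.  Per stimulus combination the
pipeline averages the four replicate sweeps, smooths with a 33-point
(16.5 ms) centered running mean, and measures trough-to-peak amplitude.
Choices not fixed by the source procedure:

* **Edge handling** of the running mean: shrinking symmetric windows, so
  trace length is preserved and a constant trace is unchanged.
* **Measurement windows**: the trough is the minimum from stimulus onset
  to 50 ms past offset; the rebound peak is the maximum from offset to
  500 ms past offset.  These bracket the PIII waveform (hyperpolarizing
  plateau during the 300-ms flash, depolarizing rebound decaying within a
  few hundred ms).  Because the windows overlap on [offset, offset+50 ms],
  the measure is structurally non-negative.
* **Stability screen**: the 650-nm block is delivered twice; the ratio of
  second- to first-block maxima must stay within [0.7, 1.3] (±30 % drift).
  The screen is only applied when the indexing response is measurable —
  at least 15 % of the dataset's peak amplitude.  Without this guard a
  red-cone-less eye, whose 650-nm "response" is rectified noise, would be
  excluded more than half the time, which contradicts the study design
  this pipeline emulates.  Datasets with *zero* first-block response have
  an undefined ratio and are excluded.
* The duplicated 650-nm combinations are averaged across blocks after the
  stability check (the alternative — keeping only the first block — was
  open; averaging uses all data).

## Fitting procedure

Genotype-level datasets are fit by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective — the bounded
analogue of Levenberg–Marquardt, which does not itself accept bounds),
unweighted, capped at 100 iterations (mapped to `max_nfev =
100 · (n_free + 1)` to account for finite-difference Jacobians).  Seeds:
V_x = 0.25, log k_x at the standard fixed values (r 4.5, g 4.0, b 3.5,
u 3.0), λ_x at the wild-type peaks of the age class.  λ windows (r
500–620, g 420–540, b 370–470, u 330–400 nm) keep the classes from
swapping labels; they are configurable.

Fallback cascade, mirroring the original procedure:

1. **Non-convergence** within the iteration cap: the semi-saturation of
   the least-constrained (smallest-amplitude) cone is fixed at its
   standard value and the fit repeated; recorded as a substitution.
2. **Boundary hit**: a free log k ending on a bound is likewise replaced
   by the standard fixed value and the fit repeated.
3. **Cone drop**: a cone whose fitted V_x falls below 0.02 (the drop
   threshold, below the smallest reliably reported fractional
   contribution) is removed from the model and reported "no fit".

Standard errors come from the Jacobian-based covariance at the solution,
σ² (JᵀJ)⁻¹ with σ² = RSS/(n − p).  A spectral peak is reported only when
the data resolve it: λ_x with a standard error above 12 nm, or sitting on
its window boundary, is flagged "no fit" while the cone's amplitude
remains reported.  The 12-nm ceiling is anchored to the largest peak
uncertainty treated as reportable in this literature (≈ 11.7 nm); peaks
with larger errors carry no usable spectral information given ~100-nm
search windows.  This per-parameter rule is needed because a near-silent
cone class can have a well-determined amplitude (see below) and an
undeterminable peak at the same time.

**Genotype comparisons.**  Two-group contrasts are Wald t statistics
(θ_A − θ_B)/√(se_A² + se_B²) with point-level degrees of freedom
n_A + n_B − p_A − p_B.  The multi-group test is an extra-sum-of-squares F
between a full model (the target parameter genotype-specific, fitted
separately per group) and a reduced joint fit sharing the parameter,
df1 = G − 1, df2 = N_total − p_full, with studentized-range (Tukey-style)
adjustment of the pairwise Wald statistics.  This is an explicit stand-in
for an undocumented original procedure; it reproduces the point-level df
bookkeeping but is not guaranteed to reproduce F values computed on data
that are not available.

## Behavioral and mosaic statistics

* **Fisher exact** (optomotor plate counts): two-sided by the
  sum-of-smaller-probabilities convention (`scipy.stats.fisher_exact`);
  an empty margin returns p = 1 with a warning.  The test suite checks
  the implementation against full-margin hypergeometric enumeration.
* **Summary t test** (chimera cone counts): reconstructed from printed
  means ± SE, t = Δmean/√(se_a² + se_b²), df = n_a + n_b − 2; for equal
  group sizes this equals the pooled equal-variance t test, matching the
  published df = 8 for 5 + 5 sections.
* **Mann–Whitney U** (optokinetic eye-movement counts): midrank ties.
  Counts are small integers with heavy ties, so the exact tie-aware null
  distribution is built by dynamic programming over doubled midranks
  (used up to n = 20 per group); the distribution is symmetric about
  n_x·n_y/2 under label exchange, giving the two-sided p directly.  Above
  n = 20 a normal approximation with tie-corrected variance (no
  continuity correction) is used.
* **One-way ANOVA** with Tukey HSD (`scipy.stats.f_oneway`, `tukey_hsd`);
  degenerate within-group variance with distinct means raises.

## Synthetic data

Generators are pure functions of (arguments, seed), with a master seed
expandable through `numpy.random.SeedSequence`.

**Presets** collect the published parameter estimates per genotype and age
class; every field carries a programmatic provenance tag (`"table"` for
printed values, `"default"` otherwise).  Notable defaults: the wild-type
green V_g = 0.25 (never printed; chosen inside the range of the reported
cone fractions), mutant green V_g = 0.20, and the adult amplitude set
(only direction-of-change is described for adults).  Printed semi-
saturations override the standard fixed values where available (e.g.
larval green k: wild type 4.57, mutant 4.93; adult red k: wild type 4.79,
heterozygote 5.21; adult mutant green k 5.64).  Mutant red and green peaks
are "no fit" in the source; the wild-type values stand in as generating
defaults.

**Amplitude datasets** draw model amplitude + Gaussian noise (σ = 0.05
normalized units, set so synthetic genotype-level fit standard errors are
of the same order as the published ones), floored at zero.  **Sweep sets**
shape a PIII-like template — 20-ms exponential onset to a hyperpolarizing
plateau, post-offset rebound transient peaking at 120 ms with amplitude
0.3 × plateau (the rebound fraction is cosmetic; only the trough-to-peak
total matters and equals 1.3 × the model amplitude to within 0.2 %) —
scaled by a 300 μV gain, with per-sample trace noise.  **Optomotor
counts** are independent binomials per condition.

**Parameter-recovery semantics.**  `simulate_genotype_dataset` emits
pooled data directly on the model's normalized scale (unit gain), because
the generator knows the true amplitude scale.  Re-dividing synthetic data
by its own empirical maximum — the right operation for gain-bearing μV
data of unknown scale — would instead shrink every V_x by a predictable
factor: the model evaluated at the wild-type preset has maximum ≈ 1.11
over the protocol grid (the red cone's β-band plateau keeps it active at
370–410 nm), and the empirical maximum of 70 noisy points adds a further
upward bias of ≈ +0.03, so the full pipeline recovers V_r ≈ 0.551/1.14 ≈
0.48.  This ≈ −13 % amplitude shrink is a property of per-dataset
max-normalization itself, not of the estimator; spectral peaks and
semi-saturations are unaffected (normalization is wavelength-neutral).
Recovery studies therefore evaluate the estimator at unit gain, and the
shrink is listed here as a known property of the pooling pipeline.

**The rectified-noise origin of the mutant's residual red amplitude.**
Fitting synthetic mutant cohorts generated with *zero* red amplitude
returns V_r ≈ 0.02–0.04: trough-to-peak measurement is non-negative, so
pure noise at 650 nm leaves a positive, irradiance-independent floor
(≈ σ·E[max(0,Z)] ≈ 0.02) that the fit absorbs into a small red cone with
an implausibly low semi-saturation.  The published mutant red fraction of
0.030 ± 0.008 is quantitatively consistent with this artifact, which is
why recovery studies treat V_r = 0 as the mutant's generative truth while
the preset keeps the printed 0.030 for reproducing reported quantities.

## What the generators do not emulate

Synthetic eyes share exact generating parameters within a genotype; real
eyes vary (a per-dataset λ jitter hook exists but defaults to off).  Noise
is Gaussian and homoscedastic; real amplitude noise likely grows with
amplitude and drifts within the 17-minute protocol.  Response kinetics do
not differ across genotypes (the source reports little change), rod
intrusion is absent, and no 50/60-Hz interference is simulated.  Passing
recovery tests therefore demonstrate correctness of the estimator under
the model's own assumptions, not robustness to every property of real
recordings.

## Numerical conventions and degenerate inputs

CSV exports fix floats at 6 significant digits; re-running a command from
its manifest reproduces outputs byte-for-byte.  Replicate counts other
than 4 average what is present, with a warning.  Even smoothing windows,
unsorted irradiance grids, negative irradiances or amplitudes, empty
pools, excluded datasets passed to pooling, and contrasts on fixed or
dropped parameters all raise immediately with context.  Problem sizes
used in the test suite and acceptance study — 100 seeded cohorts of
17 × 70 (wild type) and 12 × 70 (mutant) points — match the published
cohort sizes and keep a full run within a couple of minutes on one CPU.
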