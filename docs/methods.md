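# Methods

## Model and assumptions

The package treats bone under quasi-static uniaxial loading as a
hyperelastic solid whose reduced-stress behaviour deviates from the
classic Mooney–Rivlin form through an internal-friction term. Working
variables are the elongation ratio λ (deformed over reference length) and
engineering strain ε = λ − 1. True stress is defined from the applied load
as σ_true = F/(A·λ). Whether A means the initial or the current
cross-section is ambiguous in this convention (an incompressible-tension
convention would read Fλ/A₀); the package implements F/(A·λ) as written
and leaves the interpretation of A to the user's geometry metadata.

The Extended Mooney stress σ_Ext = σ_true·λ²/(λ²+λ+1) equals the classic
reduced stress times (λ − 1), with the (λ − 1) factors cancelled
algebraically, so it is finite and continuous at λ = 1 (value σ_true/3)
where the reduced stress is singular. `mooney_stress` still raises a
singular-deformation error for |λ − 1| ≤ 1e−9; every other code path uses
the cancelled form.

In these variables the model is the cubic

σ_Ext = B(λ_C − 1) + ε(C₂ + C₁ + H − B) + ε²(C₁ + 2H) + ε³H,

equivalently a cubic in λ with brackets [Bλ_C − C₂], [C₂ − C₁ − B],
[C₁ − H], [H] (the two forms are the same polynomial under ε = λ − 1; a
property test checks this on 1000 random coefficient sets at 1e−10
relative). Two structural features worth knowing: the σ_Ext intercept at
ε = 0 is B(λ_C − 1), and hence the true stress at zero strain is the
nonzero 3B(λ_C − 1) — the model does not pass through the origin on the
true-stress scale. λ_C defaults to 1.4655, a theoretical constant adopted
from prior work on the model; it is stored on the coefficient record and
overridable in configuration. B must be strictly positive (it is an
elastic-modulus scale); C₁, C₂, H may take either sign. No positivity is
imposed on the data: with C₂ < 0 the model's σ_Ext is legitimately
negative over part of the strain range.

The model is quasi-static and one-dimensional: no viscoelastic time
dependence, no multiaxial stress states, no alternative hyperelastic
forms (Neo-Hookean, Ogden).

## Fitting

All regressions are closed-form, unweighted ordinary least squares; fits are
fully deterministic. R² is reported on the σ_Ext scale — the scale on
which the regression is performed — with the true-stress-scale R² logged
in the diagnostics for transparency. When the D route is used, the
D-quadratic's own R² is also kept in the diagnostics, since the headline
R² of a fit is always the σ_Ext-scale agreement with the final model.

**Direct route.** Cubic LS of σ_Ext on ε (≥ 4 distinct strains), then the
affine, exactly invertible bracket map B = a₀/(λ_C − 1), H = a₃,
C₁ = a₂ − 2H, C₂ = a₁ − C₁ − H + B. If a₀ ≤ 0 the fit is flagged
inadmissible rather than returned: a negative B can minimise the residual
sum of squares while being physically meaningless.

**Admissibility fallback.** On an inadmissible direct fit, B is estimated
from the regression restricted to ε ≤ 0.5 (the window cap is
configurable; 0.5 is where the initial portion of bone curves shows a
positive intercept), extrapolated to ε = 0. The window keeps cubic order
with ≥ 4 points, degrading to quadratic or linear when sparse — and also
when a higher order returns a non-positive intercept, because a
high-order extrapolation to zero from a short window is noise-sensitive;
only if every order fails is the curve declared unusable. With B fixed,
D = (σ_Ext − B(λ_C − 1))/ε is the quadratic
[C₂ + C₁ + H − B] + ε[C₁ + 2H] + ε²[H], and a quadratic LS fit recovers
the remaining three parameters through the same bracket algebra. D is
0/0 at ε = 0, so samples below the smallest strictly positive strain are
dropped (no interpolation at zero; the floor is configurable).

On noise-free data of the model class both routes agree to numerical
tolerance, and any admissible coefficient set is recovered exactly — the
round trip that the acceptance checks exercise with the published
proximal-femur set (B = 2.410×10⁴, C₁ = 1.770×10⁶, C₂ = −2.120×10⁶,
H = 3.829×10⁴ N/m²).

**Known limitation — selection bias near inadmissibility.** The fallback
is triggered by the *estimated* sign of a₀. When the true intercept
B(λ_C − 1) is small relative to its sampling error, noise flips a
substantial fraction of replicates onto the window route, which then
conditions on a positive windowed intercept; the resulting B (and
downstream C₂) estimates are biased upward in exactly that regime. The
least-squares regressions themselves are unbiased (verified by Monte
Carlo on the raw cubic coefficients), and so is the full pipeline where
the intercept is well resolved (midshaft-scale B); the bias is a
structural property of the admissibility workaround, not of the
estimator, and the test suite pins down both facts.

## Synthetic data

Real inputs of this kind are curves digitized from published figures, so
the generator forward-models σ_true from known coefficients on a fixed
strain grid (default 60 uniform points on [0.05, 3.0] — spanning the
large-strain range such curves cover while staying off the ε = 0
D-singularity) and then emulates digitization: optional rounding of the
stress values and multiplicative Gaussian noise σ → σ(1 + η),
η ~ N(0, σ_rel²). Noise is relative rather than additive because
reading-off error scales with the magnitude of the plotted curve. The
noise level is configurable; 2% is used as the reference "digitized
figure" condition and 1% in the Monte-Carlo calibration. What the
generator does **not** emulate: the actual spreadsheet goal-seek
digitization process, instrument drift, specimen-to-specimen biological
variability, or anisotropy — so passing round-trip tests shows the
pipeline's internal consistency, not that real bone follows the model.

The six-site leg preset assigns one coefficient set per strain-gauge site
(SG#1–SG#6) across proximal/middle/distal femur and tibia, constructed so
that B peaks in the midshaft sites, C₂ (least negative) in the distal
sites, C₁ at the proximal femur, and H in the midshaft — the qualitative
regional picture expected of cortical vs trabecular bone — with
magnitudes on the scale of the reference fit. These values are invented
fixtures for exercising the reporting machinery; region labels are
explicit metadata, never inferred from site numbering. Per-site noise
seeds derive from (master seed, CRC32 of the label), so adding a site
never perturbs existing ones.

Calibration note: with B fixed to truth, 1% noise and 200 replicates on
the reference set, the median relative errors of C₁ and C₂ are ≈ 1%,
while H's is ≈ 11% — H multiplies the smallest term of a curve spanning
~10⁷ Pa. The frozen test thresholds (5% for C₁/C₂, 20% for H) come from
that calibration run.

## Regional comparison

Per coefficient, sites aggregate to regions by arithmetic mean (median by
configuration); the report lists signed per-region values, joint
argmax/argmin regions (ties are reported together, never broken
silently), peak sites, and a magnitude-spread ratio
max(|mean|)/min(|mean|) ≥ 1. The spread is defined on magnitudes because
a signed max/min ratio is meaningless when a coefficient (typically C₂)
is negative throughout. Output renders as text, lossless JSON, or CSV
with one row per (coefficient, region).

## Numerical choices

- Least squares via `numpy.linalg.lstsq` on the Vandermonde matrix;
  agreement with a direct normal-equations solve is tested at 1e−8
  relative. Rank deficiency raises rather than silently regularising.
- Duplicate-strain records are averaged (not dropped) during curve
  assembly, with a logged warning — digitized curves often repeat
  x-readings.
- All numeric file output uses 17 significant digits and CSV reads use
  round-trip float parsing, so write→read is bit-exact.
- Stresses are Pa (N/m²) throughout, loads N, lengths m; no unit
  inference. C₁, C₂ and H are carried in N/m² by analogy with B.
- Problem sizes in the tests and drivers (60-point grids, 200-replicate
  Monte Carlo, six sites) match the reference conditions above and keep
  the full suite around a second.
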