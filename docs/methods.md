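# Methods

`visrkit` simulates and analyzes VisR (viscoelastic response) ARFI
ultrasound studies of surface compression in breast tissue. This note
records the models, the parameter choices that matter, and what the
synthetic experiments do and do not demonstrate.

## The VisR measurement model

An ARFI excitation applies an impulsive body force at the focus; the
tissue's axial displacement response encodes its viscoelasticity. VisR
uses two consecutive pushes and fits the tracked displacement to a 1-D
mass-spring-damper (MSD):

```
m0 x''(t) + RV x'(t) + RE x(t) = f(t),    x(0) = x'(0) = 0
```

with `f(t)` equal to the push amplitude inside each push window and zero
otherwise. The package solves this exactly (piecewise superposition of
closed-form step responses via the characteristic roots; complex
arithmetic covers the underdamped case, with a guarded limit at critical
damping) — no numeric integrator is involved in either synthesis or
fitting. A fixed-step RK4 integration of the same ODE serves as an
independent oracle in the tests.

**Units and conventions.** Depth in mm, displacement in µm, slow time in
ms. The mass constant `m0 = 1` and the nominal push amplitude
(600 module units) are *unit conventions shared by the generator and the
fitter*, not estimated quantities: the acoustic force in vivo is
unknown, so RE (per-µm restoring constant) and RV (per-ms damping
constant) are only meaningful relative to the applied force — ratios
(DoA) and percent changes are the comparable quantities, which is
exactly how the analysis uses them. The amplitude default was chosen
once so that focal peak displacements land at 2–7 µm, the scale of
in-vivo ARFI displacements. Because the mass term is retained, the
"double the force ⇒ halve RE and RV" relation is exact only in the
massless (heavily overdamped) limit; the tests check it there.

**Sequence timing.** Two reference events, push 1, eight tracking
events, push 2, and 43 tracking events — 55 slow-time events at a PRF of
11.5 kHz. Pushes last 300 cycles at 4.21 MHz (≈71 µs) and their onsets
are separated by 8/PRF ≈ 0.696 ms. Tracking pulses are 2 cycles at
6.15 MHz.

## Transverse isotropy and compression

Apparent moduli of a transversely isotropic (TI) material vary with the
angle between the imaging plane and the material axis of symmetry (AoS)
with a 180° period. The package models this variation with the polar
ellipse

```
r(θ) = m_long · m_trans / sqrt(m_trans² cos²Δ + m_long² sin²Δ),  Δ = θ − AoS,
```

preferred over a sinusoid because it stays accurate at high anisotropy.
The same law is inverted by the anisotropy module: ROI-median PD/RE/RV
at the four protocol angles (0/30/60/90°, Nyquist sampling of the
half-period) are least-squares fit to `r(θ; a, b, φ)` with multi-start
over orientation (an analytic linearized seed — `1/r²` is linear in
`cos 2θ`/`sin 2θ` — plus a 15°-spaced φ grid), `a ≥ b` enforced by
swap-and-rotate, and DoA = a/b. With four points and three parameters
the fit is near-interpolating; R² is still reported per fit, as NaN
(degenerate) when the four values are identical.

**Compression.** Applying `c` mm of surface compression (i) scales all
moduli by `(1 + s)^c`, where `s` is the subject's per-mm stiffening rate,
and (ii) moves every scatterer toward the transducer under uniform
strain `c / 20 mm` (0, 10, 25 % at 0/2/5 mm). The geometric-stiffening
law is this package's constitutive choice: real tissue is poroelastic
and no in-vivo law is established — `s` may be negative, and no claim is
made about which regime is physiologic. Because all four moduli share
the factor, ground-truth DoA is compression-invariant; the clinical
observation that DoA changes idiosyncratically under compression is
*not* built into the generator.

## Synthetic cohorts

A subject is a homogeneous TI speckle phantom: ~55 point scatterers/mm²
(≥10 per ~0.2 mm² resolution cell — fully developed speckle) with
standard-normal amplitudes over a 20 mm × 30 mm field, imaged at 40
lateral beam positions across 2 cm with a 20-mm focus. Cohort
distributions (defaults, chosen once):

| quantity | law | default |
|---|---|---|
| RE transverse | log-normal | median 10, σ_log 0.18 |
| RV transverse | log-normal | median 5, σ_log 0.18 |
| DoA of RE | uniform | [1.5, 3.5] |
| DoA of RV | uniform | [1.5, 3.0] |
| AoS angle | uniform | [0°, 180°) (unknown a priori) |
| stiffening s (dense) | normal | 0.06 ± 0.015 per mm |
| stiffening s (non-dense) | normal | 0.025 ± 0.008 per mm |

The DoA range reflects the 1–4 (mostly 2–4) range reported for
non-tumor mammary tissue; dense-breast subjects stiffen more under
pre-load, the qualitative clinical finding. Each subject is imaged at
3 compressions × 4 angles; all randomness derives from one master seed
through fixed `SeedSequence` spawn keys, so cohorts are bit-reproducible.

**RF synthesis.** Each A-line superposes a Gaussian-enveloped 6.15-MHz
pulse at every scatterer's instantaneous axial position (its depth plus
the closed-form MSD displacement at that slow-time event), weighted by a
Gaussian lateral tracking-beam profile (σ 0.35 mm), sampled at 40 MHz
(19.25 µm/sample), plus seeded white noise at the configured broadband
SNR (default 20 dB). Sub-sample positioning uses an 8-tap Kaiser-windowed
sinc, quantized to 1/1024 sample (~0.02 µm — dither-level). The push has
a separable Gaussian spatial profile (σ 8 mm axial, 1 mm lateral),
approximating the long depth of field of an F/1.5 push; within the ±3 mm
analysis ROI the forcing is nearly uniform, which is the premise of the
focal ROI rule. No diffraction simulation, elevational beam model, or
scanner-specific beam shapes are included: tracking fidelity, not beam
physics, is what the downstream stages consume.

## Displacement tracking

Zero-normalized cross-correlation against the mean of the two reference
events, 376-µm kernels (20 samples), 80-µm search region, 75% kernel
overlap (≈94-µm axial pixel pitch). A 4th-order Butterworth band-pass
(±3.5 MHz around the tracking carrier) precedes correlation, as any
receive chain would. The sub-sample peak applies the interpolation
factor (4) to the RF: the tracked line is cubic-spline upsampled, the
correlation is evaluated at quarter-sample lags around the integer-lag
peak, and a parabolic vertex refines the estimate. (Interpolating the
correlation function itself was measured ~10× worse here — the
correlation carries the 6.5-samples-per-cycle carrier, which a spline
tracks poorly.) Estimates with peak correlation < 0.8 are invalid.
Measured accuracy at 20 dB broadband SNR: ≲0.1 µm bias and ~0.8 µm RMS
per estimate on a 2–19.25 µm shift grid; ~0.05 µm RMS noise-free. The
per-estimate jitter, not bias, is the noise floor — a static ensemble
shows ~0.1 µm spatial-mean displacement.

## Parametric images and fitting

PD is the per-pixel maximum of tracked displacement over the ensemble.
RE/RV come from least-squares fitting of the MSD response to the
fit-window curve (all events from the first push onward). Numerical
choices:

- Fitting runs in log-parameter space with bounds RE ∈ [0.05, 500],
  RV ∈ [0.02, 300] module units.
- The reference single-curve fitter is bounded trust-region least
  squares with a 3×3 log-spaced multi-start; the image fitter is an
  equivalent vectorized version — a 24×24 log-grid scan (model curves
  precomputed; the scan is one matrix product) followed by a damped
  Gauss-Newton polish of all pixels in parallel. The two agree to
  optimizer tolerance and the batch path fits a full image in ~0.1 s.
- A constant displacement offset is estimated as a nuisance parameter
  (equivalently: curve and model are mean-centered). Tracked curves
  carry a kernel-specific DC bias from the shared reference's speckle
  and noise; without the nuisance term that bias leaks into the
  recovery-rate estimate and roughly triples the RE scatter.
- The displacement field gets a 3-pixel axial running mean before
  fitting (adjacent kernels already overlap 75%, so this costs little
  resolution and buys a ~25% jitter reduction).
- Pixels with <80% valid estimates in the fit window, or flat curves,
  are invalid (NaN) and propagate into the map mask.

Measured end-to-end at 20 dB SNR, homogeneous phantom: coefficient of
variation of RE over the focal region 5–8%; ROI-median RE/RV within
~3–6% of ground truth (a small positive bias remains from the lateral
push-profile/tracking-beam mismatch).

## ROI policies

The fixed focal ROI keeps pixels within 3 mm axially of the 20-mm focus
and 3 mm laterally of the image center (an `above_only` variant covers
protocols that window strictly above the focus; the symmetric reading is
the default used for quantitative analysis). Under compression,
different tissue slides through this fixed window. The adaptive policy
estimates the bulk axial feature shift between envelope images
(per-column ZNCC, mean across columns, parabolic sub-pixel refinement;
positive = toward the transducer), translates the ROI to follow the
features (|shift| ≤ 5 mm), then crops back to within 3 mm of the focus
so forcing stays comparable. Featureless (homogeneous-speckle)
comparisons fail the 0.5 correlation gate and fall back to the fixed
window rather than chasing a spurious peak. Acquisitions reduce to ROI
medians of valid pixels; a summary with <25% valid pixels is flagged.
Both policies are computed side by side in study runs.

## Statistics

Within-patient compression effects use the Kruskal-Wallis H test
(tie-corrected, χ² p with k−1 df) on ROI pixel distributions per
(metric, angle); group contrasts use the two-sided Wilcoxon rank-sum
test, exact by enumeration when both groups have ≤10 observations and
no ties (the clinical group sizes sit at this boundary), otherwise the
tie- and continuity-corrected normal approximation. Both are provided
through `scipy.stats` behind this module's interface and are checked in
the tests against hand-rolled rank-formula and enumeration oracles, and
for type-I calibration (0.05 ± 0.01 at α = 0.05 under the null). The
family-wise threshold is Bonferroni: α/(tests per patient × patients),
with 12 tests per patient (3 metrics × 4 angles) by default. Percent
change, baseline normalization (0-mm value ≡ 1), extreme-angle
("minimum angle"/"maximum angle") selection with ties to the smallest
angle, and equal-weight angle averaging complete the layer. One- vs
two-sided testing is not dictated by the protocol; two-sided is used
throughout.

## What the synthetic experiments show — and what they do not

Passing recovery tests demonstrates that the estimation chain (tracking,
fitting, ellipse inversion, statistics) is unbiased and well-calibrated
*under the generator's assumptions*: homogeneous TI tissue, purely
axial motion, a 1-D MSD response with a shared force convention,
geometric stiffening, and stationary white receiver noise. Real breast
tissue is heterogeneous and poroelastic, moves physiologically, is
averaged over a 2–4 mm elevational volume, and is pushed by a beam whose
shape changes off focus — none of which the generator emulates. The
cohort-level "analog" results (e.g., near-universal per-patient
Kruskal-Wallis significance under nonzero stiffening, DoA invariance
under uniform stiffening) are structural properties of the synthetic
study, not reproductions of clinical medians, which cannot be recomputed
without the raw patient RF.

## Problem sizes

Default study runs use 20 subjects × 12 acquisitions, RF synthesized
over a 14–26 mm depth window, tracking and fitting restricted to a
16.8–23.2 mm × ±3.2 mm band around the focus (the analysis only ever
consumes the ±3 mm ROI). These sizes keep a full cohort run in minutes
on one core while leaving every protocol dimension (40 lines, 55 events,
3 compressions, 4 angles) at its stated value.

## Known limitations

- The MSD parameterization (m0, amplitude, fit window) is
  self-consistent between generator and fitter but is a reconstruction;
  a scanner implementation may scale RE/RV differently. Only ratios and
  percent changes should be compared across implementations.
- A small (+3–6%) multiplicative bias in RE/RV survives the chain; it
  cancels in DoA and percent change, the quantities the analysis reports.
- The ellipse fit at 4 points is near-interpolating: a single corrupted
  angle strongly moves DoA, mirroring the clinical fragility it models.
- `stiffening_per_mm` is a per-subject constant; angle- or
  depth-dependent compression responses (which would make DoA change
  under compression) are not modeled.
- No lateral/elevational displacement estimation, no physiologic-motion
  filtering (the synthetic data has none), no B-mode rendering beyond
  envelope images.
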