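# Methods

## Design sequence

All stages share one presentation design: per cycle, numerosities 1–7
once each followed by the 20-dot baseline held for three steps — ten
design points per cycle, one per TR (default 2 s), repeated for a
configurable number of cycles. Over one cycle, log10 numerosity has mean
0.761 and sample SD 0.445; these, together with the feature
correlations it implies (−0.890 for a 1/n feature, −0.969 for n^(−1/2),
−0.741 for 1/n², 0.934 for a linear-in-n feature), pin the weighting
down uniquely among simple integer-weight cycles, which is why it is the
default. The true presentation timing of the original experiment is not
public; step duration, TR and cycle count are all configurable, and
every statistic here is computed over design points rather than wall
time, so the analysis is invariant to that choice.

## Stimulus regimes

Items are circles (random shapes only in `variable_features`) placed by
uniform rejection sampling in a circular aperture of radius 0.75 deg,
centers drawn uniformly by area, bounding circles forbidden to touch,
with up to 10⁴ candidate draws before `PackingInfeasible` (larger items
are placed first, and placement restarts from scratch periodically to
escape dead ends). Defaults:

| regime             | controlled quantity              | default value |
|--------------------|----------------------------------|---------------|
| constant_area      | total item area                  | 0.064 deg²    |
| constant_item_size | per-item area                    | 0.187/8.8 deg² (≈0.0213) |
| constant_perimeter | total item perimeter             | 10^0.609 deg (≈4.064) |
| high_density       | item sizes of constant_area, placement radius | 0.375 deg |
| variable_features  | per-item area; shapes circle/square/triangle/2:1 ellipse | 0.0134 deg² |

These sizes jointly reproduce the published per-regime feature means and
correlations (item areas/perimeters, totals, and display RMS contrast
given the 0.75 deg aperture). The high-density placement radius and the
variable-features shape set are not published; 0.375 deg and the
four-shape set are this package's choices, exposed as parameters.
Variable-features perimeter statistics depend on the shape set and are
treated as qualitative only. The aperture radius 0.75 deg is the unique
value that makes binary-image display RMS contrast match the published
means, given that RMS contrast of a binary region is `sqrt(p(1-p))`
with `p` the white fraction.

Geometry is analytic throughout: item areas and perimeters are stored
exactly (ellipse perimeter via the complete elliptic integral), and a
display's totals are computed as display-mean × count, where the mean
of identical values is taken as that value exactly. With the default
constants `(x/n)·n` round-trips in IEEE double for every design
numerosity, so a regime's controlled feature is constant to the last
bit and its summary SD is exactly zero — mirrored by an exact-equality
short-circuit in the summary statistics so floating summation cannot
manufacture variance.

Rasterization (pixel-center sampling, default 128 px/deg for pipeline
features, 200 px/deg elsewhere, minimum 32) is used only where a feature
is genuinely image-based; rendered white area agrees with analytic area
to well under 1% at 200 px/deg.

## Features

Thirteen features per display plus numerosity. Tables' `log()` markers
determine each feature's axis: log10 for numerosity, total item
perimeter, hull area, hull perimeter, edge density and high-SF energy;
linear for the rest. The same axis is used for tuning models.

- **Item features** are analytic; "individual" values are display means
  over items. Individual item radius (circle-equivalent,
  `sqrt(area/π)`) is included as the representative of the
  luminance/radius family that makes predictions equivalent to item
  area's; with a dense grid, area- and radius-tuned fits agree closely
  but not bit-identically, because a Gaussian on one axis is not exactly
  a Gaussian on a monotone transform of it.
- **Convex hull** wraps item *edges*, not centers: boundary points (64
  per item; curved shapes sampled on the slightly inflated
  circumscribing polygon so the hull always contains the full item) are
  fed to Qhull. Degenerate rank-deficient point sets get area 0 and
  perimeter twice the span. Within-hull luminance, edge and numerical
  density are total area, total perimeter and count over hull area;
  a zero-area hull flags the step undefined (NaN), and tuned models
  treat undefined steps as evoking no response. Densities over the
  fixed aperture would be exactly proportional to the totals and are
  therefore not separate features.
- **RMS contrast** (display and hull) uses the binary closed form
  `sqrt(p(1-p))`, exact for non-overlapping binary items; the
  pixel-based estimator is provided and cross-validated against it.
- **High-SF contrast energy** is the per-pixel-normalized sum of squared
  DFT magnitudes at radial frequencies above 4 cycles/deg of the
  mean-subtracted image. Its absolute value depends on display
  parameters that are not published, so only its progression with
  numerosity is meaningful here; a blank image has energy 0 and is
  flagged undefined on the log axis.

Hull-dependent feature values depend on random placement; they are
regenerated per presentation (a fresh display per design step) and only
their qualitative patterns are asserted.

## Forward model and fitting

Neural response: `exp(-(x(t)-μ)²/(2σ²))` on the feature axis. BOLD
prediction convolves this with a two-gamma HRF (peak 6 s, undershoot
16 s, unit dispersions, peak:undershoot 6, 32 s kernel, peak normalized
to 1; all configurable). Because the design repeats in cycles, the
convolution is cyclic (the kernel folded modulo the run length),
modelling the steady state of a repeating run; this also guarantees
that a constant feature track predicts an exactly flat response and so
explains exactly zero variance, rather than spuriously absorbing
variance through an onset transient. Linear convolution is available
as an option.

Fitting is exhaustive over a (μ, σ) grid — default: μ spans the
feature's observed range across configurations extended 20% each side in
40 steps; σ log-spaced 0.05–3 axis units in 30 steps. Amplitude
(constrained non-negative, since tuned responses are excitatory) and
baseline are solved per candidate in closed form; R² ties resolve to the
smallest σ, then smallest μ. Constrained fits share one (μ, σ) across
configurations with per-configuration amplitude/baseline, minimizing
pooled SSE; per-configuration R² under the shared parameters is
reported alongside the SSE-pooled overall R². The same grid serves both
scopes, so the constrained optimum is always a feasible candidate of
each specific fit and the bound
`R²_constrained(c) ≤ R²_specific(c) + 1e-10` holds by construction.
A sign-constrained option for amplitude and raw-vs-demeaned R² are the
two conventions the literature leaves open; defaults are non-negative
amplitude and R² against the signal's own mean.

## Synthetic populations

The generator emulates a numerosity map: by default 100 voxels,
preferred log10 numerosity uniform over [0, log10 7], tuning width
increasing linearly 0.2–1.0 with the preferred value, amplitude 1,
baseline 0, white noise SD 0.5 (amplitude/noise = 2), identical
numerosity progression in all five configurations, noise independent
per (voxel, configuration) and seeded per voxel. AR(1) noise is
available, with innovation scaling chosen so ρ = 0 reduces *exactly* to
white noise and the marginal SD is stationary.

What this emulates — and what it does not: responses generated exactly
from the fitted model family, no drift, no physiological or spatially
correlated noise, no HRF variability across voxels, no partial-volume
mixtures of tunings. Passing tests on these populations therefore
demonstrate the *internal* correctness and discriminative behaviour of
the analysis (numerosity-tuned data are better explained by numerosity
models than by any co-varying feature model, with the same collapse
patterns of constrained fits seen in the real recordings), not that the
real recordings are numerosity-tuned; the real-data figures and
p-values cannot be reproduced without the original data, which are
available only on request.

## Comparison

Per-site overall R² within a scope is the mean of per-configuration R²
over included configurations — for both scopes, so that subsetting
configurations (e.g. dropping the regime where a feature is constant)
composes consistently with the full comparison. Paired two-sided
Wilcoxon signed-rank tests compare the numerosity model's per-site
values with each feature model's; zero differences are dropped, an
all-zero comparison reports p = 1, the null distribution is exact up to
25 effective pairs and a normal approximation with continuity
correction beyond. No multiple-testing correction is applied; p-values
are reported raw.

## Problem sizes

Default analyses use one design cycle (10 points) for feature tables
and 20 cycles (200 samples) for model fitting; the shipped synthetic
study uses 100 voxels × 14 models × 5 configurations with a 1,200-point
grid. These sizes give stable medians and exhaust the signed-rank
test's resolution while keeping any run desk-scale.

## Known limitations

- Hull-dependent published table cells are reproduced qualitatively
  only: they depend on unpublished placement details.
- The variable-features perimeter statistics depend on the chosen shape
  set.
- Grid search quantizes (μ, σ); no continuous refinement is performed.
- Very narrow tunings centered outside the sampled numerosity range are
  not identifiable from eight distinct design values; recovery
  guarantees apply within the map's parameter ranges.
- The published individual-item-perimeter mean (and one display RMS
  mean) sit ~0.4% off the ideal-circle values implied by the stated
  areas, consistent with pixel-level measurement in the original;
  scale-invariant correlations are used where this matters.
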