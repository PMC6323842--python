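# Methods

## Motion model

Within one breathing cycle the superior–inferior (SI) tumor
displacement is

    Z(t) = A · (cos⁴(π t / P) − 1/2),   t ∈ [0, P),

so a cycle starts at its inhale peak (+A/2), spends most of its time
near the exhale valley (−A/2) — the cos⁴ shape is quartically flat at
the valley but only quadratically flat at the peak, reproducing the
long end-exhale dwell of real breathing — and returns to the peak.
A session concatenates cycles whose peak-to-peak amplitude A and
period P are drawn independently per cycle from N(μ_A, σ_A) and
N(μ_P, σ_P), with σ expressed through coefficients of variation
(σ_A = cv·μ_A). Draws at or below 0.5 mm / 0.5 s are rejected and
redrawn (no point mass at a clip value). Cycles join at their peaks;
the junction step is bounded by half the amplitude difference of the
adjoining cycles. Sessions last 100 s (a typical 4DCT acquisition)
and are truncated mid-cycle if needed; a final cycle cut by the
session end is kept in the trace but excluded from cycle statistics.

Consequences used throughout:

* The occupancy density of Z is **not symmetric**: exhale dwell
  dominates, so the empirical position pdf concentrates inferiorly
  (for A = 10 mm: p(−5) ≈ 0.31 vs p(+5) ≈ 0.11). The 80% equal-tail
  coverage interval therefore extends beyond the planning range on
  the exhale side first.
* Cycle amplitude is estimated valley-anchored, A = −2·min(Z per
  cycle): the valley is interior to its cycle, whereas a detected
  peak always belongs to the larger of the two adjoining cycles,
  which would bias a peak-anchored estimate upward.

Tunable parameters (defaults): sampling interval 0.02 s for simulated
traces (fine enough for midpoint phase sampling), 1/30 s for
fiducial-like patient traces with additive Gaussian noise of sd
0.5 mm (fluoroscopic marker tracking is accurate to ~1 mm); session
duration 100 s; scenario-bank seeds derived as
`base_seed + row_index·1000 + replicate`.

## Trace processing

Noisy traces are low-pass filtered with a zero-phase (forward–
backward) 4th-order Butterworth filter, default cutoff 1 Hz: breathing
fundamentals (~0.2–0.5 Hz) and their first harmonic pass essentially
unattenuated, while measurement noise is removed, and zero-phase
filtering leaves extremum timestamps unbiased — these anchor the
phase sampling. Extrema are detected with a minimum prominence of
20% of the displacement inter-quartile range and forced to alternate
(of two same-type neighbors the more extreme is kept; ties resolve to
the earlier sample). Trace endpoints that dominate their single
neighbor count as extrema — the generator starts sessions at a peak —
but a full cycle *ending* on the final sample is excluded from
statistics, since it may stem from mid-cycle truncation.

Phase sampling follows the clinical phase-sorting rule: a cycle span
is divided into ten equal time intervals and the displacement at each
interval midpoint (linearly interpolated) is that phase's tumor
position. Whether "cycle" means the full peak-to-peak period or a
peak–valley half cycle is genuinely ambiguous in the clinical
description (phase labels put the valley at 0% and the peak at 90%,
suggesting half cycles, but ten phases per breathing period is the
common convention); both are implemented behind a `phase_mode`
switch, defaulting to the full-cycle reading. Measured: the
pipeline's acceptance-level outcomes do not differ materially between
the two.

The tumor-position pdf is the occupancy fraction of displacements
rounded half-up (toward +∞, with a 1e-9 guard against representation
error at exact half-mm values) to integer-mm bins. The coverage
interval is equal-tail: lo (hi) is the smallest position whose
cumulative probability reaches (1−c)/2 (1−(1−c)/2).

## Phantom and dose surrogate

The phantom is a purely geometric 1-mm isotropic voxel grid (default
120³) with a spherical GTV (diameter 2/3/4 cm) whose center at SI
offset 0 defines the coordinate origin; offsets are integer mm in
[−15, 15], giving the 93-entry (3 diameters × 31 positions)
phase-tagged sample bank with phase = ⌊(i+15)/3⌋ and i = 15 → 9.
Voxels belong to a sphere iff their centers do (no partial-volume
weighting). The ITV is the union of GTV masks over a position set.
No CT background is modelled: the dose stand-in below is geometric,
so tissue heterogeneity would be irrelevant.

The clinical reference dose is a two-arc VMAT lung-SBRT plan (60 Gy /
5 fractions to the ITV) from a commercial TPS; that is replaced by an
analytic field reproducing the plan's defining properties. With s the
signed Euclidean distance to the ITV surface (mask voxels adjacent to
outside sit at s = 0; outside voxels start at +1 voxel):

    dose(s ≤ 0) = D_max · (L + (1 − L) · min(1, −s / core_depth))
    dose(s > 0) = Rx · exp(−s² / (2 σ_pen²)),   D_max = Rx / L

for prescription Rx and isodose level L ∈ {0.70, 0.80, 0.90}. The ITV
surface receives exactly Rx, the interior ramps to D_max over
core_depth (default 5 mm), and the exterior falls off with a Gaussian
penumbra (σ_pen default 3 mm; the 80%→20% distance of this
exponential profile is (√(2 ln 5) − √(2 ln 1.25))·σ ≈ 1.13 σ, i.e.
~3.4 mm at default — a deliberately sharp, SBRT-like gradient, and
config-exposed to study gradient dependence). Fractionation is
dose-proportional; there is no fluence optimization, MLC/interplay
modelling, or heterogeneity correction.

## Accumulation and metrics

Motion is rigid and SI-only, so deforming a phase dose to the
reference anatomy is exact: the accumulated dose of a reference GTV
voxel is the mean of the static dose sampled at its shifted
positions. Displacements are rounded to the integer-mm sample bank
(config switch; linear SI interpolation when disabled) and clamped to
±15 mm with a logged warning. D⁴ᴰ accumulates the ten phase samples
of one cycle (I = 10); Dᵗʳᵘᵉ accumulates the whole trace resampled on
a uniform grid, default 0.4 s (I = 250 per 100 s). The resampling
uses **interval midpoints** (t = (k+½)·0.4 s): a t = 0-anchored grid
would sample every exact cycle peak of a homogeneous session — a
position the midpoint-based phase sorting never sees — and introduce
a systematic ~0.5% D₉₉ offset between D⁴ᴰ and Dᵗʳᵘᵉ even with zero
motion variance; midpoint resampling makes the null case exact by
construction and is the consistent discretization.

D_x (largest dose level, in % of Rx, covering x% of the GTV) uses the
conservative rank convention: voxel doses sorted descending, value at
rank ⌈x/100·N⌉, no interpolation. The worst-case deviation is

    ΔD̄ₓ = Σⱼ maxₖ |D⁴ᴰₓ,ⱼ,ₖ − Dᵗʳᵘᵉₓ,ⱼ| / (J · Dᵗʳᵘᵉₓ,ⱼ) × 100%,

j over curves (J = 10 simulated replicates, 5 patient fractions), k
over the cycles of curve j. The ratio form makes ΔD̄ₓ identical in Gy
or % of Rx. A signed (under/over-dose) breakdown is available from
the tidy record table. Sweeps fit ordinary-least-squares trends;
standard-vs-robust comparisons report both the paired t-test and the
Wilcoxon signed-rank test (with n = 5 fractions the Wilcoxon cannot
reach p < 0.05; the t-test carries the significance claim). With all
paired differences zero both p-values are reported as 1.

## Robust strategy

Per patient, five fiducial-like fraction traces are generated from
the printed per-fraction motion statistics, filtered, and pooled; the
traditional plan is built on a homogeneous planning curve whose
amplitude is the patient's mean excursion; the robust plan extends
the traditional phase positions with every integer mm of the pooled
80% coverage interval and rebuilds ITV and dose. Because the
extended ITV contains the standard one, the surrogate dose field
dominates the standard field voxel-wise, so Dᵗʳᵘᵉ₉₉(robust) ≥
Dᵗʳᵘᵉ₉₉(standard) holds for every fraction by construction — the
interesting quantities are the size and significance of the gain,
which track breathing irregularity (regular breather: zero to
negligible gain; irregular ~15 mm breather: positive gain,
paired-t p < 0.05).

## What the synthetic data does and does not emulate

Emulated: per-cycle amplitude/period variability at the printed
scenario and patient statistics, ~100 s sessions, 30 Hz jagged
fiducial traces with mm-scale noise, exhale-dominated dwell. Not
emulated: baseline drift, hysteresis, RL/PA motion components,
deformation (motion is rigid by design), MLC interplay, CT image
content. Passing tests therefore demonstrate the *mechanism* —
heterogeneity-driven divergence of phase-sorted accumulation from
whole-trace accumulation, and its mitigation by pdf-based ITV
extension — not clinical dosimetric magnitudes: the dose stand-in is
far sharper and more idealized than a TPS-computed VMAT dose, and all
reported percentages are specific to it.

## Numerical choices and limitations

* Problem sizes: the packaged experiments run on a 120³ grid (tests
  use a 44×44×120 grid — same SI extent, trimmed transverse margin)
  with 5–10 replicates per scenario; accumulation caches the 31
  integer-shift dose vectors per plan, making whole-banks runs a
  matter of seconds.
* Half-up rounding (toward +∞) at ±0.5 mm; ties in plateau extremum
  detection resolve to the earlier sample.
* The worst-case metric maxₖ is a heavy-tailed statistic of the
  largest cycle in a session, quantized by the 1-mm bank: at reduced
  replicate counts the amplitude ordering of ΔD̄₉₉ between adjacent
  sweep points can invert for unlucky seeds, and beyond ~15 mm mean
  excursion the combination of the sharp default penumbra (excursions
  a few mm past the ITV already reach near-zero dose) and the ±15 mm
  phantom clamp compresses the response — the amplitude trend is
  robustly positive overall (large slope, R² ≈ 0.9) but not strictly
  monotone step-by-step in every run.
* Equal-tail coverage of the exhale-heavy position distribution
  extends the ITV asymmetrically (inferior side first); a clinic
  preferring symmetric margins would symmetrize the interval.
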