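# Methods

## Signal model and T1 estimation

All images are modelled as spoiled gradient-recalled echo (SPGR) magnitude
signal, S = S0 · sin α · (1 − E1)/(1 − E1 cos α), E1 = exp(−TR/T1), with the
commanded flip angle taken as the true one (no B1 correction).  Precontrast
T10 and S0 come from the variable-flip-angle acquisition (2°, 5°, 10°, 12°;
TR = 2.3 ms) through the standard linearisation — S/sin α regressed on
S/tan α, slope E1 — which is deterministic and exact on noise-free data.  A
slope outside (0, 1) or a non-positive intercept marks the voxel as failed
rather than propagating NaNs.  During the dynamics the SPGR equation is
inverted for E1 at the single dynamic angle (12°) using the VFA S0.
Enhancement strong enough to drive the inversion out of domain
(S ≥ S0 sin α) is clamped to a 1 ms T1 floor and flagged; non-positive
signals are clamped to a 20 s ceiling and flagged.  Clamping instead of
raising keeps one pathological voxel from aborting a map.

## Concentration and the hematocrit convention

C(t) = (1/T1(t) − 1/T10)/r1, with a single longitudinal relaxivity
r1 = 4.39 s⁻¹mM⁻¹ applied to blood and tissue alike — a deliberate
simplification consistent with the acquisition the package models.
Slightly negative concentrations produced by noise are retained (clipping
would bias the baseline and the least-squares fit); the pipeline reports
their count.  Whole-blood concentration converts to plasma by division,
Cp = Cb/(1 − Hct), Hct = 0.45; a `convention="multiply"` switch preserves
the alternative literal reading Cp = Cb·(1 − Hct).  The choice rescales the
AIF and hence Ktrans and vp by a common factor, so correlation-type results
are invariant to it.

## Arterial input function

Visual AIF selection ("high, narrow, fast wash-in/wash-out") is made
operational as a composite score, peak/(time-to-peak × FWHM), with FWHM by
linear interpolation between frames (the 2.4 s frame spacing is coarse
relative to the bolus width) and ties broken by linear voxel index.  The
top-k voxels (default k = 5, configurable) are averaged as whole blood and
converted to plasma; an explicit voxel list bypasses scoring for
operator-driven use.  No partial-volume correction is applied beyond voxel
choice.

## Extended Kety model

Ct(t) = vp·Cp(t−t0) + Ktrans·Cp(t−t0) ⊗ exp(−(Ktrans/ve)t).  Rate constants
are per minute internally (the magnitudes of the bundled cohort, 0–4, are
only consistent with 1/min); grids and t0 are seconds.  The convolution is
an exact trapezoid evaluated by the order-1 recursion
I_i = E·I_{i−1} + (dt/2)(E·Cp_{i−1} + Cp_i), E = exp(−kep·dt), implemented
as an IIR filter; the delay is applied by linear interpolation of Cp so
sub-frame t0 is meaningful.  Against the analytic impulse response the
quadrature is exact (machine precision) at every frame after the impulse;
at the impulse frame itself any symmetric quadrature integrates only half
the discrete spike, so oracle comparisons start one frame later.

Fitting is bounded nonlinear least squares (scipy TRF) on
(Ktrans, ve, vp, t0) with bounds [0, 10] /min, [1e−6, 1], [0, 1], [0, 30 s]
— bracketing the observed cohort by a wide margin — from the single start
(0.1, 0.2, 0.02, 0); tolerances 1e−12 make noise-free fits effectively
exact.  A fitted Ktrans at ~0 leaves ve unidentifiable (no tracer enters
the EES): ve is then reported as NaN with a flag rather than suppressed, so
necrotic regions keep their row structure.  An all-zero curve is a valid
exact fit at Ktrans = vp = 0.  Voxels are fitted independently, so maps are
order-independent and trivially parallelisable.

## Subregions

The "9-voxel neighborhood" is interpreted as the 3×3 in-plane window: with
0.75 mm in-plane voxels and 2 mm slices, through-plane averaging would mix
anatomy.  Window placement is unstated in operator-driven practice; for
determinism the window is placed at the region voxel whose window-mean
Ktrans is the region's median among windows lying fully inside the region
(lower median for even counts, ties to the lowest linear index), with a
flagged centroid fallback for regions too thin to contain any window.  The
median-window rule makes the summary robust to a minority of outlier
voxels.  One window per region is used.  Label resampling from a
high-resolution grid is nearest/majority vote per target-voxel footprint
with ties to the lower code; histology-to-image correspondence is taken as
given (no deformable registration).

## Statistics

Wilcoxon signed-rank, two-sided, zero differences dropped and rank ties
mid-ranked.  Up to 25 effective pairs the p-value comes from the exact
permutation distribution computed by dynamic programming over doubled
(integer) ranks — mid-ranked ties included, which matters because 2-decimal
parameter tables tie often; beyond 25 the tie-corrected normal
approximation (scipy) takes over.  Pearson r uses the t-distribution
p-value (scipy), requiring n ≥ 3 and non-degenerate variance.  The combined
PNA+VTA analysis takes, per tumor, the unweighted mean of its two perfused
regions for each parameter and for MVD, keeping n at the number of tumors;
a pooled mode (2n rows) exists for sensitivity analysis but is not the
primary reading.  P ≤ 0.05 is called significant; no multiple-testing
correction is applied, matching the analysis plan the package implements.

## Digital phantom

The phantom emulates a coronal multi-slice liver acquisition (matrix
160×160, 2 mm slices, dt = 2.4 s, 120 dynamics with 2 baseline frames, VFA
2/5/10/12°, TR 2.3 ms) over one lesion per slice: concentric discs — CNA
core, PNA ring, VTA rim — inside a liver disc, plus a small blood pool.
Region Ktrans anchors (CNA 0.04, PNA 0.29, VTA 1.00 /min) and the ve/vp
anchors are the column means of the bundled cohort table, keeping synthetic
curves in the regime the pipeline targets.  Across tumors a shared
log-normal vascularity factor (σ = 0.8, matching the cohort's
coefficient of variation of about one) scales all regions of a tumor, with
small per-region jitter; the CNA < PNA < VTA ordering is enforced by
construction.  Voxel-level scatter defaults to 10 % (log-normal) for Ktrans
and small additive SDs for ve/vp; setting the SDs to zero gives
piecewise-constant maps.

The synthetic arterial curve is a gamma-variate first pass (arrival 6 s,
mode 9.6 s later, shape 3) plus a slowly washing-in biexponential tail,
normalised so the grid maximum equals the configured whole-blood peak
(5 mM) — any smooth bolus with a high narrow peak and fast wash-in/out
satisfies the selection criteria the AIF module operationalises.  MVD field
counts follow slope·Ktrans + intercept (15 vessels per unit Ktrans, +2)
with 1.5-vessel field noise, five fields averaged, truncated at zero;
necrosis draws near 1 vessel/field.  These defaults put PNA near 6 and VTA
near 17 vessels/field, the cohort's levels.

Noise is additive Gaussian on magnitude signal, not Rician: at the
signal-to-noise of interest the two are indistinguishable and Gaussian
keeps the likelihood consistent with least squares.  The phantom does not
model breathing motion, B1 inhomogeneity, inflow effects, water exchange or
T2* saturation — so passing recovery tests demonstrates correctness of the
estimation chain under the model's own assumptions, not robustness to those
physical confounds.  Rendering and fitting are an intentional inverse
crime; that is what makes the noise-free recovery bound (2 % Ktrans) a
sharp software test.

## Problem sizes and numerical tolerances

Tests and the acceptance script run the end-to-end recovery on reduced
grids (48×64 in-plane, 3 tumor slices, ~800–1500 tumor voxels) rather than
the full 160×160×8: recovery is voxel-wise, so the reduced grid checks the
identical property per voxel at a fraction of the cost.  Statistical
calibration uses 15-tumor phantoms at 24×24 per slice over 500 (null) and
200 (power) seeds.  The calibration null link uses intercept 10 so that
zero-truncation of field counts is inactive and the Pearson p-value is
exactly uniform under the null.  Fit tolerances are 1e−12 (xtol/ftol/gtol),
max 400 function evaluations; VFA and SPGR inversions round-trip to better
than 1e−8 relative.

## Known limitations

Single-input model only (no dual arterial/portal supply); no motion
correction or registration; no B1 mapping; one global r1; MVD enters as
counts, not from vessel segmentation.  The ve reported in completely
necrotic regions is weakly identified when Ktrans ≈ 0 — it is flagged, not
suppressed, to preserve the cohort table's structure.
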