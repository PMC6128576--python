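# Methods

## The measurement model

The pipeline mirrors the clinical workflow for sizing the residual
component of a coiled aneurysm on time-resolved contrast-enhanced MRA:

1. **Arterial-phase selection.** The dynamic series is summarized by the
   mean intensity inside a small spherical ROI (default radius 3 mm)
   around an operator seed in the target lumen; the phase maximizing
   that mean is the optimal contrast-filling phase. Ties break to the
   earliest phase so the result is deterministic.
2. **Signal-intensity profile.** Intensities are sampled by trilinear
   interpolation at uniform arc-length steps (default 0.25 mm, never
   coarser than the voxel spacing) along an operator-drawn line that
   crosses the residual aneurysm and extends into non-enhanced tissue on
   both sides.
3. **Baseline and FWHM.** The baseline is the pooled median of the first
   and last ⌈0.1·n⌉ samples; it is estimated, not assumed zero, because
   contrast-enhanced background tissue has nonzero signal. The peak is
   the global maximum of the profile (the operator's line is drawn so
   the target is the dominant enhancement). Walking outward from the
   peak, the first sample below the half-maximum level on each side
   brackets a crossing located by linear interpolation; the FWHM is the
   distance between the two crossings. Linear interpolation (no spline
   fit) keeps the operation exactly reproducible. The analysis requires
   peak − baseline > 1e-6 × peak, and fails loudly when the profile
   never returns below the level on one side.
4. **Window level.** The half-maximum *intensity*
   WL = baseline + (peak − baseline)/2 becomes the window level of the
   thresholded reconstruction. A boundary drawn at this intensity
   reproduces the FWHM width of the profiled structure, which is what
   makes the downstream sizes observer-independent. This is the standard
   FWHM-thresholding reading; whether a clinical workstation applies WL
   as a binary iso-surface or as the centre of a finite-width opacity
   ramp varies by vendor, and we implement the threshold reading. The
   construction is affine-equivariant: mapping intensities I → aI + b
   (a > 0) leaves every width unchanged and maps WL → a·WL + b, so
   contrast dose and scanner scaling do not affect measurements.
5. **Segmentation and morphometry.** The segmentation is the
   26-connected component of {I ≥ WL} containing the seed — a
   reproducible surrogate for the volume rendering a workstation would
   display at that window level. Measurements are made on the
   orthographic projection of the mask along an operator-chosen view
   normal, rasterized at the finest voxel pitch:
   * **Neck length** — distance between the projections of the two
     annotated neck points.
   * **Dome side** — the residual region is the part of the silhouette
     on the far side of the projected neck line. When a seed annotation
     is present its side defines the dome; without a seed, the side
     holding the centroid of the silhouette minus the neck line's
     one-pixel dilation is used. (The seed rule is preferred because a
     segmented component usually contains a long stretch of parent
     artery whose silhouette dominates the centroid.)
   * **Largest diameter** — maximum Feret diameter of the dome-side
     region measured over *pixel corners* (each pixel a unit square of
     the raster pitch, so a single pixel has Feret √2·pitch). The
     implementation takes the convex hull of the corner cloud first;
     tests verify it against brute-force pairwise search.
   * **Smallest diameter** — extent of the region along the in-plane
     direction perpendicular to the max-Feret axis. This is the clinical
     height-versus-width reading; it is *not* the minimum caliper width
     (for elongated regions the two differ).
   * **Residual volume** — count of 3D mask voxels on the dome side of
     the neck line × voxel volume.
6. **Parent-artery diameter.** The local vessel axis is the principal
   direction of above-level voxels within 5 mm of the proximal neck
   point, restricted to the parent side of the projected neck line when
   the projection is annotated (otherwise remnant voxels bias the
   axis). The profile is sampled through the fitted lumen centre,
   perpendicular both to the axis and to the parent-to-remnant
   direction — so it cannot re-enter the remnant — and its FWHM is the
   diameter. A neighbourhood without a dominant principal direction
   (eigenvalue ratio < 1.5) is rejected as degenerate rather than
   silently measured.

## The synthetic phantom

The generator emulates the acquisition the pipeline targets: ten dynamic
phases at 1.23 s temporal resolution, 1.0 mm isotropic voxels. The
geometry is a cylindrical parent artery (default radius 1.5 mm, i.e. a
3 mm vessel, typical of the supraclinoid carotid), an ellipsoidal
remnant (default semiaxes 4 × 3 × 2.5 mm) joined to it by a neck channel
(default width 2.5 mm), and a signal-void sphere (default radius 2 mm)
capping the dome as a coil mass. Structure centres default to voxel
centres; anchoring them between voxel centres can put an analytic
boundary exactly on the centre-in/centre-out decision surface of the
voxelizer, which collapses thin structures.

Signal: lumen voxels carry background + a normalized gamma-variate
bolus A·((t−t₀)/(αβ))^α·exp(α−(t−t₀)/β) — zero before onset t₀, peaking
at exactly A at t₀+αβ (defaults A = 200 intensity units above a tissue
background of 20, t₀ = 2 s, α = 3, β = 1.5 s, peak at 6.5 s — within the
40 s acquisition window of a 10-phase scan). The gamma-variate is the
standard first-pass bolus shape in perfusion modelling. Each phase is
blurred with an isotropic Gaussian PSF (default σ = 0.5 mm) and degraded
with Rician noise √((S+n₁)² + n₂²), n₁,n₂ ~ N(0, σ_noise) — the
magnitude-MRI noise model, which is Gaussian-like at high SNR but
correctly positive-biased near the signal void. Default σ_noise = 4
gives peak-enhancement SNR 50. All randomness flows from a required
seed; identical config + seed is bit-identical.

Ground truth is computed from the unblurred voxelized geometry: parent
diameter 2r, remnant largest/smallest diameter from the semiaxes, neck
length = the neck-channel width (the proximal–distal extent of the
lumen opening between parent and remnant), and remnant volume = voxel
count of the remnant component × voxel volume (exact for the voxelized
object; it differs from the analytic ellipsoid volume by the boundary
shell, roughly the surface area × voxel size).

**What the phantom does not emulate:** k-space sampling and
parallel-imaging artifacts, susceptibility ringing around the coil (the
coil is a clean zero-signal sphere, justified by the sequence's relative
insensitivity to metal artifact), vessel curvature and tapering, venous
contamination, and patient motion. Passing the recovery tests therefore
demonstrates that the *measurement chain* is unbiased at clinical
voxel/SNR scales on clean geometry — not that the method is robust to
every real-world artifact.

## Validation at desk scale

* **Analytic laws.** Gaussian profiles of σ ∈ {1, 2, 4} mm must yield
  FWHM/σ = 2√(2 ln 2) within 1%; box profiles recover their width to one
  sampling step.
* **Oracle equivalence.** The trilinear sampler, Feret diameters,
  Spearman's rho and the exact Wilcoxon p are each checked against an
  independent brute-force implementation (dense re-interpolation,
  pairwise corner search, mid-rank Pearson, full 2ⁿ enumeration and a
  10⁵-draw Monte-Carlo sign-flip oracle).
* **Parameter recovery.** Twenty seeded phantoms with remnant largest
  diameters drawn uniformly in 6–10 mm (semiaxis ratios 1 : 0.75 : 0.6),
  PSF σ in 0.4–0.75 mm and noise giving SNR 15–33: the parent-artery
  FWHM diameter must recover truth within one voxel and the remnant
  largest diameter within 15%. The 15% band absorbs the irreducible
  silhouette discretization of small structures: a corner-measured
  silhouette of a 6–10 mm object at 1 mm pitch carries an expected
  +0.5–1 voxel bias.
* **Published-table arithmetic.** The 2×2 reconstruction searches all
  (tp, fp, fn, tn) with total 97 whose exact Clopper–Pearson intervals,
  rounded half-up to two decimals, match the published sensitivity and
  specificity bounds; the search proves uniqueness, and the resulting
  table reproduces the published PPV/NPV points and intervals — which
  were not inputs — plus the 96.9% agreement. Clopper–Pearson is the
  only common interval that reproduces all printed bounds (a Wald
  interval degenerates at x = n).

## Statistical conventions

* Clopper–Pearson via Beta quantiles; lo(0, n) = 0, hi(n, n) = 1,
  lo(n, n) = (α/2)^(1/n).
* Zero denominators yield a flagged undefined metric, not an exception.
* Cohen's kappa returns 1 for perfect observed agreement even when the
  chance agreement is 1 (limit convention); on the reconstructed 2×2
  table it evaluates to 0.825. Note the published inter-modality kappa
  (0.84) is not reproduced by the 2×2 formula; it was likely computed on
  a finer categorization that is not published, so no target is tied to
  it.
* Wilcoxon signed-rank: zero differences dropped, mid-ranks for tied
  magnitudes; exact two-sided p = min(1, 2·min(P(W≤w), P(W≥w))) from the
  full sign-assignment distribution when n ≤ 20 with no ties, else a
  normal approximation with tie and continuity corrections.
* Rounding for printed-table matching is half-up (so 0.9662… prints as
  0.97), done in decimal arithmetic to avoid binary-float surprises.

## Problem sizes

Defaults keep everything desk-scale: 64³ voxel grids, 10 phases, 20
recovery phantoms, exhaustive 2×2 search over ~97²/2 denominators. The
full suite runs in well under a minute on one core.

## Known limitations

* Axis-aligned geometry only: oblique NIfTI affines are rejected, not
  resampled.
* The measurement projection is an input; the operator-driven "optimal
  projection" search of the clinical workflow is not automated.
* The smallest-diameter convention (perpendicular to max Feret) is one
  of several defensible readings; regions measured with a
  minimum-caliper convention will differ.
* Cohort-level size comparisons (means, rho, Wilcoxon p across
  patients) require patient measurements; the machinery is implemented
  and tested on synthetic pairs only.
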