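# Methods

This note documents the models, numerical choices, and open design decisions
behind `axsite`, and what the synthetic-data studies do and do not
demonstrate about real recordings.

## Fiber photometry

**Model.** A session is a 2-kHz photodetector trace with 470-nm (functional)
and 405-nm (isosbestic) excitation alternated at 100 Hz (10 samples per
phase).  Processing follows a fixed order: demultiplex → re-bin at the cycle
rate → background subtraction → baseline normalization → %ΔF/F → triggered
averaging → light-on integrals.

- *Demultiplexing.* The mux square wave must be a regular two-level
  alternation; the higher level is taken as the 470-nm phase.  The first
  k = 2 samples of each 10-sample phase are discarded (LED/photodetector
  settling; the acquisition convention does not specify a value, so it is a
  configurable parameter) and the remainder averaged into one bin per cycle.
  The stimulation trigger is down-sampled by an any-high rule per cycle.
- *Sliding-percentile baseline.* B(t) is the linearly interpolated 8th
  percentile of a 20-s window centered on t, truncated (not padded) at the
  record edges.  The percentile tracks slow bleaching while ignoring
  transients that occupy < 8% of a window.  The implementation maintains a
  sorted window incrementally (a numba kernel, O(n·w) element moves); it is
  validated against a per-window sort-and-interpolate oracle to 1e-12.
- *Background.* Non-sensor background is removed as F − f·B(t).  The
  fraction f is estimated once per rig from a no-sensor control region as
  median(control fluorescence) / median(baseline of the signal trace) — one
  reading of an ambiguous convention, isolated in
  `estimate_background_fraction` — and applied to both channels (per-channel
  values are accepted).
- *ΔF/F.* n(t) = F(t)/B(t) with a freshly computed sliding baseline of the
  background-subtracted trace, then ΔF/F = 100·(n − b)/b with b the
  whole-trace 8th percentile of n (the normalized trace, not the raw one —
  the processing description reads that way, and the choice only shifts the
  display offset).  ΔF/F is exactly invariant to rescaling the raw
  fluorescence and exactly zero on constant traces.
- *Evoked integrals.* Per stimulation, the trapezoidal integral of ΔF/F over
  the light-on window (0.5 s by default), in %·s.  For display, integrals
  are affinely mapped across the full pooled comparison set so min → −0.25
  and max → 1 (both groups on one axis); statistics always use raw
  integrals.  Because the percentile baseline sits below the noise mean,
  ΔF/F carries a small positive offset common to all groups; group ratios of
  raw integrals are therefore mildly compressed toward 1, which the
  synthetic recovery study quantifies (~0.63 recovered for a true 0.6 ratio
  under the default noise level).
- *Isosbestic control.* The 405 channel is processed identically and
  reported; no regression-based motion correction is applied.  Its evoked
  component (light-on integral referenced to the pre-onset segment mean) is
  statistically zero when the simulator injects none.

**Simulator.** Transients use the difference-of-exponentials kernel
(1 − e^(−t/τr))·e^(−t/τd), normalized to unit peak (τr = 80 ms,
τd = 400 ms — sub-second kinetics typical of current dopamine sensors);
bleaching is a slow exponential; a common low-frequency sinusoidal motion
term can be injected into both phases; noise is white Gaussian at the raw
rate.  Default stimulation design: 0.5-s trains, 8 repeats, 20 s apart.
What this does not emulate: hemodynamic artifacts, sensor saturation,
wavelength-dependent motion coupling, or non-stationary noise — so passing
recovery tests show correctness of the processing chain, not robustness to
every in-vivo artifact.

## 2D synaptosome analysis

Segmentation is the classic particle-analysis chain: rolling-ball background
subtraction (grayscale opening with a non-flat ball kernel, radius 33 px,
edge-clamped), binarization at the iterative-intermeans ("default")
threshold on a 256-bin histogram, 8-connected labeling, then calibrated area
(0.04–0.40 µm², or 0.06–0.60 µm² for TH) and circularity (0.30–1.00)
filters.  Circularity is 4πA/P² with the weighted-contour perimeter
estimator (straight/corner/diagonal border pixels weighted 1, (1+√2)/2, √2),
clipped at 1.0; the raw crack-contour length would underestimate circularity
of digital disks by ~35% and push round particles out of the filter band.
Particle "size" is interpreted in calibrated µm².

Marker positivity is strict: mean intensity over the ROI must exceed twice
the mean over *all* pixels of the image (ROI pixels included).  The chain
seeds ROIs from VAMP2, retains VAMP2+, classifies TH within them and bassoon
within the double-positives.  Overlap areas intersect independently
segmented bassoon and TH ROIs pairwise ("AND"), keep VAMP2+ overlaps, and
report the mean overlap area; an empty set is a missing value, never zero.
The whole chain is verified to agree *exactly* with a per-pixel brute-force
reference on random small fields.

## 3D active-zone density

- *Local contrast.* Channels are smoothed at σ = grain/2 (grain 0.0643 µm
  for axon surfaces, 0.06 µm for puncta) and a Gaussian baseline subtracted.
  The vendor "largest sphere" background subtraction is proprietary; a
  grayscale opening with a ball at the stated diameters (0.241 / 0.15 µm)
  would return the structures themselves — the ball is smaller than the
  objects — and null the contrast, so the baseline is a Gaussian with
  σ = 2× the stated sphere diameter: structures at or below the sphere scale
  pass largely unattenuated, larger-scale background is removed.  The
  mapping is declared and configurable.
- *Axon surfaces.* Intermeans auto-threshold on the contrast volume,
  components under 50 voxels removed, source intensities zeroed outside the
  mask.
- *Skeleton length.* 3D skeletonization; skeleton voxels form a graph over
  the 26-neighborhood with physical edge lengths (anisotropy-aware); the
  minimum spanning forest removes double-counted local triangles; terminal
  spurs shorter than 0.5 µm (surface-roughness artifacts at the tube-radius
  scale) are pruned; each remaining centerline chain is smoothed over 0.3 µm
  of arclength before summing, because the raw voxel chain zigzags — most
  expensively along a coarse z axis — and otherwise inflates length by
  10–20%.
- *Blob segmentation.* Puncta occupy ~10⁻⁴ of the volume, which defeats
  histogram thresholds (intermeans and Otsu both converge inside the noise
  distribution), so the voxel threshold is noise-referenced: 5× the robust
  background σ (1.4826·MAD of the unclipped contrast volume).  Watershed
  seeds are maxima with prominence ≥ 3σ (h-maxima); seeds closer than the
  0.1-µm split diameter are merged so only genuinely separated maxima split
  an object.  "Quality" is the peak contrast intensity per blob; its lower
  automatic bound is an iterative-intermeans threshold over *all* seed
  heights (noise seeds included), which lands in the gap between noise
  maxima and genuine puncta instead of splitting the punctum population.
  Finally blobs outside 0.003–0.04 µm³ are dropped.  At the 5σ threshold the
  measured volume of a punctum is ~2.5–3× its half-maximum volume; the
  simulator's default true volumes (0.004–0.009 µm³) therefore measure near
  the center of the filter band.
- *Assignment and density.* A blob belongs to an axon iff the fraction of
  its voxels inside the surface is ≥ r_min.  The default r_min = 1.0 (fully
  inside) follows the strictest reading of an ambiguous published setting
  and is exposed as a flag.  Density = assigned count / skeleton length;
  density × length = count holds exactly; zero-length surfaces report
  missing values, never infinities.
- *Rotation null.* The punctum channel is rotated 180° in xy
  ((z, y, x) → (z, Y−1−y, X−1−x); optical sections are not flipped in z),
  the blob pipeline re-run against the unchanged surfaces, and both
  densities reported.  Genuine within-axon puncta lose density under
  rotation; uniformly scattered puncta do not (changes stay within counting
  error).

**Simulator.** Axons are constant-radius tubes (0.3 µm) along smooth random
polylines confined to disjoint y-bands, ~12 µm per axon in a
3.2 × 12.8 × 12.8 µm volume at (0.2, 0.05, 0.05) µm voxels — desk-scale
stand-ins for SIM subvolumes.  On-axon blob count is exactly
round(density × true length) with ≥ 0.4 µm arclength separation and small
radial jitter; blobs are isotropic Gaussians whose half-maximum volume
equals the drawn truth (PSF folded into the width); off-axon blobs are
uniform.  Noise is Gaussian with the blob amplitude set by the configured
SNR.  Not emulated: SIM reconstruction artifacts, axon branching and
varicosity structure, labeling heterogeneity, punctum clustering.

## Statistics

Two-sided tests throughout.  Pooled-variance and Welch (Satterthwaite df)
two-sample t-tests; both-groups-zero-variance with equal means returns
p = 1 by convention, with unequal means it is rejected as degenerate.
Individual-vs-group comparisons (one subject's 8 stimulations against the
pooled control stimulations) use Welch with Bonferroni correction by the
number of subjects compared (per-comparison α = 0.05/5 = 0.01 for five
mutants); pooling stimulations across control animals ignores subject
identity and is retained deliberately as design fidelity (it is
pseudoreplication in the formal sense).  The two-way ANOVA uses Type III
sums of squares with sum-to-zero coding — identical to the classical
balanced decomposition, well-defined when unbalanced — computed by
comparing residual SS of reduced least-squares fits; residuals below
1e-12 of total SS are treated as exactly zero (all-equal data reports
p = 1).  Šídák post-hoc compares the second factor's levels within each
level of the first, using the pooled error term, adjusted by
1 − (1−p)^m over all comparisons made.  The volcano filter flags
p < 0.05 AND |log2FC| > 0.58 (fold change > 2^0.58 ≈ 1.5); adjusted p
values are monotone (never below raw, capped at 1, Šídák ≤ Bonferroni).

## Problem sizes and determinism

All simulations consume a single seeded `numpy` generator per call;
identical configurations and seeds give bit-identical outputs, and the CLI
derives per-stage sub-seeds deterministically (CRC-based, not `hash()`).
The validation studies use desk-scale problem sizes chosen as the package's
own defaults: 100 replicates of the two-group photometry design (10 sessions
each), 50 axon volumes for density recovery, 50 + 20 volumes for the
rotation null, 10,000 null replicates for the type-I error study, 1,000
random tables for the ANOVA conservation check.  The acceptance script runs
reduced replicate counts (printed in its output as `n`) of the same studies.

## Known limitations

- The percentile-baseline offset biases raw evoked integrals additively;
  between-group ratios are compressed toward 1 at low SNR.  Comparisons are
  unaffected under the null; effect-size estimates are conservative.
- The Gaussian-baseline local contrast and the noise-referenced blob
  threshold are declared approximations of a proprietary pipeline; absolute
  blob volumes depend on the threshold level (≈2.5–3× half-maximum volume at
  5σ) even though counts and densities are robust to it.
- Skeleton length is biased a few percent low (end erosion by
  skeletonization, chain smoothing), partially offsetting blob-count
  deficits in density.
- r_min = 1.0 drops puncta that protrude a single voxel beyond the surface;
  at realistic SNR this costs a few percent of assignments (quantified by
  the recovery study).
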