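# Methods

This note documents the measurement models implemented in `pmequant`,
the choices made where the published procedures left room, and what the
synthetic benchmarks do and do not demonstrate.

## Background

After fertilization in *Drosophila*, the sperm contributes a single
giant mitochondrion — the mitochondrial derivative (MD) — running the
length of the flagellum, alongside the microtubule axoneme. The egg
eliminates the MD (paternal mitochondrial elimination, PME) while the
axoneme persists, via egg-derived multivesicular-body (MVB) vesicles
that ensheath the flagellum and an LC3-associated-phagocytosis-like
pathway (Atg8a recruitment). `pmequant` implements the image
quantifications used to measure this process: 2D MD-elimination
kinetics, 3D distance-shell statistics around the axoneme, a
membrane/axoneme volume ratio, vesicle-level colocalization with
envelope-based background, and the proteomics enrichment filter for the
MVB fraction — plus the statistical tests attached to each.

## Normalized MD intensity (2D kinetics)

Per frame, the egg is segmented from brightfield (a trainable
random-forest pixel classifier, or a user-supplied mask), eroded 15 px
to avoid boundary artifacts, and stray small segments dropped (default
cutoff: 5% of the largest segment's area — scale-free, since no
absolute number is published). The MD channel is background-subtracted
by a rolling ball (below) and thresholded at a fixed raw-camera-scale
cutoff, 1200 by default (250 for a second microscope dialect; image bit
depth is treated as 16-bit class, a configuration decision rather than
an established fact). The statistic is

    NMI = (mean MD-positive − mean MD-negative) × (MD-positive area / egg area)

with both means taken inside the egg mask after subtraction. Degenerate
cases are defined for continuity: no positive pixel ⇒ NMI = 0; no
negative pixel ⇒ the negative mean is 0. NMI is invariant to anything
outside the egg mask and scales linearly with above-background gain.

Per-egg NMI series over 0–3 h AEL are summarized by a least-squares fit
of `I0·exp(−k·t)`; a log-linear regression on the positive values seeds
the nonlinear fit, and a constant series maps to k = 0 exactly. Eggs
flagged as failing cellularization are excluded before group analysis
(staging is manual in practice; only a metadata flag is modeled).

## Rolling-ball background subtraction

The published pipeline describes "Rolling ball (sigma = 35 pixels)",
conflating a Gaussian width with a ball radius. We implement the
radius reading: background = grayscale morphological opening with a
flat disk of radius 35 px (peaks narrower than the disk survive;
plateaus wider than twice the radius are removed), with an optional
Gaussian pre-smooth for the sigma reading; both are configurable. The
test suite checks the opening against a brute-force min/max oracle at
the published radius.

## Distance shells (envelope analysis)

Shells are computed from the exact Euclidean distance transform between
voxel centers with anisotropic physical spacing; shell k covers
distances in ((k−1)·w, k·w], with K = 10 shells of w = 1 µm by default.
Reference voxels get shell 0; voxels beyond K·w are ignored. Shells
truncated at the image border are normalized by their truncated volume,
which avoids bias at egg margins. The Atg8a profile divides total
signal-object volume per shell (voxel-wise assignment — an object may
span shells) by shell volume.

The smallest-40% object filter removes floor(0.4·n) objects in
ascending volume order (ties broken by label order) and reports the
realized retained-volume fraction. The published description pairs the
count rule with an observed ~60% retained volume; the two statements
are not equivalent in general, so the count rule is primary and the
retained fraction is whatever the data give (e.g. 45/55 ≈ 0.82 on
volumes 1..10).

"Touching" for the membrane/axoneme ratio means within one voxel of the
axoneme (26-connectivity dilation); a physical distance in µm can be
configured instead, since no distance is published. The ratio is total
touching-membrane volume over axoneme volume.

The MD-proximal envelope measurement excludes a 0.5 µm guard shell,
takes the next 1 µm shell's mean as background, and reports
target mean − background mean.

## Vesicle colocalization

Primary-channel vesicles below 15 µm³ are discarded. Each vesicle gets
a 0.2 µm guard envelope (unmeasured) and a 0.3 µm background envelope
(the published text says "300 µm", which cannot fit inside an egg; we
read 300 nm, and the thickness is configurable). Voxels belonging to
any vesicle are never counted as background. The egg-level background
is the unweighted mean of per-vesicle background-envelope means. A
vesicle whose secondary mean falls below its own envelope is omitted;
among the rest, positive means background-subtracted secondary mean
> 0. The positive fraction is reported over non-omitted vesicles, with
all counts retained.

Pearson correlation is pooled at voxel level over all non-omitted
vesicle masks across eggs ("pulled" in the source material is read as
pooled; whether the original pooled vesicle voxels or whole images is
unstated — vesicle voxels is the implemented default). Manders M1 is
the fraction of primary intensity in voxels whose background-subtracted
secondary is positive; no Costes thresholding, since the envelope
background is the assay's stated background construct.

## Proteomics enrichment

Proteins with PSM < 10 are removed (10 is kept; the published "< 10
disregarded" is strict). log2FC = log2((I_mvb + ε)/(I_lysate + ε)) with
ε defaulting to half the smallest nonzero intensity — this avoids
infinities while preserving ranks; explicit ε (including 0) is
accepted. Enriched means log2FC > 1, strictly. Intensities are treated
as single summed values per protein (single-run acquisitions).

## Statistics

The two-way repeated-measures ANOVA is the classic split-plot
decomposition (between factor: group; within: time; subjects: eggs):
F_group = MS_group / MS_subjects-within-groups, F_time and
F_interaction over MS_error. No sphericity correction is applied by
default (none is mentioned in the source procedures). Šídák
(1 − (1 − p)^m) and step-down Holm–Šídák adjustments are closed-form.
Fisher's exact two-sided p sums hypergeometric probabilities of all
margin-consistent tables at most as probable as the observed one (with
the conventional 1e−7 relative tie tolerance). The unpaired t test is
pooled-variance Student by default (matching the named test), with
Welch behind a flag. Exact Dunnett quantiles are out of proportion to
their role here; a seeded Monte-Carlo many-to-one approximation is
provided, with Šídák as the documented default substitute.

## Synthetic scenes and what they show

The generator emulates geometry and intensity structure, not optics:

- **2D kinetics**: an elliptical textured egg; an MD tube around a
  cubic-spline flagellum with intensity background + I0·exp(−k·t);
  additive Gaussian noise. Defaults: 16-bit-class scale, I0 = 30000,
  background 200, noise sd 50, frames at 0,1,2,3 h AEL, k = 1 h⁻¹
  (0.1 h⁻¹ for "knockdown" scenes). I0 is chosen so the tube stays
  above the 1200 cutoff through 3 h at k = 1, as in usable recordings.
- **3D axoneme scenes**: a curved axoneme tube; puncta placed by
  sampling voxel centers weighted by the requested radial density
  evaluated on the exact axoneme distance map, so manifest distances
  and shell indices are exact by construction and the uniform-density
  radial law is a clean multinomial; a coaxial membrane tube with a
  configurable fill fraction (0.2 for cleared/control, 0.8 for
  knockdown scenes).
- **3D vesicle fields**: non-overlapping spheres placed on a jittered
  grid (placement cannot fail when the count fits), soft Gaussian
  radial intensity profiles, a small spectral bleed of the primary
  marker into the secondary channel (2% by default), and a per-vesicle
  Bernoulli positivity draw recorded exactly. The soft skirts of
  positive vesicles elevate the egg-level envelope background above the
  bleed level of negative vesicles, which is what makes negatives
  retained-but-negative — the same structure real two-channel
  acquisitions have.

Noise is additive Gaussian on the ideal signal (clipped at zero);
photon statistics and PSF are not modeled (an optional isotropic
Gaussian blur exists, off by default, because the measurement pipelines
never deconvolve). Scenes are desk-scale (≤ 256³ voxels); the real
~1.8 mm flagellum length is not emulated — the measurements exercise
the geometry class, not the scale. Segmentation in the synthetic
experiments uses Otsu thresholds plus a largest-component cleanup for
reference structures (the automated counterpart of the published manual
false-positive removal); passing benchmarks therefore demonstrates
correctness of the measurement code on known geometry, not segmentation
robustness on real microscope data.

## Numerical choices

- Axis order (z, y, x), 0-based; distances from voxel centers; exact
  EDT via `scipy.ndimage.distance_transform_edt` with physical
  sampling.
- Shell binning rounds distance/width to 9 decimals before the ceiling
  so exact shell-boundary distances land in the inner shell.
- Component labels are assigned (and re-densified after filtering) in
  raster-scan order of each component's first voxel, for determinism.
- Erosion keeps pixels strictly farther than the radius from the
  nearest background pixel (distance-transform formulation), making it
  anti-extensive and monotone by construction.
- All generators are deterministic for (params, seed); the manifest
  re-renders scenes bit-identically.
- Problem sizes in the study-scale experiments (cohorts of 20 eggs at
  128×176 px, vesicle fields of 200, 10⁴ puncta, 10⁴ null simulations)
  were chosen as the package's desk-scale operating points.

## Known limitations

- The pixel classifier is a single-pass random forest over a fixed
  multiscale feature bank; it stands in for, but does not reproduce,
  Ilastik's AutoContext or Arivis's classifier.
- Type-I calibration is verified for the group test and the t test;
  the time and interaction tests inherit whatever sphericity the data
  have (no Greenhouse–Geisser correction).
- The positivity estimator's behavior is validated on scenes whose
  negatives carry only bleed-through; real negatives with genuine dim
  secondary signal near the decision boundary will be noisier.
- Proprietary microscope formats are out of scope; only TIFF/OME-TIFF
  with physical-size metadata (or explicit spacing overrides) are read.
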