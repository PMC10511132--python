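# Methods

This note documents the models behind each pipeline stage, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Expansion QC

**Expansion factor.** Given paired pre/post-expansion length
measurements of the same cells (long axes), the factor is the *mean of
per-cell ratios*, not the ratio of means, with the SD of the ratios as
dispersion. The two differ under heterogeneous cell sizes; per-cell
ratios weight every cell equally and match how paired measurements are
plotted cell by cell.

**Shape descriptors.** Circularity 4πA/P², aspect ratio major/minor,
roundness 4A/(π·major²), solidity A/A_convex. On rasters, area is the
pixel count, the perimeter is the Crofton estimator (4 directions),
and axes come from the second-moment ellipse; a rasterization
tolerance of 5% is attached to the descriptor invariants because no
discrete perimeter estimator is exact. Regions touching the image
border are flagged (truncated geometry), as are regions under 5 px.

**Non-rigid registration.** The deformation between the post-expansion
image and the scaled pre-expansion image is modeled as a free-form
deformation on a cubic B-spline control grid (default node spacing
6–8 µm) and optimized coarse-to-fine (image pyramid with factor-2
shrinking; the control grid is fixed across levels) by L-BFGS-B
against a correlation metric, after histogram-matching the moving
image to the reference. Implementation rides on SimpleITK's
registration framework. The similarity reported is the Pearson
correlation of the reference with the warped moving image; values
below 0.2 signal registration failure. Convention: the field u maps
`reference(x) ≈ moving(x − u(x))`, with u in micrometres of
*biological* (pre-expansion) units, because post-expansion images
carry voxel sizes already divided by the expansion factor.

The field is well constrained only where the images have gradient
content; over empty background the B-spline extrapolates. Interior
RMS summaries therefore use a 10% edge margin, and content-masked
summaries (pixels above 30% of max intensity) are the better measure
on sparse fields.

**RMS length-measurement error.** For each measurement length L,
point pairs at separation L are sampled uniformly in position and
orientation inside the field's domain; each pair's error is
|‖p₁′ − p₂′‖ − L| after applying the field. The curve reports RMS, SD
and pair count per bin (default 500 pairs). Two exact identities pin
the implementation: the identity field gives zero error, and a
residual uniform scaling by (1+s) gives RMS(L) = s·L for every L.

## FISH spots

Detection is scale-normalized Laplacian-of-Gaussian filtering at the
PSF width, local maxima with non-maximum suppression at radius 2σ, and
a threshold of `threshold_sd` (default 5) robust background SDs (MAD ×
1.4826) of the band-pass response above its median — making the
detector invariant to positive intensity rescaling. Spot positions are
refined to subpixel by a local intensity-weighted centroid. Cell
assignment is a 2D label lookup; counts conserve: assigned +
unassigned = detected. Retention regression is unweighted OLS;
intensity comparisons use Welch's t-test (unequal variances,
two-sided).

## Axonal periodicity

A signal cluster is a contiguous run of samples strictly above
background mean + 5×SD (background statistics from metadata or the
profile's outer 5% flanks), reported at its intensity-weighted
centroid; runs shorter than 2 samples are discarded as single-sample
noise crossings. Segments qualify for periodicity analysis only with
strictly more than 10 clusters. Post-expansion traces are rescaled to
biological units by dividing positions by the expansion factor — an
exact operation that commutes with period estimation.

The period comes from the mean-subtracted, variance-normalized
autocorrelation (ACF(0) = 1) up to half the profile span. After light
Gaussian smoothing (σ = 1 sample) the ACF's positive local maxima with
prominence ≥ 0.05 are peaks; inter-peak distances are consecutive
differences of the first k+1 peak lags with lag 0 as the zeroth peak,
and P̄ is their mean. The default k = 3 (three inter-peak distances);
k = 4 is available by argument since averaging four adjacent peak
spacings is an equally defensible convention. With fewer than k peaks
the result is flagged insufficient rather than extrapolated. Peak
positions are quantized to the sampling interval; no subsample
interpolation is attempted, so the resolution floor is one sampling
step (20 nm effective by default).

Multi-peak Gaussian fitting (sum of Gaussians + constant baseline,
Levenberg–Marquardt with bounds) reports centers, amplitudes and
FWHM = 2√(2 ln 2)·σ; initial centers come from the most prominent
smoothed local maxima, and non-convergence withholds the fit.

## In situ sequencing decode

Stages, in order: (1) **round registration** — fiducial beads emit in
all four channels, so the across-channel minimum projection isolates
them; bead centroids (intensity-weighted, subpixel) are matched to
round 1 by nearest neighbour and the per-round shift is their mean
offset (translation-only; at least 3 matched beads required);
(2) **crosstalk correction** — per-pixel multiplication by the inverse
of the 4×4 crosstalk matrix (condition number capped at 10⁶),
negatives clipped with the clipped fraction reported; (3)
**segmentation** — LoG puncta on the channel-summed first round, with
aperture photometry (radius 2 px) per round and channel; puncta at
bead positions are excluded, and any punctum whose weakest channel
retains >50% of its strongest in *every* round is classified as a
fiducial rather than an amplicon; (4) **basecalling** — per-round
argmax channel, margin = top minus second intensity, exact ties broken
to the lowest channel index and flagged, all-zero rounds call 'N';
(5) **codebook matching** — exact match, else the unique codeword
within Hamming radius 1 (requiring radius < d_min/2 so correction is
unambiguous; 'N' mismatches everything); (6) **cell assignment** —
2D mask lookup, with unassigned or unmatched reads retained in the
read table but excluded from the count matrix.

The default codebook holds 87 genes with 7-base barcodes over
{A,C,G,T}, chosen greedily from a seeded stream under a pairwise
Hamming distance ≥ 3 constraint, which guarantees single-error
correction; channels map to bases in wavelength order C, A, T, G. The
actual production codebooks of targeted in situ sequencing panels are
not public, so this one is a synthetic stand-in with stated distance
properties.

## Clone classification

Cells with totals outside [50, 3000] (inclusive window; the rule
removes "less than 50 / more than 3000") are dropped. Counts are
scaled per cell by median-total/cell-total and log(1+x)-transformed
(the pseudo-count avoids zeros; log base is irrelevant downstream
since only orderings and loadings are used). The first principal
component of the centered table (SVD; sign oriented so the
largest-magnitude loading is positive, making the output
deterministic) nominates marker panels from its 15 most-positive and
15 most-negative loadings. Assignment is the marker-fraction rule:
fraction_x = summed panel-x counts / total counts; the cell takes the
argmax clone if that fraction ≥ 0.30, else Unclassified (ties are
Unclassified; the threshold applies to the winning fraction).
Dimension-reduction-plus-embedding visualizations are intentionally
not part of the classification path — the fraction rule is the
deterministic, implementable contract; UMAP remains available
externally for visualization only.

RGB composites map a gene-group fraction to a channel value
min(100, fraction × scaling × 100) (% of maximum; scaling 3.33 for the
DNA-repair and proliferation groups, 2.5 for EMT), so e.g. a 40% EMT
fraction saturates its channel. Channel values are invariant to
rescaling a cell's counts.

Cross-method agreement samples 2000 clone-labeled cells from one
labeling (Unclassified excluded from the draw) and reports the
fraction given the corresponding clone by the other method, per
direction; clone correspondence is established by maximal member
overlap, never by label strings.

## Synthetic data: what it emulates, and what it does not

Generators emulate the *statistical* structure the analyses rely on:
non-overlapping elliptical nuclei with analytic geometry and a smooth
multiplicative texture (so registration has features to grip);
expansion as uniform scaling composed with a smooth random
displacement field (low-resolution Gaussian grid, cubic-upsampled,
calibrated exactly to the requested RMS — matching the B-spline family
the estimator assumes); FISH spots as Poisson-per-cell Gaussian blobs
in the decrowded regime (pairwise separation ≥ 4 PSF widths, interior
placement) where one blob = one transcript holds; axonal profiles as
Gaussian rings on a constant background with optional center jitter;
sequencing stacks with per-round base errors (uniform wrong base with
stated probability), channel crosstalk, rigid round drift, all-channel
fiducials, and optional per-round amplicon dropout; and count matrices
with lognormal-Poisson totals and multinomial gene draws in which each
clone's own markers are enriched by a stated fold.

Not emulated: realistic optics beyond Gaussian PSFs, tissue
autofluorescence, hydrogel mechanics, segmentation errors, amplicon
brightness variation, phasing/pre-phasing in sequencing chemistry, or
doublets/ambient counts in the expression data. Passing tests
therefore demonstrate correctness of the *analysis* under the stated
noise models, not robustness to every artifact of real microscopy
data. Defaults for quantities no protocol states (spot amplitude and
background, texture amplitude, bead brightness) are plain arguments
with documented values, chosen once at magnitudes typical of confocal
data.

Problem sizes in the tests and the acceptance script (e.g. 128-px
pre-expansion fields for registration, 200 amplicons per sequencing
field, 2000-cell matrices, 40–50 profile replicates) were chosen as
the smallest sizes at which the statistical assertions have comfortable
power.

## Numerical choices and limitations

- Registration is 2D (max-projection regime); 3D non-rigid
  registration is out of scope.
- The distortion curve samples pairs Monte-Carlo style; n_pairs = 500
  per bin gives ~3% relative precision on the RMS, and the seed is an
  explicit argument.
- peak detection everywhere uses deterministic tie-breaks; every
  stochastic routine takes an integer seed and is bit-reproducible.
- Images are processed in floating point; 16-bit quantization happens
  only on TIFF write, and writing rejects data outside [0, 65535]
  rather than silently rescaling.
- The amplicon "merged" flag is a flux heuristic (round-1 aperture
  flux > 2× the median punctum flux); amplicons closer than the
  non-maximum-suppression radius genuinely collapse into one punctum
  and cannot be split without deconvolution.
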