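"""Expansion quality control: magnification, nuclear shape preservation,
and non-rigid distortion.

Three questions are answered here.  How much did the specimen expand
(``expansion_factor``: mean per-cell ratio of post- to pre-expansion
long-axis lengths)?  Did nuclear morphology survive (ImageJ-style shape
descriptors computed from per-label region geometry)?  And how
non-uniform was the expansion (a B-spline deformation field estimated
by non-rigid registration of the post-expansion image against the
scaled pre-expansion image, summarized as the RMS length-measurement
error as a function of measurement length)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage
from skimage import measure

from .types import (
    DeformationField,
    DistortionCurve,
    ImageVolume,
    RegistrationError,
    SegmentationMap,
)

#: Rasterization tolerance on descriptor invariants (fraction).
RASTER_TOL = 0.05


@dataclass
class RegionGeometry:
    """Geometry of one segmented region, in consistent physical units."""

    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    convex_area: float

    def __post_init__(self):
        if self.area <= 0 or self.perimeter <= 0:
            raise ValueError("area and perimeter must be positive")
        if self.minor_axis <= 0 or self.major_axis < self.minor_axis:
            raise ValueError("axes must satisfy major >= minor > 0")
        if self.convex_area < self.area * (1 - RASTER_TOL):
            raise ValueError("convex area cannot be smaller than area")


@dataclass
class ShapeDescriptors:
    """The four dimensionless ImageJ shape descriptors."""

    circularity: float
    aspect_ratio: float
    roundness: float
    solidity: float


def shape_descriptors(region: RegionGeometry) -> ShapeDescriptors:
    """Shape descriptors of a region.

    circularity = 4*pi*area / perimeter^2, aspect_ratio = major/minor,
    roundness = 4*area / (pi*major^2), solidity = area/convex_area.
    All four equal 1 for an ideal circle and are scale-invariant.
    """
    return ShapeDescriptors(
        circularity=4 * np.pi * region.area / region.perimeter**2,
        aspect_ratio=region.major_axis / region.minor_axis,
        roundness=4 * region.area / (np.pi * region.major_axis**2),
        solidity=region.area / region.convex_area,
    )


def measure_regions(seg: SegmentationMap, voxel_size: float = None) -> pd.DataFrame:
    """Per-label region geometry in physical units.

    Areas come from pixel counts, the perimeter from the Crofton
    estimator (4 directions), and the axes from the intensity-moment
    ellipse.  Labels touching the image border are flagged ``border``
    (geometry unreliable); single-pixel or axis-degenerate labels are
    flagged ``degenerate``.
    """
    px = float(voxel_size) if voxel_size is not None else seg.pixel_size
    if seg.labels.max() == 0:
        raise ValueError("segmentation contains no labels")
    H, W = seg.labels.shape
    rows = []
    for rp in measure.regionprops(seg.labels):
        minr, minc, maxr, maxc = rp.bbox
        border = minr == 0 or minc == 0 or maxr == H or maxc == W
        degenerate = rp.area < 5 or rp.axis_minor_length <= 0
        rows.append(
            dict(
                label=rp.label,
                area=rp.area * px**2,
                perimeter=rp.perimeter_crofton * px,
                major_axis=rp.axis_major_length * px,
                minor_axis=rp.axis_minor_length * px,
                convex_area=rp.area_convex * px**2,
                centroid_y=rp.centroid[0],
                centroid_x=rp.centroid[1],
                border=border,
                degenerate=degenerate,
            )
        )
    return pd.DataFrame(rows).set_index("label")


class ExpansionFactor(NamedTuple):
    factor: float
    sd: float
    n: int


def expansion_factor(paired_lengths) -> ExpansionFactor:
    """Linear expansion factor from paired pre/post length measurements.

    The factor is the mean over cells of the post/pre length ratio (not
    the ratio of means), with the SD of the per-cell ratios as the
    dispersion.
    """
    pairs = np.asarray(paired_lengths, dtype=float).reshape(-1, 2)
    if len(pairs) < 1:
        raise ValueError("need at least one (pre, post) pair")
    if np.any(pairs <= 0):
        raise ValueError("lengths must be positive")
    ratios = pairs[:, 1] / pairs[:, 0]
    return ExpansionFactor(
        float(ratios.mean()), float(ratios.std(ddof=0)), len(ratios)
    )


# ---------------------------------------------------------------------------
# non-rigid registration


def scale_to_reference(pre: ImageVolume, factor: float, shape: tuple) -> ImageVolume:
    """Resample a pre-expansion image onto the post-expansion pixel grid
    under the measured uniform expansion factor (the rigid part of the
    mapping, leaving only non-uniformities for the registration)."""
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    scaled = ndimage.map_coordinates(
        pre.data, [yy / factor, xx / factor], order=3, mode="nearest"
    )
    return ImageVolume(
        np.clip(scaled, 0, None),
        pre.pixel_size / factor,
        expansion_state="pre",
    )


def register_nonrigid(
    reference: ImageVolume,
    moving: ImageVolume,
    grid_spacing: float = 8.0,
    levels: int = 3,
    *,
    iterations: int = 80,
    min_similarity: float = 0.2,
):
    """Estimate the smooth deformation relating two co-magnified images.

    A free-form deformation on a cubic B-spline control grid (node
    spacing ``grid_spacing`` micrometres) is optimized coarse-to-fine
    over ``levels`` resolution levels, maximizing correlation after
    histogram matching of the moving image to the reference.  The
    moving image must already be scaled to the reference's nominal
    magnification (see :func:`scale_to_reference`).

    Returns ``(DeformationField, similarity)`` where the field follows
    the convention ``reference(x) ≈ moving(x - u(x))`` (displacements in
    micrometres, sampled densely per pixel) and ``similarity`` is the
    Pearson correlation between the reference and the warped moving
    image.  A similarity below ``min_similarity`` raises
    :class:`RegistrationError`.
    """
    if reference.data.ndim != 2 or moving.data.ndim != 2:
        raise ValueError("registration operates on 2D images")
    px = reference.pixel_size
    fixed = sitk.GetImageFromArray(reference.data.astype(np.float64))
    fixed.SetSpacing((px, px))
    mov = sitk.GetImageFromArray(moving.data.astype(np.float64))
    mov.SetSpacing((moving.pixel_size, moving.pixel_size))

    matcher = sitk.HistogramMatchingImageFilter()
    matcher.SetNumberOfHistogramLevels(256)
    matcher.SetNumberOfMatchPoints(16)
    matcher.ThresholdAtMeanIntensityOn()
    mov = matcher.Execute(mov, fixed)

    extent = [sz * sp for sz, sp in zip(fixed.GetSize(), fixed.GetSpacing())]
    mesh = [max(2, int(round(e / grid_spacing))) for e in extent]
    tx = sitk.BSplineTransformInitializer(fixed, mesh, order=3)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=iterations,
        maximumNumberOfCorrections=5,
    )
    levels = max(1, int(levels))
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    smooth = [max(0.0, s / 2.0) for s in shrink]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(smooth)
    # fixed control grid across levels; coarse-to-fine acts on the images
    reg.SetInitialTransform(tx, inPlace=True)
    reg.Execute(fixed, mov)

    to_field = sitk.TransformToDisplacementFieldFilter()
    to_field.SetReferenceImage(fixed)
    disp = sitk.GetArrayFromImage(to_field.Execute(tx))  # (H, W, (dx, dy))
    # sitk's field D maps fixed physical point p to moving point p + D(p);
    # under reference(x) = moving(x - u(x)) that means u = -D.
    u = np.stack([-disp[..., 1], -disp[..., 0]])
    field = DeformationField(u, pixel_size=px, shape=reference.data.shape)

    resampler = sitk.ResampleImageFilter()
    resampler.SetReferenceImage(fixed)
    resampler.SetInterpolator(sitk.sitkLinear)
    resampler.SetTransform(tx)
    warped = sitk.GetArrayFromImage(resampler.Execute(mov))
    a = reference.data.ravel() - reference.data.mean()
    b = warped.ravel() - warped.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    similarity = float(a @ b / denom) if denom > 0 else 0.0
    if similarity < min_similarity:
        raise RegistrationError(
            f"similarity {similarity:.3f} below floor {min_similarity}"
        )
    return field, similarity


# ---------------------------------------------------------------------------
# distortion curves


def rms_length_error(
    field: DeformationField,
    lengths,
    n_pairs: int = 500,
    seed: int = 0,
) -> DistortionCurve:
    """RMS length-measurement error versus measurement length.

    For each measurement length L, ``n_pairs`` point pairs at separation
    L (random positions and orientations inside the field's domain) are
    measured after applying the deformation; the error of one pair is
    ``| |p1' - p2'| - L |``.  Lengths exceeding the domain are omitted
    with a warning.  The identity field gives exactly zero; a uniform
    residual scaling by (1+s) gives RMS(L) = s*L.
    """
    rng = np.random.default_rng(seed)
    H, W = field.shape
    px = field.pixel_size
    out_L, out_rms, out_sd, out_n = [], [], [], []
    for L in np.asarray(lengths, dtype=float):
        L_px = L / px
        if L_px > np.hypot(H - 1, W - 1):
            warnings.warn(f"length {L} exceeds field domain; bin omitted")
            continue
        p1s = np.empty((n_pairs, 2))
        p2s = np.empty((n_pairs, 2))
        filled = 0
        while filled < n_pairs:
            m = (n_pairs - filled) * 2
            p1 = rng.uniform([0, 0], [H - 1, W - 1], size=(m, 2))
            ang = rng.uniform(0, 2 * np.pi, m)
            p2 = p1 + L_px * np.stack([np.sin(ang), np.cos(ang)], axis=1)
            ok = (
                (p2[:, 0] >= 0)
                & (p2[:, 0] <= H - 1)
                & (p2[:, 1] >= 0)
                & (p2[:, 1] <= W - 1)
            )
            take = min(ok.sum(), n_pairs - filled)
            p1s[filled : filled + take] = p1[ok][:take]
            p2s[filled : filled + take] = p2[ok][:take]
            filled += take
        d_after = np.linalg.norm(field.apply(p1s) - field.apply(p2s), axis=1)
        err = np.abs(d_after - L)
        out_L.append(L)
        out_rms.append(float(np.sqrt(np.mean(err**2))))
        out_sd.append(float(err.std(ddof=0)))
        out_n.append(n_pairs)
    return DistortionCurve(
        np.array(out_L), np.array(out_rms), np.array(out_sd), np.array(out_n)
    )
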