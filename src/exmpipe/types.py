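"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Arrays are indexed ``(y, x)`` (2D) or ``(z, y, x)`` (3D); multi-round
  sequencing stacks are ``(round, channel, y, x)``.
* Pixel indices are 0-based with the origin at the center of the first
  pixel.  Physical units are micrometres unless a field says otherwise.
* Post-expansion images carry a ``voxel_size`` already calibrated back to
  pre-expansion (biological) units, so downstream distances are always in
  biological micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator


class PlacementError(RuntimeError):
    """Raised when synthetic objects cannot be placed in the field."""


class RegistrationError(RuntimeError):
    """Raised when image registration cannot be carried out reliably."""


@dataclass
class ImageVolume:
    """A calibrated intensity image with expansion-state metadata.

    Parameters
    ----------
    data:
        Non-negative float array, ``(y, x)`` or ``(z, y, x)``.
    voxel_size:
        Micrometres per pixel along each axis of ``data`` (biological,
        i.e. pre-expansion equivalent units).
    expansion_state:
        ``"pre"`` or ``"post"``.
    expansion_factor:
        Linear expansion factor, if known. Recorded for ``post`` images.
    """

    data: np.ndarray
    voxel_size: tuple
    expansion_state: str = "pre"
    expansion_factor: Optional[float] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * self.data.ndim
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.data.ndim:
            raise ValueError("voxel_size must match image dimensionality")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.expansion_state not in ("pre", "post"):
            raise ValueError("expansion_state must be 'pre' or 'post'")

    @property
    def pixel_size(self) -> float:
        """In-plane (y/x) pixel size; requires isotropic y/x sampling."""
        return self.voxel_size[-1]


@dataclass
class SegmentationMap:
    """Labeled 2D mask: 0 is background, positive integers are cells."""

    labels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("segmentation must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class DeformationField:
    """Dense 2D displacement field sampled on a regular pixel grid.

    ``displacement[0]`` is the y-component and ``displacement[1]`` the
    x-component, in micrometres, sampled every ``grid_spacing`` pixels
    starting at pixel 0.  The field maps a point ``p`` (pixels) in its
    own frame to the physically displaced position
    ``p * pixel_size + u(p)`` (micrometres).
    """

    displacement: np.ndarray  # (2, ny, nx), micrometres
    pixel_size: float  # micrometres per pixel of the underlying image
    grid_spacing: float = 1.0  # pixels between field samples
    shape: Optional[tuple] = None  # underlying image shape (H, W)
    _interp: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 3 or self.displacement.shape[0] != 2:
            raise ValueError("displacement must have shape (2, ny, nx)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacements must be finite")
        if self.shape is None:
            ny, nx = self.displacement.shape[1:]
            self.shape = (
                int((ny - 1) * self.grid_spacing) + 1,
                int((nx - 1) * self.grid_spacing) + 1,
            )

    def _interpolators(self):
        if self._interp is None:
            ny, nx = self.displacement.shape[1:]
            ys = np.arange(ny) * self.grid_spacing
            xs = np.arange(nx) * self.grid_spacing
            object.__setattr__(
                self,
                "_interp",
                tuple(
                    RegularGridInterpolator(
                        (ys, xs), comp, bounds_error=False, fill_value=None
                    )
                    for comp in self.displacement
                ),
            )
        return self._interp

    def evaluate(self, points_px: np.ndarray) -> np.ndarray:
        """Displacement (micrometres) at ``(y, x)`` pixel positions, (N, 2)."""
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        fy, fx = self._interpolators()
        return np.stack([fy(pts), fx(pts)], axis=-1)

    def apply(self, points_px: np.ndarray) -> np.ndarray:
        """Physical positions (micrometres) of displaced points, (N, 2)."""
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        return pts * self.pixel_size + self.evaluate(pts)

    def rms(self, margin: float = 0.0) -> float:
        """RMS displacement magnitude (micrometres), optionally on an
        interior crop excluding a fractional ``margin`` on every edge."""
        u = self.displacement
        if margin > 0:
            ny, nx = u.shape[1:]
            my, mx = int(round(ny * margin)), int(round(nx * margin))
            u = u[:, my : ny - my, mx : nx - mx]
        return float(np.sqrt(np.mean(u[0] ** 2 + u[1] ** 2)))


@dataclass
class DistortionCurve:
    """RMS length-measurement error as a function of measurement length."""

    lengths: np.ndarray  # micrometres, strictly increasing
    rms_error: np.ndarray  # micrometres
    sd: np.ndarray  # micrometres
    n_pairs: np.ndarray  # pairs per bin

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.rms_error = np.asarray(self.rms_error, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lengths) <= 0):
            raise ValueError("lengths must be strictly increasing")
        if np.any(self.rms_error < 0):
            raise ValueError("rms_error must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth attached to every synthetic dataset."""

    scenario_name: str
    seed: int
    parameters: dict
    truth_tables: dict = field(default_factory=dict)
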