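"""Readers and writers for the pipeline's interchange formats.

Images travel as 16-bit TIFF with a JSON metadata block (voxel size,
expansion state and factor) in the image description; codebooks as
JSON; tables as CSV via pandas; deformation fields as a JSON header
plus a ``.npy`` grid.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .exseq import Codebook
from .types import DeformationField, ImageVolume


def write_image(path, volume: ImageVolume) -> None:
    """Write an :class:`ImageVolume` as 16-bit TIFF.

    Intensities are rounded to integers and must fit the 16-bit range;
    pre-scale to [0, 65535] before writing.  Voxel size and expansion
    metadata round-trip through the image description.
    """
    data = np.asarray(volume.data)
    if data.max() > 65535 or data.min() < 0:
        raise ValueError(
            "intensities outside the 16-bit range; rescale before writing"
        )
    tifffile.imwrite(
        str(path),
        np.round(data).astype(np.uint16),
        metadata=dict(
            voxel_size_um=list(volume.voxel_size),
            expansion_state=volume.expansion_state,
            expansion_factor=volume.expansion_factor,
        ),
    )


def read_image(path) -> ImageVolume:
    """Read a TIFF written by :func:`write_image` (or any 8/16-bit TIFF;
    missing metadata falls back to 1 um voxels with a warning)."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = None
        if tif.shaped_metadata:
            meta = tif.shaped_metadata[0]
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(
            f"unsupported bit depth: {data.dtype.itemsize * 8}-bit "
            f"({data.dtype.name}); expected 8- or 16-bit unsigned"
        )
    if meta and "voxel_size_um" in meta:
        voxel = tuple(meta["voxel_size_um"])
        state = meta.get("expansion_state", "pre")
        factor = meta.get("expansion_factor")
    else:
        warnings.warn(f"{path}: no voxel-size metadata; assuming 1 um/px")
        voxel, state, factor = (1.0,) * data.ndim, "pre", None
    return ImageVolume(
        data.astype(float), voxel, expansion_state=state, expansion_factor=factor
    )


def write_codebook(path, codebook: Codebook) -> None:
    payload = dict(
        genes=codebook.barcodes,
        channel_to_base={str(c): b for c, b in codebook.channel_to_base.items()},
        alphabet="ACGT",
    )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_codebook(path) -> Codebook:
    """Load and validate a codebook JSON ({"genes": {gene: barcode},
    "channel_to_base": {...}}); lowercase bases are normalized, and
    duplicate/ragged/invalid barcodes are rejected."""
    payload = json.loads(Path(path).read_text())
    if "genes" not in payload:
        raise ValueError("codebook JSON must contain a 'genes' mapping")
    channel_to_base = payload.get(
        "channel_to_base", {"0": "C", "1": "A", "2": "T", "3": "G"}
    )
    return Codebook(
        barcodes=payload["genes"],
        channel_to_base={int(c): b for c, b in channel_to_base.items()},
    )


def write_deformation_field(path_prefix, field: DeformationField) -> None:
    """Write a field as ``<prefix>.json`` (header) + ``<prefix>.npy``."""
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), field.displacement)
    prefix.with_suffix(".json").write_text(
        json.dumps(
            dict(
                pixel_size_um=field.pixel_size,
                grid_spacing_px=field.grid_spacing,
                image_shape=list(field.shape),
                displacement_units="um",
                grid_file=prefix.with_suffix(".npy").name,
            ),
            indent=1,
        )
    )


def read_deformation_field(path_prefix) -> DeformationField:
    prefix = Path(path_prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    displacement = np.load(prefix.parent / header["grid_file"])
    return DeformationField(
        displacement,
        pixel_size=header["pixel_size_um"],
        grid_spacing=header["grid_spacing_px"],
        shape=tuple(header["image_shape"]),
    )
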