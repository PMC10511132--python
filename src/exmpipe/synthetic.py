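"""Synthetic data generators with attached ground truth.

Every generator emulates one class of input the analysis pipeline
consumes — paired pre/post-expansion cell fields, diffraction-limited
FISH spots, periodic axonal intensity profiles, multi-round 4-channel
in situ sequencing stacks, and two-clone cell-by-gene count matrices —
and returns a :class:`~exmpipe.types.SyntheticTruth` holding everything
needed to score the downstream analysis without re-reading the images.

All randomness flows from an integer seed through ``numpy.random
.default_rng``; identical seeds and parameters give bit-identical
output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .exseq import Codebook
from .periodicity import AxonProfile
from .types import ImageVolume, PlacementError, SegmentationMap, SyntheticTruth

# Marker-gene panels for the two transcriptionally distinct tumor clones
# of the SA501 breast-cancer PDX model (15 genes each, bulk RNA-seq
# derived), plus filler genes to complete an 87-gene panel.
MARKERS_CLONE_ZNF24 = [
    "RNF146", "DDX24", "OAZ2", "ZNF24", "TXNL1", "IDH2", "SEPT4", "CDCA7",
    "CP", "RAD21", "WDR61", "RBP1", "COX5A", "HSPE1", "IER3IP1",
]
MARKERS_CLONE_XIST = [
    "XIST", "CD44", "FBXO32", "LGALS1", "ARC", "HLA-A", "HLA-C", "S100A11",
    "CTSV", "SLC25A6", "ANXA1", "ARHGDIB", "SQLE", "B2M", "NDUFS5",
]
BACKGROUND_GENES = [f"GENE{i:03d}" for i in range(1, 58)]

#: Emission channel -> sequencing base, ordered by detection wavelength
#: (longest first): C, A, T, G.
CHANNEL_TO_BASE = {0: "C", 1: "A", 2: "T", 3: "G"}


# ---------------------------------------------------------------------------
# cell fields


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's second approximation; exact enough for rasterized truth
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def gen_cell_images(
    n_cells: int,
    field_size: int = 512,
    seed: int = 0,
    *,
    pixel_size: float = 0.4,
    radius_range: tuple = (10.0, 20.0),
    axis_ratio_range: tuple = (1.0, 2.0),
    amplitude: float = 1.0,
    texture_amp: float = 0.4,
    texture_scale: float = 3.0,
    noise_sd: float = 0.02,
    max_tries: int = 2000,
):
    """Render a field of non-overlapping elliptical nuclei.

    Nuclei are filled ellipses with minor semi-axis drawn uniformly from
    ``radius_range`` (pixels) and major/minor axis ratio uniform in
    ``axis_ratio_range``; a smooth multiplicative intracellular texture
    emulates cytoskeletal staining so the images carry registrable
    features.  Gaussian background noise of SD ``noise_sd`` is added.

    Returns ``(ImageVolume, SegmentationMap, SyntheticTruth)``; the truth
    table records analytic center, axes, orientation, area and perimeter
    per nucleus.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (int(field_size), int(field_size))
    labels = np.zeros(shape, dtype=np.int32)
    img = np.zeros(shape, dtype=float)
    rows = []
    placed = []  # (cy, cx, major_semi)
    for label in range(1, n_cells + 1):
        b = rng.uniform(*radius_range)
        ratio = rng.uniform(*axis_ratio_range)
        a = b * ratio
        theta = rng.uniform(0, np.pi)
        if a + 2 >= field_size - a - 2:
            raise PlacementError(
                f"cell {label} (major semi-axis {a:.1f} px) does not fit a "
                f"{field_size}x{field_size} field"
            )
        ok = False
        for _ in range(max_tries):
            cy = rng.uniform(a + 2, field_size - a - 2)
            cx = rng.uniform(a + 2, field_size - a - 2)
            if all(np.hypot(cy - py, cx - px) > a + pa + 2 for py, px, pa in placed):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place cell {label} of {n_cells} in a "
                f"{field_size}x{field_size} field"
            )
        placed.append((cy, cx, a))
        rr, cc = draw_ellipse(cy, cx, b, a, rotation=theta, shape=shape)
        labels[rr, cc] = label
        rows.append(
            dict(
                label=label,
                center_y=cy,
                center_x=cx,
                major_px=2 * a,
                minor_px=2 * b,
                axis_ratio=ratio,
                orientation=theta,
                area_px2=np.pi * a * b,
                perimeter_px=_ellipse_perimeter(a, b),
            )
        )
    mask = labels > 0
    body = ndimage.gaussian_filter(mask.astype(float), 1.0)
    if texture_amp > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(shape), texture_scale)
        tex /= max(tex.std(), 1e-12)
        body = body * (1.0 + texture_amp * tex)
    img = amplitude * np.clip(body, 0, None)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, shape)
    img = np.clip(img, 0, None)
    cells = pd.DataFrame(rows)
    truth = SyntheticTruth(
        scenario_name="cell-field",
        seed=seed,
        parameters=dict(
            n_cells=n_cells,
            field_size=field_size,
            pixel_size_um=pixel_size,
            radius_range_px=tuple(radius_range),
            axis_ratio_range=tuple(axis_ratio_range),
            noise_sd=noise_sd,
        ),
        truth_tables=dict(cells=cells),
    )
    vol = ImageVolume(img, pixel_size, expansion_state="pre")
    return vol, SegmentationMap(labels, pixel_size), truth


# ---------------------------------------------------------------------------
# expansion pairs


def smooth_displacement_field(
    shape: tuple, rms_um: float, smoothness_px: float, rng
) -> np.ndarray:
    """Smooth random 2D displacement field of requested RMS magnitude.

    Built from a low-resolution Gaussian random grid (node spacing
    ``smoothness_px``) upsampled by cubic interpolation, then calibrated
    so that sqrt(mean(|u|^2)) equals ``rms_um`` exactly.
    """
    if rms_um == 0:
        return np.zeros((2,) + tuple(shape))
    spacing = max(2.0, float(smoothness_px))
    coarse_shape = tuple(int(np.ceil(s / spacing)) + 3 for s in shape)
    comps = []
    for _ in range(2):
        coarse = rng.standard_normal(coarse_shape)
        dense = ndimage.zoom(coarse, spacing, order=3, grid_mode=False)
        comps.append(dense[: shape[0], : shape[1]])
    u = np.stack(comps)
    cur = np.sqrt(np.mean(u[0] ** 2 + u[1] ** 2))
    return u * (rms_um / max(cur, 1e-12))


def gen_expansion_pair(
    pre: ImageVolume,
    factor: float,
    distortion_amp: float = 0.0,
    smoothness: float = 5.0,
    seed: int = 0,
):
    """Expanded copy of ``pre`` under uniform scaling plus smooth distortion.

    The post image is the pre image resampled under linear magnification
    ``factor`` composed with a smooth random residual displacement field
    of RMS magnitude ``distortion_amp`` (micrometres, biological units)
    and correlation length ``smoothness`` (micrometres).  The post
    image's ``voxel_size`` is calibrated back to biological units
    (pre voxel size / factor), so distances measured on it are directly
    comparable with the pre image.

    Returns ``(post ImageVolume, true DeformationField, SyntheticTruth)``;
    the field lives in post-image pixel coordinates and micrometre
    displacements, with the convention ``post(x) = scaled_pre(x - u(x))``.
    """
    from .types import DeformationField

    if factor <= 1:
        raise ValueError("expansion factor must exceed 1")
    if distortion_amp < 0:
        raise ValueError("distortion_amp must be non-negative")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if pre.data.ndim != 2:
        raise ValueError("expansion pairs are generated from 2D images")
    rng = np.random.default_rng(seed)
    post_px = pre.pixel_size / factor
    post_shape = tuple(int(round(s * factor)) for s in pre.data.shape)
    u_um = smooth_displacement_field(
        post_shape, distortion_amp, smoothness / post_px, rng
    )
    u_px = u_um / post_px
    yy, xx = np.meshgrid(
        np.arange(post_shape[0]), np.arange(post_shape[1]), indexing="ij"
    )
    src_y = (yy - u_px[0]) / factor
    src_x = (xx - u_px[1]) / factor
    post = ndimage.map_coordinates(
        pre.data, [src_y, src_x], order=3, mode="nearest"
    )
    post = np.clip(post, 0, None)
    field = DeformationField(u_um, pixel_size=post_px, shape=post_shape)
    truth = SyntheticTruth(
        scenario_name="expansion-pair",
        seed=seed,
        parameters=dict(
            factor=factor,
            distortion_amp_um=distortion_amp,
            smoothness_um=smoothness,
            post_pixel_size_um=post_px,
        ),
        truth_tables=dict(true_field=field),
    )
    vol = ImageVolume(
        post, post_px, expansion_state="post", expansion_factor=factor
    )
    return vol, field, truth


# ---------------------------------------------------------------------------
# FISH spots


def gen_fish_spots(
    seg: SegmentationMap,
    mean_spots_per_cell: float,
    psf_sigma: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    amplitude: float = 1.0,
    background: float = 0.1,
    min_sep_factor: float = 4.0,
    edge_margin_px: int = 2,
    max_tries: int = 1000,
):
    """Poisson-distributed diffraction-limited spots inside segmented cells.

    Per-cell counts are Poisson(``mean_spots_per_cell``); each spot is an
    isotropic Gaussian blob of width ``psf_sigma``, placed in the cell
    interior (``edge_margin_px`` inside the boundary) at least
    ``min_sep_factor * psf_sigma`` pixels from every other spot — the
    decrowded, post-expansion regime, where every transcript stays an
    individually resolvable blob.  Cells too small to hold their drawn
    count at that separation get a reduced count, flagged in the truth
    table.
    """
    if mean_spots_per_cell <= 0:
        raise ValueError("spot rate must be positive")
    rng = np.random.default_rng(seed)
    shape = seg.labels.shape
    img = np.full(shape, float(background))
    min_sep = min_sep_factor * psf_sigma
    rows = []
    for label in seg.label_ids:
        interior = ndimage.binary_erosion(
            seg.labels == label, iterations=edge_margin_px
        )
        if not interior.any():
            interior = seg.labels == label
        ys, xs = np.nonzero(interior)
        n_target = rng.poisson(mean_spots_per_cell)
        pts = []
        truncated = False
        for _ in range(int(n_target)):
            ok = False
            for _ in range(max_tries):
                i = rng.integers(len(ys))
                y = ys[i] + rng.uniform(-0.5, 0.5)
                x = xs[i] + rng.uniform(-0.5, 0.5)
                if all(np.hypot(y - py, x - px) >= min_sep for py, px in pts):
                    ok = True
                    break
            if not ok:
                truncated = True
                break
            pts.append((y, x))
        for y, x in pts:
            rows.append(
                dict(
                    y=y,
                    x=x,
                    cell_id=int(label),
                    amplitude=amplitude,
                    truncated=truncated,
                )
            )
        if truncated:
            for r in rows:
                if r["cell_id"] == int(label):
                    r["truncated"] = True
    spots = pd.DataFrame(
        rows, columns=["y", "x", "cell_id", "amplitude", "truncated"]
    )
    _render_gaussians(
        img, spots[["y", "x"]].to_numpy().reshape(-1, 2), amplitude, psf_sigma
    )
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, shape)
    img = np.clip(img, 0, None)
    truth = SyntheticTruth(
        scenario_name="fish-spots",
        seed=seed,
        parameters=dict(
            mean_spots_per_cell=mean_spots_per_cell,
            psf_sigma_px=psf_sigma,
            noise_sd=noise_sd,
            amplitude=amplitude,
            background=background,
        ),
        truth_tables=dict(spots=spots),
    )
    return ImageVolume(img, seg.pixel_size), truth


def _render_gaussians(img, positions, amplitude, sigma):
    half = int(np.ceil(4 * sigma))
    H, W = img.shape
    for y, x in positions:
        y0, y1 = max(0, int(y) - half), min(H, int(y) + half + 1)
        x0, x1 = max(0, int(x) - half), min(W, int(x) + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
        )


# ---------------------------------------------------------------------------
# axonal profiles


def gen_axon_profile(
    period_nm: float = 190.0,
    n_rings: int = 15,
    amplitude: float = 1.0,
    background: float = 0.2,
    noise_sd: float = 0.05,
    expansion_factor: float = 4.2,
    sampling_nm: float = 20.0,
    seed: int = 0,
    *,
    ring_sigma_nm: float = 30.0,
    jitter_sd_nm: float = 0.0,
):
    """1D axonal intensity profile with periodic spectrin-like rings.

    ``period_nm``, ``ring_sigma_nm``, ``jitter_sd_nm`` and ``sampling_nm``
    are all in pre-expansion (biological) nanometres; the profile's
    ``positions`` are physical post-expansion nanometres, i.e. everything
    is stretched by ``expansion_factor``.  ``sampling_nm`` is the
    effective (pre-expansion-equivalent) sample spacing and must resolve
    the period (``< period_nm / 4``).
    """
    if n_rings < 3:
        raise ValueError("need at least 3 rings")
    if sampling_nm >= period_nm / 4:
        raise ValueError("sampling too coarse to resolve the period")
    if expansion_factor < 1:
        raise ValueError("expansion_factor must be >= 1")
    rng = np.random.default_rng(seed)
    pad = 2 * period_nm
    length_pre = (n_rings - 1) * period_nm + 2 * pad
    n_samples = int(np.round(length_pre / sampling_nm)) + 1
    positions_pre = np.arange(n_samples) * sampling_nm
    centers_pre = pad + np.arange(n_rings) * period_nm
    if jitter_sd_nm > 0:
        centers_pre = centers_pre + rng.normal(0, jitter_sd_nm, n_rings)
    intensity = np.full(n_samples, float(background))
    for c in centers_pre:
        intensity += amplitude * np.exp(
            -((positions_pre - c) ** 2) / (2 * ring_sigma_nm**2)
        )
    if noise_sd > 0:
        intensity = intensity + rng.normal(0, noise_sd, n_samples)
    intensity = np.clip(intensity, 0, None)
    profile = AxonProfile(
        positions=positions_pre * expansion_factor,
        intensities=intensity,
        expansion_factor=expansion_factor,
        background_mean=background,
        background_sd=noise_sd if noise_sd > 0 else None,
    )
    truth = SyntheticTruth(
        scenario_name="axon-profile",
        seed=seed,
        parameters=dict(
            period_nm=period_nm,
            n_rings=n_rings,
            amplitude=amplitude,
            background=background,
            noise_sd=noise_sd,
            expansion_factor=expansion_factor,
            sampling_nm=sampling_nm,
            ring_sigma_nm=ring_sigma_nm,
            jitter_sd_nm=jitter_sd_nm,
        ),
        truth_tables=dict(ring_centers_nm=centers_pre, period_nm=period_nm),
    )
    return profile, truth


# ---------------------------------------------------------------------------
# in situ sequencing stacks


def default_codebook(
    n_genes: int = 87, length: int = 7, min_distance: int = 3, seed: int = 2023
) -> Codebook:
    """87-gene, 7-base codebook with pairwise Hamming distance >= 3.

    Barcodes are chosen greedily from a seeded random stream, giving a
    deterministic code with single-error correction capacity.  Gene names
    are the two 15-gene clone marker panels plus numbered filler genes.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    words = []
    while len(words) < n_genes:
        cand = "".join(bases[rng.integers(0, 4, length)])
        if all(
            sum(a != b for a, b in zip(cand, w)) >= min_distance for w in words
        ):
            words.append(cand)
    genes = (MARKERS_CLONE_ZNF24 + MARKERS_CLONE_XIST + BACKGROUND_GENES)[
        :n_genes
    ]
    if len(genes) < n_genes:
        genes += [f"GENE{i:03d}" for i in range(58, 58 + n_genes - len(genes))]
    return Codebook(
        barcodes=dict(zip(genes, words)), channel_to_base=dict(CHANNEL_TO_BASE)
    )


def gen_exseq_stacks(
    codebook: Codebook,
    n_amplicons: int = 200,
    crosstalk: np.ndarray = None,
    base_error_rate: float = 0.0,
    drift_px: float = 0.0,
    n_fiducials: int = 4,
    seed: int = 0,
    *,
    field_size: int = 288,
    n_cells: int = 8,
    psf_sigma: float = 1.2,
    amplitude: float = 1000.0,
    fiducial_amplitude: float = 4000.0,
    noise_sd: float = 0.0,
    dropout_rate: float = 0.0,
    min_sep: float = 6.0,
    pixel_size: float = 0.3,
):
    """Multi-round 4-channel stacks of barcoded amplicons plus fiducials.

    Each amplicon carries a codebook gene; in every round it emits into
    the channel of its barcode's base at that position (with probability
    ``base_error_rate`` a uniformly chosen wrong base is emitted
    instead), channels are then mixed by the ``crosstalk`` matrix.
    Rounds after the first are offset by a random rigid drift of
    magnitude at most ``drift_px``.  Fiducial beads appear in all four
    channels in every round.  ``dropout_rate`` removes an amplicon from
    a round entirely (used to emulate round-to-round detection loss).

    Returns ``(stacks, SegmentationMap, SyntheticTruth)`` where
    ``stacks`` has shape ``(n_rounds, 4, H, W)``.
    """
    if len(codebook.barcodes) == 0:
        raise ValueError("codebook is empty")
    if not 0 <= base_error_rate < 1:
        raise ValueError("base_error_rate must be in [0, 1)")
    crosstalk = np.eye(4) if crosstalk is None else np.asarray(crosstalk, float)
    if crosstalk.shape != (4, 4) or np.any(crosstalk < 0):
        raise ValueError("crosstalk must be a nonnegative 4x4 matrix")
    rng = np.random.default_rng(seed)
    n_rounds = codebook.barcode_length
    base_to_channel = {b: c for c, b in codebook.channel_to_base.items()}
    alphabet = list("ACGT")

    _, seg, _ = gen_cell_images(
        n_cells,
        field_size,
        seed=int(rng.integers(2**31)),
        radius_range=(20.0, 28.0),
        axis_ratio_range=(1.0, 1.3),
        noise_sd=0.0,
        texture_amp=0.0,
    )
    interior = ndimage.binary_erosion(seg.labels > 0, iterations=2)
    ys, xs = np.nonzero(interior)
    genes = list(codebook.barcodes)
    placed = []
    rows = []
    for i in range(n_amplicons):
        ok = False
        for _ in range(500):
            j = rng.integers(len(ys))
            y = ys[j] + rng.uniform(-0.5, 0.5)
            x = xs[j] + rng.uniform(-0.5, 0.5)
            if all(np.hypot(y - py, x - px) >= min_sep for py, px in placed):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could only place {i} of {n_amplicons} amplicons"
            )
        placed.append((y, x))
        gene = genes[rng.integers(len(genes))]
        barcode = codebook.barcodes[gene]
        realized = []
        for b in barcode:
            if base_error_rate > 0 and rng.random() < base_error_rate:
                wrong = [c for c in alphabet if c != b]
                realized.append(wrong[rng.integers(3)])
            else:
                realized.append(b)
        present = (
            rng.random(n_rounds) >= dropout_rate
            if dropout_rate > 0
            else np.ones(n_rounds, bool)
        )
        rows.append(
            dict(
                amplicon_id=i,
                gene=gene,
                barcode=barcode,
                realized_bases="".join(realized),
                y=y,
                x=x,
                cell_id=int(seg.labels[int(round(y)), int(round(x))]),
                present_rounds="".join("1" if p else "0" for p in present),
            )
        )
    reads = pd.DataFrame(rows)

    fid_pos = []
    for _ in range(n_fiducials):
        for _ in range(500):
            y = rng.uniform(4, field_size - 4)
            x = rng.uniform(4, field_size - 4)
            if all(
                np.hypot(y - py, x - px) >= 2 * min_sep
                for py, px in placed + fid_pos
            ):
                fid_pos.append((y, x))
                break
        else:
            raise PlacementError("could not place fiducials")
    fiducials = pd.DataFrame(fid_pos, columns=["y", "x"])

    drifts = np.zeros((n_rounds, 2))
    if drift_px > 0:
        for r in range(1, n_rounds):
            ang = rng.uniform(0, 2 * np.pi)
            rad = drift_px * np.sqrt(rng.random())
            drifts[r] = rad * np.array([np.sin(ang), np.cos(ang)])

    stacks = np.zeros((n_rounds, 4, field_size, field_size))
    for r in range(n_rounds):
        dy, dx = drifts[r]
        for row in rows:
            if row["present_rounds"][r] == "0":
                continue
            ch = base_to_channel[row["realized_bases"][r]]
            _render_gaussians(
                stacks[r, ch],
                [(row["y"] + dy, row["x"] + dx)],
                amplitude,
                psf_sigma,
            )
        for y, x in fid_pos:
            for ch in range(4):
                _render_gaussians(
                    stacks[r, ch], [(y + dy, x + dx)], fiducial_amplitude, psf_sigma
                )
        stacks[r] = np.einsum("ij,jhw->ihw", crosstalk, stacks[r])
    if noise_sd > 0:
        stacks = stacks + rng.normal(0, noise_sd, stacks.shape)
    stacks = np.clip(stacks, 0, None)
    truth = SyntheticTruth(
        scenario_name="exseq-stacks",
        seed=seed,
        parameters=dict(
            n_amplicons=n_amplicons,
            n_rounds=n_rounds,
            base_error_rate=base_error_rate,
            drift_px=drift_px,
            n_fiducials=n_fiducials,
            dropout_rate=dropout_rate,
            pixel_size_um=pixel_size,
            psf_sigma_px=psf_sigma,
        ),
        truth_tables=dict(
            reads=reads, fiducials=fiducials, drifts=drifts, crosstalk=crosstalk
        ),
    )
    return stacks, seg, truth


# ---------------------------------------------------------------------------
# count matrices


def gen_count_matrix(
    n_cells: int = 2000,
    markers_a: list = None,
    markers_b: list = None,
    background_genes: list = None,
    clone_fraction: float = 0.5,
    marker_enrichment: float = 5.0,
    mean_counts=500.0,
    seed: int = 0,
    *,
    total_cv: float = 0.4,
):
    """Cells-by-genes counts for a two-clone population.

    Per-cell totals are Poisson around a lognormal mean (coefficient of
    variation ``total_cv``); within a cell, counts are multinomial with
    own-clone marker genes enriched ``marker_enrichment``-fold over the
    other clone's markers and background genes.  ``mean_counts`` may be
    a scalar or a per-cell array (e.g. to plant cells outside the
    [50, 3000] retention window used downstream).

    Returns ``(CountMatrix DataFrame, SyntheticTruth)`` with per-cell
    clone labels (``clone_a`` carries the ZNF24-style panel).
    """
    markers_a = MARKERS_CLONE_ZNF24 if markers_a is None else list(markers_a)
    markers_b = MARKERS_CLONE_XIST if markers_b is None else list(markers_b)
    background_genes = (
        BACKGROUND_GENES if background_genes is None else list(background_genes)
    )
    if set(markers_a) & set(markers_b):
        raise ValueError("marker lists must be disjoint")
    if not 0 < clone_fraction < 1:
        raise ValueError("clone_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = markers_a + markers_b + background_genes
    n_genes = len(genes)
    idx_a = np.arange(len(markers_a))
    idx_b = np.arange(len(markers_a), len(markers_a) + len(markers_b))

    means = np.broadcast_to(
        np.asarray(mean_counts, dtype=float), (n_cells,)
    ).copy()
    sigma = np.sqrt(np.log(1 + total_cv**2))
    cell_means = means * rng.lognormal(-(sigma**2) / 2, sigma, n_cells)
    totals = rng.poisson(np.clip(cell_means, 0.01, None))

    is_a = rng.random(n_cells) < clone_fraction
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    w_a = np.ones(n_genes)
    w_a[idx_a] = marker_enrichment
    w_b = np.ones(n_genes)
    w_b[idx_b] = marker_enrichment
    p_a, p_b = w_a / w_a.sum(), w_b / w_b.sum()
    for i in range(n_cells):
        if totals[i] > 0:
            counts[i] = rng.multinomial(totals[i], p_a if is_a[i] else p_b)
    matrix = pd.DataFrame(
        counts,
        index=[f"cell{i:05d}" for i in range(n_cells)],
        columns=genes,
    )
    labels = pd.Series(
        np.where(is_a, "clone_a", "clone_b"), index=matrix.index, name="clone"
    )
    truth = SyntheticTruth(
        scenario_name="two-clone-counts",
        seed=seed,
        parameters=dict(
            n_cells=n_cells,
            clone_fraction=clone_fraction,
            marker_enrichment=marker_enrichment,
            total_cv=total_cv,
        ),
        truth_tables=dict(
            labels=labels, markers_a=markers_a, markers_b=markers_b
        ),
    )
    return matrix, truth
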