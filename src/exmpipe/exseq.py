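"""Decoding of multi-round, 4-channel in situ sequencing stacks.

Barcoded rolling-circle amplicons are read out over B sequencing
rounds, one base per round, each base emitting in one of four color
channels.  The pipeline stages mirror the standard processing order:
fiducial-based rigid registration of rounds, channel crosstalk
correction, amplicon segmentation, per-round argmax basecalling, and
codebook matching with Hamming-distance error correction, followed by
assignment of reads to segmented cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import RegistrationError, SegmentationMap

_ALPHABET = set("ACGT")


@dataclass
class Codebook:
    """Gene-to-barcode map with channel assignments.

    Barcodes are equal-length strings over {A, C, G, T}; the minimum
    pairwise Hamming distance determines the error-correction radius
    (unambiguous correction requires ``radius < min_pairwise_hamming/2``).
    """

    barcodes: dict  # gene -> barcode
    channel_to_base: dict  # channel index -> base
    min_pairwise_hamming: int = field(init=False)

    def __post_init__(self):
        if not self.barcodes:
            raise ValueError("codebook must contain at least one gene")
        self.barcodes = {
            g: str(b).upper() for g, b in self.barcodes.items()
        }
        words = list(self.barcodes.values())
        lengths = {len(w) for w in words}
        if len(lengths) != 1:
            raise ValueError("barcodes must all have the same length")
        if len(set(words)) != len(words):
            raise ValueError("barcodes must be unique")
        bad = set("".join(words)) - _ALPHABET
        if bad:
            raise ValueError(f"invalid barcode characters: {sorted(bad)}")
        if sorted(self.channel_to_base.values()) != sorted(_ALPHABET):
            raise ValueError("channel_to_base must be a bijection onto ACGT")
        self.channel_to_base = {
            int(c): b.upper() for c, b in self.channel_to_base.items()
        }
        if len(words) > 1:
            self.min_pairwise_hamming = min(
                _hamming(a, b)
                for i, a in enumerate(words)
                for b in words[i + 1 :]
            )
        else:
            self.min_pairwise_hamming = len(words[0])

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes.values())))

    @property
    def genes(self) -> list:
        return list(self.barcodes)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# registration


def _detect_fiducials(stack_round: np.ndarray, min_distance: int = 4):
    """Fiducial candidates on one round: beads emit in all channels, so
    the across-channel minimum projection isolates them from amplicons."""
    minproj = stack_round.min(axis=0)
    if minproj.max() <= 0:
        return np.empty((0, 2))
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        minproj, min_distance=min_distance, threshold_abs=0.5 * minproj.max()
    )
    return np.array(
        [_weighted_centroid(minproj, p, half=3) for p in peaks]
    ).reshape(-1, 2)


def _weighted_centroid(img: np.ndarray, peak, half: int = 3):
    y, x = int(peak[0]), int(peak[1])
    y0, y1 = max(0, y - half), min(img.shape[0], y + half + 1)
    x0, x1 = max(0, x - half), min(img.shape[1], x + half + 1)
    w = np.clip(img[y0:y1, x0:x1], 0, None)
    yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
    s = w.sum()
    if s <= 0:
        return float(y), float(x)
    return float((w * yy).sum() / s), float((w * xx).sum() / s)


def register_rounds(
    stacks: np.ndarray,
    *,
    min_fiducials: int = 3,
    match_radius: float = 6.0,
):
    """Rigid (translation-only) alignment of rounds from fiducial beads.

    Round 0 is the reference.  Per round, bead centroids are matched to
    the reference set by nearest neighbour within ``match_radius``
    pixels and the shift is their mean offset; stacks are resampled onto
    the reference frame by bilinear interpolation.

    Returns ``(aligned stacks, shifts (n_rounds, 2), reference fiducial
    positions)``.  Fewer than ``min_fiducials`` matched beads in any
    round raises :class:`RegistrationError`.
    """
    stacks = np.asarray(stacks, dtype=float)
    if stacks.ndim != 4:
        raise ValueError("stacks must be (round, channel, y, x)")
    n_rounds = stacks.shape[0]
    if n_rounds < 2:
        raise ValueError("need at least two rounds to register")
    ref = _detect_fiducials(stacks[0])
    if len(ref) < min_fiducials:
        raise RegistrationError(
            f"only {len(ref)} fiducials detected in reference round"
        )
    tree = cKDTree(ref)
    aligned = np.empty_like(stacks)
    aligned[0] = stacks[0]
    shifts = np.zeros((n_rounds, 2))
    for r in range(1, n_rounds):
        pos = _detect_fiducials(stacks[r])
        offsets = []
        for p in pos:
            d, i = tree.query(p)
            if d <= match_radius:
                offsets.append(p - ref[i])
        if len(offsets) < min_fiducials:
            raise RegistrationError(
                f"round {r}: only {len(offsets)} fiducials matched"
            )
        shifts[r] = np.mean(offsets, axis=0)
        for ch in range(stacks.shape[1]):
            aligned[r, ch] = ndimage.shift(
                stacks[r, ch], -shifts[r], order=1, mode="nearest"
            )
    return aligned, shifts, ref


# ---------------------------------------------------------------------------
# color correction


def color_correct(stack: np.ndarray, crosstalk: np.ndarray, max_condition: float = 1e6):
    """Invert channel crosstalk: per-pixel channel vectors are multiplied
    by the crosstalk inverse; negatives are clipped to zero.

    Accepts a single round ``(4, H, W)`` or a full stack
    ``(rounds, 4, H, W)``.  Returns ``(corrected, clipped_fraction)``.
    """
    crosstalk = np.asarray(crosstalk, dtype=float)
    if crosstalk.shape != (4, 4):
        raise ValueError("crosstalk must be 4x4")
    cond = np.linalg.cond(crosstalk)
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(
            f"crosstalk matrix is ill-conditioned (cond={cond:.3g})"
        )
    inv = np.linalg.inv(crosstalk)
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 3:
        corrected = np.einsum("ij,jhw->ihw", inv, stack)
    elif stack.ndim == 4:
        corrected = np.einsum("ij,rjhw->rihw", inv, stack)
    else:
        raise ValueError("stack must be (4, H, W) or (rounds, 4, H, W)")
    clipped = float(np.mean(corrected < -1e-9))
    return np.clip(corrected, 0, None), clipped


# ---------------------------------------------------------------------------
# segmentation and photometry


def segment_amplicons(
    stacks: np.ndarray,
    psf_sigma: float = 1.2,
    threshold_sd: float = 5.0,
    *,
    aperture_radius: float = 2.0,
    exclude: np.ndarray = None,
    exclude_radius: float = 5.0,
    merge_flag_factor: float = 2.0,
):
    """Detect amplicon puncta and sample per-round, per-channel flux.

    Puncta are LoG local maxima of the channel-summed first round;
    non-maximum suppression at radius ``2 * psf_sigma`` collapses
    amplicons closer than that into a single punctum (flagged ``merged``
    when its round-1 flux exceeds ``merge_flag_factor`` times the median
    punctum flux).  Positions in ``exclude`` (e.g. fiducial beads) are
    dropped.  Intensities are summed over a fixed circular aperture at
    the punctum position in every round and channel.

    Returns ``(puncta DataFrame, intensities (n, rounds, 4))``.
    """
    from .spots import _log_maxima

    stacks = np.asarray(stacks, dtype=float)
    detection = stacks[0].sum(axis=0)
    peaks = _log_maxima(detection, psf_sigma, threshold_sd)
    if exclude is not None and len(exclude) and len(peaks):
        tree = cKDTree(np.asarray(exclude, dtype=float))
        d, _ = tree.query(peaks)
        peaks = peaks[d > exclude_radius]
    n = len(peaks)
    n_rounds, n_channels = stacks.shape[:2]
    intensities = np.zeros((n, n_rounds, n_channels))
    H, W = detection.shape
    rad = int(np.ceil(aperture_radius))
    for i, (py, px) in enumerate(peaks):
        y0, y1 = max(0, py - rad), min(H, py + rad + 1)
        x0, x1 = max(0, px - rad), min(W, px + rad + 1)
        yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
        disk = (yy - py) ** 2 + (xx - px) ** 2 <= aperture_radius**2
        intensities[i] = stacks[:, :, y0:y1, x0:x1][:, :, disk].sum(axis=-1)
    flux0 = intensities[:, 0, :].sum(axis=-1)
    med = np.median(flux0) if n else 0.0
    puncta = pd.DataFrame(
        dict(
            y=peaks[:, 0] if n else np.array([], dtype=int),
            x=peaks[:, 1] if n else np.array([], dtype=int),
            merged=(flux0 > merge_flag_factor * med) if n else np.array([], bool),
        )
    )
    return puncta, intensities


# ---------------------------------------------------------------------------
# basecalling and codebook matching


def basecall(intensities: np.ndarray, channel_to_base: dict):
    """Per-round argmax basecalling.

    For each punctum and round, the called base is the channel with the
    highest aperture flux; the margin is top minus second intensity.
    Exact ties break deterministically to the lowest channel index and
    are flagged; an all-zero round calls 'N' with margin 0.

    Returns ``(called_bases list of str, margins (n, rounds),
    tie_flags (n, rounds))``.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.ndim != 3 or intensities.shape[2] != len(channel_to_base):
        raise ValueError("intensities must be (n, rounds, n_channels)")
    n, n_rounds, _ = intensities.shape
    order = np.sort(intensities, axis=2)
    top, second = order[:, :, -1], order[:, :, -2]
    argmax = intensities.argmax(axis=2)  # first (lowest) index on ties
    margins = top - second
    ties = (top == second) & (top > 0)
    calls = []
    for i in range(n):
        bases = []
        for r in range(n_rounds):
            if top[i, r] <= 0:
                bases.append("N")
            else:
                bases.append(channel_to_base[int(argmax[i, r])])
        calls.append("".join(bases))
    margins = np.where(top <= 0, 0.0, margins)
    return calls, margins, ties


def match_codebook(called_bases, codebook: Codebook, radius: int = 1):
    """Match called base strings to codebook genes with error correction.

    Exact matches are returned directly; otherwise the unique codeword
    within Hamming distance ``radius`` wins.  Ambiguous or more distant
    calls return no gene.  Requires ``radius < min_pairwise_hamming / 2``
    so correction is unambiguous; 'N' mismatches every base.

    For a single string returns ``(gene or None, hamming_used)``; for a
    sequence of strings returns parallel lists.
    """
    if radius >= codebook.min_pairwise_hamming / 2:
        raise ValueError(
            f"radius {radius} is not < min_pairwise_hamming/2 "
            f"({codebook.min_pairwise_hamming}/2)"
        )
    single = isinstance(called_bases, str)
    queries = [called_bases] if single else list(called_bases)
    exact = {b: g for g, b in codebook.barcodes.items()}
    words = list(codebook.barcodes.values())
    genes = list(codebook.barcodes)
    out_gene, out_ham = [], []
    for q in queries:
        if q in exact:
            out_gene.append(exact[q])
            out_ham.append(0)
            continue
        dists = np.array([_hamming(q, w) for w in words])
        best = dists.min()
        if best <= radius and (dists == best).sum() == 1:
            out_gene.append(genes[int(dists.argmin())])
            out_ham.append(int(best))
        else:
            out_gene.append(None)
            out_ham.append(int(best))
    if single:
        return out_gene[0], out_ham[0]
    return out_gene, out_ham


# ---------------------------------------------------------------------------
# cell assignment


def reads_to_cells(reads: pd.DataFrame, seg: SegmentationMap, genes=None):
    """Assign reads to cells by 2D mask lookup and tabulate counts.

    Adds a ``cell_id`` column (0 = unassigned/background); the returned
    CountMatrix aggregates matched, cell-assigned reads per cell x gene.
    Unassigned or unmatched reads stay in the ReadTable but not in the
    matrix.
    """
    reads = reads.copy()
    H, W = seg.labels.shape
    ys = np.clip(np.round(reads["y"].to_numpy()).astype(int), 0, H - 1)
    xs = np.clip(np.round(reads["x"].to_numpy()).astype(int), 0, W - 1)
    reads["cell_id"] = seg.labels[ys, xs]
    matched = reads[(reads["cell_id"] > 0) & reads["matched_gene"].notna()]
    cols = list(genes) if genes is not None else sorted(
        matched["matched_gene"].unique()
    )
    matrix = (
        matched.groupby(["cell_id", "matched_gene"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=seg.label_ids, columns=cols, fill_value=0)
    )
    matrix.index.name = "cell_id"
    return reads, matrix


# ---------------------------------------------------------------------------
# round-to-round detection rate


def round_detection_rate(
    reference_positions: np.ndarray,
    per_round_positions,
    tolerance_px: float = 2.0,
):
    """Fraction of reference amplicons re-detected in each round.

    A reference amplicon counts as detected in a round when some
    detection lies within ``tolerance_px``.  Returns ``(rates array,
    mean rate)``; an empty reference is rejected.
    """
    reference_positions = np.asarray(reference_positions, dtype=float)
    if len(reference_positions) == 0:
        raise ValueError("reference amplicon set is empty")
    rates = []
    for pos in per_round_positions:
        pos = np.asarray(pos, dtype=float).reshape(-1, 2)
        if len(pos) == 0:
            rates.append(0.0)
            continue
        tree = cKDTree(pos)
        d, _ = tree.query(reference_positions)
        rates.append(float(np.mean(d <= tolerance_px)))
    rates = np.array(rates)
    return rates, float(rates.mean())


# ---------------------------------------------------------------------------
# end-to-end convenience


def decode_stacks(
    stacks: np.ndarray,
    codebook: Codebook,
    seg: SegmentationMap = None,
    crosstalk: np.ndarray = None,
    radius: int = 1,
    psf_sigma: float = 1.2,
    threshold_sd: float = 5.0,
    register: bool = True,
):
    """Full decode: register -> color-correct -> segment -> basecall ->
    match -> assign to cells.

    Returns ``(ReadTable, CountMatrix or None)``.  Every punctum appears
    exactly once with a terminal ``status`` in {matched, unmatched}.
    """
    fiducials = None
    if register:
        stacks, _, fiducials = register_rounds(stacks)
    if crosstalk is not None:
        stacks, _ = color_correct(stacks, crosstalk)
    puncta, intensities = segment_amplicons(
        stacks, psf_sigma=psf_sigma, threshold_sd=threshold_sd, exclude=fiducials
    )
    calls, margins, ties = basecall(intensities, codebook.channel_to_base)
    genes, hams = match_codebook(calls, codebook, radius=radius) if calls else ([], [])
    reads = puncta.copy()
    reads["called_bases"] = calls
    reads["margin"] = margins.mean(axis=1) if len(calls) else []
    reads["tie_rounds"] = ties.sum(axis=1) if len(calls) else []
    reads["matched_gene"] = pd.Series(genes, index=reads.index, dtype=object)
    reads["hamming_used"] = hams
    # beads emit in every channel: a punctum whose weakest channel holds a
    # large share of its strongest, in every round, is a fiducial
    if len(calls):
        with np.errstate(invalid="ignore"):
            ratio = np.where(
                intensities.max(axis=2) > 0,
                intensities.min(axis=2) / np.maximum(intensities.max(axis=2), 1e-12),
                0.0,
            )
        is_fiducial = ratio.min(axis=1) > 0.5
        reads.loc[is_fiducial, "matched_gene"] = None
    reads["status"] = np.where(reads["matched_gene"].notna(), "matched", "unmatched")
    if len(calls):
        reads.loc[is_fiducial, "status"] = "fiducial"
    matrix = None
    if seg is not None:
        reads, matrix = reads_to_cells(reads, seg, genes=codebook.genes)
    return reads, matrix
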