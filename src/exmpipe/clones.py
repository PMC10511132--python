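"""Tumor-clone classification from per-cell gene counts.

Cells are filtered on total counts, median-normalized and
log-transformed; clone structure is then read out two ways: an
unsupervised route where the first principal component's extreme
loadings nominate marker panels, and a supervised route where known
marker panels are given.  Either way a cell is assigned to the clone
whose 15-gene marker fraction (summed marker counts over total counts)
wins and exceeds a 30% threshold, otherwise it stays Unclassified.
Marker fractions also drive RGB composite channels through a linear
scaling clipped at 100%.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

UNCLASSIFIED = "Unclassified"

#: Channel scaling factors used for the functional-group composites
#: (DNA repair and proliferation share 3.33; EMT uses 2.5).
DEFAULT_CHANNEL_SCALING = {"dna_repair": 3.33, "proliferation": 3.33, "emt": 2.5}


def filter_cells(
    matrix: pd.DataFrame, min_counts: int = 50, max_counts: int = 3000
):
    """Retain cells whose total counts lie in [min_counts, max_counts].

    The window is inclusive: the rule removes cells with *less than*
    ``min_counts`` or *more than* ``max_counts`` total counts.  Returns
    ``(filtered matrix, report dict)`` with retained/removed counts; an
    all-removed result is flagged ``empty`` in the report.
    """
    if matrix.shape[0] == 0:
        raise ValueError("count matrix is empty")
    totals = matrix.sum(axis=1)
    keep = (totals >= min_counts) & (totals <= max_counts)
    filtered = matrix.loc[keep]
    report = dict(
        retained=int(keep.sum()),
        removed=int((~keep).sum()),
        empty=bool(keep.sum() == 0),
    )
    return filtered, report


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-of-totals normalization followed by log(1 + x).

    Each cell's counts are scaled by (median total across cells / cell
    total), equalizing depth, then log-transformed with a pseudo-count
    of 1.  Zero-total cells must be filtered out beforehand.
    """
    totals = matrix.sum(axis=1).astype(float)
    if (totals <= 0).any():
        raise ValueError("zero-total cells must be filtered before normalize")
    median = float(totals.median())
    scaled = matrix.div(totals, axis=0) * median
    return np.log1p(scaled)


def pca_gene_groups(normalized: pd.DataFrame, n_per_side: int = 15):
    """Marker panels nominated by the first principal component.

    The centered expression table is decomposed by SVD; the
    ``n_per_side`` most-positive and most-negative gene loadings on the
    first component form the two candidate marker lists (30 genes for
    the default panel size).  Sign convention: the component is oriented
    so its largest-magnitude loading is positive, making the lists
    deterministic.  Returns ``(positive genes, negative genes, info)``
    where ``info`` carries the loadings and variance explained (a
    near-zero first component is flagged ``low_variance``).
    """
    if normalized.shape[1] < 2 * n_per_side:
        raise ValueError("need at least 2 * n_per_side genes")
    if normalized.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    X = normalized.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    total_var = float(np.var(X, axis=0).sum())
    if total_var <= 0:
        raise ValueError("expression table has zero variance")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    pc1 = vt[0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    loadings = pd.Series(pc1, index=normalized.columns)
    order = loadings.sort_values(ascending=False)
    positive = list(order.index[:n_per_side])
    negative = list(order.index[-n_per_side:][::-1])
    var_ratio = float(s[0] ** 2 / (s**2).sum())
    info = dict(
        loadings=loadings,
        variance_ratio=var_ratio,
        low_variance=var_ratio < 0.05,
    )
    return positive, negative, info


def group_fraction_to_channel(fraction, scaling: float):
    """Map a gene-group count fraction to an RGB channel value in % of
    maximum: ``min(100, fraction * scaling * 100)``.

    With the EMT scaling of 2.5, a group holding 40% of a cell's
    transcripts saturates its channel (40% x 2.5 = 100%).
    """
    fraction = np.asarray(fraction, dtype=float)
    if np.any((fraction < 0) | (fraction > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if scaling <= 0:
        raise ValueError("scaling must be positive")
    value = np.minimum(100.0, fraction * scaling * 100.0)
    return float(value) if value.ndim == 0 else value


def assign_clone(
    counts,
    markers_a,
    markers_b,
    threshold: float = 0.30,
    labels=("clone_a", "clone_b"),
):
    """Assign one cell to a clone by its winning marker fraction.

    ``fraction_x`` is the summed counts of clone x's markers over the
    cell's total counts; the cell takes the argmax clone's label if that
    fraction reaches ``threshold``, otherwise (or on an exact tie) it is
    Unclassified.  Returns ``(label, max_marker_fraction)``.
    """
    counts = pd.Series(counts, dtype=float)
    fa, fb = _marker_fractions(counts.to_frame().T, markers_a, markers_b)
    return _label_from_fractions(
        float(fa.iloc[0]), float(fb.iloc[0]), threshold, labels
    )


def _marker_fractions(matrix, markers_a, markers_b):
    markers_a, markers_b = list(markers_a), list(markers_b)
    if not markers_a or not markers_b:
        raise ValueError("marker lists must be non-empty")
    if set(markers_a) & set(markers_b):
        raise ValueError("marker lists must be disjoint")
    totals = matrix.sum(axis=1).astype(float)
    if (totals <= 0).any():
        raise ValueError("cells must have positive total counts")
    in_a = [g for g in markers_a if g in matrix.columns]
    in_b = [g for g in markers_b if g in matrix.columns]
    fa = matrix[in_a].sum(axis=1) / totals if in_a else totals * 0.0
    fb = matrix[in_b].sum(axis=1) / totals if in_b else totals * 0.0
    return fa, fb


def _label_from_fractions(fa, fb, threshold, labels):
    if fa == fb:
        return UNCLASSIFIED, fa
    if fa > fb:
        return (labels[0] if fa >= threshold else UNCLASSIFIED), fa
    return (labels[1] if fb >= threshold else UNCLASSIFIED), fb


def assign_clones(
    matrix: pd.DataFrame,
    markers_a,
    markers_b,
    threshold: float = 0.30,
    labels=("clone_a", "clone_b"),
) -> pd.DataFrame:
    """Vectorized :func:`assign_clone` over a CountMatrix.

    Returns a CloneScores DataFrame with ``fraction_a``, ``fraction_b``,
    ``max_marker_fraction`` and ``clone_label`` per cell.
    """
    fa, fb = _marker_fractions(matrix, markers_a, markers_b)
    label = np.where(
        fa > fb,
        np.where(fa >= threshold, labels[0], UNCLASSIFIED),
        np.where((fb > fa) & (fb >= threshold), labels[1], UNCLASSIFIED),
    )
    return pd.DataFrame(
        dict(
            fraction_a=fa,
            fraction_b=fb,
            max_marker_fraction=np.maximum(fa, fb),
            clone_label=label,
        ),
        index=matrix.index,
    )


def clone_correspondence(labels_1: pd.Series, labels_2: pd.Series) -> dict:
    """Map method-2 clone names onto method-1 clone names by maximal
    overlap of their member cells (Unclassified maps to itself)."""
    labels_1, labels_2 = labels_1.align(labels_2, join="inner")
    mapping = {UNCLASSIFIED: UNCLASSIFIED}
    for c2 in sorted(set(labels_2) - {UNCLASSIFIED}):
        members = labels_1[labels_2 == c2]
        members = members[members != UNCLASSIFIED]
        mapping[c2] = (
            members.value_counts().idxmax() if len(members) else UNCLASSIFIED
        )
    return mapping


def cross_method_agreement(
    labels_1: pd.Series,
    labels_2: pd.Series,
    sample_n: int = 2000,
    seed: int = 0,
) -> dict:
    """Agreement between two clone labelings, per direction.

    For each direction, ``sample_n`` cells carrying a clone label under
    the reference method are sampled (Unclassified excluded from the
    draw; fewer labeled cells than ``sample_n`` samples all, with a
    warning) and agreement is the fraction given the corresponding
    clone by the other method.  Clone-name correspondence is established
    by maximal member overlap, not by label strings.
    """
    labels_1 = pd.Series(labels_1)
    labels_2 = pd.Series(labels_2)
    labels_1, labels_2 = labels_1.align(labels_2, join="inner")
    map_2_to_1 = clone_correspondence(labels_1, labels_2)
    map_1_to_2 = clone_correspondence(labels_2, labels_1)
    rng = np.random.default_rng(seed)

    def direction(ref, other, mapping):
        labeled = ref.index[ref != UNCLASSIFIED]
        if len(labeled) == 0:
            raise ValueError("reference labeling has no clone-labeled cells")
        if len(labeled) < sample_n:
            warnings.warn(
                f"only {len(labeled)} labeled cells available; sampling all"
            )
            chosen = labeled
        else:
            chosen = rng.choice(labeled, size=sample_n, replace=False)
        same = [mapping[other[c]] == ref[c] for c in chosen]
        return float(np.mean(same)), len(chosen)

    a12, n12 = direction(labels_1, labels_2, map_2_to_1)
    a21, n21 = direction(labels_2, labels_1, map_1_to_2)
    return dict(
        agreement_1_to_2=a12,
        agreement_2_to_1=a21,
        n_1=n12,
        n_2=n21,
        correspondence_2_to_1=map_2_to_1,
    )
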