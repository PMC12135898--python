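"""Static functional connectome and the affinity matrix for embedding.

The chain is Pearson correlation -> row-wise sparsification (top-density
entries per row) -> pairwise cosine similarity of the sparsified rows, with
negative cosines clipped to zero so the result is an admissible kernel for
diffusion embedding.
"""

from __future__ import annotations

import math

import numpy as np

from .types import FCMatrix, SessionSeries

__all__ = ["pearson_fc", "sparsify_rows", "cosine_affinity", "session_affinity"]

DEFAULT_DENSITY = 0.10


def pearson_fc(series: SessionSeries) -> FCMatrix:
    """Full Pearson correlation matrix of the ROI time series."""
    if series.n_volumes < 3:
        raise ValueError("Pearson FC needs at least 3 volumes")
    sd = series.data.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        labels = [series.roi_labels[i] for i in flat[:5]]
        raise ValueError(f"constant ROI series (no variance): {labels}")
    values = np.corrcoef(series.data, rowvar=False)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return FCMatrix(values=values, kind="pearson", roi_labels=list(series.roi_labels))


def _sparsify_array(values: np.ndarray, density: float) -> np.ndarray:
    """Row-wise top-density thresholding; ties broken toward lower column index.

    Accepts a single matrix or a stack of matrices (..., n, n).
    """
    n = values.shape[-1]
    k = math.ceil(density * (n - 1))
    if k < 1:
        raise ValueError(f"density {density} retains no off-diagonal entries")
    idx = np.arange(n)
    # Sort each row by (-value) with a stable sort so equal values keep the
    # lower column index first; the diagonal is masked out then restored.
    masked = values.copy()
    masked[..., idx, idx] = -np.inf
    order = np.argsort(-masked, axis=-1, kind="stable")[..., :k]
    out = np.zeros_like(values)
    np.put_along_axis(out, order, np.take_along_axis(values, order, axis=-1), axis=-1)
    out[..., idx, idx] = values[..., idx, idx]
    return out


def sparsify_rows(fc: FCMatrix, density: float = DEFAULT_DENSITY) -> FCMatrix:
    """Keep the top ``ceil(density*(n-1))`` off-diagonal entries of each row.

    The operation is row-wise, so the result is generally asymmetric; the
    downstream cosine step restores symmetry.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    out = _sparsify_array(fc.values, density)
    return FCMatrix(values=out, kind="sparsified", density=density, roi_labels=fc.roi_labels)


def _cosine_affinity_array(rows: np.ndarray) -> np.ndarray:
    """Pairwise cosine of connectivity rows, self-positions excluded.

    For the pair (i, j) the vectors compared are rows i and j restricted to
    columns k not in {i, j}, so identical connectivity profiles get affinity
    exactly 1 regardless of their self-entries. Negative cosines are clipped
    to 0 and the diagonal is set to 1.
    """
    n = rows.shape[-1]
    idx = np.arange(n)
    rows_t = np.swapaxes(rows, -1, -2)
    G = rows @ rows_t
    d = rows[..., idx, idx]  # self entries R_ii
    # numerator: <r_i, r_j> - R_ii * R_ji - R_ij * R_jj
    num = G - d[..., :, None] * rows_t - rows * d[..., None, :]
    sq = np.einsum("...ij,...ij->...i", rows, rows)
    # squared norm of row i with positions i and j removed
    denom_i = sq[..., :, None] - d[..., :, None] ** 2 - rows**2
    denom_j = np.swapaxes(denom_i, -1, -2)
    bad = (denom_i <= 0) | (denom_j <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        aff = num / np.sqrt(np.where(bad, 1.0, denom_i * denom_j))
    aff[bad] = 0.0
    aff = np.clip(aff, 0.0, 1.0)
    aff = (aff + np.swapaxes(aff, -1, -2)) / 2.0
    aff[..., idx, idx] = 1.0
    return aff


def cosine_affinity(sparse: FCMatrix) -> FCMatrix:
    """Cosine-similarity affinity of the sparsified connectome rows."""
    rows = sparse.values
    offdiag = rows.copy()
    np.fill_diagonal(offdiag, 0.0)
    zero_rows = np.flatnonzero(~offdiag.any(axis=1))
    if zero_rows.size:
        labels = (
            [sparse.roi_labels[i] for i in zero_rows[:5]]
            if sparse.roi_labels
            else zero_rows[:5].tolist()
        )
        raise ValueError(f"all-zero connectivity rows for ROIs: {labels}")
    aff = _cosine_affinity_array(rows)
    return FCMatrix(values=aff, kind="affinity", density=sparse.density, roi_labels=sparse.roi_labels)


def session_affinity(series: SessionSeries, density: float = DEFAULT_DENSITY) -> FCMatrix:
    """Pearson -> sparsify -> cosine affinity for one session."""
    return cosine_affinity(sparsify_rows(pearson_fc(series), density))
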