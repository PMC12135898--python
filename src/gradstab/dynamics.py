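"""Phase-locking dynamics: instantaneous phase, per-TR dPL matrices, and
template-aligned per-TR gradient maps.

Phases come from the analytic signal (Hilbert transform) of each demeaned
ROI series. The dynamic phase-locking (dPL) matrix at volume t has entries
``cos(theta_i(t) - theta_j(t))`` in [-1, 1]: +1 when two regions' band-limited
signals move together, -1 when they move in opposition. Each TR's dPL slice
is carried through the same sparsify -> cosine-affinity -> diffusion-embed
path as the static connectome and then rotated onto the group template by
orthogonal Procrustes. No edge TRs are trimmed, so a 230-volume session
yields 230 per-TR gradient maps (and 201 sliding windows downstream).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .connectome import DEFAULT_DENSITY, _cosine_affinity_array, _sparsify_array
from .gradient import _fix_signs
from .types import (
    DPLStack,
    DynamicGradientStack,
    EmbeddingParams,
    GradientTemplate,
    PhaseStack,
    SessionSeries,
)

__all__ = [
    "hilbert_phase",
    "dpl_at_tr",
    "dpl_stack",
    "dynamic_gradients",
    "windowed_dpl_gradients",
]

_EIG_TOL = 1e-10


def hilbert_phase(series: SessionSeries) -> PhaseStack:
    """Instantaneous phase of each ROI's demeaned analytic signal.

    Input should already be band-limited; all volumes are retained (edge
    distortion of the analytic signal is accepted rather than trimming).
    """
    data = series.data - series.data.mean(axis=0)
    if np.any(data.std(axis=0) == 0):
        bad = np.flatnonzero(data.std(axis=0) == 0)[:5]
        raise ValueError(f"constant ROI series, no phase defined: {bad.tolist()}")
    analytic = hilbert(data, axis=0)
    return PhaseStack(phases=np.angle(analytic))


def dpl_at_tr(phases: PhaseStack, t: int) -> np.ndarray:
    """Dynamic phase-locking matrix at one volume: cos(theta_i - theta_j)."""
    th = phases.phases[t]
    mat = np.cos(th[:, None] - th[None, :])
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return mat


def dpl_stack(phases: PhaseStack, dtype=np.float64) -> DPLStack:
    """All per-TR dPL matrices, computed via the cosine angle-difference
    identity as ``C C^T + S S^T`` with C = cos(theta), S = sin(theta)."""
    C = np.cos(phases.phases).astype(dtype, copy=False)  # n_volumes x n_roi
    S = np.sin(phases.phases).astype(dtype, copy=False)
    mats = C[:, :, None] * C[:, None, :] + S[:, :, None] * S[:, None, :]
    idx = np.arange(mats.shape[1])
    mats[:, idx, idx] = 1.0
    return DPLStack(matrices=mats)


def _dpl_affinities(dpl: DPLStack, density: float, mode: str, dtype=np.float64) -> np.ndarray:
    """Map signed dPL slices to nonnegative affinities.

    ``mode='sparse-cosine'`` (default): rank-sparsify each row of the raw dPL
    slice, then cosine similarity with negative cosines clipped — the same
    path as the static connectome. ``mode='shift'``: affinity = (1+dPL)/2.
    """
    mats = dpl.matrices.astype(dtype, copy=False)
    if mode == "sparse-cosine":
        sparse = _sparsify_array(mats, density)
        return _cosine_affinity_array(sparse)
    if mode == "shift":
        return ((1.0 + mats) / 2.0).astype(dtype, copy=False)
    raise ValueError(f"unknown dPL affinity mode {mode!r}")


def _batched_embed(
    affinities: np.ndarray, params: EmbeddingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diffusion embedding of a stack of affinity matrices.

    Returns (coords (T, n, k), eigenvalues (T, k), flagged (T,)). Slices that
    are degenerate (no nontrivial structure) or disconnected are flagged and
    get zero coordinates instead of raising, so one bad TR cannot abort a
    session.
    """
    T, n, _ = affinities.shape
    k = min(params.n_components, n - 1)
    # dtype-aware spectral tolerances (float32 eigenvalues carry ~1e-6 error)
    single = affinities.dtype == np.float32
    unit_tol = 1e-5 if single else 1e-8
    eig_tol = 1e-6 if single else _EIG_TOL
    d = affinities.sum(axis=2)
    flagged = np.any(d <= 0, axis=1)
    d_safe = np.where(d <= 0, 1.0, d)

    da = d_safe ** (-params.alpha)
    Wp = affinities * da[:, :, None] * da[:, None, :]
    dp = Wp.sum(axis=2)
    dp = np.where(dp <= 0, 1.0, dp)
    inv_sqrt = 1.0 / np.sqrt(dp)
    Smat = Wp * inv_sqrt[:, :, None] * inv_sqrt[:, None, :]
    Smat = (Smat + np.swapaxes(Smat, 1, 2)) / 2.0

    evals, evecs = np.linalg.eigh(Smat)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]

    flagged |= np.sum(evals > 1.0 - unit_tol, axis=1) > 1  # disconnected graph
    lam = evals[:, 1 : k + 1].copy()
    flagged |= np.max(np.abs(lam), axis=1) < eig_tol  # uniform/degenerate

    phis = evecs[:, :, 1 : k + 1] * inv_sqrt[:, :, None]
    norms = np.linalg.norm(phis, axis=1, keepdims=True)
    phis /= np.where(norms == 0, 1.0, norms)
    for t in range(T):  # cheap relative to eigh; keeps the sign rule exact
        phis[t] = _fix_signs(phis[t])

    if params.diffusion_time == 0:
        with np.errstate(divide="ignore"):
            scale = np.where(np.abs(1.0 - lam) < 1e-14, 0.0, lam / (1.0 - lam))
    else:
        scale = np.sign(lam) * np.abs(lam) ** params.diffusion_time
    coords = phis * scale[:, None, :]
    coords[flagged] = 0.0
    lam[flagged] = 0.0
    return coords, lam, flagged


def dynamic_gradients(
    dpl: DPLStack,
    template: GradientTemplate,
    params: EmbeddingParams | None = None,
    density: float = DEFAULT_DENSITY,
    affinity_mode: str = "sparse-cosine",
    compute_dtype=np.float32,
) -> DynamicGradientStack:
    """Per-TR gradient maps aligned to the group template.

    Each TR: dPL slice -> nonnegative affinity -> diffusion embedding ->
    orthogonal Procrustes rotation onto the template. Degenerate TRs (e.g.
    all-equal phases giving a uniform matrix) are flagged, keep the zero
    embedding, and are skipped by window averaging downstream.

    ``compute_dtype`` controls the per-TR linear algebra precision; single
    precision is the default (coordinate error ~1e-6, far below the rank
    resolution the stability statistic consumes) and halves the cost.
    """
    params = params or EmbeddingParams()
    n = dpl.n_roi
    if template.n_roi != n:
        raise ValueError("template ROI count does not match dPL stack")
    k = min(params.n_components, n - 1)
    if template.n_components < k:
        raise ValueError("template has fewer components than requested")
    tmpl = template.coords[:, :k]

    affinities = _dpl_affinities(dpl, density, affinity_mode, dtype=compute_dtype)
    # an all-equal dPL slice (uniform phase state) carries no structure; force
    # the uniform affinity so the embedding flags it rather than embedding the
    # artificial support pattern the sparsifier's tie-break would create
    spread = dpl.matrices.max(axis=(1, 2)) - dpl.matrices.min(axis=(1, 2))
    affinities[spread < 1e-9] = 1.0
    coords, lam, flagged = _batched_embed(affinities, params)
    coords = coords.astype(np.float64)
    lam = lam.astype(np.float64)

    # batched orthogonal Procrustes onto the template
    M = np.einsum("tnk,nj->tkj", coords, tmpl)
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    aligned = np.einsum("tnk,tkj->tnj", coords, R)
    aligned[flagged] = 0.0
    return DynamicGradientStack(coords=aligned, eigenvalues=lam, flagged=flagged)


def windowed_dpl_gradients(
    dpl: DPLStack,
    template: GradientTemplate,
    scheme,
    params: EmbeddingParams | None = None,
    density: float = DEFAULT_DENSITY,
    affinity_mode: str = "sparse-cosine",
    compute_dtype=np.float32,
) -> np.ndarray:
    """Window-aggregation alternative: embed the window-averaged dPL.

    Instead of averaging per-TR aligned gradients over each window, the dPL
    matrices are averaged within each sliding window first and each window
    mean is embedded and aligned to the template. Returns per-window
    gradient maps (n_windows, n_roi, n_components).
    """
    params = params or EmbeddingParams()
    n = dpl.n_roi
    if template.n_roi != n:
        raise ValueError("template ROI count does not match dPL stack")
    if scheme.n_volumes != dpl.n_volumes:
        raise ValueError("window scheme was built for a different session length")
    k = min(params.n_components, n - 1)
    tmpl = template.coords[:, :k]

    csum = np.concatenate([np.zeros((1, n, n)), np.cumsum(dpl.matrices, axis=0)])
    starts = scheme.starts()
    wmean = (csum[starts + scheme.window_tr] - csum[starts]) / scheme.window_tr
    affinities = _dpl_affinities(DPLStack(matrices=wmean), density, affinity_mode, dtype=compute_dtype)
    coords, _, flagged = _batched_embed(affinities, params)
    coords = coords.astype(np.float64)
    M = np.einsum("tnk,nj->tkj", coords, tmpl)
    U, _, Vt = np.linalg.svd(M)
    aligned = np.einsum("tnk,tkj->tnj", coords, U @ Vt)
    if flagged.any():
        raise ValueError(
            f"{int(flagged.sum())} window-mean dPL matrices are degenerate"
        )
    return aligned
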