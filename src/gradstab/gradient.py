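"""Diffusion-map embedding, group template and Procrustes alignment.

The embedding follows the standard connectome-gradient recipe: anisotropic
normalisation of the affinity kernel (exponent ``alpha``), eigendecomposition
of the induced Markov operator, and eigenvalue scaling by
``lambda/(1-lambda)`` at diffusion time 0 (the multiscale convention of the
gradient toolboxes) or ``lambda**t`` otherwise.

The eigenproblem of the row-stochastic operator ``P = D'^-1 W'`` is solved
through the conjugate symmetric matrix ``S = D'^-1/2 W' D'^-1/2`` (same
spectrum; right eigenvectors of P are ``D'^-1/2`` times those of S), which
keeps the solve symmetric-definite and fast.
"""

from __future__ import annotations

import numpy as np

from .types import EmbeddingParams, FCMatrix, GradientSet, GradientTemplate

__all__ = [
    "diffusion_embed",
    "diffusion_embed_array",
    "build_group_template",
    "procrustes_align",
    "procrustes_rotation",
    "variance_explained_summary",
]

_EIG_TOL = 1e-10


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def diffusion_embed_array(
    affinity: np.ndarray, params: EmbeddingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Core embedding on a raw affinity array.

    Returns ``(coords, eigenvalues, variance_explained, degenerate)``.
    ``variance_explained`` is computed over all nontrivial nonnegative
    eigenvalues (recorded in output metadata by callers).
    """
    W = np.asarray(affinity, dtype=float)
    n = W.shape[0]
    if not np.all(np.isfinite(W)):
        raise ValueError("affinity contains non-finite entries")
    if W.shape[0] != W.shape[1]:
        raise ValueError("affinity must be square")
    if np.any(W < 0):
        raise ValueError("affinity must be nonnegative")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("affinity must be symmetric")
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("affinity has zero rows; graph is not connected")

    # anisotropic normalisation W' = D^-a W D^-a, then Markov operator rows
    da = d ** (-params.alpha)
    Wp = W * np.outer(da, da)
    dp = Wp.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dp)
    S = Wp * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    if np.sum(evals > 1.0 - 1e-8) > 1:
        raise ValueError(
            "multiple unit eigenvalues: affinity graph is disconnected; "
            "increase the sparsification density"
        )
    # drop the trivial stationary component (eigenvalue 1)
    evals = evals[1:]
    phis = evecs[:, 1:] * inv_sqrt[:, None]
    phis /= np.linalg.norm(phis, axis=0, keepdims=True)

    k = min(params.n_components, n - 1)
    lam = evals[:k]
    vec = _fix_signs(phis[:, :k])

    nonneg = np.clip(evals, 0.0, None)
    total = nonneg.sum()
    degenerate = bool(lam.size == 0 or np.max(np.abs(lam)) < _EIG_TOL or total < _EIG_TOL)
    if degenerate:
        coords = np.zeros((n, k))
        var = np.zeros(k)
        return coords, np.clip(lam, 0.0, None), var, True

    if params.diffusion_time == 0:
        with np.errstate(divide="ignore"):
            scale = np.where(np.abs(1.0 - lam) < 1e-14, 0.0, lam / (1.0 - lam))
    else:
        scale = np.sign(lam) * np.abs(lam) ** params.diffusion_time
    coords = vec * scale[None, :]
    var = np.clip(lam, 0.0, None) / total
    return coords, lam, var, False


def diffusion_embed(affinity: FCMatrix, params: EmbeddingParams | None = None) -> GradientSet:
    """Embed an affinity matrix into gradient coordinates."""
    params = params or EmbeddingParams()
    coords, lam, var, degenerate = diffusion_embed_array(affinity.values, params)
    return GradientSet(coords=coords, eigenvalues=lam, variance_explained=var, degenerate=degenerate)


def build_group_template(
    affinities: list[FCMatrix], params: EmbeddingParams | None = None
) -> GradientTemplate:
    """Template = embedding of the element-wise mean affinity across sessions.

    By convention the template is built from the retained subjects' pre-task
    static connectomes.
    """
    if not affinities:
        raise ValueError("template needs at least one session affinity")
    n = affinities[0].n_roi
    for a in affinities:
        if a.n_roi != n:
            raise ValueError("inconsistent ROI counts across sessions")
    mean_aff = np.mean([a.values for a in affinities], axis=0)
    gs = diffusion_embed(FCMatrix(values=mean_aff, kind="affinity"), params)
    return GradientTemplate(
        coords=gs.coords, provenance=f"mean affinity of {len(affinities)} sessions"
    )


def procrustes_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal matrix R minimising ||source @ R - target||_F (no scaling)."""
    if source.shape != target.shape:
        raise ValueError("source and target dimensions must match")
    U, _, Vt = np.linalg.svd(source.T @ target)
    return U @ Vt


def procrustes_align(source: GradientSet, template: GradientTemplate) -> GradientSet:
    """Rotate/reflect a gradient set onto the template (orthogonal Procrustes).

    Rotation-only alignment preserves the gradient units so stability ranks
    remain comparable across TRs and sessions.
    """
    if source.coords.shape != template.coords.shape:
        raise ValueError(
            f"source {source.coords.shape} vs template {template.coords.shape} mismatch"
        )
    R = procrustes_rotation(source.coords, template.coords)
    return GradientSet(
        coords=source.coords @ R,
        eigenvalues=source.eigenvalues,
        variance_explained=source.variance_explained,
        degenerate=source.degenerate,
        aligned=True,
    )


def variance_explained_summary(gradient_sets: dict) -> "pd.DataFrame":
    """Mean +/- SD of variance explained per (group, dataset, component).

    ``gradient_sets`` maps ``(group, dataset)`` to a list of GradientSet; the
    result is a tidy frame with mean and SD per component, means on the
    fraction scale.
    """
    import pandas as pd

    rows = []
    for (group, dataset), sets in gradient_sets.items():
        if not sets:
            raise ValueError(f"empty cell for group={group}, dataset={dataset}")
        ve = np.array([g.variance_explained for g in sets])
        for c in range(ve.shape[1]):
            rows.append(
                {
                    "group": group,
                    "dataset": dataset,
                    "component": c + 1,
                    "mean": float(ve[:, c].mean()),
                    "sd": float(ve[:, c].std(ddof=1)) if ve.shape[0] > 1 else 0.0,
                    "n": ve.shape[0],
                }
            )
    return pd.DataFrame(rows)
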