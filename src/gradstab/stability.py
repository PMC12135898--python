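"""Sliding-window stability of the dynamic functional gradient.

For each ROI the per-window "gradient relationship profile" is the vector of
absolute coordinate differences |g_roi - g_j| (one entry per other ROI) on a
chosen gradient component, window-averaged from the aligned per-TR maps.
Stability is Kendall's coefficient of concordance (W) of these profiles
across windows: W = 1 when the ROI keeps exactly the same relationship
ranking to the rest of the brain in every window, ~0 when the ranking is
reshuffled at random.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import STABILITY_COLUMNS, DynamicGradientStack, WindowScheme

__all__ = [
    "make_windows",
    "window_gradient",
    "window_gradients",
    "roi_gradient_profile",
    "kendalls_w",
    "stability_map",
    "stability_map_from_windows",
    "stability_map_dpl",
]

DEFAULT_WINDOW_S = 60.0
DEFAULT_STEP_S = 2.0


def make_windows(
    n_volumes: int,
    tr_s: float,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
) -> WindowScheme:
    """Sliding-window layout; e.g. 230 volumes at TR 2 s with a 60 s window
    and 2 s step gives 201 windows."""
    return WindowScheme(window_s=window_s, step_s=step_s, tr_s=tr_s, n_volumes=n_volumes)


def window_gradient(dyn: DynamicGradientStack, window: slice) -> np.ndarray:
    """Mean aligned gradient over one window's TRs (flagged TRs excluded)."""
    start, stop = window.start or 0, window.stop
    if stop is None or stop > dyn.n_volumes or start < 0:
        raise ValueError("window outside the dynamic stack")
    keep = ~dyn.flagged[start:stop]
    if not keep.any():
        raise ValueError(f"all TRs in window [{start}, {stop}) are flagged degenerate")
    return dyn.coords[start:stop][keep].mean(axis=0)


def window_gradients(dyn: DynamicGradientStack, scheme: WindowScheme) -> np.ndarray:
    """All window means at once: (n_windows, n_roi, n_components).

    Uses a cumulative sum over TRs so the cost is independent of the window
    length; flagged TRs are excluded from each window's average.
    """
    if scheme.n_volumes != dyn.n_volumes:
        raise ValueError("window scheme was built for a different session length")
    good = (~dyn.flagged).astype(float)
    coords = np.where(dyn.flagged[:, None, None], 0.0, dyn.coords)
    csum = np.concatenate([np.zeros((1,) + coords.shape[1:]), np.cumsum(coords, axis=0)])
    ccnt = np.concatenate([[0.0], np.cumsum(good)])
    starts = scheme.starts()
    stops = starts + scheme.window_tr
    counts = ccnt[stops] - ccnt[starts]
    if np.any(counts == 0):
        bad = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"all TRs in window {bad} are flagged degenerate")
    sums = csum[stops] - csum[starts]
    return sums / counts[:, None, None]


def roi_gradient_profile(window_grad: np.ndarray, roi: int, component: int) -> np.ndarray:
    """|g_roi - g_j| on one component for all j != roi (length n_roi - 1)."""
    g = window_grad[:, component]
    prof = np.abs(g[roi] - g)
    return np.delete(prof, roi)


def kendalls_w(rankings: np.ndarray) -> float:
    """Kendall's coefficient of concordance with mid-rank tie correction.

    ``rankings`` is an m x n value matrix (m judges ranking n items); values
    are converted to ranks per judge. W = 12 S / (m^2 (n^3 - n) - m sum_j T_j)
    with S the sum of squared deviations of item rank sums and
    T_j = sum (t^3 - t) over tie groups of judge j.
    """
    vals = np.asarray(rankings, dtype=float)
    if vals.ndim != 2 or vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need at least 2 judges and 2 items")
    m, n = vals.shape
    ranks = rankdata(vals, axis=1)
    rank_sums = ranks.sum(axis=0)
    S = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    T = _tie_correction(ranks)
    denom = m * m * (n**3 - n) - m * T
    if denom <= 0:
        raise ValueError("degenerate table: tie correction exhausts the denominator")
    return min(1.0, 12.0 * S / denom)


def _tie_correction(ranks: np.ndarray) -> float:
    """Sum over judges of sum(t^3 - t) across tie groups."""
    total = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        total += float(np.sum(counts.astype(float) ** 3 - counts))
    return total


def stability_map(
    dyn: DynamicGradientStack,
    scheme: WindowScheme,
    components: tuple[int, ...] = (0, 1),
    subject_id: str = "unknown",
    group: str = "unknown",
    session: str = "pre",
    roi_labels: list[str] | None = None,
    networks: list[str] | None = None,
) -> pd.DataFrame:
    """Per-ROI, per-component KCC stability table for one session.

    For each ROI and component the m = n_windows by n = n_roi - 1 profile
    matrix is ranked per window (mid-rank ties) and reduced to the
    tie-corrected Kendall's W.
    """
    wg = window_gradients(dyn, scheme)  # (m, n_roi, k)
    return stability_map_from_windows(
        wg,
        components=components,
        subject_id=subject_id,
        group=group,
        session=session,
        roi_labels=roi_labels,
        networks=networks,
    )


def stability_map_from_windows(
    wg: np.ndarray,
    components: tuple[int, ...] = (0, 1),
    subject_id: str = "unknown",
    group: str = "unknown",
    session: str = "pre",
    roi_labels: list[str] | None = None,
    networks: list[str] | None = None,
) -> pd.DataFrame:
    """KCC table from precomputed per-window gradient maps (m, n_roi, k);
    used by both window-aggregation modes (mean of per-TR gradients, or
    re-embedding of window-averaged dPL)."""
    m, n_roi, _ = wg.shape
    n_items = n_roi - 1
    # column indices excluding the ROI itself, per ROI
    base = np.arange(n_roi)
    cols = np.stack([np.delete(base, r) for r in range(n_roi)])  # (n_roi, n_items)
    rows = []
    for comp in components:
        g = wg[:, :, comp]  # (m, n_roi)
        # prof[roi, w, j] = |g[w, roi] - g[w, j]| for j != roi
        full = np.abs(g.T[:, :, None] - g[None, :, :])  # (roi, m, n_roi)
        prof = np.take_along_axis(full, cols[:, None, :], axis=2)
        w_vals = _kcc_over_windows(prof)
        for roi in range(n_roi):
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "session": session,
                    "roi_index": roi,
                    "roi_label": roi_labels[roi] if roi_labels else f"ROI_{roi + 1}",
                    "network": networks[roi] if networks else "NA",
                    "component": comp + 1,
                    "kcc": float(w_vals[roi]),
                }
            )
    return pd.DataFrame(rows, columns=STABILITY_COLUMNS)


def stability_map_dpl(
    dpl_matrices: np.ndarray,
    scheme: WindowScheme,
    subject_id: str = "unknown",
    group: str = "unknown",
    session: str = "pre",
    roi_labels: list[str] | None = None,
    networks: list[str] | None = None,
) -> pd.DataFrame:
    """Sensitivity-analysis variant: concordance of windowed dPL
    connectivity profiles, bypassing the gradient embedding.

    Each ROI's per-window profile is its window-averaged dPL row to all
    other ROIs. Records carry component 0 to mark the no-gradient path.
    """
    mats = np.asarray(dpl_matrices, dtype=float)
    T, n_roi, _ = mats.shape
    if scheme.n_volumes != T:
        raise ValueError("window scheme was built for a different session length")
    csum = np.concatenate([np.zeros((1, n_roi, n_roi)), np.cumsum(mats, axis=0)])
    starts = scheme.starts()
    stops = starts + scheme.window_tr
    wmean = (csum[stops] - csum[starts]) / scheme.window_tr  # (m, n, n)
    base = np.arange(n_roi)
    cols = np.stack([np.delete(base, r) for r in range(n_roi)])
    # prof[roi, w, j] = window-mean dPL between roi and j != roi
    prof = np.take_along_axis(wmean.transpose(1, 0, 2), cols[:, None, :], axis=2)
    w_vals = _kcc_over_windows(prof)
    rows = [
        {
            "subject_id": subject_id,
            "group": group,
            "session": session,
            "roi_index": roi,
            "roi_label": roi_labels[roi] if roi_labels else f"ROI_{roi + 1}",
            "network": networks[roi] if networks else "NA",
            "component": 0,
            "kcc": float(w_vals[roi]),
        }
        for roi in range(n_roi)
    ]
    return pd.DataFrame(rows, columns=STABILITY_COLUMNS)


def _kcc_over_windows(prof: np.ndarray) -> np.ndarray:
    """Kendall's W along the first axis of a (n_roi, m, n_items) stack.

    Continuous profiles make ties measure-zero, so ranks come from a double
    argsort; slices that do contain ties fall back to the tie-corrected
    scalar routine.
    """
    n_roi, m, n_items = prof.shape
    # single precision for the sort: orderings are identical unless two
    # profile entries sit within float32 resolution, and those slices take
    # the exact tie-corrected fallback below anyway
    prof32 = prof.astype(np.float32, copy=False)
    order = np.argsort(prof32, axis=2, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, n_items + 1)[None, None, :], axis=2)
    srt = np.take_along_axis(prof32, order, axis=2)
    tied = (np.diff(srt, axis=2) == 0).any(axis=2).any(axis=1)  # per ROI
    rank_sums = ranks.sum(axis=1, dtype=float)
    S = np.sum((rank_sums - rank_sums.mean(axis=1, keepdims=True)) ** 2, axis=1)
    w = 12.0 * S / (m * m * (n_items**3 - n_items))
    for roi in np.flatnonzero(tied):
        w[roi] = kendalls_w(prof[roi])
    return np.minimum(w, 1.0)
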