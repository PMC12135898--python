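"""Denoising of parcellated BOLD series.

Implements the standard resting-state chain on ROI time series: framewise
displacement screening (Power formulation), nuisance regression of motion and
tissue signals plus their temporal derivatives, and zero-phase temporal
bandpass filtering in the 0.01-0.1 Hz band. Spatial steps (realignment,
normalisation, segmentation) are out of scope; the chain starts at the
parcellated matrix. A toy volumetric ROI extractor is provided for testing
label-based extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import MotionTrace, NuisanceDesign, SessionSeries

__all__ = [
    "framewise_displacement",
    "screen_by_fd",
    "build_nuisance_design",
    "regress_nuisance",
    "bandpass",
    "extract_roi_series",
    "denoise_session",
    "ExclusionReport",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.2
DEFAULT_BAND_HZ = (0.01, 0.1)


def framewise_displacement(
    motion: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-volume framewise displacement in mm (Power et al. formulation).

    FD[t] is the sum of absolute backward differences of the six rigid-body
    parameters, with rotations converted to arc length on a sphere of
    ``head_radius`` mm. FD[0] = 0 by convention.
    """
    if motion.n_volumes < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    diffs = np.abs(np.diff(motion.params, axis=0))
    diffs[:, 3:] *= head_radius
    fd = np.zeros(motion.n_volumes)
    fd[1:] = diffs.sum(axis=1)
    return fd


@dataclass
class ExclusionReport:
    """Per-session mean FD with the exclusion decision."""

    rows: list[dict]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["subject_id", "session", "mean_fd", "excluded"])


def screen_by_fd(
    sessions: list[SessionSeries],
    motions: dict[tuple[str, str], MotionTrace],
    threshold: float = DEFAULT_FD_THRESHOLD_MM,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
) -> tuple[list[SessionSeries], ExclusionReport]:
    """Drop whole subjects whose any session exceeds mean FD ``threshold``.

    Subject-level exclusion is used because the session contrast needs both
    sessions of a subject; a subject failing in either scan is removed from
    all subsequent analysis.
    """
    mean_fd: dict[tuple[str, str], float] = {}
    bad_subjects: set[str] = set()
    for s in sessions:
        key = (s.subject_id, s.session_label)
        if key not in motions:
            raise KeyError(f"no motion trace for session {key}")
        fd = framewise_displacement(motions[key], head_radius)
        mean_fd[key] = float(fd.mean())
        if mean_fd[key] > threshold:
            bad_subjects.add(s.subject_id)
    rows = [
        {
            "subject_id": sub,
            "session": ses,
            "mean_fd": mean_fd[(sub, ses)],
            "excluded": sub in bad_subjects,
        }
        for (sub, ses) in sorted(mean_fd)
    ]
    retained = [s for s in sessions if s.subject_id not in bad_subjects]
    return retained, ExclusionReport(rows=rows)


def _backward_diff(x: np.ndarray) -> np.ndarray:
    """Backward temporal difference with a leading zero row."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def build_nuisance_design(
    motion: MotionTrace,
    csf: np.ndarray,
    wm: np.ndarray,
) -> NuisanceDesign:
    """Motion + CSF + WM regressors and their temporal derivatives.

    The base set is 6 motion parameters plus the two tissue mean signals;
    each column's backward-difference derivative (leading row zero-padded) is
    appended, giving 16 columns. Zero-variance columns (e.g. the derivative
    of a constant) are dropped with a warning so the design stays full rank.
    """
    csf = np.asarray(csf, dtype=float).ravel()
    wm = np.asarray(wm, dtype=float).ravel()
    n = motion.n_volumes
    if len(csf) != n or len(wm) != n:
        raise ValueError("motion, CSF and WM series must have equal length")

    base = np.column_stack([motion.params, csf, wm])
    base_names = [f"motion_{k}" for k in range(1, 7)] + ["csf", "wm"]
    deriv = _backward_diff(base)
    cols = np.column_stack([base, deriv])
    names = base_names + [f"d_{nm}" for nm in base_names]

    keep, kept_names = [], []
    for j, nm in enumerate(names):
        if np.allclose(cols[:, j], cols[0, j]):
            warnings.warn(f"dropping constant/zero nuisance column {nm!r}", stacklevel=2)
            continue
        keep.append(j)
        kept_names.append(nm)
    if not keep:
        raise ValueError("all nuisance columns are constant; nothing to regress")
    return NuisanceDesign(regressors=cols[:, keep], names=kept_names)


def regress_nuisance(series: SessionSeries, design: NuisanceDesign) -> SessionSeries:
    """Replace each ROI series by its residual against [intercept | design]."""
    if design.n_volumes != series.n_volumes:
        raise ValueError("design rows must match session volumes")
    X = np.column_stack([np.ones(series.n_volumes), design.regressors])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("nuisance design is rank deficient after guards")
    beta, *_ = np.linalg.lstsq(X, series.data, rcond=None)
    resid = series.data - X @ beta
    return series.replace_data(resid, step="regress")


def bandpass(
    series: SessionSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = 2,
) -> SessionSeries:
    """Zero-phase Butterworth bandpass (forward-backward, order per pass)."""
    nyq = 0.5 / series.tr_s
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie strictly inside (0, {nyq}) Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / series.tr_s, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=0)
    return series.replace_data(filtered, step="bandpass")


def denoise_session(
    series: SessionSeries,
    design: NuisanceDesign | None,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    filter_first: bool = False,
) -> SessionSeries:
    """Full denoising chain; regression before filtering by default.

    ``filter_first=True`` swaps the order for sensitivity analysis; the
    applied order is recorded in the output's processing flags either way.
    """
    steps = [
        lambda s: regress_nuisance(s, design) if design is not None else s.replace_data(
            s.data - s.data.mean(axis=0), step="demean"
        ),
        lambda s: bandpass(s, low_hz, high_hz),
    ]
    if filter_first:
        steps.reverse()
    out = series
    for step in steps:
        out = step(out)
    return out


def extract_roi_series(
    image_4d: np.ndarray,
    labels_3d: np.ndarray,
    tr_s: float,
    subject_id: str = "unknown",
    session_label: str = "pre",
    n_roi: int | None = None,
) -> SessionSeries:
    """Mean-over-voxels extraction from a toy 4-D array (x, y, z, t).

    ``labels_3d`` holds integer labels 0 (background) .. n_roi; every label
    1..n_roi must be present.
    """
    image_4d = np.asarray(image_4d, dtype=float)
    labels_3d = np.asarray(labels_3d)
    if image_4d.shape[:3] != labels_3d.shape:
        raise ValueError("image and label volumes have mismatched spatial shapes")
    present = np.unique(labels_3d)
    present = present[present > 0]
    if n_roi is None:
        n_roi = int(present.max()) if present.size else 0
    missing = sorted(set(range(1, n_roi + 1)) - set(int(v) for v in present))
    if missing:
        raise ValueError(f"label volume is missing ROIs: {missing}")
    n_t = image_4d.shape[3]
    data = np.empty((n_t, n_roi))
    flat = image_4d.reshape(-1, n_t)
    lab = labels_3d.ravel()
    for k in range(1, n_roi + 1):
        data[:, k - 1] = flat[lab == k].mean(axis=0)
    labels = [f"ROI_{k}" for k in range(1, n_roi + 1)]
    return SessionSeries(
        data=data, tr_s=tr_s, subject_id=subject_id, session_label=session_label, roi_labels=labels
    )
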