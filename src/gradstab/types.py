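"""Core data containers shared across the pipeline.

Conventions
-----------
* Time series are ``n_volumes x n_roi`` float arrays (rows = volumes).
* Motion parameters follow the rp-file convention: three translations in
  mm, then three rotations in radians.
* Stability records live in a long-format :class:`pandas.DataFrame` with
  the columns in :data:`STABILITY_COLUMNS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SessionSeries",
    "MotionTrace",
    "NuisanceDesign",
    "FCMatrix",
    "EmbeddingParams",
    "GradientSet",
    "GradientTemplate",
    "PhaseStack",
    "DPLStack",
    "DynamicGradientStack",
    "WindowScheme",
    "STABILITY_COLUMNS",
    "PRE",
    "POST",
]

#: canonical session labels (task-free / task-modulated resting scans)
PRE = "pre"
POST = "post"

#: columns of the long-format stability table
STABILITY_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "roi_index",
    "roi_label",
    "network",
    "component",
    "kcc",
]


@dataclass
class SessionSeries:
    """One subject-session's parcellated BOLD matrix (volumes x ROIs)."""

    data: np.ndarray
    tr_s: float
    subject_id: str
    session_label: str
    roi_labels: list[str]
    #: processing provenance flags, e.g. ("regress", "bandpass")
    processing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("series data must be 2-D (volumes x ROIs)")
        if self.data.shape[0] < 2:
            raise ValueError("a session needs at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.roi_labels)} ROI labels for {self.data.shape[1]} columns"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]

    def replace_data(self, data: np.ndarray, step: str | None = None) -> "SessionSeries":
        """Return a copy with new data and an appended processing flag."""
        flags = self.processing + ((step,) if step else ())
        return SessionSeries(
            data=data,
            tr_s=self.tr_s,
            subject_id=self.subject_id,
            session_label=self.session_label,
            roi_labels=list(self.roi_labels),
            processing=flags,
        )


@dataclass
class MotionTrace:
    """Six rigid-body parameters per volume (3 translations mm, 3 rotations rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be n_volumes x 6")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class NuisanceDesign:
    """Confound regressor matrix (no intercept; one is added at fit time)."""

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2:
            raise ValueError("design must be 2-D")
        if self.regressors.shape[1] != len(self.names):
            raise ValueError("one name per regressor column required")
        if self.regressors.shape[1] < 1:
            raise ValueError("design needs at least one column")

    @property
    def n_volumes(self) -> int:
        return self.regressors.shape[0]


@dataclass
class FCMatrix:
    """Square ROI x ROI connectivity-derived matrix.

    ``kind`` distinguishes the three stages of the affinity construction:
    ``pearson`` (full correlation), ``sparsified`` (row-thresholded, generally
    asymmetric) and ``affinity`` (cosine similarity, symmetric nonnegative).
    """

    values: np.ndarray
    kind: str
    density: float | None = None
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("FC matrix must be square")
        if self.kind not in ("pearson", "sparsified", "affinity"):
            raise ValueError(f"unknown FC kind {self.kind!r}")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass
class EmbeddingParams:
    """Diffusion-map embedding settings.

    alpha : anisotropic normalisation exponent (0 = graph Laplacian walk,
        1 = Laplace–Beltrami; 0.5 balances sampling density).
    diffusion_time : t in the eigenvalue scaling; t = 0 selects the
        lambda/(1-lambda) multiscale convention.
    n_components : nontrivial components retained.
    """

    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.diffusion_time < 0:
            raise ValueError("diffusion_time must be >= 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class GradientSet:
    """Embedding coordinates (n_roi x n_components) with spectrum metadata."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    degenerate: bool = False
    aligned: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)

    @property
    def n_roi(self) -> int:
        return self.coords.shape[0]

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class GradientTemplate:
    """Reference embedding every per-TR / per-session gradient is aligned to."""

    coords: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_roi(self) -> int:
        return self.coords.shape[0]

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class PhaseStack:
    """Instantaneous phases (n_volumes x n_roi), wrapped to (-pi, pi]."""

    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases contain non-finite values")
        # wrap into (-pi, pi]
        wrapped = np.mod(-self.phases + np.pi, 2 * np.pi)
        self.phases = -(wrapped - np.pi)

    @property
    def n_volumes(self) -> int:
        return self.phases.shape[0]

    @property
    def n_roi(self) -> int:
        return self.phases.shape[1]


@dataclass
class DPLStack:
    """Per-TR dynamic phase-locking matrices (n_volumes x n_roi x n_roi)."""

    matrices: np.ndarray

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices)
        if not np.issubdtype(self.matrices.dtype, np.floating):
            self.matrices = self.matrices.astype(float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("dPL stack must be n_volumes x n_roi x n_roi")

    @property
    def n_volumes(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_roi(self) -> int:
        return self.matrices.shape[1]


@dataclass
class DynamicGradientStack:
    """Template-aligned per-TR gradient coordinates.

    ``flagged`` marks TRs whose phase structure was degenerate (uniform
    affinity); those slices hold the degenerate zero embedding and are
    excluded from window averages downstream.
    """

    coords: np.ndarray  # n_volumes x n_roi x n_components
    eigenvalues: np.ndarray  # n_volumes x n_components
    flagged: np.ndarray = field(default=None)  # bool per TR

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("dynamic gradient stack must be 3-D")
        if self.flagged is None:
            self.flagged = np.zeros(self.coords.shape[0], dtype=bool)
        self.flagged = np.asarray(self.flagged, dtype=bool)

    @property
    def n_volumes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_roi(self) -> int:
        return self.coords.shape[1]

    @property
    def n_components(self) -> int:
        return self.coords.shape[2]


@dataclass
class WindowScheme:
    """Sliding-window layout in TR units, derived from second-valued settings."""

    window_s: float
    step_s: float
    tr_s: float
    n_volumes: int
    window_tr: int = field(init=False)
    step_tr: int = field(init=False)
    n_windows: int = field(init=False)

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        for name, value in (("window_s", self.window_s), ("step_s", self.step_s)):
            ratio = value / self.tr_s
            if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
                raise ValueError(f"{name}={value} is not a positive multiple of tr_s={self.tr_s}")
        self.window_tr = round(self.window_s / self.tr_s)
        self.step_tr = round(self.step_s / self.tr_s)
        if self.window_tr > self.n_volumes:
            raise ValueError(
                f"window of {self.window_tr} TRs exceeds session length {self.n_volumes}"
            )
        self.n_windows = math.floor((self.n_volumes - self.window_tr) / self.step_tr) + 1
        if self.n_windows < 2:
            raise ValueError("window scheme must produce at least 2 windows")

    def starts(self) -> np.ndarray:
        """Start TR index of every window."""
        return np.arange(self.n_windows) * self.step_tr

    def window(self, w: int) -> slice:
        """Half-open TR slice of window ``w``."""
        start = w * self.step_tr
        return slice(start, start + self.window_tr)


def empty_stability_table() -> pd.DataFrame:
    return pd.DataFrame(columns=STABILITY_COLUMNS)
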