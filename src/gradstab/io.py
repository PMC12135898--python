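"""Plain-text persistence for every pipeline artifact.

Sessions are TSV (header row of ROI labels, one row per volume) with a JSON
sidecar holding TR and identity metadata; motion follows the rp-file
convention (six whitespace-separated columns). Matrices and tables are TSV
with JSON sidecars; dynamic gradient stacks are compressed ``.npz`` arrays
(runtime artifacts, too large for text) with a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import DynamicGradientStack, FCMatrix, GradientSet, MotionTrace, SessionSeries

__all__ = [
    "write_session",
    "read_session",
    "write_motion",
    "read_motion",
    "write_matrix",
    "read_matrix",
    "write_gradient",
    "write_dynamic_stack",
    "write_dynamic_tr",
    "read_dynamic_stack",
    "write_table",
    "file_sha256",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_session(series: SessionSeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(series.data, columns=series.roi_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "tr_s": series.tr_s,
        "subject_id": series.subject_id,
        "session_label": series.session_label,
        "processing": list(series.processing),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_session(path: str | Path) -> SessionSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(_sidecar(path).read_text())
    return SessionSeries(
        data=df.to_numpy(dtype=float),
        tr_s=meta["tr_s"],
        subject_id=meta["subject_id"],
        session_label=meta["session_label"],
        roi_labels=list(df.columns),
        processing=tuple(meta.get("processing", [])),
    )


def write_motion(motion: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, motion.params, fmt="%.8e")
    return path


def read_motion(path: str | Path) -> MotionTrace:
    return MotionTrace(params=np.loadtxt(path, ndmin=2))


def write_matrix(fc: FCMatrix, path: str | Path, source: str = "") -> Path:
    path = Path(path)
    labels = fc.roi_labels or [f"ROI_{k + 1}" for k in range(fc.n_roi)]
    pd.DataFrame(fc.values, columns=labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    meta = {"kind": fc.kind, "density": fc.density, "source": source}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_matrix(path: str | Path) -> FCMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(_sidecar(path).read_text())
    return FCMatrix(
        values=df.to_numpy(dtype=float),
        kind=meta["kind"],
        density=meta.get("density"),
        roi_labels=list(df.columns),
    )


def write_gradient(gs: GradientSet, path: str | Path, roi_labels: list[str] | None = None) -> Path:
    path = Path(path)
    labels = roi_labels or [f"ROI_{k + 1}" for k in range(gs.n_roi)]
    cols = {f"g{c + 1}": gs.coords[:, c] for c in range(gs.n_components)}
    pd.DataFrame({"roi_label": labels, **cols}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    meta = {
        "eigenvalues": gs.eigenvalues.tolist(),
        "variance_explained": gs.variance_explained.tolist(),
        "variance_denominator": "all nontrivial nonnegative eigenvalues",
        "degenerate": gs.degenerate,
        "aligned": gs.aligned,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def write_dynamic_stack(dyn: DynamicGradientStack, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    np.savez_compressed(path, coords=dyn.coords, eigenvalues=dyn.eigenvalues, flagged=dyn.flagged)
    out = {"dims": list(dyn.coords.shape), "n_flagged": int(dyn.flagged.sum())}
    out.update(meta or {})
    _sidecar(path if path.suffix == ".npz" else path.with_suffix(".npz")).write_text(
        json.dumps(out, indent=1)
    )
    return path


def write_dynamic_tr(
    dyn: DynamicGradientStack, t: int, path: str | Path, roi_labels: list[str] | None = None
) -> Path:
    """Export one TR's aligned gradient map as TSV."""
    from .types import GradientSet

    gs = GradientSet(
        coords=dyn.coords[t],
        eigenvalues=dyn.eigenvalues[t],
        variance_explained=np.zeros_like(dyn.eigenvalues[t]),
        degenerate=bool(dyn.flagged[t]),
        aligned=True,
    )
    return write_gradient(gs, path, roi_labels)


def read_dynamic_stack(path: str | Path) -> DynamicGradientStack:
    with np.load(path) as z:
        return DynamicGradientStack(
            coords=z["coords"], eigenvalues=z["eigenvalues"], flagged=z["flagged"]
        )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
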