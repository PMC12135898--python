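"""End-to-end orchestration: cohort in, stability table and statistics out.

Stages: FD screening -> nuisance regression + bandpass -> static connectome
affinities -> group template (mean pre-task affinity) -> per-TR phase-locking
gradients aligned to the template -> sliding-window Kendall's-W stability ->
group statistics. Each stage is also usable on its own; this module only
wires the declared interfaces together.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectome, dynamics, preprocess, stability
from .gradient import (
    EmbeddingParams,
    build_group_template,
    diffusion_embed,
    procrustes_align,
    variance_explained_summary,
)
from .synth import SyntheticCohort
from .types import PRE, GradientTemplate, SessionSeries

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "session_stability_table"]


@dataclass
class PipelineConfig:
    fd_threshold_mm: float = preprocess.DEFAULT_FD_THRESHOLD_MM
    band_hz: tuple[float, float] = preprocess.DEFAULT_BAND_HZ
    filter_first: bool = False
    density: float = connectome.DEFAULT_DENSITY
    embedding: EmbeddingParams = field(default_factory=lambda: EmbeddingParams(n_components=10))
    dpl_affinity_mode: str = "sparse-cosine"
    window_s: float = stability.DEFAULT_WINDOW_S
    step_s: float = stability.DEFAULT_STEP_S
    components: tuple[int, ...] = (0, 1)  # zero-based gradient components
    #: restrict the (expensive) dynamic-stability stage to these groups;
    #: None = all groups. Static connectomes and the template always use
    #: every retained subject.
    stability_groups: tuple[str, ...] | None = None
    #: "gradient": KCC of gradient relationship profiles (default);
    #: "dpl": KCC of windowed dPL connectivity profiles (no embedding)
    profile_mode: str = "gradient"
    #: "mean": window = mean of per-TR aligned gradients (default);
    #: "reembed": window = embedding of the window-averaged dPL
    window_mode: str = "mean"


@dataclass
class PipelineResult:
    stability: pd.DataFrame
    template: GradientTemplate
    exclusions: pd.DataFrame
    variance_summary: pd.DataFrame
    #: per (subject, session): variance explained of the static embedding
    static_variance: pd.DataFrame
    timings: dict = field(default_factory=dict)
    flagged_trs: int = 0


def _denoise(cohort: SyntheticCohort, series: SessionSeries, cfg: PipelineConfig) -> SessionSeries:
    key = (series.subject_id, series.session_label)
    design = preprocess.build_nuisance_design(
        cohort.motions[key], cohort.nuisance[key]["csf"], cohort.nuisance[key]["wm"]
    )
    return preprocess.denoise_session(
        series, design, *cfg.band_hz, filter_first=cfg.filter_first
    )


def session_stability_table(
    clean: SessionSeries,
    template: GradientTemplate,
    cfg: PipelineConfig,
    group: str,
    networks: list[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Stability records for one denoised session; returns (table, n_flagged_trs)."""
    phases = dynamics.hilbert_phase(clean)
    dpl = dynamics.dpl_stack(phases, dtype=np.float32)
    scheme = stability.make_windows(clean.n_volumes, clean.tr_s, cfg.window_s, cfg.step_s)
    meta = dict(
        subject_id=clean.subject_id,
        group=group,
        session=clean.session_label,
        roi_labels=clean.roi_labels,
        networks=networks,
    )
    if cfg.profile_mode == "dpl":
        table = stability.stability_map_dpl(
            np.asarray(dpl.matrices, dtype=float), scheme, **meta
        )
        return table, 0
    if cfg.profile_mode != "gradient":
        raise ValueError(f"unknown profile mode {cfg.profile_mode!r}")

    if cfg.window_mode == "reembed":
        wg = dynamics.windowed_dpl_gradients(
            dpl, template, scheme,
            params=cfg.embedding, density=cfg.density,
            affinity_mode=cfg.dpl_affinity_mode,
        )
        table = stability.stability_map_from_windows(wg, components=cfg.components, **meta)
        return table, 0
    if cfg.window_mode != "mean":
        raise ValueError(f"unknown window mode {cfg.window_mode!r}")

    dyn = dynamics.dynamic_gradients(
        dpl,
        template,
        params=cfg.embedding,
        density=cfg.density,
        affinity_mode=cfg.dpl_affinity_mode,
    )
    table = stability.stability_map(dyn, scheme, components=cfg.components, **meta)
    return table, int(dyn.flagged.sum())


def run_pipeline(cohort: SyntheticCohort, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Full analysis on an in-memory cohort."""
    cfg = cfg or PipelineConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    retained, report = preprocess.screen_by_fd(
        cohort.sessions, cohort.motions, threshold=cfg.fd_threshold_mm
    )
    groups = cohort.manifest.set_index("subject_id")["group"].to_dict()
    networks = cohort.truth.networks
    timings["screen"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clean_sessions = [_denoise(cohort, s, cfg) for s in retained]
    timings["denoise"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    affinities = {
        (s.subject_id, s.session_label): connectome.session_affinity(s, cfg.density)
        for s in clean_sessions
    }
    pre_affinities = [a for (sub, ses), a in affinities.items() if ses == PRE]
    template = build_group_template(pre_affinities, cfg.embedding)
    timings["template"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    static_rows = []
    grad_sets: dict[tuple[str, str], list] = {}
    for s in clean_sessions:
        gs = procrustes_align(diffusion_embed(affinities[(s.subject_id, s.session_label)], cfg.embedding), template)
        grad_sets.setdefault((groups[s.subject_id], s.session_label), []).append(gs)
        for c, ve in enumerate(gs.variance_explained):
            static_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": groups[s.subject_id],
                    "session": s.session_label,
                    "component": c + 1,
                    "variance_explained": float(ve),
                }
            )
    static_variance = pd.DataFrame(static_rows)
    variance_summary = variance_explained_summary(grad_sets)
    timings["static_gradients"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tables = []
    flagged = 0
    stab_sessions = [
        s
        for s in clean_sessions
        if cfg.stability_groups is None or groups[s.subject_id] in cfg.stability_groups
    ]
    for s in stab_sessions:
        table, n_flag = session_stability_table(
            s, template, cfg, group=groups[s.subject_id], networks=networks
        )
        tables.append(table)
        flagged += n_flag
    stab = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    timings["stability"] = time.perf_counter() - t0

    return PipelineResult(
        stability=stab,
        template=template,
        exclusions=report.to_frame(),
        variance_summary=variance_summary,
        static_variance=static_variance,
        timings=timings,
        flagged_trs=flagged,
    )
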