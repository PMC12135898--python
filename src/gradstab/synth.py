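"""Synthetic cohort generator with known ground truth.

The generative model is a phase-coupled oscillator field: every ROI carries a
band-limited oscillation (base frequency ~0.05 Hz) whose phase is the sum of
a community-level stochastic phase, a per-ROI phase-noise process and a small
deterministic hierarchy lag. Community phases are correlated Ornstein-
Uhlenbeck deviations whose cross-correlation decays with distance along a
unimodal -> transmodal hierarchy axis, so static connectivity (and therefore
the principal diffusion gradient) orders communities by hierarchy. The
per-ROI phase-noise process is the Kuramoto-style dispersion term: its
standard deviation shrinks as ``coupling_strength`` grows.

Session effects are planted physiologically, not statistically: for effect
ROIs in the post-task session of the effect group, the per-ROI phase-noise
SD is reduced by a fraction ``stability_shift * a_s`` where ``a_s`` is the
subject's realized effect amplitude. Lower phase noise makes the region's
gradient relationship profile more consistent across windows, which raises
its Kendall's-W stability only after travelling through the entire pipeline.
IELT is co-generated with ``a_s`` (coupled to the standardised amplitude)
so that the correlation between the per-subject stability change and IELT
equals ``planted_corr`` in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .stability import DEFAULT_WINDOW_S
from .types import POST, PRE, MotionTrace, SessionSeries

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticCohort",
    "NETWORK_NAMES",
    "generate_cohort",
    "generate_motion",
]

#: seven canonical large-scale systems, ordered along the hierarchy axis
NETWORK_NAMES = ["Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default"]
#: hierarchy position of each community on the unimodal->transmodal axis
NETWORK_HIERARCHY = np.array([0.03, 0.12, 0.32, 0.48, 0.60, 0.78, 0.95])

#: group-wise clinical score distributions: mean, SD per instrument
DEFAULT_CLINICAL_PARAMS = {
    "patient": {
        "age": (27.43, 4.16),
        "ielt": (0.83, 0.41),
        "cipe5": (8.85, 2.10),
        "iief5": (23.86, 1.15),
    },
    "control": {
        "age": (27.59, 3.72),
        "ielt": (10.75, 6.42),
        "cipe5": (22.06, 2.01),
        "iief5": (24.12, 0.70),
    },
}

_MARITAL_P = {"patient": [0.4643, 0.5357], "control": [0.4117, 0.5883]}
_EDUCATION_P = {"patient": [0.1429, 0.3214, 0.5357], "control": [0.1176, 0.4117, 0.4707]}
_IELT_FLOOR_MIN = 0.1
_SCORE_RANGES = {"cipe5": (5.0, 25.0), "iief5": (5.0, 25.0)}


@dataclass
class SynthConfig:
    """Cohort-level generative settings (defaults emulate the study design)."""

    n_patients: int = 28
    n_controls: int = 17
    n_roi: int = 400
    n_volumes: int = 230
    tr_s: float = 2.0
    noise_sd: float = 0.15
    coupling_strength: float = 1.0
    stability_shift: float = 0.45
    n_effect_roi: int = 20
    planted_corr: float = -0.6
    effect_groups: tuple[str, ...] = ("patient",)
    effect_amp_sd: float = 0.35
    clinical_params: dict = field(default_factory=lambda: DEFAULT_CLINICAL_PARAMS)
    seed: int = 0
    # oscillator field details
    #: carrier frequency band (Hz); a single common carrier keeps subject
    #: heterogeneity in the phase field rather than the oscillation rate
    base_freq_hz: tuple[float, float] = (0.05, 0.05)
    community_phase_sd: float = 1.0
    community_tau_s: float = 20.0
    roi_phase_sd: float = 0.65
    roi_tau_s: float = 10.0
    hierarchy_corr_length: float = 0.35
    #: floor on cross-ROI phase correlation; emulates the global BOLD
    #: component that keeps real connectomes connected at sparse densities
    community_corr_floor: float = 0.25
    #: extra phase correlation between ROIs of the same community
    community_bonus: float = 0.15
    hierarchy_jitter: float = 0.03
    phase_lag_scale: float = 0.05
    #: fraction of idiosyncratic phase-noise variance that is session-specific
    #: (the rest is part of the subject's dynamic fingerprint, shared pre/post)
    session_noise_frac: float = 0.05
    motion_amplitude: float = 0.5
    motion_spike_prob: float = 0.02

    def validate(self) -> None:
        if self.n_roi < 2 or self.n_volumes < 2:
            raise ValueError("need at least 2 ROIs and 2 volumes")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_volumes * self.tr_s < DEFAULT_WINDOW_S:
            raise ValueError(
                f"session of {self.n_volumes * self.tr_s:.0f} s is shorter than the "
                f"{DEFAULT_WINDOW_S:.0f} s stability window"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.coupling_strength <= 0:
            raise ValueError("coupling_strength must be positive")
        if not -1.0 <= self.planted_corr <= 1.0:
            raise ValueError("planted_corr must be a correlation in [-1, 1]")


@dataclass
class GroundTruth:
    """Generative parameters the pipeline should recover."""

    roi_community: np.ndarray  # community index per ROI, 1..7
    hierarchy_score: np.ndarray  # per-ROI position in [0, 1]
    planted_effect: dict  # session label -> per-ROI signed perturbation
    planted_corr: float
    effect_rois: np.ndarray  # indices of ROIs carrying the planted effect
    subject_amplitude: dict  # subject_id -> realized effect amplitude a_s

    @property
    def networks(self) -> list[str]:
        return [NETWORK_NAMES[c - 1] for c in self.roi_community]


@dataclass
class SyntheticCohort:
    manifest: pd.DataFrame
    truth: GroundTruth
    sessions: list[SessionSeries]
    motions: dict[tuple[str, str], MotionTrace]
    nuisance: dict[tuple[str, str], dict[str, np.ndarray]]
    config: SynthConfig


def _community_layout(cfg: SynthConfig, rng: np.random.Generator):
    """Assign ROIs to the 7 communities and draw hierarchy scores.

    The hierarchy axis is continuous: ROI scores are evenly spaced over
    [0, 1] (plus jitter) and the communities are contiguous bins along the
    axis, mirroring the smooth unimodal -> transmodal organisation on which
    the canonical systems sit.
    """
    n_comm = len(NETWORK_NAMES)
    sizes = np.full(n_comm, cfg.n_roi // n_comm)
    sizes[: cfg.n_roi % n_comm] += 1
    community = np.repeat(np.arange(1, n_comm + 1), sizes)
    base = (np.arange(cfg.n_roi) + 0.5) / cfg.n_roi
    jitter = rng.uniform(-cfg.hierarchy_jitter, cfg.hierarchy_jitter, size=cfg.n_roi)
    hierarchy = np.clip(base + jitter, 0.0, 1.0)
    return community, hierarchy


def _ou_step_factors(tau_s: float, dt: float) -> tuple[float, float]:
    a = math.exp(-dt / tau_s)
    return a, math.sqrt(max(0.0, 1.0 - a * a))


def _phase_field_cholesky(cfg: SynthConfig, community: np.ndarray, hierarchy: np.ndarray) -> np.ndarray:
    """Cholesky factor of the ROI-level phase-field correlation.

    Correlation between two ROIs decays smoothly with their hierarchy
    distance (a 1-D manifold kernel, which makes the principal diffusion
    gradient a single dominant monotone axis), with a same-community bonus
    and a global floor. The matrix is renormalised to unit diagonal.
    """
    dist = np.abs(hierarchy[:, None] - hierarchy[None, :])
    same = (community[:, None] == community[None, :]).astype(float)
    floor, bonus = cfg.community_corr_floor, cfg.community_bonus
    smooth = max(0.0, 1.0 - floor - bonus)
    cov = smooth * np.exp(-dist / cfg.hierarchy_corr_length) + bonus * same + floor
    cov /= cov[0, 0]
    return np.linalg.cholesky(cov + 1e-10 * np.eye(cfg.n_roi))


def _simulate_session(
    cfg: SynthConfig,
    field_chol: np.ndarray,
    hierarchy: np.ndarray,
    roi_sigma: np.ndarray,
    f0_hz: float,
    rng: np.random.Generator,
    field_z: np.ndarray,
    roi_z: np.ndarray,
) -> np.ndarray:
    """One session's n_volumes x n_roi signal matrix.

    ``field_z`` and ``roi_z`` hold innovation draws for the correlated
    field and the idiosyncratic phase noise. Both of a subject's sessions
    share ``field_z`` fully and ``roi_z`` partially (see
    ``session_noise_frac``): the phase dynamics are a subject-level
    fingerprint, so a session contrast isolates session-specific change.
    """
    n_t, n_roi = cfg.n_volumes, cfg.n_roi
    dt = cfg.tr_s

    # correlated ROI phase field (exact OU discretisation)
    a_c, b_c = _ou_step_factors(cfg.community_tau_s, dt)
    u = np.empty((n_t, n_roi))
    u[0] = cfg.community_phase_sd * (field_chol @ field_z[0])
    for t in range(1, n_t):
        u[t] = a_c * u[t - 1] + b_c * cfg.community_phase_sd * (field_chol @ field_z[t])

    # per-ROI phase noise (independent OU streams, stationary init)
    a_r, b_r = _ou_step_factors(cfg.roi_tau_s, dt)
    v = np.empty((n_t, n_roi))
    v[0] = roi_sigma * roi_z[0]
    for t in range(1, n_t):
        v[t] = a_r * v[t - 1] + b_r * roi_sigma * roi_z[t]

    lag = 2.0 * np.pi * cfg.phase_lag_scale * hierarchy
    tgrid = np.arange(n_t)[:, None] * dt
    theta = 2.0 * np.pi * f0_hz * tgrid + u + v + lag[None, :]
    x = np.cos(theta)
    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * rng.standard_normal((n_t, n_roi))
    return x


def _roi_sigma(cfg: SynthConfig, hierarchy: np.ndarray) -> np.ndarray:
    """Baseline per-ROI phase-noise SD: shrinks with coupling, grows with
    hierarchy (transmodal phase dispersion exceeds unimodal)."""
    base = cfg.roi_phase_sd / cfg.coupling_strength
    return base * (0.7 + 0.6 * hierarchy)


def _censored_normal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and SD of max(0, N(mu, sigma^2))."""
    if sigma <= 0:
        return mu, 1.0
    from scipy.stats import norm

    a = mu / sigma
    m1 = mu * norm.cdf(a) + sigma * norm.pdf(a)
    m2 = (mu * mu + sigma * sigma) * norm.cdf(a) + mu * sigma * norm.pdf(a)
    var = max(m2 - m1 * m1, 1e-12)
    return m1, math.sqrt(var)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int):
    out = rng.normal(mean, sd, size=size)
    return np.clip(out, lo, hi)


def generate_motion(
    n_volumes: int,
    amplitude: float = 0.5,
    spike_prob: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> MotionTrace:
    """Smooth six-parameter random walk with occasional displacement spikes.

    ``amplitude`` scales the walk (mm for translations; rotations are scaled
    so their arc length at 50 mm matches the translations).
    """
    if n_volumes < 2:
        raise ValueError("motion trace needs at least 2 volumes")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    step_sd = np.array([0.01, 0.01, 0.01, 0.0002, 0.0002, 0.0002]) * amplitude
    steps = rng.standard_normal((n_volumes, 6)) * step_sd
    steps[0] = 0.0
    # light smoothing keeps the walk physiological rather than white
    if n_volumes >= 4 and amplitude > 0:
        kernel = np.array([0.25, 0.5, 0.25])
        steps = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, steps)
    params = np.cumsum(steps, axis=0)
    if spike_prob > 0 and amplitude > 0:
        spikes = rng.random(n_volumes) < spike_prob
        spikes[0] = False
        jumps = rng.standard_normal((n_volumes, 6)) * step_sd * 25.0
        params[spikes] += jumps[spikes]
    return MotionTrace(params=params)


def _nuisance_signals(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Synthetic CSF / WM mean signals: band-limited noise plus slow drift."""
    n = cfg.n_volumes
    out = {}
    sos = sp_signal.butter(2, [0.01, 0.1], btype="bandpass", fs=1.0 / cfg.tr_s, output="sos")
    for name in ("csf", "wm"):
        raw = rng.standard_normal(n + 40)
        band = sp_signal.sosfiltfilt(sos, raw)[20:-20]
        drift = np.linspace(0, rng.normal(0, 0.5), n)
        out[name] = band + drift
    return out


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Full two-session cohort: signals, motion, nuisance and clinical scores.

    Deterministic given ``config.seed``; each subject draws from its own
    spawned random substream, so growing the cohort leaves existing subjects
    byte-identical.
    """
    cfg = config
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    cohort_ss, *subject_ss = root.spawn(1 + cfg.n_patients + cfg.n_controls)
    layout_rng = np.random.default_rng(cohort_ss)

    community, hierarchy = _community_layout(cfg, layout_rng)
    field_chol = _phase_field_cholesky(cfg, community, hierarchy)
    sigma0 = _roi_sigma(cfg, hierarchy)
    roi_labels = [
        f"{NETWORK_NAMES[c - 1]}_{i + 1}" for i, c in enumerate(community)
    ]

    # effect ROIs: drawn from the transmodal (Default) community
    default_rois = np.flatnonzero(community == len(NETWORK_NAMES))
    n_eff = min(cfg.n_effect_roi, default_rois.size)
    effect_rois = default_rois[:n_eff]
    # the shift is split across sessions: elevated phase noise pre, reduced
    # post, so the pre->post stability change carries the full contrast
    planted = {PRE: np.zeros(cfg.n_roi), POST: np.zeros(cfg.n_roi)}
    planted[PRE][effect_rois] = -cfg.stability_shift
    planted[POST][effect_rois] = cfg.stability_shift

    groups = ["patient"] * cfg.n_patients + ["control"] * cfg.n_controls
    manifest_rows = []
    sessions: list[SessionSeries] = []
    motions: dict[tuple[str, str], MotionTrace] = {}
    nuisance: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    subject_amp: dict[str, float] = {}

    rho = cfg.planted_corr
    for k, (group, ss) in enumerate(zip(groups, subject_ss)):
        subject_id = f"sub-{k + 1:03d}"
        rng = np.random.default_rng(ss)
        cp = cfg.clinical_params[group]

        # latent effect amplitude (normal around 1, censored at 0) and the
        # correlated IELT draw: IELT couples to the amplitude standardised by
        # its exact censored-normal moments, so corr(amplitude, IELT) equals
        # planted_corr exactly in the population
        z = rng.standard_normal()
        w = rng.standard_normal()
        has_effect = group in cfg.effect_groups and cfg.stability_shift != 0
        amp = max(0.0, 1.0 + cfg.effect_amp_sd * z) if has_effect else 0.0
        subject_amp[subject_id] = amp
        ielt_mu, ielt_sd = cp["ielt"]
        if has_effect:
            amp_mean, amp_scale = _censored_normal_moments(1.0, cfg.effect_amp_sd)
            amp_std = (amp - amp_mean) / amp_scale
            ielt = ielt_mu + ielt_sd * (
                rho * amp_std + math.sqrt(max(0.0, 1 - rho * rho)) * w
            )
        else:
            ielt = ielt_mu + ielt_sd * w
        ielt = max(_IELT_FLOOR_MIN, float(ielt))

        age = float(np.round(_truncnorm(rng, *cp["age"], 18, 60, 1)[0], 1))
        cipe5 = float(np.round(np.clip(rng.normal(*cp["cipe5"]), *_SCORE_RANGES["cipe5"])))
        iief5 = float(np.round(np.clip(rng.normal(*cp["iief5"]), *_SCORE_RANGES["iief5"])))
        marital = ["single", "married"][rng.choice(2, p=_MARITAL_P[group])]
        education = ["elementary", "high_school", "university"][
            rng.choice(3, p=_EDUCATION_P[group])
        ]
        manifest_rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "age": age,
                "marital": marital,
                "education": education,
                "ielt": round(ielt, 3),
                "cipe5": cipe5,
                "iief5": iief5,
            }
        )

        f0 = rng.uniform(*cfg.base_freq_hz)
        # the phase dynamics are a subject-level fingerprint: the field
        # innovations are shared by both sessions, the idiosyncratic
        # innovations partially so
        field_z = rng.standard_normal((cfg.n_volumes, cfg.n_roi))
        shared_z = rng.standard_normal((cfg.n_volumes, cfg.n_roi))
        w_new = cfg.session_noise_frac
        for session in (PRE, POST):
            sigma = sigma0.copy()
            if has_effect:
                # positive planted values deflate the ROI's idiosyncratic
                # phase noise (stabilise), negative values inflate it; the
                # floor keeps effect ROIs from becoming mutually degenerate
                factor = np.clip(1.0 - amp * planted[session], 0.1, None)
                sigma = sigma * factor
            roi_z = (
                math.sqrt(1.0 - w_new) * shared_z
                + math.sqrt(w_new) * rng.standard_normal((cfg.n_volumes, cfg.n_roi))
            )
            data = _simulate_session(cfg, field_chol, hierarchy, sigma, f0, rng, field_z, roi_z)
            sessions.append(
                SessionSeries(
                    data=data,
                    tr_s=cfg.tr_s,
                    subject_id=subject_id,
                    session_label=session,
                    roi_labels=roi_labels,
                )
            )
            motions[(subject_id, session)] = generate_motion(
                cfg.n_volumes, cfg.motion_amplitude, cfg.motion_spike_prob, seed=rng
            )
            nuisance[(subject_id, session)] = _nuisance_signals(cfg, rng)

    truth = GroundTruth(
        roi_community=community,
        hierarchy_score=hierarchy,
        planted_effect=planted,
        planted_corr=cfg.planted_corr,
        effect_rois=effect_rois,
        subject_amplitude=subject_amp,
    )
    manifest = pd.DataFrame(manifest_rows)
    return SyntheticCohort(
        manifest=manifest,
        truth=truth,
        sessions=sessions,
        motions=motions,
        nuisance=nuisance,
        config=cfg,
    )
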