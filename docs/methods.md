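# Methods

## Overview

`gradstab` implements a stability analysis of dynamic functional gradients
(DFG) for two-session (pre/post) resting-state fMRI designs, driven entirely
by a synthetic-cohort generator. The analysis chain is:

1. **Denoising** of parcellated BOLD series: framewise-displacement (FD)
   screening, nuisance regression (motion, CSF, WM, temporal derivatives),
   zero-phase bandpass 0.01–0.1 Hz.
2. **Static connectome**: Pearson correlation → row-wise sparsification →
   cosine-similarity affinity.
3. **Gradients**: diffusion-map embedding of the affinity (α = 0.5, t = 0),
   a group template from the mean pre-session affinity, and orthogonal
   Procrustes alignment of every embedding to the template.
4. **Phase-locking dynamics**: Hilbert-transform instantaneous phases, a
   dynamic phase-locking (dPL) matrix `cos(θ_i − θ_j)` at every TR, per-TR
   gradient embeddings aligned to the template.
5. **Stability**: sliding windows (60 s window, 2 s step; 201 windows for
   230 volumes at TR 2 s) over the per-TR gradients; for each ROI and
   gradient component, Kendall's coefficient of concordance (KCC/W) of the
   ROI's "gradient relationship profile" — the vector of absolute
   coordinate differences to all other ROIs — across windows.
6. **Statistics**: within-group pre/post contrasts per ROI × component via
   a linear mixed-effects model with subject random intercepts and
   Bonferroni control (0.05/400 = 0.000125 at the full atlas scale);
   network-level Cohen's d and two-sample Kolmogorov–Smirnov distances;
   Pearson correlation of per-subject stability change with IELT; group
   descriptives (t / chi-squared).

## Model details and numerical choices

**Diffusion embedding.** The affinity `W` is normalised anisotropically,
`W' = D^(−α) W D^(−α)` with `D = diag(row sums)` and α = 0.5, and the Markov
operator `P = D'^(−1) W'` is eigendecomposed through its symmetric conjugate
`S = D'^(−1/2) W' D'^(−1/2)` (dense `eigh`; all matrices here are ≤ 400 ×
400). The trivial stationary eigenvector (λ = 1) is discarded. Component
coordinates are unit-norm eigenvectors scaled by `λ/(1−λ)` at diffusion time
t = 0 (the multiscale convention of the gradient toolboxes) or `λ^t`
otherwise. Variance explained uses all nontrivial nonnegative eigenvalues in
the denominator (recorded in output metadata). Eigenvector sign is fixed by
making the largest-magnitude entry positive. A graph with multiple unit
eigenvalues (disconnected affinity) is rejected with advice to raise the
sparsification density; a slice with no nontrivial spectrum (uniform
affinity) is flagged degenerate and embeds to zero.

**Sparsification and cosine affinity.** Each connectivity row keeps its top
`ceil(density·(n−1))` off-diagonal entries (ties broken toward the lower
column index, making the support deterministic). Cosine similarity between
rows `i` and `j` excludes positions `i` and `j` from both vectors, so
identical connectivity profiles get affinity exactly 1; negative cosines are
clipped to 0 (diffusion kernels need nonnegative weights). Density defaults
to 10% at the 400-ROI scale; reduced-scale runs (100 ROIs) use 20% because
a 100-node graph at 10-entry rows routinely disconnects.

**dPL → affinity.** The signed per-TR dPL matrix enters the embedding
through the same sparsify → cosine path as the static connectome (negative
survivors are clipped at the cosine step); the alternative
`(1 + dPL)/2` shift is available via `affinity_mode="shift"`. The per-TR
linear algebra runs in single precision by default (coordinate error
~1e−6, far below the rank resolution the concordance statistic consumes);
the static path is double precision throughout.

**Stability.** Window aggregation is the mean of per-TR aligned gradient
coordinates (not a re-embedding of window-averaged dPL). Kendall's W uses
mid-rank ties and the standard tie correction; the batched path uses
tie-free double-argsort ranks and falls back to the corrected scalar
routine for windows that actually contain ties. The ROI profile on a
component is `|g_roi − g_j|` for all j ≠ roi: it is per-ROI, rankable per
window, and defined per gradient component. Flagged (degenerate) TRs are
excluded from window means; a window with all TRs flagged is an error.

**Mixed model.** With two sessions per subject and a single random
intercept, the REML solution is closed-form: the session effect equals the
mean paired difference, its standard error is `sd(diff)/√n`, and the Wald t
equals the paired t with exact Satterthwaite df = n − 1. This closed form is
the default; `method="mixedlm"` routes through statsmodels MixedLM (REML,
Powell optimisation) and agrees to ~1e−8 — it is the cross-check and the
fallback for unbalanced data. `F_main = t²` with (1, n−1) df for the
balanced design; the df convention is recorded on every result. The
Bonferroni divisor defaults to the atlas ROI count (400) even when two
components are screened, matching the conventional printed threshold;
`n_tests` is configurable (reduced-scale screens use the number of tests
actually run). Cohen's d at network level uses the SD of paired ROI
differences; zero-variance cases return flagged results instead of raising.

## The synthetic cohort generator

The generator is a phase-coupled oscillator field chosen because the
analysis statistic is phase-locking concordance:

* Every ROI oscillates at a common 0.05 Hz carrier. Its phase adds (a) a
  **correlated field deviation** `u_i(t)`: an Ornstein–Uhlenbeck process
  (τ = 20 s, SD 1.0 rad) whose cross-ROI correlation decays smoothly with
  distance along a continuous unimodal→transmodal hierarchy axis
  (correlation length 0.35), plus a same-community bonus (0.15) and a
  global floor (0.25) that stands in for the global BOLD component and
  keeps sparse affinity graphs connected; (b) an **idiosyncratic
  deviation** `v_i(t)` (OU, τ = 10 s) whose SD shrinks with
  `coupling_strength` and grows with hierarchy position (transmodal cortex
  disperses more); and (c) a small deterministic hierarchy lag. The smooth
  1-D kernel makes the principal diffusion gradient a single dominant
  monotone axis, recoverable from the aligned group-mean gradient with
  Spearman |ρ| ≳ 0.9.
* Signals are `cos(phase)` plus white measurement noise (SD 0.15); after
  the pipeline's own bandpass > 95% of the variance lies in 0.01–0.1 Hz.
* **Dynamic fingerprint.** Both of a subject's sessions share the field
  innovation draws entirely and the idiosyncratic innovations up to a
  session-specific fraction (5% of variance by default). This places the
  generator at the optimistic end of test–retest reliability for dynamic
  features: paired session contrasts are correspondingly precise, and the
  planted effects below are calibrated against that baseline. Real scan
  pairs separated by ~30 min share less state; passing recovery tests here
  demonstrates that the pipeline transmits planted effects faithfully, not
  that effects of this size are detectable in noisier real data.
* **Planted stability effect.** For effect ROIs (20 ROIs of the transmodal
  community by default) in the effect group, the idiosyncratic phase-noise
  SD is inflated by `1 + a_s·shift` pre-session and deflated by
  `1 − a_s·shift` post-session (floored at 0.1 of baseline — complete
  phase-noise removal would make effect ROIs mutually degenerate, with
  near-tied profiles whose ranks churn, destroying rather than raising
  concordance). The effect must travel through phases → dPL → embedding →
  alignment → windows → ranks before it reaches the statistic.
* **Subject amplitude and IELT.** The realized amplitude is a censored
  normal, `a_s = max(0, 1 + σ_a z)` (near-Gaussian, so sample correlations
  at small n are well behaved); IELT is drawn with its group mean ± SD but
  coupled to the amplitude standardised by its exact censored-normal
  moments, so the planted correlation holds exactly in the population and
  any shortfall in recovery is attributable to the measurement pipeline. Clinical scores are truncated
  to instrument ranges (IELT ≥ 0.1 min, questionnaire scores within 5–25).
* One master seed spawns one substream per subject, so growing the cohort
  leaves existing subjects byte-identical.

**Default calibration.** `stability_shift = 0.45` with amplitude SD 0.35
produces a standardized paired effect of roughly 0.8-1.2 at the planted
ROIs at the reduced scale (component-dependent) — the order of magnitude of
the strongest network-level effect such studies report. The named validation experiments deviate
deliberately: the *detection* experiment uses `shift = 1.0` with amplitude
SD 0.1 (a strong, homogeneous effect, because flagging at 0.05/100 with 14
subjects requires a standardized effect ≈ 1.5), and the *correlation*
experiment uses `shift = 0.35` with amplitude SD 0.8 (a moderate dose in
the linear response regime with wide amplitude heterogeneity, which is what
makes a between-subject correlation recoverable).

## Problem sizes

Full scale is 400 ROIs × 230 volumes with 28 patients + 17 controls — the
study design the defaults emulate. The recovery experiments
(`gradstab.experiments`) run at 100 ROIs with 14 + 14 subjects and ≥ 20
seeds, and the null-calibration sweep at 20 ROIs with 8 subjects and 100
seeds; these sizes keep a full multi-seed Monte-Carlo within minutes on a
single CPU while preserving every pipeline stage. The dynamic-stability
stage is computed for the screened group only (static connectomes and the
template always use every retained subject).

## Known limitations

* The generator has no hemodynamic forward model; oscillator phases stand
  in for band-limited BOLD, and no voxel-level 4-D synthesis is attempted
  (a toy label-volume extractor exists for testing extraction only).
* Session exchangeability under the null is exact by construction, so null
  calibration tests validate the statistics, not physiological null
  variability.
* The secondary gradient of real connectomes (visual–somatomotor
  segregation) has no dedicated generative axis here; component 2 captures
  residual field structure instead.
* Whether the original analysis ranked gradient-derived profiles or
  windowed connectivity profiles is not decidable from its description;
  the gradient-profile path is the default and the windowed-dPL
  alternative is available behind a flag (`profile` mode), with the choice
  recorded in output metadata.
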