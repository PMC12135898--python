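# gradstab

Dynamic functional gradient stability analysis for two-session resting-state
fMRI, with a synthetic-cohort generator so the entire analysis runs without
scan data.

## The problem

Functional connectome **gradients** embed each brain region into a
low-dimensional space derived from its connectivity profile; the principal
gradient orders regions along the unimodal → transmodal hierarchy. When the
embedding is recomputed at every acquisition volume from the **dynamic
phase-locking (dPL)** matrix — `cos(θᵢ − θⱼ)` between the Hilbert phases of
band-limited BOLD — each region traces a trajectory through gradient space.
The **stability** of a region's *dynamic functional gradient* is the
Kendall coefficient of concordance (KCC, Kendall's W ∈ [0, 1]) of its
gradient relationship profile `|g_roi − g_j|, j ≠ roi` across sliding
windows (60 s window, 2 s step → 201 windows for 230 volumes at TR 2 s):
W = 1 when the region keeps the same relationship ranking to the rest of
the brain in every window.

The package targets pre/post designs — e.g. resting scans acquired before
and ~30 min after an in-scanner task — and asks, per region and per
gradient component, whether stability changed between sessions
(mixed-effects model, Bonferroni `0.05/400 = 0.000125`), which networks
carry the change (Cohen's d, Kolmogorov–Smirnov), and whether the change
tracks a clinical severity score (Pearson r with IELT). It is written for
researchers who want to evaluate or reuse this stability statistic with a
fully known ground truth: the generator plants per-region phase-noise
changes and a stability-change ↔ IELT correlation, and every planted
quantity is recoverable through the complete pipeline.

## Worked example

```python
import gradstab as g
from gradstab.pipeline import run_pipeline, PipelineConfig
from gradstab.stats import roi_screen

cfg = g.SynthConfig(n_patients=14, n_controls=14, n_roi=100, n_volumes=230,
                    seed=7, stability_shift=1.0, effect_amp_sd=0.1)
cohort = g.generate_cohort(cfg)          # 28 subjects x 2 sessions, planted effect
result = run_pipeline(cohort, PipelineConfig(density=0.2,
                                             stability_groups=("patient",)))
screen = roi_screen(result.stability, "patient", components=(1, 2), n_tests=100)
flagged = sorted({r.roi for r in screen if r.significant})
print("planted:", sorted(cohort.truth.effect_rois.tolist()))
print("flagged:", flagged)
```

Output from this exact run:

```
planted: [86, 87, 88, 89, 90, 91, 92, 93, 94, 95, 96, 97, 98, 99]
flagged: [86, 87, 88, 89, 90, 91, 92, 93, 95, 96, 98, 99]
```

The generator planted a stabilisation (reduced idiosyncratic phase noise
post-session) at the 14 transmodal regions of this 100-ROI parcellation;
the Bonferroni-corrected screen (threshold 0.05/100 = 5·10⁻⁴) recovers 12
of them with no false positives.
`result.stability` is the long-format KCC table, and
`result.variance_summary` holds the variance explained by each gradient
(mean ± SD per group and session).

There is also a CLI over the same library:

```bash
gradstab simulate -c config.yaml -o cohort/      # synthetic cohort on disk
gradstab run      -c config.yaml -o results/     # full analysis
gradstab report   -r results/                    # single-file Markdown report
```

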