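"""Statistical surface: LME session contrasts, network effect sizes,
clinical correlations and cohort descriptives.

The session contrast fits, per ROI and gradient component, the linear
mixed-effects model

    kcc ~ intercept + session  (+ random intercept per subject)

by restricted maximum likelihood. With two sessions per subject and a single
random intercept the REML solution is available in closed form and its Wald
t for the session effect coincides with the paired t-test; the closed form
is the default for balanced data and ``method="mixedlm"`` routes through
statsmodels MixedLM (used for unbalanced data and as a cross-check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "RoiTestResult",
    "NetworkTestResult",
    "bonferroni_threshold",
    "lme_session_effect",
    "roi_screen",
    "network_compare",
    "clinical_correlation",
    "compare_variance_explained",
    "demographics_table",
]

DEFAULT_ALPHA = 0.05
DEFAULT_N_TESTS = 400


@dataclass
class RoiTestResult:
    roi: int
    component: int
    beta: float
    t_fixed: float
    p_fixed: float
    F_main: float
    p_main: float
    t_posthoc: float
    p_posthoc: float
    significant: bool = False
    degenerate: bool = False
    n_subjects: int = 0
    df_method: str = "exact balanced (1, n-1)"


@dataclass
class NetworkTestResult:
    network: str
    component: int
    cohens_d: float
    ks_stat: float
    p_value: float
    p_bonferroni: float
    degenerate: bool = False


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, n_tests: int = DEFAULT_N_TESTS) -> float:
    """Family-wise significance threshold alpha / n_tests (0.05/400 = 0.000125)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _paired_matrix(
    stab: pd.DataFrame, group: str, component: int
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Per-subject pre/post KCC matrices (subjects x ROIs) for one component."""
    sub = stab[(stab["group"] == group) & (stab["component"] == component)]
    if sub.empty:
        raise ValueError(f"no stability records for group={group}, component={component}")
    wide = sub.pivot_table(
        index="subject_id", columns=["session", "roi_index"], values="kcc", aggfunc="first"
    )
    pre = wide.get("pre")
    post = wide.get("post")
    if pre is None or post is None:
        raise ValueError("both sessions are required for the session contrast")
    complete = pre.notna().all(axis=1) & post.notna().all(axis=1)
    dropped = wide.index[~complete]
    if len(dropped):
        warnings.warn(f"excluding subjects with a missing session: {list(dropped)}", stacklevel=3)
    pre, post = pre.loc[complete], post.loc[complete]
    if len(pre) < 3:
        raise ValueError("fewer than 3 subjects with both sessions")
    rois = np.asarray(sorted(sub["roi_index"].unique()))
    return pre[rois].to_numpy(), post[rois].to_numpy(), list(pre.index), rois


def _balanced_reml_contrast(pre: np.ndarray, post: np.ndarray) -> tuple[float, float, float, int]:
    """Closed-form REML session effect for one ROI: (beta, t, p, df).

    For the balanced random-intercept model the session fixed effect equals
    the mean paired difference and its REML standard error equals
    sd(diff)/sqrt(n); the Wald t therefore equals the paired t with n-1 df
    (Satterthwaite is exact here).
    """
    d = post - pre
    n = d.size
    beta = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return beta, np.inf if beta != 0 else 0.0, 0.0 if beta != 0 else 1.0, n - 1
    t = beta / (sd / np.sqrt(n))
    p = 2.0 * sp_stats.t.sf(abs(t), n - 1)
    return beta, float(t), float(p), n - 1


def _mixedlm_contrast(pre: np.ndarray, post: np.ndarray, subjects: list[str]):
    """statsmodels MixedLM (REML) route for the same contrast."""
    import statsmodels.formula.api as smf

    n = len(subjects)
    df = pd.DataFrame(
        {
            "kcc": np.concatenate([pre, post]),
            "session": np.repeat([0.0, 1.0], n),
            "subject": subjects * 2,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # powell converges the REML profile tightly enough for the
        # closed-form equivalence to hold to ~1e-8
        fit = smf.mixedlm("kcc ~ session", df, groups=df["subject"]).fit(
            reml=True, method="powell"
        )
    beta = float(fit.params["session"])
    t = float(fit.tvalues["session"])
    # statsmodels reports normal-approximation p; rescale to the exact
    # t(n-1) reference appropriate for the balanced design
    p = 2.0 * sp_stats.t.sf(abs(t), n - 1)
    return beta, t, p, n - 1


def lme_session_effect(
    stab: pd.DataFrame,
    group: str,
    roi: int,
    component: int,
    method: str = "auto",
) -> RoiTestResult:
    """Session (post vs pre) effect on KCC at one ROI/component within a group."""
    pre, post, subjects, rois = _paired_matrix(stab, group, component)
    col = int(np.flatnonzero(rois == roi)[0]) if roi in rois else None
    if col is None:
        raise ValueError(f"roi {roi} absent from stability table")
    p_vec, q_vec = pre[:, col], post[:, col]
    if method in ("auto", "closed"):
        beta, t, p, df = _balanced_reml_contrast(p_vec, q_vec)
    elif method == "mixedlm":
        beta, t, p, df = _mixedlm_contrast(p_vec, q_vec, subjects)
    else:
        raise ValueError(f"unknown method {method!r}")
    degenerate = not np.isfinite(t)
    F = t * t if np.isfinite(t) else np.inf
    p_main = sp_stats.f.sf(F, 1, df) if np.isfinite(F) else 0.0
    return RoiTestResult(
        roi=int(roi),
        component=int(component),
        beta=beta,
        t_fixed=t,
        p_fixed=p,
        F_main=float(F),
        p_main=float(p_main),
        t_posthoc=t,
        p_posthoc=p,
        degenerate=degenerate,
        n_subjects=len(subjects),
    )


def roi_screen(
    stab: pd.DataFrame,
    group: str,
    components: tuple[int, ...] = (1, 2),
    alpha: float = DEFAULT_ALPHA,
    n_tests: int = DEFAULT_N_TESTS,
    method: str = "auto",
) -> list[RoiTestResult]:
    """Session contrast at every ROI x component with Bonferroni flagging.

    The Bonferroni divisor defaults to the atlas ROI count (400) even when
    both components are screened, matching the printed threshold; pass
    ``n_tests`` explicitly for a stricter family.
    """
    threshold = bonferroni_threshold(alpha, n_tests)
    results: list[RoiTestResult] = []
    for comp in components:
        pre, post, subjects, rois = _paired_matrix(stab, group, comp)
        if method in ("auto", "closed"):
            # vectorised closed form across ROIs
            d = post - pre
            n = d.shape[0]
            beta = d.mean(axis=0)
            sd = d.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = beta / (sd / np.sqrt(n))
            t = np.where(sd == 0, np.where(beta == 0, 0.0, np.inf), t)
            pvals = np.where(
                np.isfinite(t), 2.0 * sp_stats.t.sf(np.abs(t), n - 1), 0.0
            )
            pvals = np.where((sd == 0) & (beta == 0), 1.0, pvals)
            for j, roi in enumerate(rois):
                F = t[j] * t[j]
                res = RoiTestResult(
                    roi=int(roi),
                    component=int(comp),
                    beta=float(beta[j]),
                    t_fixed=float(t[j]),
                    p_fixed=float(pvals[j]),
                    F_main=float(F),
                    p_main=float(sp_stats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0,
                    t_posthoc=float(t[j]),
                    p_posthoc=float(pvals[j]),
                    significant=bool(pvals[j] < threshold),
                    degenerate=bool(~np.isfinite(t[j])),
                    n_subjects=n,
                )
                results.append(res)
        else:
            for roi in rois:
                res = lme_session_effect(stab, group, int(roi), comp, method=method)
                res.significant = res.p_fixed < threshold
                results.append(res)
    return results


def network_compare(
    stab: pd.DataFrame,
    group: str,
    partition: dict[int, str] | None = None,
    component: int = 1,
) -> list[NetworkTestResult]:
    """Pre/post comparison of network-mean stability distributions.

    Per network: subject-mean KCC per ROI and session gives a pre vector and
    a post vector over the network's ROIs. Cohen's d uses the SD of the
    paired ROI differences; the K-S statistic is the two-sample distance
    between the pre and post ROI distributions (asymptotic p), Bonferroni-
    corrected over networks.
    """
    sub = stab[(stab["group"] == group) & (stab["component"] == component)]
    if sub.empty:
        raise ValueError(f"no records for group={group}, component={component}")
    roi_mean = sub.groupby(["roi_index", "session"], observed=True)["kcc"].mean().unstack()
    if partition is None:
        partition = (
            sub.drop_duplicates("roi_index").set_index("roi_index")["network"].to_dict()
        )
    networks = sorted(set(partition.values()))
    n_networks = len(networks)
    out = []
    for net in networks:
        rois = [r for r, v in partition.items() if v == net]
        if len(rois) < 2:
            raise ValueError(f"network {net!r} has fewer than 2 ROIs")
        pre = roi_mean.loc[rois, "pre"].to_numpy()
        post = roi_mean.loc[rois, "post"].to_numpy()
        diff = post - pre
        sd = diff.std(ddof=1)
        degenerate = sd <= 1e-12 * max(1.0, float(np.abs(diff).max(initial=0.0)))
        d = 0.0 if degenerate else float(diff.mean() / sd)
        if np.allclose(pre, post, atol=1e-12):
            ks, p = 0.0, 1.0
        else:
            ks_res = sp_stats.ks_2samp(pre, post, method="asymp")
            ks, p = float(ks_res.statistic), float(ks_res.pvalue)
        out.append(
            NetworkTestResult(
                network=net,
                component=component,
                cohens_d=d,
                ks_stat=ks,
                p_value=p,
                p_bonferroni=min(1.0, p * n_networks),
                degenerate=bool(degenerate),
            )
        )
    return out


def clinical_correlation(
    stab: pd.DataFrame,
    manifest: pd.DataFrame,
    roi: int,
    component: int,
    group: str,
    variable: str = "ielt",
) -> tuple[float, float]:
    """Pearson r between per-subject stability change (post - pre) and a
    clinical score at one ROI/component."""
    sub = stab[
        (stab["group"] == group)
        & (stab["component"] == component)
        & (stab["roi_index"] == roi)
    ]
    wide = sub.pivot_table(index="subject_id", columns="session", values="kcc", aggfunc="first")
    wide = wide.dropna()
    if len(wide) < 3:
        raise ValueError("need at least 3 subjects with both sessions")
    delta = (wide["post"] - wide["pre"]).rename("delta")
    scores = manifest.set_index("subject_id").loc[delta.index, variable]
    if delta.std(ddof=1) == 0 or scores.std(ddof=1) == 0:
        raise ValueError("zero variance in stability change or clinical score")
    r, p = sp_stats.pearsonr(delta.to_numpy(), scores.to_numpy(dtype=float))
    return float(r), float(p)


def compare_variance_explained(
    summary_values: dict[str, np.ndarray]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two groups' per-subject
    variance-explained values for one component.

    ``summary_values`` maps exactly two group names to 1-D value arrays.
    """
    if len(summary_values) != 2:
        raise ValueError("exactly two groups required")
    (g1, x), (g2, y) = summary_values.items()
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: U is exactly its null mean, p maximal
        return float(x.size * y.size / 2.0), 1.0
    res = sp_stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


_CONTINUOUS = ["age", "ielt", "cipe5", "iief5"]
_CATEGORICAL = ["marital", "education"]


def demographics_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Group descriptives with two-sample t (continuous) and chi-squared
    (categorical) tests, mirroring a standard cohort table."""
    groups = sorted(manifest["group"].unique())
    if len(groups) != 2:
        raise ValueError("demographics table expects exactly two groups")
    g1, g2 = groups
    rows = []
    for var in _CONTINUOUS:
        if var not in manifest:
            continue
        a = manifest.loc[manifest["group"] == g1, var].astype(float)
        b = manifest.loc[manifest["group"] == g2, var].astype(float)
        if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = sp_stats.ttest_ind(a, b)
        rows.append(
            {
                "variable": var,
                "test": "t",
                f"{g1}": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                f"{g2}": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                "statistic": float(t),
                "p": float(p),
            }
        )
    for var in _CATEGORICAL:
        if var not in manifest:
            continue
        table = pd.crosstab(manifest["group"], manifest[var])
        expected = sp_stats.contingency.expected_freq(table.to_numpy())
        if (expected < 5).any():
            warnings.warn(
                f"chi-squared validity: expected cell count < 5 for {var!r}", stacklevel=2
            )
        chi2, p, *_ = sp_stats.chi2_contingency(table)
        counts = {
            g: " / ".join(f"{c}:{table.loc[g, c]}" for c in table.columns) for g in groups
        }
        rows.append(
            {
                "variable": var,
                "test": "chi2",
                f"{g1}": counts[g1],
                f"{g2}": counts[g2],
                "statistic": float(chi2),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
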