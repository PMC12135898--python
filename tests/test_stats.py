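"""Session-contrast mixed model, network effect sizes, clinical correlation
and cohort descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from gradstab.stats import (
    bonferroni_threshold,
    clinical_correlation,
    compare_variance_explained,
    demographics_table,
    lme_session_effect,
    network_compare,
    roi_screen,
)


def make_stab(pre, post, group="patient", component=1, networks=None):
    """Long-format stability table from subjects x ROIs matrices."""
    n_sub, n_roi = pre.shape
    rows = []
    for s in range(n_sub):
        for r in range(n_roi):
            for ses, mat in (("pre", pre), ("post", post)):
                rows.append(
                    {
                        "subject_id": f"sub-{s:03d}",
                        "group": group,
                        "session": ses,
                        "roi_index": r,
                        "roi_label": f"R{r}",
                        "network": networks[r] if networks else "NA",
                        "component": component,
                        "kcc": mat[s, r],
                    }
                )
    return pd.DataFrame(rows)


class TestBonferroni:
    def test_study_threshold(self):
        assert bonferroni_threshold(0.05, 400) == pytest.approx(0.000125, abs=0)

    def test_monotone_in_alpha(self):
        assert bonferroni_threshold(0.01, 400) < bonferroni_threshold(0.05, 400)


class TestLmeSessionEffect:
    def test_no_change_gives_zero_beta(self, rng):
        pre = rng.random((6, 3))
        stab = make_stab(pre, pre.copy())
        res = lme_session_effect(stab, "patient", roi=1, component=1)
        assert res.beta == pytest.approx(0.0, abs=1e-12)
        assert res.p_fixed == pytest.approx(1.0)

    def test_exact_constant_shift_flagged_degenerate(self, rng):
        pre = rng.random((5, 2))
        stab = make_stab(pre, pre + 0.1)
        res = lme_session_effect(stab, "patient", roi=0, component=1)
        assert res.beta == pytest.approx(0.1)
        assert res.degenerate

    def test_matches_paired_t_oracle(self, rng):
        pre = rng.random((12, 4))
        post = pre + 0.03 + 0.04 * rng.standard_normal((12, 4))
        stab = make_stab(pre, post)
        for roi in range(4):
            res = lme_session_effect(stab, "patient", roi=roi, component=1)
            t_ref, p_ref = sp_stats.ttest_rel(post[:, roi], pre[:, roi])
            assert res.t_fixed == pytest.approx(t_ref, abs=1e-10)
            assert res.p_fixed == pytest.approx(p_ref, abs=1e-10)
            assert res.F_main == pytest.approx(res.t_fixed**2, rel=1e-9)

    def test_mixedlm_route_agrees_with_paired_t(self, rng):
        pre = 0.3 + 0.05 * rng.standard_normal((10, 1))
        post = pre + 0.02 + 0.03 * rng.standard_normal((10, 1))
        stab = make_stab(pre, post)
        res = lme_session_effect(stab, "patient", roi=0, component=1, method="mixedlm")
        t_ref, _ = sp_stats.ttest_rel(post[:, 0], pre[:, 0])
        assert res.t_fixed == pytest.approx(t_ref, abs=1e-6)

    def test_beta_coverage_under_simulation(self):
        # planted shift 0.03, residual SD 0.04: the estimate lands within
        # 2 SE of truth in ~95% of repetitions
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            pre = 0.3 + 0.04 * r.standard_normal((28, 1))
            post = pre + 0.03 + 0.04 * r.standard_normal((28, 1))
            stab = make_stab(pre, post)
            res = lme_session_effect(stab, "patient", roi=0, component=1)
            se = abs(res.beta / res.t_fixed)
            hits += abs(res.beta - 0.03) <= 2 * se
        assert hits >= 90

    def test_incomplete_subject_excluded_with_warning(self, rng):
        pre = rng.random((5, 2))
        stab = make_stab(pre, pre + 0.1 + 0.01 * rng.standard_normal((5, 2)))
        stab = stab[
            ~((stab.subject_id == "sub-000") & (stab.session == "post"))
        ]
        with pytest.warns(UserWarning, match="sub-000"):
            res = lme_session_effect(stab, "patient", roi=0, component=1)
        assert res.n_subjects == 4

    def test_too_few_subjects_rejected(self, rng):
        pre = rng.random((2, 2))
        stab = make_stab(pre, pre + 0.1)
        with pytest.raises(ValueError, match="3 subjects"):
            lme_session_effect(stab, "patient", roi=0, component=1)


class TestRoiScreen:
    def test_flags_match_threshold(self, rng):
        pre = rng.random((10, 5))
        post = pre + 0.01 * rng.standard_normal((10, 5))
        post[:, 2] = pre[:, 2] + 0.2 + 0.01 * rng.standard_normal(10)  # strong effect
        stab = make_stab(pre, post)
        results = roi_screen(stab, "patient", components=(1,), alpha=0.05, n_tests=5)
        sig = [r.roi for r in results if r.significant]
        assert 2 in sig
        for r in results:
            assert r.significant == (r.p_fixed < 0.05 / 5)

    def test_screen_agrees_with_single_fits(self, rng):
        pre = rng.random((8, 4))
        post = pre + 0.02 * rng.standard_normal((8, 4))
        stab = make_stab(pre, post)
        screened = {r.roi: r for r in roi_screen(stab, "patient", components=(1,), n_tests=4)}
        for roi in range(4):
            single = lme_session_effect(stab, "patient", roi=roi, component=1)
            assert screened[roi].t_fixed == pytest.approx(single.t_fixed, abs=1e-10)
            assert screened[roi].p_fixed == pytest.approx(single.p_fixed, abs=1e-10)

    def test_bonferroni_monotone_in_alpha(self, rng):
        pre = rng.random((10, 6))
        post = pre + 0.05 * rng.standard_normal((10, 6)) + 0.05
        stab = make_stab(pre, post)
        sig_strict = {r.roi for r in roi_screen(stab, "patient", (1,), alpha=0.01, n_tests=6) if r.significant}
        sig_loose = {r.roi for r in roi_screen(stab, "patient", (1,), alpha=0.05, n_tests=6) if r.significant}
        assert sig_strict <= sig_loose

    def test_all_pvalues_in_unit_interval_and_rows_complete(self, rng):
        pre = rng.random((6, 7))
        post = pre + 0.02 * rng.standard_normal((6, 7))
        stab = make_stab(pre, post)
        results = roi_screen(stab, "patient", components=(1,), n_tests=7)
        assert len(results) == 7
        assert all(0.0 <= r.p_fixed <= 1.0 for r in results)


class TestNetworkCompare:
    def test_no_change_degenerate_zero(self, rng):
        pre = rng.random((6, 8))
        nets = ["A"] * 4 + ["B"] * 4
        stab = make_stab(pre, pre.copy(), networks=nets)
        out = network_compare(stab, "patient", component=1)
        for r in out:
            assert r.cohens_d == 0.0 and r.ks_stat == 0.0 and r.p_value == 1.0

    def test_constant_shift_flagged(self, rng):
        pre = rng.random((6, 8))
        nets = ["A"] * 4 + ["B"] * 4
        stab = make_stab(pre, pre + 0.25, networks=nets)
        out = network_compare(stab, "patient", component=1)
        assert all(r.degenerate for r in out)

    def test_matches_direct_formula_oracle(self, rng):
        pre = rng.random((10, 10))
        post = pre + 0.1 * rng.standard_normal((10, 10)) + 0.05
        nets = ["A"] * 5 + ["B"] * 5
        stab = make_stab(pre, post, networks=nets)
        out = {r.network: r for r in network_compare(stab, "patient", component=1)}
        pre_m = pre.mean(axis=0)
        post_m = post.mean(axis=0)
        for net, idx in (("A", slice(0, 5)), ("B", slice(5, 10))):
            diff = post_m[idx] - pre_m[idx]
            d_ref = diff.mean() / diff.std(ddof=1)
            ks_ref = sp_stats.ks_2samp(pre_m[idx], post_m[idx], method="asymp")
            assert out[net].cohens_d == pytest.approx(d_ref, abs=1e-12)
            assert out[net].ks_stat == pytest.approx(ks_ref.statistic, abs=1e-12)
            assert out[net].p_value == pytest.approx(ks_ref.pvalue, abs=1e-12)
            assert out[net].p_bonferroni == pytest.approx(min(1.0, ks_ref.pvalue * 2), abs=1e-12)

    def test_small_network_rejected(self, rng):
        pre = rng.random((5, 3))
        nets = ["A", "A", "B"]
        stab = make_stab(pre, pre + 0.1, networks=nets)
        with pytest.raises(ValueError, match="fewer than 2"):
            network_compare(stab, "patient", component=1)


class TestClinicalCorrelation:
    def _manifest(self, ielt):
        return pd.DataFrame(
            {"subject_id": [f"sub-{s:03d}" for s in range(len(ielt))], "ielt": ielt}
        )

    def test_exact_negative_proportionality(self, rng):
        n = 10
        ielt = rng.random(n) * 5 + 1
        pre = np.tile(0.5, (n, 2))
        post = pre.copy()
        post[:, 0] = pre[:, 0] - 0.01 * ielt  # delta = -0.01*IELT
        stab = make_stab(pre, post)
        r, p = clinical_correlation(stab, self._manifest(ielt), roi=0, component=1, group="patient")
        assert r == pytest.approx(-1.0)

    def test_null_pvalues_uniform(self):
        # independent delta and IELT: p-values follow U(0,1)
        pvals = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            n = 15
            pre = 0.3 + 0.02 * r.standard_normal((n, 1))
            post = pre + 0.02 * r.standard_normal((n, 1))
            ielt = r.random(n) * 10 + 0.5
            stab = make_stab(pre, post)
            pvals.append(
                clinical_correlation(stab, self._manifest(ielt), 0, 1, "patient")[1]
            )
        ks = sp_stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_rejected(self, rng):
        n = 6
        pre = rng.random((n, 1))
        stab = make_stab(pre, pre.copy())
        with pytest.raises(ValueError, match="variance"):
            clinical_correlation(stab, self._manifest(np.full(n, 3.0)), 0, 1, "patient")


class TestVarianceComparison:
    def test_identical_groups_maximal_p(self):
        x = np.array([0.3, 0.35, 0.4, 0.28])
        u, p = compare_variance_explained({"a": x, "b": x.copy()})
        assert p == 1.0
        assert u == pytest.approx(len(x) ** 2 / 2)

    def test_fully_separated_groups_extreme_u(self):
        u, p = compare_variance_explained({"a": [1.0, 2, 3], "b": [10.0, 11, 12]})
        assert u in (0.0, 9.0)

    def test_matches_bruteforce_pair_count(self, rng):
        x = rng.random(5)
        y = rng.random(5)
        u, _ = compare_variance_explained({"a": x, "b": y})
        gt = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        assert u == pytest.approx(max(gt, 25 - gt)) or u == pytest.approx(gt)


class TestDemographics:
    def _manifest(self, rng, shift=0.0):
        n = 20
        rows = []
        for g in ("patient", "control"):
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"{g}-{i}",
                        "group": g,
                        "age": 27 + rng.standard_normal() + (shift if g == "patient" else 0),
                        "ielt": abs(rng.standard_normal()) + 0.5,
                        "cipe5": 15 + rng.standard_normal(),
                        "iief5": 23 + rng.standard_normal(),
                        "marital": ["single", "married"][i % 2],
                        "education": ["elementary", "high_school", "university"][i % 3],
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_categorical_distributions_p_one(self, rng):
        table = demographics_table(self._manifest(rng))
        cat = table[table.test == "chi2"]
        assert np.allclose(cat["p"], 1.0)

    def test_t_statistic_matches_pooled_formula(self, rng):
        m = self._manifest(rng, shift=2.0)
        table = demographics_table(m)
        row = table[table.variable == "age"].iloc[0]
        a = m.loc[m.group == "control", "age"]
        b = m.loc[m.group == "patient", "age"]
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2))
        t_ref = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        assert abs(row["statistic"]) == pytest.approx(abs(t_ref), rel=1e-10)

    def test_low_expected_count_warns(self):
        rows = []
        for g, n in (("patient", 4), ("control", 4)):
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"{g}-{i}",
                        "group": g,
                        "age": 25.0 + i,
                        "marital": "single" if i else "married",
                        "education": "university",
                    }
                )
        with pytest.warns(UserWarning, match="expected cell"):
            demographics_table(pd.DataFrame(rows))
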