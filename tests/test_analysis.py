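"""Risk-dominant selection, ROC/AUC, DeLong test, demographics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from nodulerisk import (
    NoduleType,
    System,
    SizeDefinition,
    build_cohort,
    compare_systems,
    delong_test,
    demographics_table,
    participant_scores,
    roc,
    score_all,
    select_dominant,
)

from conftest import make_nodule, make_participant


def brute_force_auc(labels, scores):
    """Pair-counting oracle: wins + half-ties over all pos-neg pairs."""
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    total = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_no_discrimination(self):
        r = roc([1, 1, 0, 0, 0], [2.0] * 5)
        assert r.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        r = roc([1, 1, 0, 0], [9.0, 8.0, 1.0, 2.0])
        assert r.auc == pytest.approx(1.0)

    def test_frozen_pair_counting_example(self):
        # oracle: pairs (4,3)+ (4,1)+ (4,1)+ (2,3)- (2,1)+ (2,1)+ = 5 wins,
        # 0 ties -> 5/6; recomputed with brute_force_auc below
        labels = [1, 1, 0, 0, 0]
        scores = [4.0, 2.0, 3.0, 1.0, 1.0]
        expected = brute_force_auc(labels, scores)
        assert expected == pytest.approx(5.0 / 6.0)
        assert roc(labels, scores).auc == pytest.approx(expected)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 1, 1], [1.0, 2.0, 3.0])

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_auc_equals_pair_counting_and_sklearn(self, data):
        n = data.draw(st.integers(4, 40))
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        scores = data.draw(
            st.lists(
                st.integers(0, 6).map(float), min_size=n, max_size=n
            )
        )
        r = roc(labels, scores)
        assert r.auc == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)
        assert r.auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @given(st.data())
    @settings(deadline=None, max_examples=40)
    def test_curve_monotone_and_trapezoid_equals_auc(self, data):
        n = data.draw(st.integers(4, 60))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31)))
        labels = np.zeros(n, bool)
        labels[: max(1, n // 3)] = True
        rng.shuffle(labels)
        scores = rng.integers(0, 8, n).astype(float)
        r = roc(labels, scores)
        fpr = np.array([p[0] for p in r.curve_points])
        tpr = np.array([p[1] for p in r.curve_points])
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert np.trapezoid(tpr, fpr) == pytest.approx(r.auc, abs=1e-12)

    def test_operating_points_on_curve(self):
        labels = [1, 0, 1, 0, 0, 1, 0]
        scores = [3.0, 2.0, 2.0, 1.0, 1.0, 4.0, 3.0]
        r = roc(labels, scores, category_cutoffs=[2.0, 3.0, 4.0])
        assert set(r.operating_points) <= set(r.curve_points)


class TestDelong:
    def test_identical_scores_give_p_one(self):
        y = [1, 0, 1, 0, 1, 0]
        s = [3.0, 1.0, 2.0, 2.0, 4.0, 1.0]
        auc_a, auc_b, z, p = delong_test(y, s, s)
        assert auc_a == auc_b
        assert z == 0.0
        assert p == 1.0

    def test_reflection_antisymmetry(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(8, bool), np.zeros(12, bool)]
        a = rng.normal(size=20) + y
        auc_a, auc_b, z, p = delong_test(y, a, -a)
        assert auc_b == pytest.approx(1.0 - auc_a, abs=1e-12)

    def test_matches_proc_reference(self):
        """DeLong z and p agree with R pROC's paired roc.test exactly."""
        rng = np.random.default_rng(42)
        n, m = 40, 15
        y = np.zeros(n, bool)
        y[:m] = True
        a = (rng.integers(1, 7, n) + y * rng.integers(0, 3, n)).astype(float)
        b = rng.normal(0, 1, n) + y * 0.8
        auc_a, auc_b, z, p = delong_test(y, a, b)
        fmt = lambda arr: ",".join(repr(float(v)) for v in arr)
        script = f"""
suppressMessages(library(pROC))
y <- c({fmt(y.astype(float))})
a <- c({fmt(a)})
b <- c({fmt(b)})
ra <- roc(y, a, quiet=TRUE, direction="<")
rb <- roc(y, b, quiet=TRUE, direction="<")
t <- roc.test(ra, rb, method="delong", paired=TRUE)
cat(sprintf("%.12f %.12f %.12f %.12f", as.numeric(auc(ra)),
    as.numeric(auc(rb)), t$statistic, t$p.value))
"""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            check=True,
        )
        r_auc_a, r_auc_b, r_z, r_p = map(float, out.stdout.split())
        assert auc_a == pytest.approx(r_auc_a, abs=1e-10)
        assert auc_b == pytest.approx(r_auc_b, abs=1e-10)
        assert z == pytest.approx(r_z, abs=1e-8)
        assert p == pytest.approx(r_p, abs=1e-8)

    def test_single_auc_variance_matches_mann_whitney_closed_form(self):
        # under continuous scores with no ties and exchangeability the
        # DeLong variance of one AUC estimates the Mann-Whitney variance;
        # check on the exact-null closed form var = (m+n+1)/(12 m n)
        rng = np.random.default_rng(11)
        m, n = 40, 60
        reps = 400
        variances = []
        for _ in range(reps):
            y = np.r_[np.ones(m, bool), np.zeros(n, bool)]
            s = rng.normal(size=m + n)
            from nodulerisk.analysis import _delong_components

            auc, v10, v01 = _delong_components(y, s)
            variances.append(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
        closed_form = (m + n + 1) / (12.0 * m * n)
        assert np.mean(variances) == pytest.approx(closed_form, rel=0.1)

    def test_agrees_with_permutation_oracle_at_approximation_level(self):
        """Normal-approximation p tracks a swap-permutation p closely.

        The permutation oracle is exact while delong_test is asymptotic;
        at n=30 the two agree to about the size of the normal
        approximation error, which for these ordinal instances stays
        below 0.08 in absolute p; that approximation-level bound is
        what this asserts.
        """
        rng = np.random.default_rng(7)
        B = 20000
        for _ in range(6):
            n, m = 30, 10
            y = np.zeros(n, bool)
            y[:m] = True
            base = rng.integers(1, 6, n).astype(float)
            a = base + y * rng.integers(0, 3, n)
            b = np.clip(base + rng.integers(-1, 2, n), 1, 6).astype(
                float
            ) + y * rng.integers(0, 2, n)
            _, _, _, p_delong = delong_test(y, a, b)
            d_obs = brute_force_auc(y, a) - brute_force_auc(y, b)
            swap = rng.random((B, n)) < 0.5
            A = np.where(swap, b, a)
            Bm = np.where(swap, a, b)
            x = A[:, y][:, :, None]
            w = A[:, ~y][:, None, :]
            auc_a = ((x > w).sum(axis=(1, 2)) + 0.5 * (x == w).sum(axis=(1, 2))) / (m * (n - m))
            x = Bm[:, y][:, :, None]
            w = Bm[:, ~y][:, None, :]
            auc_b = ((x > w).sum(axis=(1, 2)) + 0.5 * (x == w).sum(axis=(1, 2))) / (m * (n - m))
            d = auc_a - auc_b
            p_perm = (1 + np.sum(np.abs(d) >= abs(d_obs) - 1e-12)) / (B + 1)
            assert abs(p_delong - p_perm) < 0.08

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 0], [1.0, 2.0], [1.0, 2.0, 3.0])


class TestSelectDominant:
    def _cohort_three_nodules(self):
        nodules = [
            make_nodule("n1", "p1", d_longest_axial=7.0, d_perp_axial=7.0,
                        d_mean3d=7.0),
            make_nodule("n2", "p1", d_longest_axial=9.0, d_perp_axial=9.0,
                        d_mean3d=9.0),
            make_nodule("n3", "p1", d_longest_axial=9.0, d_perp_axial=9.0,
                        d_mean3d=9.0),
        ]
        return build_cohort(
            [make_participant("p1", nodule_count_additional=2)], nodules
        )

    def test_single_nodule_participant(self, small_cohort):
        table = score_all(small_cohort, System.NCCN)
        sel = select_dominant(
            small_cohort, table, System.NCCN, SizeDefinition.MEAN_AXIAL, 0
        )
        assert sel.selection["p2"] == "n3"

    def test_tie_break_is_seed_deterministic(self):
        cohort = self._cohort_three_nodules()
        table = score_all(cohort, System.NCCN)
        picks = set()
        for seed in range(20):
            sel1 = select_dominant(
                cohort, table, System.NCCN, SizeDefinition.MEAN_AXIAL, seed
            )
            sel2 = select_dominant(
                cohort, table, System.NCCN, SizeDefinition.MEAN_AXIAL, seed
            )
            assert sel1.selection == sel2.selection
            assert sel1.selection["p1"] in {"n2", "n3"}
            picks.add(sel1.selection["p1"])
        assert picks == {"n2", "n3"}  # both tied nodules reachable

    def test_three_systems_can_pick_three_different_nodules(self):
        # one solid nodule dominant for NCCN (largest mean axial), one
        # dominant for Lung-RADS (largest volumetric mean), and a large
        # calcification-free GGN dominant for PanCan risk
        nodules = [
            make_nodule(
                "nccn_pick", "p1", d_longest_axial=6.6, d_mean_axial=6.1,
                d_mean3d=5.0,
            ),
            make_nodule(
                "lr_pick", "p1", d_longest_axial=9.0, d_mean_axial=5.9,
                d_mean3d=8.7,
            ),
            make_nodule(
                "pancan_pick", "p1", type=NoduleType.GROUND_GLASS,
                d_longest_axial=14.3, d_mean_axial=9.0, d_mean3d=5.5,
            ),
        ]
        cohort = build_cohort(
            [make_participant("p1", nodule_count_additional=2)], nodules
        )
        picks = {}
        for sys_ in System:
            table = score_all(cohort, sys_)
            sel = select_dominant(cohort, table, sys_, None, 0)
            picks[sys_] = sel.selection["p1"]
        assert picks[System.NCCN] == "nccn_pick"
        assert picks[System.LUNG_RADS] == "lr_pick"
        assert picks[System.PANCAN] == "pancan_pick"

    def test_scores_must_cover_cohort(self, small_cohort):
        table = score_all(small_cohort, System.NCCN)
        partial = table.iloc[:-1]
        with pytest.raises(ValueError, match="cover"):
            select_dominant(
                small_cohort, partial, System.NCCN,
                SizeDefinition.MEAN_AXIAL, 0,
            )


@pytest.fixture(scope="module")
def crafted_cohort():
    """20 participants, 1 nodule each, sizes strictly ordered."""
    nodules, participants = [], []
    for i in range(20):
        cancer = i >= 14
        d = 4.0 + i * (1.5 if cancer else 0.3) + (10.0 if cancer else 0.0)
        nodules.append(
            make_nodule(
                f"n{i}", f"p{i}", d_longest_axial=d, d_perp_axial=d,
                d_mean3d=d, malignant=cancer,
            )
        )
        participants.append(
            make_participant(f"p{i}", age=55.0 + i, has_cancer=cancer)
        )
    return build_cohort(participants, nodules)


class TestCompareSystems:
    def test_bonferroni_threshold(self, crafted_cohort):
        res = compare_systems(crafted_cohort, seed=1)
        assert res.significance_threshold == pytest.approx(0.05 / 3)
        assert res.significance_threshold == pytest.approx(0.0167, abs=5e-4)

    def test_rows_and_pairs_complete(self, crafted_cohort):
        res = compare_systems(crafted_cohort, seed=1)
        row_labels = {k[0] for k in res.rocs}
        assert row_labels == {
            "as_published", "longest_c", "mean_3d", "mean_axial"
        }
        assert len(res.pairwise_systems) == 4 * 3
        assert len(res.pairwise_definitions) == 3 * 3

    def test_identical_ranks_give_p_one(self):
        # all nodules identical in size: every system gives constant
        # ranks across participants except separation by label absent ->
        # AUC 0.5 everywhere, all pairwise p = 1
        nodules = [
            make_nodule(
                f"n{i}", f"p{i}", d_longest_axial=7.0, d_perp_axial=7.0,
                d_mean3d=7.0, malignant=i < 4,
            )
            for i in range(12)
        ]
        participants = [
            make_participant(f"p{i}", has_cancer=i < 4) for i in range(12)
        ]
        cohort = build_cohort(participants, nodules)
        res = compare_systems(cohort, seed=0)
        for t in res.pairwise_systems:
            assert t.p_two_sided == pytest.approx(1.0)
            assert not t.significant

    def test_deterministic_given_seed(self, crafted_cohort):
        r1 = compare_systems(crafted_cohort, seed=9)
        r2 = compare_systems(crafted_cohort, seed=9)
        assert r1.pairwise_systems == r2.pairwise_systems
        for k in r1.rocs:
            assert r1.rocs[k].auc == r2.rocs[k].auc


class TestDemographics:
    def _selected(self, cohort):
        sels = []
        for sys_ in System:
            table = score_all(cohort, sys_)
            sels.append(select_dominant(cohort, table, sys_, None, 0))
        return sels

    def test_family_history_contingency_significant(self):
        # 2x2 counts (17,47) vs (90,459): chi-square p below 0.05
        table = np.array([[17, 47], [90, 459]], dtype=float)
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert p < 0.05

    def test_zero_statistic_gives_p_one(self):
        table = np.array([[10, 30], [20, 60]], dtype=float)
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_identical_groups_give_large_p(self):
        nodules, participants = [], []
        for i in range(40):
            cancer = i % 2 == 0
            d = 8.0 + (i // 2) * 0.1  # same size marginals in both groups
            nodules.append(
                make_nodule(
                    f"n{i}", f"p{i}", d_longest_axial=d, d_perp_axial=d,
                    d_mean3d=d, malignant=cancer,
                )
            )
            participants.append(
                make_participant(
                    f"p{i}", age=60.0 + (i // 2) * 0.1, has_cancer=cancer
                )
            )
        cohort = build_cohort(participants, nodules)
        table = demographics_table(cohort, self._selected(cohort))
        by_param = table.set_index("parameter")["p_value"]
        assert by_param["size: longest axial (mm)"] > 0.9
        assert by_param["age (years)"] > 0.9

    def test_table_layout(self, small_cohort):
        table = demographics_table(small_cohort, self._selected(small_cohort))
        assert list(table.columns) == [
            "parameter", "cancers", "benign", "total", "p_value",
        ]
        assert "spiculation" in set(table["parameter"])

    def test_empty_group_rejected(self):
        nodules = [
            make_nodule(
                f"n{i}", f"p{i}", d_longest_axial=8.0, d_perp_axial=8.0,
                d_mean3d=8.0, malignant=True,
            )
            for i in range(4)
        ]
        participants = [
            make_participant(f"p{i}", has_cancer=True) for i in range(4)
        ]
        cohort = build_cohort(participants, nodules)
        with pytest.raises(ValueError, match="group"):
            demographics_table(cohort, self._selected(cohort))
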