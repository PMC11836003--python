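"""ROI statistics, rank tests, ROC, and logistic combinations."""

import numpy as np
import pandas as pd
import pytest

from aptperf.phantom import LABELS
from aptperf.roistats import (cohort_report, extract_region_stats,
                              logistic_combine, mann_whitney,
                              normalize_to_nawm, roc_auc)


def brute_force_u(a, b):
    """Pairwise counting oracle: min-orientation Mann-Whitney U."""
    a, b = np.asarray(a), np.asarray(b)
    wins = sum(1.0 if x > y else (0.5 if x == y else 0.0)
               for x in a for y in b)
    return min(wins, len(a) * len(b) - wins)


def make_labels():
    lab = np.zeros((6, 6, 2), np.int16)
    lab[0:2, 0:2] = LABELS["NAWM"]
    lab[2:4, 0:2] = LABELS["ET"]
    lab[4, 0] = LABELS["necrosis"]
    lab[4:6, 1] = LABELS["edema"]
    return lab


class TestExtractRegionStats:
    def test_constant_region(self):
        lab = make_labels()
        vol = np.where(lab == LABELS["ET"], 7.5, 1.0)
        stats = {s.region: s for s in extract_region_stats(vol, lab, "APTw")}
        assert stats["ET"].mean == stats["ET"].max == 7.5
        assert stats["ET"].sd == 0.0

    def test_small_region_values(self):
        lab = np.zeros((3, 1, 1), np.int16)
        lab[:, 0, 0] = LABELS["ET"]
        vol = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        s = extract_region_stats(vol, lab, "x")
        et = next(r for r in s if r.region == "ET")
        assert et.mean == 2.0 and et.max == 3.0 and et.n_voxels == 3

    def test_wt_equals_pooled_union_oracle(self):
        lab = make_labels()
        rng = np.random.default_rng(0)
        vol = rng.normal(size=lab.shape)
        stats = {s.region: s for s in extract_region_stats(vol, lab, "x")}
        pooled = vol[np.isin(lab, [LABELS["ET"], LABELS["ET_hot"],
                                   LABELS["necrosis"], LABELS["edema"]])]
        assert stats["WT"].mean == pytest.approx(pooled.mean())
        assert stats["WT"].max == pytest.approx(pooled.max())
        assert stats["WT"].n_voxels == pooled.size

    def test_missing_voxels_excluded_and_empty_region_omitted(self):
        lab = make_labels()
        vol = np.ones(lab.shape)
        vol[lab == LABELS["necrosis"]] = np.nan
        regions = {s.region for s in extract_region_stats(vol, lab, "x")}
        assert "necrosis" not in regions
        assert "WT" in regions and "ET" in regions


class TestNormalize:
    def make_stats(self):
        lab = make_labels()
        vol = np.where(lab == LABELS["ET"], 8.0, np.where(lab > 0, 2.0, np.nan))
        return extract_region_stats(vol, lab, "APTw")

    def test_division_by_nawm_mean(self):
        out = {s.region: s for s in normalize_to_nawm(self.make_stats())}
        assert out["NAWM"].mean == pytest.approx(1.0)
        assert out["ET"].mean == pytest.approx(4.0)
        assert all(s.is_normalized for s in out.values())

    def test_k2_passes_through(self):
        lab = make_labels()
        vol = np.where(lab > 0, 0.05, np.nan)
        out = normalize_to_nawm(extract_region_stats(vol, lab, "K2"))
        assert all(s.mean == pytest.approx(0.05) for s in out)
        assert not any(s.is_normalized for s in out)

    def test_renormalization_rejected(self):
        once = normalize_to_nawm(self.make_stats())
        with pytest.raises(ValueError):
            normalize_to_nawm(once)

    def test_nonpositive_nawm_rejected(self):
        lab = make_labels()
        vol = np.where(lab == LABELS["NAWM"], -1.0, 2.0)
        with pytest.raises(ValueError):
            normalize_to_nawm(extract_region_stats(vol, lab, "APTw"))


class TestMannWhitney:
    def test_fully_tied_groups(self):
        u, p = mann_whitney([5.0] * 10, [5.0] * 8)
        assert u == 40.0  # n1*n2/2
        assert p == pytest.approx(1.0)

    def test_perfect_separation_10_vs_8(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(10, 20, 10)
        b = rng.uniform(0, 1, 8)
        u, p = mann_whitney(a, b)
        assert u == 0.0
        assert p < 0.001

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.normal(size=10), rng.normal(size=8)
            u, _ = mann_whitney(a, b)
            assert u == brute_force_u(a, b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestRocAuc:
    def test_perfect_separation(self):
        v = np.r_[np.ones(10), np.zeros(8)]
        y = np.r_[np.ones(10, int), np.zeros(8, int)]
        auc, se, (lo, hi) = roc_auc(v, y)
        assert auc == 1.0 and se == 0.0 and lo == hi == 1.0

    def test_orientation_not_flipped(self):
        v = np.r_[np.zeros(10), np.ones(8)]  # positives LOWER
        y = np.r_[np.ones(10, int), np.zeros(8, int)]
        auc, *_ = roc_auc(v, y)
        assert auc == 0.0

    def test_u_auc_identity_on_tie_free_data(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            pos, neg = rng.normal(0.3, 1, 10), rng.normal(0, 1, 8)
            auc, *_ = roc_auc(np.r_[pos, neg],
                              np.r_[np.ones(10, int), np.zeros(8, int)])
            u = brute_force_u(pos, neg)
            assert auc == pytest.approx(1 - u / 80) or \
                auc == pytest.approx(u / 80)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=18)
        y = (rng.random(18) < 0.5).astype(int)
        y[0], y[1] = 1, 0  # both classes present
        a1, *_ = roc_auc(v, y)
        a2, *_ = roc_auc(np.exp(3 * v), y)
        assert a1 == a2

    def test_null_distribution_converges_to_half(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=4000)
        y = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        auc, *_ = roc_auc(v, y)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestLogisticCombine:
    def test_single_predictor_preserves_auc(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=18)
        y = (x + rng.normal(0, 2, 18) > 0).astype(int)
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        model = logistic_combine(x[:, None], y, names=["x"])
        direct, *_ = roc_auc(x, y)
        assert model.auc == pytest.approx(direct) or model.separation

    def test_joint_separation_flagged(self):
        x = np.r_[np.ones(10), np.zeros(8)]
        x2 = np.r_[np.full(10, 2.0), np.full(8, -1.0)]
        y = np.r_[np.ones(10, int), np.zeros(8, int)]
        model = logistic_combine(np.c_[x, x2], y)
        assert model.separation and model.auc == 1.0

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(18, 2))
        x[:, 1] = 3.0
        y = (x[:, 0] > 0).astype(int)
        y[0] = 1 - y[0]  # break separation
        with pytest.warns(UserWarning):
            model = logistic_combine(x, y, names=["a", "b"])
        assert model.predictors == ["a"]

    def test_combination_improves_on_best_single_on_average(self):
        """In-sample logistic combination of correlated informative
        predictors typically matches or beats the best single predictor;
        the likelihood fit can rank slightly worse in individual small
        samples, but not on average."""
        rng = np.random.default_rng(7)
        deficits = []
        for _ in range(100):
            mean = np.array([0.8, 0.5])
            cov = np.array([[1.0, 0.4], [0.4, 1.0]])
            xp = rng.multivariate_normal(mean, cov, size=10)
            xn = rng.multivariate_normal([0, 0], cov, size=8)
            X = np.vstack([xp, xn])
            y = np.r_[np.ones(10, int), np.zeros(8, int)]
            singles = max(roc_auc(X[:, 0], y)[0], roc_auc(X[:, 1], y)[0])
            combo = logistic_combine(X, y).auc
            deficits.append(combo - singles)
        deficits = np.array(deficits)
        assert deficits.mean() > 0.0
        assert np.mean(deficits >= -0.02) > 0.85

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            logistic_combine(np.ones((3, 2)), [0, 1, 1])


class TestCohortReport:
    @staticmethod
    def null_cohort_df():
        rows = []
        for i in range(18):
            group = "GBM" if i < 10 else "MET"
            for region in ("ET", "edema", "NAWM"):
                for param in ("APTw", "cCBV", "K2"):
                    rows.append({"subject": f"s{i}", "group": group,
                                 "region": region, "parameter": param,
                                 "mean": 1.0, "max": 2.0})
        return pd.DataFrame(rows)

    def test_identical_subjects_give_null_statistics(self):
        gt, roc, combo = cohort_report(self.null_cohort_df())
        assert np.allclose(gt["p"], 1.0)
        assert np.allclose(roc["auc"], 0.5)

    def test_report_grid_complete(self):
        gt, roc, combo = cohort_report(self.null_cohort_df())
        assert set(roc["parameter"]) == {"nAPTw", "ncCBV", "K2"}
        assert set(roc["region"]) == {"ET", "edema"}  # NAWM excluded
        assert set(roc["statistic"]) == {"max", "mean"}
        # combos limited to those whose predictors exist in the maps
        assert set(combo["parameters"]) <= {"nAPTw + ncCBV", "nAPTw + K2"}

    def test_absent_region_rows_omitted(self):
        df = self.null_cohort_df()
        df = df[~((df.subject == "s0") & (df.region == "edema"))]
        gt, roc, combo = cohort_report(df)
        edema = gt[(gt.region == "edema") & (gt.statistic == "mean")]
        assert (edema["n_gbm"] == 9).all()
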