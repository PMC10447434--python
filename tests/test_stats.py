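import itertools

import numpy as np
import pandas as pd
import pytest

from pentadraw.stats import (
    assign_folds,
    calibrate_to_probability,
    delong_test,
    diagnosis_contrast_table,
    mmse_integrate,
    mmse_item_columns,
    out_of_fold_predict,
    roc_auc,
    variance_explained,
)


def toy_table(n_participants=30, visits=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_participants):
        for v in range(visits):
            rows.append({
                "participant_id": pid,
                "visit_index": v,
                "outcome": float(rng.normal()),
            })
    return pd.DataFrame(rows)


class TestAssignFolds:
    def test_balanced_participant_counts(self):
        tab = assign_folds(toy_table(100, 1), k=10, seed=1)
        counts = tab.groupby("fold")["participant_id"].nunique()
        assert (counts == 10).all()

    def test_all_visits_share_fold(self):
        tab = assign_folds(toy_table(20, 5), k=4, seed=2)
        per_pid = tab.groupby("participant_id")["fold"].nunique()
        assert (per_pid == 1).all()

    def test_deterministic(self):
        a = assign_folds(toy_table(), k=5, seed=3)["fold"]
        b = assign_folds(toy_table(), k=5, seed=3)["fold"]
        assert a.equals(b)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            assign_folds(toy_table(5, 1), k=10)


class TestOutOfFoldPredict:
    def test_train_mean_fitter_hand_computable(self):
        # 9 rows, 3 folds: each row's prediction is the mean outcome of
        # the other two folds
        tab = pd.DataFrame({
            "participant_id": list(range(9)),
            "visit_index": 0,
            "outcome": [1.0, 2, 3, 4, 5, 6, 7, 8, 9],
            "fold": [0, 0, 0, 1, 1, 1, 2, 2, 2],
        })

        def fitter(train):
            mean = train["outcome"].mean()
            return lambda rows: np.full(len(rows), mean)

        preds, models = out_of_fold_predict(tab, fitter)
        assert len(models) == 3
        assert np.allclose(preds[:3], np.mean([4, 5, 6, 7, 8, 9]))
        assert np.allclose(preds[3:6], np.mean([1, 2, 3, 7, 8, 9]))
        assert np.allclose(preds[6:], np.mean([1, 2, 3, 4, 5, 6]))

    def test_no_participant_leakage(self):
        tab = toy_table(40, 3)
        seen = []

        def fitter(train):
            seen.append(set(train["participant_id"]))
            return lambda rows: np.zeros(len(rows))

        work = assign_folds(tab, k=5, seed=0)
        preds, _ = out_of_fold_predict(work, fitter)
        assert len(preds) == len(tab) and np.isfinite(preds).all()
        for fold, train_pids in enumerate(seen):
            test_pids = set(work.loc[work["fold"] == fold, "participant_id"])
            assert not (train_pids & test_pids)

    def test_fitter_failure_names_fold(self):
        tab = assign_folds(toy_table(10, 1), k=2, seed=0)

        def bad(train):
            raise ValueError("nope")

        with pytest.raises(RuntimeError, match="fold 0"):
            out_of_fold_predict(tab, bad)


class TestVarianceExplained:
    def test_single_predictor_is_squared_correlation(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        ri = variance_explained(y, x[:, None], names=["x"])
        r = np.corrcoef(x, y)[0, 1]
        assert ri.shares[0] == pytest.approx(r * r, abs=1e-12)
        assert ri.r_squared == pytest.approx(r * r, abs=1e-12)

    def test_orthogonal_predictors_get_marginal_r2(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rngl = np.random.default_rng(5)
        y = 0.8 * x1 + 0.3 * x2 + rngl.normal(0, 0.5, n)
        ri = variance_explained(y, np.column_stack([x1, x2]))
        r2_1 = np.corrcoef(x1, y)[0, 1] ** 2
        r2_2 = np.corrcoef(x2, y)[0, 1] ** 2
        assert ri.shares[0] == pytest.approx(r2_1, abs=1e-10)
        assert ri.shares[1] == pytest.approx(r2_2, abs=1e-10)

    def test_matches_permutation_oracle(self, rng):
        # brute force: average incremental R^2 over all predictor orderings
        n, p = 120, 3
        L = np.array([[1, 0, 0], [0.6, 0.8, 0], [0.3, 0.4, 0.86]])
        X = rng.normal(size=(n, p)) @ L.T
        y = X @ [0.5, -0.3, 0.2] + rng.normal(size=n)

        def r2(cols):
            if not cols:
                return 0.0
            Z = np.column_stack([np.ones(n), X[:, list(cols)]])
            beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ beta
            return 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()

        oracle = np.zeros(p)
        perms = list(itertools.permutations(range(p)))
        for perm in perms:
            so_far = []
            for j in perm:
                before = r2(so_far)
                so_far.append(j)
                oracle[j] += r2(so_far) - before
        oracle /= len(perms)

        ri = variance_explained(y, X)
        assert np.allclose(ri.shares, oracle, atol=1e-10)
        assert sum(ri.shares) == pytest.approx(ri.r_squared, abs=1e-10)

    def test_shares_nonnegative_and_sum_to_r2(self, rng):
        X = rng.normal(size=(100, 4))
        y = X @ [1, 0.5, 0.2, 0] + rng.normal(size=100)
        ri = variance_explained(y, X)
        assert all(s >= -1e-12 for s in ri.shares)
        assert sum(ri.shares) == pytest.approx(ri.r_squared, abs=1e-10)

    def test_rank_deficient_rejected(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            variance_explained(rng.normal(size=50), X)

    def test_too_many_predictors_rejected(self, rng):
        X = rng.normal(size=(100, 11))
        with pytest.raises(ValueError, match="10"):
            variance_explained(rng.normal(size=100), X)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_printed_four_point_example(self):
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]) == 0.75

    def test_ties_counted_half(self):
        assert roc_auc([1, 1, 1, 1], [0, 0, 1, 1]) == 0.5

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=100)
        y = (rng.uniform(size=100) < 1 / (1 + np.exp(-s))).astype(int)
        assert roc_auc(np.exp(s), y) == pytest.approx(roc_auc(s, y), abs=1e-12)
        assert roc_auc(s**3, y) == pytest.approx(roc_auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores(self, rng):
        s = rng.normal(size=80)
        y = (rng.uniform(size=80) < 0.4).astype(int)
        auc_a, auc_b, z, p = delong_test(s, s, y)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_swap_flips_sign(self, rng):
        a = rng.normal(size=120)
        y = (rng.uniform(size=120) < 0.5).astype(int)
        b = a + rng.normal(0, 0.8, 120) + y * 0.5
        _, _, z1, p1 = delong_test(a, b, y)
        _, _, z2, p2 = delong_test(b, a, y)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_auc_matches_roc_auc(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        y = (rng.uniform(size=60) < 0.5).astype(int)
        auc_a, auc_b, _, _ = delong_test(a, b, y)
        assert auc_a == pytest.approx(roc_auc(a, y), abs=1e-12)
        assert auc_b == pytest.approx(roc_auc(b, y), abs=1e-12)

    def test_detects_known_difference(self, rng):
        n = 400
        y = np.repeat([0, 1], n // 2)
        strong = y * 1.5 + rng.normal(size=n)
        weak = y * 0.2 + rng.normal(size=n)
        auc_s, auc_w, z, p = delong_test(strong, weak, y)
        assert auc_s > auc_w and p < 0.001

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2], [1, 2, 3], [0, 1])


class TestCalibration:
    @staticmethod
    def simulated(n=400, slope=1.5, seed=0):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + slope * s)))
        y = (rng.uniform(size=n) < p).astype(int)
        folds = np.arange(n) % 4
        return s, y, folds

    def test_probabilities_in_unit_interval(self):
        s, y, folds = self.simulated()
        prob = calibrate_to_probability(s, y, folds)
        assert np.all((prob >= 0) & (prob <= 1))

    def test_constant_score_gives_prevalence(self):
        y = np.array([0, 1, 1, 0, 1, 0, 1, 1])
        folds = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        prob = calibrate_to_probability(np.ones(8), y, folds)
        assert np.allclose(prob[:4], y[4:].mean())
        assert np.allclose(prob[4:], y[:4].mean())

    def test_monotone_in_score_within_fold(self):
        s, y, folds = self.simulated()
        prob = calibrate_to_probability(s, y, folds)
        for f in np.unique(folds):
            m = folds == f
            order = np.argsort(s[m])
            assert np.all(np.diff(prob[m][order]) >= -1e-12)

    def test_recovers_known_slope(self):
        import statsmodels.api as sm

        s, y, _ = self.simulated(n=1000, slope=1.5, seed=3)
        fit = sm.Logit(y, sm.add_constant(s)).fit(disp=0)
        assert abs(fit.params[1] - 1.5) < 2 * fit.bse[1]

    def test_single_class_partition_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            calibrate_to_probability([1.0, 2.0, 3.0, 4.0], [0, 1, 1, 1],
                                     [0, 0, 1, 1])


class TestMMSEIntegrate:
    @staticmethod
    def items(n=6, seed=0):
        rng = np.random.default_rng(seed)
        data = {c: rng.integers(0, 2, n) for c in mmse_item_columns()}
        return pd.DataFrame(data)

    def test_zero_probability_recovers_mmse29(self):
        items = self.items()
        m29 = mmse_integrate(items, mode="MMSE29")
        m29s = mmse_integrate(items, np.zeros(len(items)), "MMSE29+score")
        assert np.allclose(m29s, m29)

    def test_unit_probability_with_passing_item_equals_mmse30(self):
        items = self.items()
        items["mmse_item_30"] = 1
        m30 = mmse_integrate(items, mode="MMSE30")
        m29s = mmse_integrate(items, np.ones(len(items)), "MMSE29+score")
        assert np.allclose(m29s, m30)

    def test_missing_pentagon_item_rejected(self):
        items = self.items().drop(columns=["mmse_item_30"])
        with pytest.raises(ValueError, match="mmse_item_30"):
            mmse_integrate(items, mode="MMSE30")

    def test_bad_mode_and_bad_probability(self):
        items = self.items()
        with pytest.raises(ValueError):
            mmse_integrate(items, mode="MMSE28")
        with pytest.raises(ValueError):
            mmse_integrate(items, np.full(len(items), 1.5), "MMSE29+score")


class TestDiagnosisContrast:
    def test_first_diagnosed_visit_selected(self):
        tab = pd.DataFrame({
            "participant_id": [1, 1, 1, 2, 2, 3],
            "visit_index": [0, 1, 2, 0, 1, 0],
            "diagnosis": ["NCI", "MCI", "DM", "NCI", "NCI", "DM"],
        })
        ct = diagnosis_contrast_table(tab, "NCI-DM")
        # participant 1 contributes the visit-2 DM row, participant 2 the
        # baseline NCI row, participant 3 the DM row
        assert set(ct["label"]) == {0, 1}
        p1 = ct[(ct["participant_id"] == 1)]
        assert (p1["visit_index"] == 2).all() and (p1["label"] == 1).all()
        p2 = ct[(ct["participant_id"] == 2)]
        assert (p2["visit_index"] == 0).all()

    def test_unknown_group_rejected(self):
        tab = pd.DataFrame({
            "participant_id": [1], "visit_index": [0], "diagnosis": ["NCI"]})
        with pytest.raises(ValueError):
            diagnosis_contrast_table(tab, "NCI-DM")
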