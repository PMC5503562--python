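"""Dichotomization, scaling/splitting, model families, AUC, DeLong, permutation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prolifindex.io import ExpressionMatrix, ValidationError
from prolifindex.model import (DichotomizedDesign, delong_test, dichotomize,
                               evaluate_model, fit_model, full_cohort_assessment,
                               permutation_null, scale_and_partition)


def _cohort(entries):
    """entries: (sample_id, days, event) for one cancer 'X'."""
    return pd.DataFrame([{"sample_id": s, "cancer_type": "X",
                          "survival_days": float(d), "event": bool(e)}
                         for s, d, e in entries])


class TestDichotomize:
    def test_exact_fit_all_assigned(self):
        # 2k patients, k deaths among the k shortest survivors
        entries = [(f"p{i:02d}", i + 1, i < 3) for i in range(6)]
        design = dichotomize(_cohort(entries), k=3)
        a = design.assignments
        assert len(a) == 6
        short = a[a["outcome"] == 0]
        assert sorted(short["sample_id"]) == ["p00", "p01", "p02"]
        assert short["event"].all()     # outcome 0 is uncensored by construction
        assert sorted(a.loc[a["outcome"] == 1, "sample_id"]) == ["p03", "p04", "p05"]

    def test_tie_at_kth_keeps_lexicographically_smaller_id(self):
        entries = [("pB", 5, 1), ("pA", 5, 1), ("pC", 1, 1),
                   ("pD", 9, 1), ("pE", 10, 0), ("pF", 11, 0)]
        design = dichotomize(_cohort(entries), k=2)
        short = design.assignments.query("outcome == 0")
        assert sorted(short["sample_id"]) == ["pA", "pC"]

    def test_insufficient_cancer_excluded_with_warning(self):
        entries = [(f"p{i}", i, i < 2) for i in range(6)]   # only 2 deaths < k=3
        both = pd.concat([_cohort(entries),
                          _cohort([(f"q{i}", i + 1, i < 3) for i in range(6)])
                         .assign(cancer_type="Y",
                                 sample_id=lambda d: "Y" + d["sample_id"])])
        with pytest.warns(UserWarning, match="excluded"):
            design = dichotomize(both, k=3)
        assert design.excluded_cancers == ["X"]


@pytest.fixture()
def toy_design():
    rng = np.random.default_rng(0)
    entries = [(f"p{i:02d}", i + 1.0, i < 18) for i in range(18)]
    entries += [(f"q{i:02d}", 100.0 + i, 1) for i in range(18)]
    cohort = _cohort(entries)
    design = dichotomize(cohort, k=18)
    genes = [f"g{i}" for i in range(40)]
    data = pd.DataFrame(rng.normal(5, 2, (40, 36)), index=genes,
                        columns=cohort["sample_id"])
    data.iloc[1] = 7.0   # zero-variance gene
    expr = {"X": ExpressionMatrix(data, "vst")}
    return expr, design


class TestScaleAndPartition:
    def test_per_cancer_scaling_and_split_arithmetic(self, toy_design):
        expr, design = toy_design
        out = scale_and_partition(expr, design, seed=1)
        feats = out.features
        assert np.allclose(feats.mean(axis=0), 0, atol=1e-12)
        sds = feats.std(axis=0, ddof=0)
        assert np.allclose(sds[sds > 0], 1, atol=1e-12)
        assert np.allclose(feats["g1"], 0)   # zero-variance gene scaled to 0
        # 36 patients -> ceil(0.7*18)=13 per outcome: 26 train / 10 test
        assert len(out.train_ids) == 26 and len(out.test_ids) == 10
        y_train = out.outcomes.loc[out.train_ids]
        assert abs((y_train == 0).sum() - (y_train == 1).sum()) <= 1

    def test_same_seed_same_partition(self, toy_design):
        expr, design = toy_design
        a = scale_and_partition(expr, design, seed=7)
        b = scale_and_partition(expr, design, seed=7)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        c = scale_and_partition(expr, design, seed=8)
        assert c.train_ids != a.train_ids


def _design_from_arrays(X, y):
    ids = [f"s{i:03d}" for i in range(len(y))]
    assignments = pd.DataFrame({"sample_id": ids, "cancer_type": "X",
                                "survival_days": 1.0, "event": True,
                                "outcome": y})
    feats = pd.DataFrame(X, index=ids, columns=[f"g{j}" for j in range(X.shape[1])])
    n_train = int(0.7 * len(y))
    return DichotomizedDesign(assignments=assignments, k=18, features=feats,
                              train_ids=ids[:n_train], test_ids=ids[n_train:])


class TestFitAndEvaluate:
    def test_lasso_selects_perfectly_separating_feature(self):
        rng = np.random.default_rng(3)
        y = np.tile([0, 1], 40)
        X = rng.normal(size=(80, 10))
        X[:, 4] = y * 2 - 1 + rng.normal(0, 0.05, 80)
        design = _design_from_arrays(X, y)
        model = fit_model(design, "lasso", seed=0)
        assert model.coefficients["g4"] != 0
        ev = evaluate_model(model, design)
        assert ev.auc == 1.0

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(5)
        y = rng.permutation(np.repeat([0, 1], 125))
        X = rng.normal(size=(250, 50))
        design = _design_from_arrays(X, y)
        model = fit_model(design, "lasso", seed=1)
        ev = evaluate_model(model, design)
        assert 0.35 <= ev.auc <= 0.65

    def test_penalty_geometry_lasso_zeros_ridge_none(self):
        rng = np.random.default_rng(7)
        y = np.tile([0, 1], 30)
        X = rng.normal(size=(60, 30)) + 0.3 * (y * 2 - 1)[:, None] * rng.uniform(
            0, 1, 30)[None, :]
        design = _design_from_arrays(X, y)
        lasso = fit_model(design, "lasso", seed=0)
        ridge = fit_model(design, "ridge", seed=0)
        assert (lasso.coefficients == 0).any()
        assert (ridge.coefficients != 0).all()
        assert lasso.hyperparameters["alpha"] == 1.0
        assert ridge.hyperparameters["alpha"] == 0.0

    def test_alternative_families_fit_and_score(self):
        rng = np.random.default_rng(11)
        y = np.tile([0, 1], 30)
        X = rng.normal(size=(60, 8))
        X[:, 0] += 1.5 * y
        design = _design_from_arrays(X, y)
        for family in ("random_forest", "linear_svm"):
            ev = evaluate_model(fit_model(design, family, seed=2), design)
            assert ev.auc > 0.7

    def test_single_class_training_set_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        design = _design_from_arrays(X, np.zeros(20, dtype=int))
        with pytest.raises(ValidationError, match="single-class"):
            fit_model(design, "lasso")

    def test_constant_scores_auc_half_and_perfect_scores_auc_one(self):
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        X = np.zeros((10, 2))
        design = _design_from_arrays(X, y)
        design.test_ids = design.assignments["sample_id"].tolist()

        class Stub:
            def __init__(self, scores):
                self.family = "lasso"
                self.feature_names = ["g0", "g1"]
                self.coefficients = pd.Series([0.0, 0.0], index=["g0", "g1"])
                self.intercept = 0.0
                self._s = scores

            def score(self, Xdf):
                return self._s[:len(Xdf)]

        ev = evaluate_model(Stub(np.zeros(10)), design)
        assert ev.auc == pytest.approx(0.5)
        ev = evaluate_model(Stub(y.astype(float)), design)
        assert ev.auc == pytest.approx(1.0)

    def test_auc_equals_mann_whitney_u_statistic(self):
        y = np.array([0, 1, 1, 0, 1, 0])
        scores = np.array([0.1, 0.9, 0.4, 0.35, 0.8, 0.2])
        design = _design_from_arrays(np.zeros((6, 2)), y)
        design.test_ids = design.assignments["sample_id"].tolist()

        class Stub:
            family = "random_forest"
            feature_names = ["g0", "g1"]

            def score(self, Xdf):
                return scores

        ev = evaluate_model(Stub(), design)
        u = stats.mannwhitneyu(scores[y == 1], scores[y == 0],
                               alternative="two-sided").statistic
        assert ev.auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_auc_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        scores = rng.normal(size=40)
        design = _design_from_arrays(np.zeros((40, 2)), y)
        design.test_ids = design.assignments["sample_id"].tolist()

        class Stub:
            family = "random_forest"
            feature_names = ["g0", "g1"]

            def __init__(self, s):
                self._s = s

            def score(self, Xdf):
                return self._s

        auc_raw = evaluate_model(Stub(scores), design).auc
        auc_mono = evaluate_model(Stub(np.exp(3 * scores)), design).auc
        assert auc_raw == pytest.approx(auc_mono)

    def test_single_class_test_set_rejected(self):
        y = np.array([0, 1] * 5 + [1, 1, 1, 1])
        design = _design_from_arrays(np.zeros((14, 2)), y)
        design.train_ids = design.assignments["sample_id"].tolist()[:10]
        design.test_ids = design.assignments["sample_id"].tolist()[10:]

        class Stub:
            family = "random_forest"
            feature_names = ["g0", "g1"]

            def score(self, Xdf):
                return np.zeros(len(Xdf))

        with pytest.raises(ValidationError, match="single-class"):
            evaluate_model(Stub(), design)


class TestDeLong:
    def test_identical_scores_no_difference(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 20)
        s = rng.normal(size=40)
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_detects_clear_auc_difference(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 100)
        good = y + rng.normal(0, 0.3, 200)
        bad = rng.normal(size=200)
        z, p = delong_test(good, bad, y)
        assert z > 0 and p < 0.01


class TestPermutationAndFullCohort:
    def test_permutation_proportional_to_planted_pics(self, small_sim,
                                                      small_analysis):
        _, _, truth = small_sim
        res = small_analysis
        run = permutation_null(res["cohort"], res["vst"], res["labels"].pics,
                               n_draws=6, set_size=3, seed=4)
        assert len(run.draws) == 6
        assert set(run.draws.columns) == {"cancers", "n_pics", "auc"}
        # determinism of the draw sequence
        run2 = permutation_null(res["cohort"], res["vst"], res["labels"].pics,
                                n_draws=6, set_size=3, seed=4)
        pd.testing.assert_frame_equal(run.draws, run2.draws)

    def test_all_pic_draws_have_undefined_rho(self, small_sim, small_analysis):
        res = small_analysis
        all_cancers = list(res["cohort"]["cancer_type"].unique())
        with pytest.warns(UserWarning, match="rho undefined"):
            run = permutation_null(res["cohort"], res["vst"], all_cancers,
                                   n_draws=3, set_size=6, seed=0)
        assert np.isnan(run.rho)
        assert (run.draws["n_pics"] == 6).all()

    def test_full_cohort_flags_follow_heldout_rule(self, small_sim, small_analysis):
        _, cohort, truth = small_sim
        res = small_analysis
        pics = res["labels"].pics
        sub = res["cohort"][res["cohort"]["cancer_type"].isin(pics)]
        design = dichotomize(sub, k=18)
        design = scale_and_partition(res["vst"], design, seed=0)
        # ridge: guaranteed non-constant scores even on this underpowered toy
        # world (the 1-SE lasso can defensibly choose the empty model here)
        model = fit_model(design, "ridge", seed=0)
        out = full_cohort_assessment(model, res["cohort"], res["vst"], design,
                                     cancers=pics)
        for cancer in pics:
            non_train = res["cohort"][
                (res["cohort"]["cancer_type"] == cancer)
                & ~res["cohort"]["sample_id"].isin(design.train_ids)]
            expected = ("held_out" if non_train["event"].sum() > 25
                        else "includes_training")
            assert out.table.loc[cancer, "flag"] == expected
        assert (out.table["p_value"] <= 1).all()
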