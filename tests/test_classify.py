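"""LOOCV random-forest screening: accuracy, intervals, ROC, invariances."""

import numpy as np
import pytest

import thermomics as tm
from thermomics.classify import DesignMatrix
from thermomics.errors import ValidationError
from thermomics.phantom_sim import CohortRecord


def make_dm(X, y, feature_set="latent_only", prefix="S"):
    return DesignMatrix(X=X, labels=y,
                        subject_ids=[f"{prefix}{i:04d}" for i in range(len(y))],
                        feature_names=[f"x{j}" for j in range(X.shape[1])],
                        feature_set=feature_set)


@pytest.fixture
def separable_dm(rng):
    X = np.vstack([rng.normal(0, 0.5, (20, 5)), rng.normal(10, 0.5, (20, 5))])
    y = np.array([0] * 20 + [1] * 20)
    return make_dm(X, y)


class TestLoocvRandomForest:
    def test_separable_clusters_give_perfect_accuracy(self, separable_dm):
        rep = tm.loocv_random_forest(separable_dm, n_trees=200, seed=0,
                                     n_bootstrap=300)
        assert rep.accuracy == 100.0
        assert rep.roc_auc == 1.0
        assert rep.n_subjects == 40

    def test_permuted_labels_fall_in_chance_bounds(self, rng):
        """Label-permuted balanced design: accuracy within +/- 3 binomial SD
        of chance, i.e. [25%, 75%] at n=40."""
        X = rng.normal(0, 1, (40, 5))
        y = rng.permutation([0] * 20 + [1] * 20)
        rep = tm.loocv_random_forest(make_dm(X, y), n_trees=200, seed=1,
                                     n_bootstrap=300)
        assert 25.0 <= rep.accuracy <= 75.0

    def test_interval_contains_point_accuracy(self, separable_dm):
        rep = tm.loocv_random_forest(separable_dm, n_trees=100, seed=0,
                                     n_bootstrap=200)
        lo, hi = rep.accuracy_interval
        assert lo <= rep.accuracy <= hi

    def test_interval_width_shrinks_with_n(self, rng):
        def width(n):
            X = np.vstack([rng.normal(0, 1.2, (n // 2, 3)),
                           rng.normal(1.2, 1.2, (n // 2, 3))])
            y = np.array([0] * (n // 2) + [1] * (n // 2))
            rep = tm.loocv_random_forest(make_dm(X, y), n_trees=100, seed=2,
                                         n_bootstrap=500)
            lo, hi = rep.accuracy_interval
            return hi - lo
        assert width(200) < width(40)

    def test_row_order_invariance(self, separable_dm, rng):
        """Permuting subjects permutes out-of-fold predictions identically."""
        rep0 = tm.loocv_random_forest(separable_dm, n_trees=100, seed=0,
                                      n_bootstrap=200)
        perm = rng.permutation(separable_dm.n_subjects)
        dmp = DesignMatrix(
            X=separable_dm.X[perm], labels=separable_dm.labels[perm],
            subject_ids=[separable_dm.subject_ids[i] for i in perm],
            feature_names=separable_dm.feature_names)
        repp = tm.loocv_random_forest(dmp, n_trees=100, seed=0, n_bootstrap=200)
        a = rep0.predictions.sort_values("subject_id").reset_index(drop=True)
        b = repp.predictions.sort_values("subject_id").reset_index(drop=True)
        assert a.equals(b)
        assert rep0.accuracy == repp.accuracy

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (10, 3))
        with pytest.raises(ValidationError, match="class"):
            tm.loocv_random_forest(make_dm(X, np.zeros(10, dtype=int)))

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValidationError, match="3 subjects"):
            tm.loocv_random_forest(make_dm(rng.normal(0, 1, (2, 2)),
                                           np.array([0, 1])))


class TestBuildDesignMatrix:
    @pytest.fixture
    def records(self, rng):
        recs = []
        for i in range(12):
            label = "healthy" if i < 6 else "symptomatic"
            recs.append(CohortRecord(f"S{i:04d}", 40.0 + i, "diabetes" if i % 3 == 0 else "none",
                                     bool(i % 2), label))
        return recs

    def test_latent_only_shape_and_labels(self, records, rng):
        codes = rng.normal(0, 1, (12, 16))
        dm = tm.build_design_matrix(codes, records, feature_set="latent_only")
        assert dm.X.shape == (12, 16)
        assert dm.labels.tolist() == [0] * 6 + [1] * 6

    def test_clinical_any_vs_none_encoding(self, records):
        dm = tm.build_design_matrix(None, records, feature_set="clinical_only")
        assert dm.feature_names == ["age", "family_history_any"]
        fh = dm.X[:, 1]
        assert set(fh.tolist()) == {0.0, 1.0}

    def test_clinical_one_hot_encoding(self, records):
        dm = tm.build_design_matrix(None, records, feature_set="clinical_only",
                                    family_history_any=False,
                                    include_hormone_therapy=True)
        assert "family_history_diabetes" in dm.feature_names
        assert "hormone_therapy" in dm.feature_names

    def test_missing_codes_rejected(self, records):
        with pytest.raises(ValidationError):
            tm.build_design_matrix(None, records, feature_set="latent_only")


class TestCompareFeatureSets:
    def test_additive_covariate_signal_helps(self, rng):
        """Weak latent signal + informative age: latent+clinical >= latent."""
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        X = np.vstack([rng.normal(0, 1.0, (20, 4)), rng.normal(0.8, 1.0, (20, 4))])
        sids = [f"S{i:04d}" for i in range(n)]
        recs = [CohortRecord(sids[i],
                             50.0 + 5 * rng.standard_normal() if y[i] == 0
                             else 72.0 + 5 * rng.standard_normal(),
                             "none", False,
                             "healthy" if y[i] == 0 else "symptomatic")
                for i in range(n)]
        dml = tm.build_design_matrix(X, recs, subject_ids=sids,
                                     feature_set="latent_only")
        dmc = tm.build_design_matrix(X, recs, subject_ids=sids,
                                     feature_set="latent_plus_clinical")
        table, reports = tm.compare_feature_sets([dml, dmc], seed=0,
                                                 n_trees=300, n_bootstrap=300)
        assert (reports["latent_plus_clinical"].accuracy
                >= reports["latent_only"].accuracy)
        assert set(table["feature_set"]) == {"latent_only", "latent_plus_clinical"}

    def test_label_independent_covariates_are_chance(self, rng):
        """Clinical-only on a cohort whose covariates ignore the label."""
        n = 40
        y = np.array([0, 1] * 20)
        sids = [f"S{i:04d}" for i in range(n)]
        recs = [CohortRecord(sids[i], float(rng.integers(30, 90)),
                             "diabetes" if rng.random() < 0.25 else "none",
                             bool(rng.random() < 0.18),
                             "healthy" if y[i] == 0 else "symptomatic")
                for i in range(n)]
        dm = tm.build_design_matrix(None, recs, subject_ids=sids,
                                    feature_set="clinical_only")
        rep = tm.loocv_random_forest(dm, n_trees=200, seed=3, n_bootstrap=300)
        assert 25.0 <= rep.accuracy <= 75.0

    def test_single_variant_equals_direct_call(self, separable_dm):
        table, reports = tm.compare_feature_sets([separable_dm], seed=0,
                                                 n_trees=100, n_bootstrap=200)
        direct = tm.loocv_random_forest(separable_dm, n_trees=100, seed=0,
                                        n_bootstrap=200)
        assert len(table) == 1
        assert reports["latent_only"].accuracy == direct.accuracy
        assert reports["latent_only"].roc_auc == direct.roc_auc

    def test_subject_mismatch_rejected(self, rng):
        y = np.array([0] * 5 + [1] * 5)
        a = make_dm(rng.normal(0, 1, (10, 3)), y, prefix="A")
        b = make_dm(rng.normal(0, 1, (10, 3)), y, prefix="B")
        with pytest.raises(ValidationError, match="identical subjects"):
            tm.compare_feature_sets([a, b])


def test_eval_report_json_round_trip(separable_dm, tmp_path):
    import json

    rep = tm.loocv_random_forest(separable_dm, n_trees=50, seed=0, n_bootstrap=100)
    rep.save_json(tmp_path / "rep.json")
    with open(tmp_path / "rep.json") as fh:
        d = json.load(fh)
    assert d["accuracy"] == rep.accuracy
    assert len(d["predictions"]["subject_id"]) == rep.n_subjects
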