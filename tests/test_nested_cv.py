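import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ccpredict.classifiers import ClassifierSpec
from ccpredict.expression_io import DomainError, ExpressionMatrix, LabelVector
from ccpredict.nested_cv import (
    CVResult,
    FeatureSelectionConfig,
    choose_optimal,
    confusion_metrics,
    final_signature,
    loocv,
    select_features_ttest,
)
from ccpredict.preprocess import filter_above_background
from ccpredict.synthetic_data import SimulationConfig, simulate_study


def toy_study(values, n_pos, n_neg):
    values = np.asarray(values, dtype=float)
    sample_ids = [f"s{j}" for j in range(n_pos + n_neg)]
    X = ExpressionMatrix([f"p{i}" for i in range(values.shape[0])],
                         sample_ids, values)
    y = LabelVector({s: ("LB" if j < n_pos else "NP")
                     for j, s in enumerate(sample_ids)}, "LB", "NP")
    return X, y


class TestFeatureSelection:
    def test_textbook_pooled_t(self):
        # A = (1,2,3) vs B = (7,8,9): hand-computed Student t
        X, y = toy_study([[1, 2, 3, 7, 8, 9]], 3, 3)
        sig = select_features_ttest(X, y, 0.05)
        m1, m2 = 2.0, 8.0
        sp2 = (2 * 1.0 + 2 * 1.0) / 4  # both sample variances are 1
        t_expected = (m1 - m2) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), 4)
        assert sig.table["t_statistic"][0] == pytest.approx(t_expected, abs=1e-10)
        assert sig.table["p_value"][0] == pytest.approx(p_expected, abs=1e-10)

    @given(st.integers(0, 100))
    def test_matches_scipy_ttest_ind(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(15, 9))
        X, y = toy_study(np.abs(vals), 4, 5)
        sig = select_features_ttest(X, y, 0.999999)
        ypos = y.y(X.sample_ids)
        t_ref, p_ref = stats.ttest_ind(X.values[:, ypos], X.values[:, ~ypos],
                                       axis=1)
        by_probe = dict(zip(sig.table["probe_id"],
                            zip(sig.table["t_statistic"], sig.table["p_value"])))
        for i, probe in enumerate(X.probe_ids):
            if probe in by_probe:
                t, p = by_probe[probe]
                assert t == pytest.approx(t_ref[i], abs=1e-10)
                assert p == pytest.approx(p_ref[i], abs=1e-10)

    def test_constant_probe_never_selected(self):
        X, y = toy_study([[5.0] * 6, [1, 2, 3, 7, 8, 9]], 3, 3)
        sig = select_features_ttest(X, y, 0.9999)
        assert "p0" not in sig.probe_ids
        assert "p1" in sig.probe_ids

    def test_all_p_below_cutoff_and_sorted(self):
        rng = np.random.default_rng(5)
        X, y = toy_study(rng.uniform(1, 100, size=(200, 10)), 5, 5)
        sig = select_features_ttest(X, y, 0.2)
        p = sig.table["p_value"].to_numpy()
        assert (p < 0.2).all()
        assert (np.diff(p) >= 0).all()

    def test_signed_fold_change(self):
        X, y = toy_study([[10, 11, 2.0, 2.2], [2.0, 2.2, 10, 11]], 2, 2)
        sig = select_features_ttest(X, y, 0.9999)
        fc = dict(zip(sig.table["probe_id"], sig.table["fold_change"]))
        assert fc["p0"] == pytest.approx(10.5 / 2.1)    # up in positive class
        assert fc["p1"] == pytest.approx(-10.5 / 2.1)   # down: -1/ratio

    def test_default_grid_is_the_four_cutoffs(self):
        assert FeatureSelectionConfig().p_grid == (0.001, 0.005, 0.01, 0.05)

    def test_grid_must_increase(self):
        with pytest.raises(DomainError):
            FeatureSelectionConfig((0.01, 0.005))

    def test_welch_variant_available(self):
        X, y = toy_study([[1, 2, 3, 7, 8, 100]], 3, 3)
        s = select_features_ttest(X, y, 0.9999, test="welch")
        ypos = y.y(X.sample_ids)
        t_ref, p_ref = stats.ttest_ind(X.values[:, ypos], X.values[:, ~ypos],
                                       axis=1, equal_var=False)
        assert s.table["t_statistic"][0] == pytest.approx(t_ref[0], abs=1e-10)
        assert s.table["p_value"][0] == pytest.approx(p_ref[0], abs=1e-10)


class TestLOOCV:
    def planted(self, seed=0, n_probes=300, fold_change=8.0, cv=0.15):
        cfg = SimulationConfig(n_pos=6, n_neg=7, n_probes=n_probes, n_de=10,
                               fold_change=fold_change, cv_within=cv,
                               frac_unannotated=0.0, frac_background=0.0,
                               seed=seed)
        X, _, y, truth = simulate_study(cfg)
        return X, y, truth

    def test_one_fold_per_sample_each_held_out_once(self):
        X, y, _ = self.planted()
        cv = loocv(X, y, ClassifierSpec("dLDA", p_cutoff=0.05))
        assert cv.n_folds == X.n_samples
        assert sorted(f.held_out for f in cv.per_fold) == sorted(X.sample_ids)

    def test_strong_signal_gives_perfect_accuracy(self):
        X, y, _ = self.planted()
        for spec in (ClassifierSpec("dLDA", p_cutoff=0.01),
                     ClassifierSpec("kNN", k=3, p_cutoff=0.01),
                     ClassifierSpec("SVM_linear", cost=1.0, p_cutoff=0.01)):
            assert loocv(X, y, spec).accuracy == 1.0, spec

    def test_support_equals_recount_of_fold_selections(self):
        X, y, _ = self.planted(seed=3, fold_change=2.0, cv=0.4)
        cv = loocv(X, y, ClassifierSpec("dLDA", p_cutoff=0.05))
        counts = {}
        for f in cv.per_fold:
            for p in f.selected:
                counts[p] = counts.get(p, 0) + 1
        expected = {p: 100.0 * c / cv.n_folds for p, c in counts.items()}
        assert cv.support == pytest.approx(expected)
        assert all(0 <= v <= 100 for v in cv.support.values())

    def test_fold_selection_ignores_held_out_sample(self):
        X, y, _ = self.planted(seed=4)
        spec = ClassifierSpec("dLDA", p_cutoff=0.05)
        base = loocv(X, y, spec)
        for i in (0, 5, 12):
            corrupted = X.values.copy()
            corrupted[:, i] = 1e6  # arbitrary garbage in the held-out sample
            Xc = ExpressionMatrix(X.probe_ids, X.sample_ids, corrupted)
            redo = loocv(Xc, y, spec)
            assert redo.per_fold[i].selected == base.per_fold[i].selected

    def test_empty_selection_predicts_training_majority(self, caplog):
        # constant matrix: no probe can ever pass selection
        X, y = toy_study(np.full((10, 7), 42.0), 3, 4)
        cv = loocv(X, y, ClassifierSpec("dLDA", p_cutoff=0.01))
        for f in cv.per_fold:
            assert f.proba == 0.5
            assert f.selected == []
        # training majority is NP except when an NP sample is held out and
        # counts tie at 3-3 (tie resolves to the negative class)
        assert all(f.predicted == "NP" for f in cv.per_fold)

    def test_requires_three_per_class(self):
        X, y = toy_study(np.random.default_rng(0).uniform(1, 9, (5, 5)), 2, 3)
        with pytest.raises(DomainError):
            loocv(X, y, ClassifierSpec("dLDA"))

    def test_probabilities_attached_for_svm(self):
        X, y, _ = self.planted(seed=6)
        cv = loocv(X, y, ClassifierSpec("SVM_linear", cost=1.0, p_cutoff=0.01))
        probs = [f.proba for f in cv.per_fold]
        assert all(0.0 <= p <= 1.0 for p in probs)


class TestChooseOptimal:
    def fake_cv(self, accuracy, n_sel):
        m = confusion_metrics(1, 0, 1, 0)
        return CVResult([], accuracy, {}, m, {}, [n_sel] * 4)

    def test_argmax_accuracy(self):
        entries = [
            (ClassifierSpec("dLDA"), self.fake_cv(0.57, 10)),
            (ClassifierSpec("kNN", k=3), self.fake_cv(0.85, 40)),
            (ClassifierSpec("SVM_linear", cost=1.0), self.fake_cv(0.81, 34)),
        ]
        spec, cv = choose_optimal(entries)
        assert cv.accuracy == 0.85

    def test_tie_prefers_fewer_selected_features(self):
        entries = [
            (ClassifierSpec("SVM_linear", cost=1.0, p_cutoff=0.05),
             self.fake_cv(0.81, 82)),
            (ClassifierSpec("SVM_linear", cost=1.0, p_cutoff=0.01),
             self.fake_cv(0.81, 34)),
        ]
        spec, cv = choose_optimal(entries)
        assert spec.p_cutoff == 0.01

    def test_remaining_tie_prefers_svm_then_knn(self):
        entries = [
            (ClassifierSpec("dLDA"), self.fake_cv(0.8, 20)),
            (ClassifierSpec("kNN", k=3), self.fake_cv(0.8, 20)),
            (ClassifierSpec("SVM_linear", cost=1.0), self.fake_cv(0.8, 20)),
        ]
        assert choose_optimal(entries)[0].algorithm == "SVM_linear"
        assert choose_optimal(entries[:2])[0].algorithm == "kNN"

    def test_equals_brute_force_max(self):
        rng = np.random.default_rng(7)
        entries = [(ClassifierSpec("dLDA", p_cutoff=p), self.fake_cv(a, n))
                   for p, a, n in zip((0.001, 0.005, 0.01, 0.05),
                                      rng.uniform(0.4, 1.0, 4),
                                      rng.integers(5, 100, 4))]
        best = max(e[1].accuracy for e in entries)
        assert choose_optimal(entries)[1].accuracy == best

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            choose_optimal([])


class TestFinalSignature:
    def test_planted_probes_recovered_and_support_attached(self):
        cfg = SimulationConfig(n_pos=6, n_neg=7, n_probes=400, n_de=12,
                               fold_change=8.0, cv_within=0.15,
                               frac_unannotated=0.0, frac_background=0.0,
                               seed=9)
        X, annot, y, truth = simulate_study(cfg)
        spec = ClassifierSpec("dLDA", p_cutoff=0.01)
        cv = loocv(X, y, spec)
        sig = final_signature(X, y, 0.01, cv, annot=annot)
        # every planted probe passing full-data selection appears
        full = set(select_features_ttest(X, y, 0.01).probe_ids)
        assert truth.de_probe_ids & full <= set(sig.probe_ids)
        # probes selected in all folds carry 100% support, and with this
        # strong signal more than half the signature reaches >= 89%
        sup = sig.table["cv_support"].to_numpy()
        always = [p for p, v in cv.support.items() if v == 100.0]
        by_probe = dict(zip(sig.table["probe_id"], sup))
        assert all(by_probe[p] == 100.0 for p in always if p in by_probe)
        assert (sup >= 89.0).sum() > len(sig) / 2
        # ordering: descending support, then ascending p
        key = list(zip(-sig.table["cv_support"], sig.table["p_value"]))
        assert key == sorted(key)
        # symbols filled from the annotation
        assert all(s for s in sig.table["gene_symbol"])

    def test_empty_selection_advises_larger_cutoff(self):
        X, y = toy_study(np.full((5, 7), 3.0), 3, 4)
        cv = loocv(X, y, ClassifierSpec("dLDA", p_cutoff=0.01))
        with pytest.raises(DomainError, match="larger cutoff"):
            final_signature(X, y, 0.01, cv)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(8, 0, 0, 0)
        assert m.accuracy == 1.0 and m.sensitivity == 1.0 and m.ppv == 1.0
        assert "specificity" in m.undefined and "npv" in m.undefined

    def test_all_zero_rejected(self):
        with pytest.raises(DomainError):
            confusion_metrics(0, 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(DomainError):
            confusion_metrics(-1, 0, 1, 0)

    @given(st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50), st.integers(0, 50))
    def test_identities_hold_for_all_counts(self, tp, fn, tn, fp):
        if tp + fn + tn + fp == 0:
            return
        m = confusion_metrics(tp, fn, tn, fp)
        assert m.accuracy == pytest.approx((tp + tn) / (tp + fn + tn + fp))
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
        else:
            assert m.sensitivity == 0.0 and "sensitivity" in m.undefined
        if tn + fp:
            assert m.specificity == pytest.approx(tn / (tn + fp))
        if tp + fp:
            assert m.ppv == pytest.approx(tp / (tp + fp))
        if tn + fn:
            assert m.npv == pytest.approx(tn / (tn + fn))
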