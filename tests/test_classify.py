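import numpy as np
import pandas as pd
import pytest

from morphoscreen.classify import (
    ClassifierSpec,
    TrainedModel,
    evaluate_classifier,
    score_treated,
    split_controls,
    train_classifier,
)


def _control_table(n_wt_wells, n_ko_wells, fields=1, sep=0.0, seed=0, k=4):
    """Control image records in score space; classes shifted by ``sep``."""
    rng = np.random.default_rng(seed)
    rows = []
    widx = 0
    for cls, n_wells in (("WT", n_wt_wells), ("KO", n_ko_wells)):
        mu = np.zeros(k) if cls == "KO" else np.full(k, sep)
        for _ in range(n_wells):
            widx += 1
            for f in range(1, fields + 1):
                rows.append(
                    {"plate_id": f"P{1 + widx % 3:02d}", "well": f"W{widx:03d}",
                     "subclone_id": "SC1", "genotype": cls, "treatment": "VEHICLE",
                     "concentration_nM": 0.0, "field": f,
                     **{f"PC{j + 1:02d}": mu[j] + rng.standard_normal()
                        for j in range(k)}}
                )
    return pd.DataFrame(rows)


class TestSplitControls:
    def test_stratified_counts(self):
        t = _control_table(100, 50)
        spec = ClassifierSpec(test_fraction=0.2, seed=1)
        train, test = split_controls(t, spec)
        assert (test["genotype"] == "WT").sum() == 20
        assert (test["genotype"] == "KO").sum() == 10

    def test_disjoint_and_exhaustive(self):
        t = _control_table(30, 20, fields=2)
        train, test = split_controls(t, ClassifierSpec(seed=2))
        assert len(train) + len(test) == len(t)
        key = lambda d: set(map(tuple, d[["plate_id", "well", "field"]].to_numpy()))
        assert key(train) & key(test) == set()

    def test_wells_never_straddle_the_split(self):
        t = _control_table(24, 16, fields=4)
        train, test = split_controls(t, ClassifierSpec(seed=3))
        for part in (train, test):
            sides = part.groupby(["plate_id", "well"]).size()
            assert (sides == 4).all()

    def test_single_class_rejected(self):
        t = _control_table(10, 5)
        with pytest.raises(ValueError):
            split_controls(t[t["genotype"] == "WT"], ClassifierSpec())


class TestTraining:
    def test_separable_controls_classified_perfectly(self):
        t = _control_table(40, 30, fields=2, sep=8.0, seed=4)
        spec = ClassifierSpec(sizes=(3,), decays=(1e-3,), seed=5)
        train, test = split_controls(t, spec)
        model = train_classifier(train, spec)
        report = evaluate_classifier(model, test)
        assert report.accuracy == 1.0
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0

    def test_shuffled_labels_give_chance_accuracy(self):
        t = _control_table(60, 60, fields=2, sep=6.0, seed=6)
        rng = np.random.default_rng(8)
        t["genotype"] = rng.permutation(t["genotype"].to_numpy())
        # regroup labels per well so the split contract still holds
        lab = t.groupby(["plate_id", "well"])["genotype"].transform("first")
        t["genotype"] = lab
        spec = ClassifierSpec(sizes=(3,), decays=(1e-2,), seed=9)
        train, test = split_controls(t, spec)
        model = train_classifier(train, spec)
        report = evaluate_classifier(model, test)
        majority = max((test["genotype"] == "WT").mean(),
                       (test["genotype"] == "KO").mean())
        assert abs(report.accuracy - majority) <= 0.25  # chance-level behaviour

    def test_same_seed_identical_predictions(self):
        t = _control_table(20, 15, fields=2, sep=2.0, seed=10)
        spec = ClassifierSpec(sizes=(3, 5), decays=(1e-3, 1e-1), seed=11)
        train, test = split_controls(t, spec)
        m1 = train_classifier(train, spec)
        m2 = train_classifier(train, spec)
        assert np.array_equal(m1.predict(test), m2.predict(test))
        assert (m1.chosen_size, m1.chosen_decay) == (m2.chosen_size, m2.chosen_decay)

    def test_single_class_training_rejected(self):
        t = _control_table(10, 5, sep=1.0)
        with pytest.raises(ValueError):
            train_classifier(t[t["genotype"] == "WT"], ClassifierSpec())

    @pytest.mark.parametrize("algorithm", ["rf", "svm"])
    def test_comparators_share_the_interface(self, algorithm):
        t = _control_table(30, 20, fields=2, sep=8.0, seed=12)
        spec = ClassifierSpec(algorithm=algorithm, seed=13)
        train, test = split_controls(t, spec)
        model = train_classifier(train, spec)
        report = evaluate_classifier(model, test)
        assert report.algorithm == algorithm
        assert report.accuracy == 1.0
        prob = model.focus_probability(test)
        assert np.all((0 <= prob) & (prob <= 1))


class _StubEstimator:
    """Fixed predictions/probabilities for metric arithmetic checks."""

    def __init__(self, pred, prob_wt):
        self._pred = np.asarray(pred)
        self._prob = np.asarray(prob_wt)
        self.classes_ = np.array(["KO", "WT"])

    def predict(self, X):
        return self._pred

    def predict_proba(self, X):
        return np.column_stack([1 - self._prob, self._prob])


def _stub_model(pred, prob_wt, k=2):
    return TrainedModel(
        estimator=_StubEstimator(pred, prob_wt), focus_class="WT",
        feature_columns=[f"PC{j + 1:02d}" for j in range(k)],
        algorithm="nn", chosen_size=3, chosen_decay=0.1, seed=0,
    )


class TestEvaluationArithmetic:
    def test_hand_computed_confusion_metrics(self):
        """TP=3, FN=1, TN=4, FP=0: sensitivity 0.75, specificity 1.0,
        detection rate 3/8 = 0.375."""
        t = _control_table(4, 4)
        truth = ["WT"] * 4 + ["KO"] * 4
        t["genotype"] = truth
        pred = ["WT", "WT", "WT", "KO", "KO", "KO", "KO", "KO"]
        model = _stub_model(pred, np.linspace(0, 1, 8), k=4)
        report = evaluate_classifier(model, t)
        assert (report.tp, report.fn, report.tn, report.fp) == (3, 1, 4, 0)
        assert report.sensitivity == 0.75
        assert report.specificity == 1.0
        assert report.detection_rate == 0.375

    def test_all_predicted_focus_gives_zero_specificity(self):
        t = _control_table(3, 3)
        model = _stub_model(["WT"] * 6, np.full(6, 0.9), k=4)
        report = evaluate_classifier(model, t)
        assert report.specificity == 0.0
        assert report.sensitivity == 1.0

    def test_empty_test_set_rejected(self):
        model = _stub_model([], [], k=4)
        with pytest.raises(ValueError):
            evaluate_classifier(model, _control_table(2, 2).iloc[0:0])


class TestScoreTreated:
    def test_well_score_is_median_of_field_probabilities(self):
        rows = []
        probs = [0.1, 0.2, 0.8, 0.9]
        for f, p in enumerate(probs, start=1):
            rows.append(
                {"plate_id": "P01", "well": "B02", "subclone_id": "SC2",
                 "genotype": "KO", "treatment": "C007", "concentration_nM": 300.0,
                 "field": f, "PC01": 0.0, "PC02": 0.0}
            )
        t = pd.DataFrame(rows)
        model = _stub_model(["WT"] * 4, np.array(probs))
        scored = score_treated(model, t)
        assert len(scored) == 1
        assert scored.loc[0, "score"] == pytest.approx(np.median(probs))
        assert scored.loc[0, "compound_id"] == "C007"

    def test_schema_mismatch_rejected(self):
        t = _control_table(2, 2)[["plate_id", "well", "subclone_id", "genotype",
                                  "treatment", "concentration_nM", "field",
                                  "PC01", "PC02"]]
        model = _stub_model(["WT"] * 4, np.full(4, 0.5), k=3)
        with pytest.raises(ValueError, match="schema"):
            model.focus_probability(t)
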