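"""Control-anchored classification and wild-type-similarity scoring.

A classifier (single-hidden-layer neural network by default; random
forest and SVM comparators share the interface) is trained on
vehicle-treated wild-type vs knock-out control images in signature
space, evaluated on held-out control wells, and then used to score every
compound-treated sample by its probability of classifying as wild-type
(the focus class).  Well scores are the median over the well's image
fields: 1.0 means fully wild-type-like, 0.0 fully mutant-like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

SCORE_COLUMN_PREFIX = "PC"


def _score_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith(SCORE_COLUMN_PREFIX)]
    if not cols:
        raise ValueError("no component-score columns (PC01..PCk) in table")
    return cols


@dataclass
class ClassifierSpec:
    """Algorithm and hyper-parameter search settings.

    The neural network is a three-layer perceptron (input, one hidden
    layer of ``size`` units, logistic output); ``decay`` is the L2
    weight penalty.  Hyper-parameters are chosen by cross-validated
    accuracy over the size x decay grid; ties prefer the smaller size,
    then the larger decay.
    """

    algorithm: str = "nn"
    sizes: tuple[int, ...] = (3, 5, 10)
    decays: tuple[float, ...] = (1e-4, 1e-2, 1.0)
    cv_folds: int = 2
    test_fraction: float = 0.2
    focus_class: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("nn", "rf", "svm"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.sizes or not self.decays:
            raise ValueError("hyper-parameter grids must be non-empty")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class ClassifierReport:
    """Held-out-control evaluation of a trained model."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    detection_rate: float
    mean_focus_probability: dict[str, float]        # per true class, image level
    mean_focus_probability_well: dict[str, float]   # per true class, well level
    accuracy: float
    algorithm: str
    chosen_size: int | None
    chosen_decay: float | None
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class TrainedModel:
    estimator: object
    focus_class: str
    feature_columns: list[str]
    algorithm: str
    chosen_size: int | None
    chosen_decay: float | None
    seed: int

    def focus_probability(self, table: pd.DataFrame) -> np.ndarray:
        """Image-level probability of the focus (wild-type) class."""
        cols = _score_columns(table)
        if cols != self.feature_columns:
            raise ValueError(
                f"schema mismatch: model expects {self.feature_columns[:3]}..., "
                f"table has {cols[:3]}..."
            )
        proba = self.estimator.predict_proba(table[cols].to_numpy(dtype=float))
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(self.focus_class)]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        cols = _score_columns(table)
        return self.estimator.predict(table[cols].to_numpy(dtype=float))


def split_controls(
    controls: pd.DataFrame, spec: ClassifierSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Well-grouped, class-stratified train/test split of control records.

    All image fields of a well land on the same side.  Per class, the
    number of test wells is round(test_fraction x wells in class);
    the split is disjoint and exhaustive.
    """
    if controls["genotype"].nunique() < 2:
        raise ValueError("both control classes must be present")
    rng = np.random.default_rng(spec.seed)
    test_keys: list[tuple] = []
    for cls, sub in controls.groupby("genotype", sort=True):
        wells = sub[["plate_id", "well"]].drop_duplicates().to_numpy()
        if len(wells) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 wells")
        n_test = round(spec.test_fraction * len(wells))
        n_test = min(max(n_test, 1), len(wells) - 1)
        idx = rng.permutation(len(wells))[:n_test]
        test_keys.extend(map(tuple, wells[idx]))
    key = list(map(tuple, controls[["plate_id", "well"]].to_numpy()))
    is_test = np.array([k in set(test_keys) for k in key])
    return controls[~is_test].copy(), controls[is_test].copy()


def _balanced_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Oversample minority classes to equal counts (inverse-frequency
    weighting for estimators without sample weights)."""
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    idx = []
    for cls, cnt in zip(classes, counts):
        members = np.flatnonzero(y == cls)
        reps = np.tile(members, n_max // cnt)
        extra = (
            rng.choice(members, n_max - len(reps), replace=False)
            if n_max > len(reps)
            else np.empty(0, dtype=int)
        )
        idx.append(np.concatenate([reps, extra]))
    out = np.concatenate(idx)
    rng.shuffle(out)
    return out


def _make_estimator(spec: ClassifierSpec, size: int, decay: float, seed: int):
    if spec.algorithm == "nn":
        return MLPClassifier(
            hidden_layer_sizes=(size,),
            alpha=decay,
            solver="lbfgs",
            max_iter=500,
            tol=1e-6,
            random_state=seed,
        )
    if spec.algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=200, random_state=seed, class_weight="balanced"
        )
    return SVC(C=1.0 / max(decay, 1e-12), probability=True, random_state=seed,
               class_weight="balanced")


def _cv_accuracy(X, y, spec: ClassifierSpec, size: int, decay: float) -> float:
    """k-fold CV accuracy, stratified by class, deterministic."""
    rng = np.random.default_rng(spec.seed + 1)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        folds[members] = rng.permutation(len(members)) % spec.cv_folds
    accs = []
    for f in range(spec.cv_folds):
        tr, te = folds != f, folds == f
        rng_bal = np.random.default_rng(spec.seed + 2 + f)
        bal = _balanced_indices(y[tr], rng_bal) if spec.algorithm == "nn" else slice(None)
        Xtr, ytr = X[tr][bal], y[tr][bal]
        est = _make_estimator(spec, size, decay, spec.seed + 10 + f)
        est.fit(Xtr, ytr)
        accs.append(float(np.mean(est.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def train_classifier(train: pd.DataFrame, spec: ClassifierSpec) -> TrainedModel:
    """Fit the classifier on training-control image records.

    Hyper-parameters are selected by cross-validated accuracy on the
    size x decay grid (the grid applies to the neural network; the RF
    and SVM comparators are fitted with fixed settings).  Training is
    seeded and deterministic.
    """
    cols = _score_columns(train)
    X = train[cols].to_numpy(dtype=float)
    y = train["genotype"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set has a single class")
    if np.any(counts < 2):
        raise ValueError("each class needs >= 2 training records")

    size_choice, decay_choice = None, None
    if spec.algorithm == "nn":
        results = []
        for size, decay in product(spec.sizes, spec.decays):
            acc = _cv_accuracy(X, y, spec, size, decay)
            results.append((acc, -size, decay))  # ties: smaller size, larger decay
        best = max(results)
        size_choice, decay_choice = -best[1], best[2]
    est = _make_estimator(spec, size_choice or 0, decay_choice or 0.0, spec.seed)
    if spec.algorithm == "nn":
        bal = _balanced_indices(y, np.random.default_rng(spec.seed + 99))
        est.fit(X[bal], y[bal])
    else:
        est.fit(X, y)
    return TrainedModel(
        estimator=est,
        focus_class=spec.focus_class,
        feature_columns=cols,
        algorithm=spec.algorithm,
        chosen_size=size_choice,
        chosen_decay=decay_choice,
        seed=spec.seed,
    )


def evaluate_classifier(model: TrainedModel, test: pd.DataFrame) -> ClassifierReport:
    """Confusion matrix and derived metrics on held-out control records.

    Positive = focus class (wild-type): sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), detection rate = TP/(TP+FP+TN+FN).
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    y = test["genotype"].to_numpy()
    pred = model.predict(test)
    focus = model.focus_class
    tp = int(np.sum((y == focus) & (pred == focus)))
    fn = int(np.sum((y == focus) & (pred != focus)))
    tn = int(np.sum((y != focus) & (pred != focus)))
    fp = int(np.sum((y != focus) & (pred == focus)))
    total = tp + fp + tn + fn
    prob = model.focus_probability(test)
    mean_prob = {
        str(cls): float(np.mean(prob[y == cls])) for cls in np.unique(y)
    }
    well_scores = (
        test.assign(_prob=prob)
        .groupby(["plate_id", "well"], sort=False)
        .agg(genotype=("genotype", "first"), score=("_prob", "median"))
    )
    mean_prob_well = {
        str(cls): float(sub["score"].mean())
        for cls, sub in well_scores.groupby("genotype")
    }
    return ClassifierReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        detection_rate=tp / total,
        mean_focus_probability=mean_prob,
        mean_focus_probability_well=mean_prob_well,
        accuracy=(tp + tn) / total,
        algorithm=model.algorithm,
        chosen_size=model.chosen_size,
        chosen_decay=model.chosen_decay,
        seed=model.seed,
    )


def score_treated(model: TrainedModel, treated: pd.DataFrame) -> pd.DataFrame:
    """Per-well wild-type-similarity scores for compound-treated records.

    The well score is the median of its image-level focus-class
    probabilities.  Returns compound_id, subclone_id, concentration_nM,
    plate_id, well, score.
    """
    prob = model.focus_probability(treated)
    out = (
        treated.assign(_prob=prob)
        .groupby(["plate_id", "well"], sort=False)
        .agg(
            compound_id=("treatment", "first"),
            subclone_id=("subclone_id", "first"),
            concentration_nM=("concentration_nM", "first"),
            score=("_prob", "median"),
        )
        .reset_index()
    )
    return out[["compound_id", "subclone_id", "concentration_nM", "plate_id", "well", "score"]]
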