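"""Classifier harness: shared fold plans, the four models, CV evaluation.

All classifiers are evaluated on the *same* repeated stratified 5-fold
partitions (a :class:`FoldPlan`), and three measures are reported per
classifier: overall accuracy and the two per-class accuracies (male /
female recall), each averaged over all repeats and folds.

Models
------
* ``majority`` — predicts the most frequent training class.
* ``cn2``      — the native CN2 rule inducer (:mod:`cranangles.rules`).
* ``svm``      — RBF-kernel SVC.  By default the (C, gamma) pair is chosen
  once, by an internal grid search on the full dataset before the first CV
  run — reproducing a protocol in which hyperparameters are fixed up front.
  That search sees the evaluation data; a leak-free per-training-fold
  search is available via ``svm_per_fold=True`` and is the recommended
  setting when absolute accuracy matters.
* ``lr``       — logistic regression with very weak ridge (C = 1e6), i.e.
  effectively unregularized but numerically safe under separability.
* ``nb``       — naive Bayes on MDL-discretized attributes (Laplace
  smoothing); ``nb_gaussian=True`` switches to Gaussian naive Bayes.

Continuous features are standardized and missing values median-imputed
using training-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .discretize import apply_cut_points, mdl_cut_points
from .rules import RuleList, cn2_induce, cn2_predict

CLASSIFIER_NAMES = ("majority", "cn2", "svm", "nb", "lr")


def majority_baseline(labels) -> float:
    """Accuracy of always predicting the most frequent class."""
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / counts.sum())


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignment per repeat; shared across classifiers."""

    assignments: np.ndarray  # shape (repeats, n_examples), fold id per example
    folds: int
    seed: int

    @property
    def repeats(self) -> int:
        return self.assignments.shape[0]

    def splits(self):
        for r in range(self.repeats):
            row = self.assignments[r]
            for f in range(self.folds):
                test = row == f
                yield r, f, np.nonzero(~test)[0], np.nonzero(test)[0]


def make_fold_plan(labels, folds: int = 5, repeats: int = 10, seed: int = 0) -> FoldPlan:
    """Repeated stratified fold plan; per class, fold sizes differ by at most 1."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer members ({counts.min()}) than folds")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        row = np.empty(len(y), dtype=int)
        for f, (_tr, te) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
            row[te] = f
        rows.append(row)
    return FoldPlan(np.array(rows), folds, seed)


# ---------------------------------------------------------------------------
# Model wrappers (fit/predict over DataFrames with possible NaN cells)
# ---------------------------------------------------------------------------

class _Preprocessor:
    """Training-fold median imputation + standardization."""

    def fit(self, frame: pd.DataFrame) -> "_Preprocessor":
        x = frame.to_numpy(dtype=float)
        self.median_ = np.nanmedian(x, axis=0)
        self.median_ = np.where(np.isfinite(self.median_), self.median_, 0.0)
        filled = np.where(np.isfinite(x), x, self.median_)
        self.mean_ = filled.mean(axis=0)
        sd = filled.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame.to_numpy(dtype=float)
        filled = np.where(np.isfinite(x), x, self.median_)
        return (filled - self.mean_) / self.sd_


class MajorityModel:
    def fit(self, frame, y):
        classes, counts = np.unique(y, return_counts=True)
        self.cls_ = classes[np.argmax(counts)]
        return self

    def predict(self, frame):
        return np.array([self.cls_] * len(frame), dtype=object)


class CN2Model:
    def __init__(self, beam_width=5, min_coverage=15, variant="unordered", max_conditions=5):
        self.params = dict(beam_width=beam_width, min_coverage=min_coverage,
                           variant=variant, max_conditions=max_conditions)
        self.rule_list_: RuleList | None = None

    def fit(self, frame, y):
        self.rule_list_ = cn2_induce(frame, y, **self.params)
        return self

    def predict(self, frame):
        return cn2_predict(self.rule_list_, frame)


class _SklearnModel:
    """Imputation + standardization around a scikit-learn estimator."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, frame, y):
        self.prep_ = _Preprocessor().fit(frame)
        self.estimator.fit(self.prep_.transform(frame), np.asarray(y).astype(str))
        return self

    def predict(self, frame):
        return self.estimator.predict(self.prep_.transform(frame))


class DiscretizedNB:
    """Naive Bayes over MDL-discretized attributes with Laplace smoothing."""

    def fit(self, frame, y):
        y = np.asarray(y).astype(str)
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self.priors_ = np.bincount(codes, minlength=len(self.classes_)) / len(y)
        self.cuts_ = {}
        self.cond_ = {}
        for attr in frame.columns:
            vals = frame[attr].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            cuts = mdl_cut_points(vals[ok], codes[ok]) if ok.any() else []
            self.cuts_[attr] = cuts
            n_bins = len(cuts) + 1
            table = np.ones((len(self.classes_), n_bins))  # Laplace prior
            bins = apply_cut_points(vals, cuts)
            for c in range(len(self.classes_)):
                sel = bins[(codes == c) & (bins >= 0)]
                table[c] += np.bincount(sel, minlength=n_bins)
            self.cond_[attr] = table / table.sum(axis=1, keepdims=True)
        return self

    def predict(self, frame):
        log_post = np.tile(np.log(self.priors_), (len(frame), 1))
        for attr in frame.columns:
            bins = apply_cut_points(frame[attr].to_numpy(dtype=float), self.cuts_[attr])
            known = bins >= 0
            log_post[known] += np.log(self.cond_[attr][:, bins[known]]).T
        return self.classes_[np.argmax(log_post, axis=1)]


DEFAULT_SVM_GRID = {"C": (0.1, 1.0, 10.0, 100.0), "gamma": (0.01, 0.1, 1.0, "scale")}


def svm_grid_search(frame: pd.DataFrame, y, grid=None, folds: int = 5,
                    seed: int = 0) -> dict:
    """Pick (C, gamma) by internal stratified CV accuracy; deterministic."""
    grid = grid or DEFAULT_SVM_GRID
    y = np.asarray(y).astype(str)
    prep = _Preprocessor().fit(frame)
    x = prep.transform(frame)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(x, y))
    best = None
    for c in grid["C"]:
        for g in grid["gamma"]:
            correct = 0
            for tr, te in splits:
                model = SVC(C=c, gamma=g, kernel="rbf")
                model.fit(x[tr], y[tr])
                correct += int((model.predict(x[te]) == y[te]).sum())
            acc = correct / len(y)
            if best is None or acc > best[0] + 1e-12:
                best = (acc, {"C": c, "gamma": g})
    return best[1]


@dataclass
class EvalSettings:
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    cn2_beam_width: int = 5
    cn2_min_coverage: int = 15
    cn2_variant: str = "unordered"
    svm_per_fold: bool = False
    svm_grid: dict | None = None
    nb_gaussian: bool = False
    lr_c: float = 1e6


def _build(name: str, settings: EvalSettings, svm_params: dict | None):
    if name == "majority":
        return MajorityModel()
    if name == "cn2":
        return CN2Model(settings.cn2_beam_width, settings.cn2_min_coverage,
                        settings.cn2_variant)
    if name == "svm":
        params = svm_params or {"C": 1.0, "gamma": "scale"}
        return _SklearnModel(SVC(kernel="rbf", **params))
    if name == "lr":
        return _SklearnModel(LogisticRegression(C=settings.lr_c, max_iter=5000))
    if name == "nb":
        return _SklearnModel(GaussianNB()) if settings.nb_gaussian else DiscretizedNB()
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class EvaluationResult:
    """Accuracies per classifier, averaged over all repeats x folds."""

    overall: dict[str, float]
    per_class: dict[str, dict[str, float]]     # classifier -> class -> recall
    fold_frame: pd.DataFrame                   # raw per-fold rows
    classes: tuple[str, ...]
    svm_params: dict | None = None
    rule_lists: list[RuleList] = field(default_factory=list)
    notes: dict[str, str] = field(default_factory=dict)


def evaluate(
    frame: pd.DataFrame,
    labels,
    plan: FoldPlan,
    settings: EvalSettings | None = None,
) -> EvaluationResult:
    """Train/test every classifier on every fold of the shared plan."""
    settings = settings or EvalSettings()
    y = np.asarray(labels).astype(str)
    if len(y) != len(frame) or plan.assignments.shape[1] != len(frame):
        raise ValueError("fold plan, table and labels must align")
    classes = tuple(np.unique(y))
    svm_params = None
    if "svm" in settings.classifiers and not settings.svm_per_fold:
        svm_params = svm_grid_search(frame, y, settings.svm_grid, seed=plan.seed)

    records = []
    rule_lists: list[RuleList] = []
    for repeat, fold, train_idx, test_idx in plan.splits():
        ftr, fte = frame.iloc[train_idx], frame.iloc[test_idx]
        ytr, yte = y[train_idx], y[test_idx]
        fold_svm = svm_params
        if "svm" in settings.classifiers and settings.svm_per_fold:
            fold_svm = svm_grid_search(ftr, ytr, settings.svm_grid, seed=plan.seed)
        for name in settings.classifiers:
            model = _build(name, settings, fold_svm)
            model.fit(ftr, ytr)
            pred = np.asarray(model.predict(fte)).astype(str)
            rec = {"classifier": name, "repeat": repeat, "fold": fold,
                   "n_test": len(yte),
                   "correct": int((pred == yte).sum())}
            for cls in classes:
                sel = yte == cls
                rec[f"n_{cls}"] = int(sel.sum())
                rec[f"correct_{cls}"] = int((pred[sel] == cls).sum())
            records.append(rec)
            if name == "cn2" and isinstance(model, CN2Model):
                rule_lists.append(model.rule_list_)

    fold_frame = pd.DataFrame(records)
    overall, per_class = {}, {}
    for name in settings.classifiers:
        sub = fold_frame[fold_frame["classifier"] == name]
        overall[name] = float((sub["correct"] / sub["n_test"]).mean())
        per_class[name] = {
            cls: float((sub[f"correct_{cls}"] / sub[f"n_{cls}"]).mean())
            for cls in classes
        }
    notes = {"missing_values": "per-fold training-median imputation",
             "svm_search": "per-fold (leak-free)" if settings.svm_per_fold
             else "once on full data before CV"}
    return EvaluationResult(overall, per_class, fold_frame, classes,
                            svm_params, rule_lists, notes)
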