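"""Classifier and calibrated-probability risk models for the binary HYR.

Nine methods share one evaluation harness: XGBoost, random forest (RF),
RBF-kernel SVM, a one-hidden-layer back-propagation network (BPANN),
logistic regression (LOG), resampling AdaBoost wrappers of the last three
(SVMBoost / BPANNBoost / LOGBoost), and a stacking ensemble (STACK) whose
base learners RF, SVM, BPANN and LOG feed a meta logistic regression
through out-of-fold scores.

Evaluation scheme: patients are assigned to 10 label-stratified folds; per
repeat, 7 randomly chosen folds train and the remaining 3 test. Within the
training folds a stratified quarter is held out to fit an isotonic
(pool-adjacent-violators) calibration map from raw scores to probabilities;
the model itself trains on the other three quarters. Reports aggregate
mean +/- SD over repeats.

Metrics — classifier block from hard labels (accuracy, sensitivity, F
measure, balanced G-mean, hard-label RMSE) plus rank AUC of the continuous
score; probability block from calibrated probabilities (rank AUC, RMSE,
mean calibration error over 10 equal-frequency bins, and Brier scores
overall and per class). Raw (uncalibrated) probability metrics are reported
alongside, since margin-based scores read as probabilities are exactly what
calibration repairs. Identities that hold by construction:
``bs_all = prevalence * bs_1 + (1 - prevalence) * bs_0`` and
``rmse_prob**2 = bs_all``.

Class imbalance (roughly 1:4 and steeper) is handled by stratified folds
and class weights, never by resampling the evaluation data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

logger = logging.getLogger("fhrisk")

METHOD_NAMES = ("XGBoost", "RF", "SVM", "SVMBoost", "BPANN", "BPANNBoost",
                "LOG", "LOGBoost", "STACK")
STACK_BASES = ("RF", "SVM", "BPANN", "LOG")

CLASSIFIER_KEYS = ("accuracy", "sensitivity", "f_measure", "auc_class",
                   "rmse_class", "g_score")
PROBABILITY_KEYS = ("auc_prob", "rmse_prob", "cal_mean", "bs_1", "bs_0", "bs_all")


# ---------------------------------------------------------------------------
# split plan

@dataclass(frozen=True)
class SplitPlan:
    """Stratified fold assignment plus per-repeat 7/3 train-test fold draws."""

    fold_of: np.ndarray  # fold index per patient
    repeats: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    n_folds: int
    seed: int

    def indices(self, repeat: int) -> tuple[np.ndarray, np.ndarray]:
        train_folds, test_folds = self.repeats[repeat]
        train = np.flatnonzero(np.isin(self.fold_of, train_folds))
        test = np.flatnonzero(np.isin(self.fold_of, test_folds))
        return train, test

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


def make_splits(labels: Sequence[int], folds: int = 10, train_folds: int = 7,
                repeats: int = 10, seed: int = 0) -> SplitPlan:
    """Label-stratified folds and seeded random train-fold choices."""
    y = np.asarray(labels).astype(int)
    if len(y) < folds:
        raise ValueError(f"cohort of {len(y)} cannot fill {folds} folds")
    if not 0 < train_folds < folds:
        raise ValueError("train_folds must be in (0, folds)")
    pos_per_fold = (y == 1).sum() / folds
    if pos_per_fold < 1:
        warnings.warn("fewer positives than folds; stratification infeasible")
    fold_of = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_of[test_idx] = k
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(repeats):
        train = tuple(sorted(rng.choice(folds, size=train_folds, replace=False).tolist()))
        test = tuple(k for k in range(folds) if k not in train)
        reps.append((train, test))
    return SplitPlan(fold_of=fold_of, repeats=tuple(reps), n_folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# estimators

#: features whose effect on risk is constrained non-decreasing in the tree
#: learners (a clinical prior: FH risk never drops as untreated LDL-C rises)
MONOTONE_RISK_FEATURES = ("ldl_c",)


def monotone_constraints(feature_names: Sequence[str] | None) -> tuple[int, ...] | None:
    """Per-feature {-1, 0, +1} constraint vector for tree-based learners."""
    if feature_names is None:
        return None
    cst = tuple(1 if f in MONOTONE_RISK_FEATURES else 0 for f in feature_names)
    return cst if any(cst) else None


def _base_estimator(method: str, n_features: int, seed: int,
                    monotone_cst: Sequence[int] | None = None):
    if method == "XGBoost":
        return XGBClassifier(n_estimators=200, max_depth=4, learning_rate=0.1,
                             subsample=0.9, tree_method="hist", n_jobs=1,
                             random_state=seed, eval_metric="logloss",
                             monotone_constraints=(tuple(monotone_cst)
                                                   if monotone_cst else None))
    if method == "RF":
        return RandomForestClassifier(n_estimators=300, class_weight="balanced",
                                      min_samples_leaf=20, n_jobs=1,
                                      random_state=seed,
                                      monotonic_cst=(list(monotone_cst)
                                                     if monotone_cst else None))
    if method == "SVM":
        # a deliberately smooth kernel: regularizes and keeps the fitted
        # risk surface close to monotone along the dominant lipid axis
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", gamma=0.01, class_weight="balanced",
                random_state=seed))
    if method == "BPANN":
        # one hidden layer, 2*features + 1 logistic units, early stopping
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(2 * n_features + 1,),
                          activation="logistic", early_stopping=True,
                          max_iter=400, random_state=seed))
    if method == "LOG":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, class_weight="balanced",
                               random_state=seed))
    raise ValueError(f"unknown base method {method!r}")


def build_model(method: str, n_features: int, seed: int,
                monotone_cst: Sequence[int] | None = None):
    if method in ("XGBoost", "RF", "SVM", "BPANN", "LOG"):
        return _base_estimator(method, n_features, seed, monotone_cst)
    if method.endswith("Boost") and method != "XGBoost":
        base = method[:-5]
        return ResampleAdaBoost(
            build_base=lambda s, b=base: _base_estimator(b, n_features, s,
                                                         monotone_cst),
            n_rounds=10, seed=seed)
    if method == "STACK":
        return StackingModel(
            build_bases={b: (lambda s, b=b: _base_estimator(b, n_features, s,
                                                            monotone_cst))
                         for b in STACK_BASES},
            seed=seed)
    raise ValueError(f"unknown method {method!r}")


def raw_score(model, X) -> np.ndarray:
    """Continuous score: P(class 1) when available, else the SVM margin."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    return np.asarray(model.decision_function(X))


def score_as_probability(model, X) -> np.ndarray:
    """Raw score squashed into [0, 1] (identity for probability models)."""
    s = raw_score(model, X)
    if hasattr(model, "predict_proba"):
        return s
    return 1.0 / (1.0 + np.exp(-s))


class ResampleAdaBoost(BaseEstimator, ClassifierMixin):
    """AdaBoost by weighted resampling, usable with any base classifier.

    Each round draws a bootstrap sample from the current weight
    distribution, fits a fresh base learner, and reweights mistakes by the
    round's log-odds error — so base learners never need native
    sample-weight support. The decision score is the alpha-weighted vote.
    """

    def __init__(self, build_base: Callable[[int], object], n_rounds: int = 10,
                 seed: int = 0):
        self.build_base = build_base
        self.n_rounds = n_rounds
        self.seed = seed

    def fit(self, X, y):
        X, y = np.asarray(X), np.asarray(y).astype(int)
        n = len(y)
        rng = np.random.default_rng(self.seed)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        for m in range(self.n_rounds):
            idx = rng.choice(n, size=n, replace=True, p=w)
            if len(np.unique(y[idx])) < 2:  # degenerate resample
                continue
            est = self.build_base(int(rng.integers(2**31 - 1)))
            est.fit(X[idx], y[idx])
            pred = est.predict(X)
            err = float(w[pred != y].sum())
            if err >= 0.5:  # no better than chance on current weights: reset
                w = np.full(n, 1.0 / n)
                continue
            err = max(err, 1e-10)
            alpha = 0.5 * np.log((1.0 - err) / err)
            self.estimators_.append(est)
            self.alphas_.append(alpha)
            w = w * np.exp(alpha * (pred != y))
            w /= w.sum()
            if err <= 1e-10:
                break
        if not self.estimators_:  # fall back to one unweighted fit
            est = self.build_base(self.seed)
            est.fit(X, y)
            self.estimators_, self.alphas_ = [est], [1.0]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X)
        total = np.zeros(len(X))
        for est, alpha in zip(self.estimators_, self.alphas_):
            total += alpha * (2.0 * est.predict(X) - 1.0)
        return total / sum(self.alphas_)

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


class _NonNegativeLogit:
    """Logistic meta-model with nonnegative weights on the base scores.

    Base learners all emit positively oriented risk scores, so negative
    stacking weights only ever fit noise; constraining them keeps the
    ensemble a monotone function of every base score (free intercept).
    """

    def fit(self, S, y):
        from scipy.optimize import minimize
        S = np.asarray(S, dtype=float)
        y = np.asarray(y, dtype=float)
        k = S.shape[1]

        def nll(theta):
            z = S @ theta[:k] + theta[k]
            # stable log-loss
            return float(np.mean(np.logaddexp(0.0, z) - y * z))

        res = minimize(nll, x0=np.r_[np.ones(k), 0.0], method="L-BFGS-B",
                       bounds=[(0.0, None)] * k + [(None, None)])
        self.coef_ = res.x[:k].reshape(1, -1)
        self.intercept_ = res.x[k:]
        return self

    def predict_proba(self, S) -> np.ndarray:
        z = np.asarray(S, float) @ self.coef_.ravel() + self.intercept_[0]
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])


class StackingModel(BaseEstimator, ClassifierMixin):
    """Heterogeneous stacking: base scores -> meta logistic regression.

    The meta model is trained on out-of-fold base scores (5 stratified
    folds inside the training data) to avoid leaking base-learner training
    fit into the meta fit; its weights are constrained nonnegative (see
    :class:`_NonNegativeLogit`); bases are then refit on all training data.
    """

    def __init__(self, build_bases: Mapping[str, Callable[[int], object]],
                 seed: int = 0, oof_folds: int = 5):
        self.build_bases = build_bases
        self.seed = seed
        self.oof_folds = oof_folds

    def fit(self, X, y):
        X, y = np.asarray(X), np.asarray(y).astype(int)
        names = list(self.build_bases)
        oof = np.zeros((len(y), len(names)))
        skf = StratifiedKFold(n_splits=self.oof_folds, shuffle=True,
                              random_state=self.seed)
        for tr, va in skf.split(X, y):
            for j, name in enumerate(names):
                est = self.build_bases[name](self.seed + j)
                est.fit(X[tr], y[tr])
                oof[va, j] = score_as_probability(est, X[va])
        self.meta_ = _NonNegativeLogit().fit(oof, y)
        self.bases_ = {}
        for j, name in enumerate(names):
            est = self.build_bases[name](self.seed + j)
            est.fit(X, y)
            self.bases_[name] = est
        return self

    def _base_matrix(self, X) -> np.ndarray:
        X = np.asarray(X)
        return np.column_stack([score_as_probability(self.bases_[n], X)
                                for n in self.bases_])

    def predict_proba(self, X) -> np.ndarray:
        return self.meta_.predict_proba(self._base_matrix(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class CalibrationMap:
    """Monotone non-decreasing map from raw score to probability in [0, 1]."""

    _iso: IsotonicRegression

    def __call__(self, scores) -> np.ndarray:
        return np.clip(self._iso.predict(np.asarray(scores, dtype=float)), 0.0, 1.0)


def calibrate(scores, truth) -> CalibrationMap:
    """Pool-adjacent-violators fit of truth on score; clamps outside range."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(float)
    if np.unique(scores).size < 2:
        warnings.warn("constant scores: calibration map is the prevalence")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(scores, truth)
    return CalibrationMap(iso)


# ---------------------------------------------------------------------------
# metrics

def classifier_metrics(hard, score, truth) -> dict[str, float | None]:
    hard = np.asarray(hard).astype(int)
    truth = np.asarray(truth).astype(int)
    tp = int(((hard == 1) & (truth == 1)).sum())
    fp = int(((hard == 1) & (truth == 0)).sum())
    fn = int(((hard == 0) & (truth == 1)).sum())
    tn = int(((hard == 0) & (truth == 0)).sum())
    sen = tp / (tp + fn) if tp + fn else None
    spe = tn / (tn + fp) if tn + fp else None
    pre = tp / (tp + fp) if tp + fp else None
    f = (2 * pre * sen / (pre + sen)
         if pre is not None and sen is not None and pre + sen > 0 else None)
    auc = (float(roc_auc_score(truth, np.asarray(score, dtype=float)))
           if score is not None and len(np.unique(truth)) == 2 else None)
    return {
        "accuracy": (tp + tn) / len(truth),
        "sensitivity": sen,
        "f_measure": f,
        "auc_class": auc,
        "rmse_class": float(np.sqrt(np.mean((hard - truth) ** 2))),
        "g_score": (np.sqrt(sen * spe)
                    if sen is not None and spe is not None else None),
    }


def probability_metrics(prob, truth, n_bins: int = 10) -> dict[str, float | None]:
    p = np.asarray(prob, dtype=float)
    truth = np.asarray(truth).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pos, neg = truth == 1, truth == 0
    bs_1 = float(np.mean((1.0 - p[pos]) ** 2)) if pos.any() else None
    bs_0 = float(np.mean(p[neg] ** 2)) if neg.any() else None
    bs_all = float(np.mean((truth - p) ** 2))
    auc = (float(roc_auc_score(truth, p))
           if pos.any() and neg.any() and np.unique(p).size > 1 else None)
    return {
        "auc_prob": auc,
        "rmse_prob": float(np.sqrt(bs_all)),
        "cal_mean": _calibration_error(p, truth, n_bins),
        "bs_1": bs_1,
        "bs_0": bs_0,
        "bs_all": bs_all,
    }


def _calibration_error(p: np.ndarray, truth: np.ndarray, n_bins: int) -> float:
    """Mean |mean predicted - observed rate| over equal-frequency bins."""
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, n_bins)
    errs = [abs(p[b].mean() - truth[b].mean()) for b in bins if len(b)]
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# the evaluation harness

@dataclass
class ModelReport:
    """Per-repeat metrics and their mean +/- SD; one Table-style row."""

    method: str
    per_repeat: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def aggregate(self) -> dict[str, dict[str, float]]:
        keys = [k for k in self.per_repeat[0] if not k.startswith("_")]
        out = {}
        for k in keys:
            vals = [r[k] for r in self.per_repeat if r.get(k) is not None]
            if not vals:
                out[k] = {"mean": None, "sd": None}
            else:
                out[k] = {"mean": float(np.mean(vals)),
                          "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
        return out

    def to_dict(self) -> dict:
        return {"method": self.method, "n_repeats": len(self.per_repeat),
                "metrics": self.aggregate(), "extras": self.extras}


def _fit_with_calibration(model, X_tr, y_tr, seed: int, cal_fraction: float = 0.25):
    """Fit on 3/4 of the training data, isotonic-calibrate on the rest."""
    fit_idx, cal_idx = train_test_split(
        np.arange(len(y_tr)), test_size=cal_fraction, stratify=y_tr,
        random_state=seed)
    model.fit(X_tr[fit_idx], y_tr[fit_idx])
    calmap = calibrate(raw_score(model, X_tr[cal_idx]), y_tr[cal_idx])
    return model, calmap


def train_evaluate(method: str, features, labels, plan: SplitPlan,
                   config: dict | None = None) -> ModelReport:
    """Fit and test one method under the repeated 7/3 fold scheme."""
    config = config or {}
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    cst = monotone_constraints(config.get("feature_names"))
    report = ModelReport(method=method)
    base_auc: dict[str, list[float]] = {}
    for rep in range(plan.n_repeats):
        tr, te = plan.indices(rep)
        seed_r = (plan.seed * 1000 + rep) % (2**31 - 1)
        model = build_model(method, X.shape[1], seed_r, monotone_cst=cst)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model, calmap = _fit_with_calibration(model, X[tr], y[tr], seed_r)
        except Exception as exc:  # non-converged repeat: flag and skip
            warnings.warn(f"{method} repeat {rep} failed ({exc}); excluded")
            continue
        score_te = raw_score(model, X[te])
        hard_te = np.asarray(model.predict(X[te])).astype(int)
        p_cal = calmap(score_te)
        p_raw = score_as_probability(model, X[te])
        row = dict(classifier_metrics(hard_te, score_te, y[te]))
        row.update(probability_metrics(p_cal, y[te]))
        row.update({f"raw_{k}": v
                    for k, v in probability_metrics(p_raw, y[te]).items()})
        report.per_repeat.append(row)
        if method == "STACK":
            # base-learner probability AUCs on the same test split; rank AUC
            # is invariant under the monotone calibration map, so the raw
            # score AUC is the calibrated-probability AUC
            for name, est in model.bases_.items():
                if len(np.unique(y[te])) == 2:
                    auc_b = float(roc_auc_score(y[te], raw_score(est, X[te])))
                    base_auc.setdefault(name, []).append(auc_b)
        logger.info("%s repeat %d done", method, rep)
    if not report.per_repeat:
        raise RuntimeError(f"{method}: every repeat failed")
    if base_auc:
        report.extras["base_auc_prob"] = {k: float(np.mean(v))
                                          for k, v in base_auc.items()}
    return report


def evaluate_methods(methods: Sequence[str], features, labels, plan: SplitPlan,
                     config: dict | None = None) -> dict[str, ModelReport]:
    return {m: train_evaluate(m, features, labels, plan, config) for m in methods}
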