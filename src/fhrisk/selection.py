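"""Variable screening and four-method selection consensus.

The cohort is stratified by the binary HYR label and every candidate
variable is screened univariately (two-sided): continuous variables with
Student's t-test when both groups pass a Shapiro normality check on a
capped subsample (alpha = 0.05), otherwise Kruskal-Wallis; categorical
variables with the chi-squared test, falling back to Fisher's exact test
when expected counts are small (>= 20% of cells under 5, 2x2 only).

Four selection methods then vote:

* ``logistic_stepwise`` — forward/backward Wald-p stepwise logistic
  regression, entry p 0.1 / stay p 0.2; reports odds ratios.
* ``rf_importance`` — random-forest Gini importance; variables above the
  largest gap in the sorted importances are selected.
* ``lasso`` / ``elastic_net`` — L1 / mixed-penalty logistic paths, penalty
  chosen by 10-fold cross-validated log-loss with the one-standard-error
  rule (elastic-net mixing 0.5); nonzero coefficient means selected.

``consensus`` keeps variables selected by at least ``min_methods`` (default
3, reading "more than two of the four") plus a force list minus a drop
list; the force/drop lists formalize any manual curation step and are
recorded in the selection report. Continuous inputs are standardized for
the penalized methods; categorical inputs arrive pre-encoded as indicators
or ordinal codes (see :func:`fhrisk.pipeline.encode_features`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict

logger = logging.getLogger("fhrisk")

METHODS = ("logistic_stepwise", "rf_importance", "elastic_net", "lasso")

#: the consensus-selected feature set used by the shipped risk models
PRESET_NINE = ("ldl_c", "pCHDTW", "pCHD_fhTW", "pStroke_fh", "pStroke",
               "pPVD", "tendon_xanthomata", "age", "therapy_level")


@dataclass
class SelectionMatrix:
    """Per-variable selection flags and statistics, one column per method."""

    variables: tuple[str, ...]
    selected: dict = field(default_factory=dict)  # method -> {var: bool}
    statistic: dict = field(default_factory=dict)  # method -> {var: float|None}
    univariate_p: dict = field(default_factory=dict)  # var -> float|None

    def votes(self, var: str) -> int:
        return sum(bool(self.selected[m].get(var)) for m in self.selected)

    def to_frame(self) -> pd.DataFrame:
        """Report layout: statistics where selected, NaN (dash) elsewhere."""
        rows = {}
        for var in self.variables:
            row = {"univariate_p": self.univariate_p.get(var)}
            for m in self.selected:
                row[m] = self.statistic[m].get(var) if self.selected[m].get(var) else None
            row["votes"] = self.votes(var)
            rows[var] = row
        return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# univariate screen

_SHAPIRO_CAP = 500


def _is_binaryish(x: np.ndarray) -> bool:
    return np.unique(x[~np.isnan(x)]).size <= 5 and \
        np.allclose(x[~np.isnan(x)], np.round(x[~np.isnan(x)]))


def univariate_screen(X: pd.DataFrame, y: np.ndarray,
                      categorical: set[str] | None = None) -> dict[str, float | None]:
    """Two-sided per-variable p-values between the two label groups."""
    y = np.asarray(y).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 patients per group")
    categorical = categorical or set()
    out: dict[str, float | None] = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        xi, yi = x[ok], y[ok]
        if np.unique(xi).size < 2:
            warnings.warn(f"{col}: constant variable, no test")
            out[col] = None
            continue
        if col in categorical or _is_binaryish(xi):
            out[col] = _categorical_p(xi, yi)
        else:
            out[col] = _continuous_p(xi, yi)
    return out


def _continuous_p(x: np.ndarray, y: np.ndarray) -> float:
    g0, g1 = x[y == 0], x[y == 1]

    def normal(g):
        sub = g if g.size <= _SHAPIRO_CAP else g[:: max(1, g.size // _SHAPIRO_CAP)][:_SHAPIRO_CAP]
        if np.unique(sub).size < 3:
            return False
        return stats.shapiro(sub).pvalue >= 0.05

    if normal(g0) and normal(g1):
        return float(stats.ttest_ind(g0, g1, equal_var=False).pvalue)
    return float(stats.kruskal(g0, g1).pvalue)


def _categorical_p(x: np.ndarray, y: np.ndarray) -> float:
    table = pd.crosstab(pd.Series(x, name="x"), pd.Series(y, name="y")).to_numpy()
    chi2, p, dof, expected = stats.chi2_contingency(table)
    if (expected < 5).mean() >= 0.20 and table.shape == (2, 2):
        return float(stats.fisher_exact(table).pvalue)
    return float(p)


def chi2_from_counts(tp: int, fn: int, fp: int, tn: int) -> float:
    """Chi-squared p-value for a 2x2 of (flag x reference) counts."""
    _, p, _, _ = stats.chi2_contingency(np.array([[tp, fn], [fp, tn]]))
    return float(p)


# ---------------------------------------------------------------------------
# the four methods

def _standardize(X: pd.DataFrame) -> np.ndarray:
    Z = X.to_numpy(dtype=float)
    mu, sd = Z.mean(axis=0), Z.std(axis=0)
    sd[sd == 0] = 1.0
    return (Z - mu) / sd


def _cv_penalty_one_se(Z, y, l1_ratio: float, seed: int, n_folds: int = 10,
                       n_cs: int = 15) -> float:
    """Pick C on a log grid by CV log-loss with the one-SE rule.

    The standard error follows the glmnet convention: the spread of the
    per-observation out-of-fold losses, not of the fold means — the rule
    that makes "one SE" prune aggressively.
    """
    cs = np.logspace(-3, 2, n_cs)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    eps = 1e-12
    means, ses = [], []
    for c in cs:
        est = _penalized_logistic(c, l1_ratio, seed)
        prob = cross_val_predict(est, Z, y, cv=cv, method="predict_proba",
                                 n_jobs=1)[:, 1]
        prob = np.clip(prob, eps, 1 - eps)
        losses = -(y * np.log(prob) + (1 - y) * np.log1p(-prob))
        means.append(losses.mean())
        ses.append(losses.std(ddof=1) / np.sqrt(len(losses)))
    means, ses = np.asarray(means), np.asarray(ses)
    best = int(np.argmin(means))
    ceiling = means[best] + ses[best]
    # smallest C (strongest penalty) whose loss stays within one SE
    for i in range(n_cs):
        if means[i] <= ceiling:
            return float(cs[i])
    return float(cs[best])


def _penalized_logistic(c: float, l1_ratio: float, seed: int) -> LogisticRegression:
    if l1_ratio >= 1.0:
        return LogisticRegression(C=c, l1_ratio=1.0, solver="liblinear",
                                  max_iter=2000, random_state=seed)
    return LogisticRegression(C=c, l1_ratio=l1_ratio, solver="saga",
                              max_iter=5000, tol=1e-3, random_state=seed)


def _penalized_select(X: pd.DataFrame, y, l1_ratio: float, seed: int):
    Z = _standardize(X)
    y = np.asarray(y).astype(int)
    c = _cv_penalty_one_se(Z, y, l1_ratio, seed)
    est = _penalized_logistic(c, l1_ratio, seed).fit(Z, y)
    coefs = est.coef_.ravel()
    out_sel, out_stat = {}, {}
    for var, b in zip(X.columns, coefs):
        out_sel[var] = bool(abs(b) > 1e-10)
        out_stat[var] = float(b)
    return out_sel, out_stat


def _rf_select(X: pd.DataFrame, y, seed: int, n_trees: int = 300,
               gap_threshold: float | None = None):
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(dtype=float), np.asarray(y).astype(int))
    imp = rf.feature_importances_
    order = np.argsort(imp)[::-1]
    if gap_threshold is None:
        sorted_imp = imp[order]
        gaps = sorted_imp[:-1] - sorted_imp[1:]
        cut = int(np.argmax(gaps)) + 1 if len(gaps) else 1
        keep = set(order[:cut])
    else:
        keep = {i for i in range(len(imp)) if imp[i] >= gap_threshold}
    out_sel = {var: (i in keep) for i, var in enumerate(X.columns)}
    out_stat = {var: float(imp[i]) for i, var in enumerate(X.columns)}
    return out_sel, out_stat


def _stepwise_logistic(X: pd.DataFrame, y, p_enter: float = 0.1,
                       p_stay: float = 0.2):
    """Forward/backward stepwise on likelihood-ratio tests; reports ORs.

    LRTs stay informative under complete separation, where Wald statistics
    collapse; a ridge-regularized refit backs up non-converging models.
    """
    y = np.asarray(y).astype(int)
    included: list[str] = []
    for _ in range(2 * len(X.columns) + 10):  # guards add/remove cycles
        changed = False
        base_llf = _llf(X[included], y)
        best_p, best_c = None, None
        for c in (c for c in X.columns if c not in included):
            llf = _llf(X[included + [c]], y)
            if llf is None or base_llf is None:
                continue
            p = float(stats.chi2.sf(max(2 * (llf - base_llf), 0.0), 1))
            if p < p_enter and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is not None:
            included.append(best_c)
            changed = True
        if included:  # backward pass: drop the least defensible variable
            full_llf = _llf(X[included], y)
            worst_p, worst_c = None, None
            for c in included:
                red_llf = _llf(X[[v for v in included if v != c]], y)
                if full_llf is None or red_llf is None:
                    continue
                p = float(stats.chi2.sf(max(2 * (full_llf - red_llf), 0.0), 1))
                if worst_p is None or p > worst_p:
                    worst_p, worst_c = p, c
            if worst_p is not None and worst_p > p_stay:
                included.remove(worst_c)
                changed = True
        if not changed:
            break
    else:
        warnings.warn("stepwise selection did not settle; using current set")
    out_sel = {var: var in included for var in X.columns}
    out_stat: dict[str, float | None] = {var: None for var in X.columns}
    if included:
        fit = _logit_fit(X[included], y)
        if fit is not None:
            for var, b in zip(included, np.asarray(fit.params)[1:]):
                out_stat[var] = float(np.exp(b))
    return out_sel, out_stat


def _logit_fit(Xsub: pd.DataFrame, y):
    Z = sm.add_constant(Xsub.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Z).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(fit.params)):
                return fit
        except Exception:
            pass
        try:  # separation / non-convergence: ridge-regularized backup
            return sm.Logit(y, Z).fit_regularized(
                disp=0, alpha=1e-4, L1_wt=0.0, maxiter=200)
        except Exception:
            warnings.warn("logistic fit failed; model skipped")
            return None


def _llf(Xsub: pd.DataFrame, y) -> float | None:
    if Xsub.shape[1] == 0:
        p = y.mean()
        if p in (0.0, 1.0):
            return 0.0
        n = len(y)
        return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))
    fit = _logit_fit(Xsub, y)
    return None if fit is None else float(fit.llf)


def method_select(X: pd.DataFrame, y, method: str, seed: int = 0,
                  config: dict | None = None):
    """Run one selection method; returns ``(selected, statistic)`` dicts."""
    config = config or {}
    if method == "lasso":
        return _penalized_select(X, y, l1_ratio=1.0, seed=seed)
    if method == "elastic_net":
        return _penalized_select(X, y, l1_ratio=config.get("l1_ratio", 0.5), seed=seed)
    if method == "rf_importance":
        return _rf_select(X, y, seed=seed,
                          n_trees=config.get("n_trees", 300),
                          gap_threshold=config.get("gap_threshold"))
    if method == "logistic_stepwise":
        return _stepwise_logistic(X, y, p_enter=config.get("p_enter", 0.1),
                                  p_stay=config.get("p_stay", 0.2))
    raise ValueError(f"unknown selection method {method!r}")


def build_selection_matrix(X: pd.DataFrame, y, seed: int = 0,
                           categorical: set[str] | None = None,
                           config: dict | None = None) -> SelectionMatrix:
    """Univariate screen plus all four methods on the encoded cohort."""
    matrix = SelectionMatrix(variables=tuple(X.columns))
    matrix.univariate_p = univariate_screen(X, y, categorical=categorical)
    for method in METHODS:
        sel, stat = method_select(X, y, method, seed=seed,
                                  config=(config or {}).get(method))
        matrix.selected[method] = sel
        matrix.statistic[method] = stat
        logger.info("selection/%s picked %d variables", method, sum(sel.values()))
    return matrix


def consensus(matrix: SelectionMatrix, min_methods: int = 3,
              force: tuple[str, ...] = (), drop: tuple[str, ...] = ()) -> list[str]:
    """Variables selected by >= min_methods, plus force, minus drop."""
    if not 1 <= min_methods <= 4:
        raise ValueError("min_methods must be in [1, 4]")
    unknown = (set(force) | set(drop)) - set(matrix.variables)
    if unknown:
        raise ValueError(f"force/drop references unknown variables {sorted(unknown)}")
    chosen = [v for v in matrix.variables
              if (matrix.votes(v) >= min_methods or v in force) and v not in drop]
    if not chosen:
        raise ValueError("consensus selected no variables")
    return chosen
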