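"""Candidate biomarker selection.

Significant metabolites are ranked by random-forest permutation
importance (mean decrease in out-of-bag accuracy under per-tree feature
permutation, the quantity classic random-forest implementations report
as mean decrease in accuracy), then a bidirectional stepwise search on
a logistic regression model adds and drops metabolites one at a time,
keeping the subset with minimal AIC.  Models are scored by ROC AUC via
the rank-sum (Mann-Whitney) formulation and compared by likelihood
ratio.

The logistic maximum-likelihood fit is a Newton (IRLS) iteration with
explicit complete-separation capping; AIC counts the intercept as a
parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

# ---------------------------------------------------------------------------
# logistic regression with AIC


@dataclass
class LogisticFit:
    """A fitted logistic model on a feature subset.

    ``coef`` holds the intercept first, then one coefficient per entry
    of ``features``.  ``aic = 2 * (len(features) + 1) - 2 * log_lik``.
    """

    features: tuple[str, ...]
    coef: np.ndarray
    log_lik: float
    aic: float
    separation: bool
    n_iter: int

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Z = np.column_stack(
            [np.ones(len(X))]
            + [pd.DataFrame(X)[f].to_numpy(dtype=float) for f in self.features]
        )
        return _sigmoid(Z @ self.coef)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _validate_binary(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got classes {classes}")
    return (y == classes[1]).astype(float)


def fit_logistic(
    X: pd.DataFrame | None,
    y,
    features: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 30.0,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by Newton iteration.

    Converges when the gradient's max norm drops below ``tol``.  Under
    complete separation the likelihood has no maximizer; iteration is
    capped once a coefficient magnitude exceeds ``separation_bound``
    and the fit is flagged.
    """
    y01 = _validate_binary(y)
    if X is None or (features is not None and len(features) == 0):
        feats: tuple[str, ...] = ()
        Z = np.ones((len(y01), 1))
    else:
        X = pd.DataFrame(X)
        feats = tuple(features) if features is not None else tuple(X.columns)
        Z = np.column_stack(
            [np.ones(len(X))] + [X[f].to_numpy(dtype=float) for f in feats]
        )
    n, k = Z.shape
    beta = np.zeros(k)
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(Z @ beta)
        grad = Z.T @ (y01 - p)
        if np.max(np.abs(grad)) < tol:
            break
        W = np.clip(p * (1.0 - p), 1e-10, None)
        H = Z.T @ (Z * W[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > separation_bound:
            separation = True
            break
    p = np.clip(_sigmoid(Z @ beta), 1e-12, 1 - 1e-12)
    log_lik = float(np.sum(y01 * np.log(p) + (1 - y01) * np.log(1 - p)))
    aic = 2.0 * k - 2.0 * log_lik
    return LogisticFit(feats, beta, log_lik, aic, separation, it)


# ---------------------------------------------------------------------------
# stepwise AIC


@dataclass
class StepwiseTrace:
    """Every model evaluated during the stepwise search."""

    records: list[dict] = field(default_factory=list)

    def log(self, move: str, feature: str | None, features: tuple[str, ...],
            aic: float, chosen: bool) -> None:
        self.records.append(
            {
                "move": move,
                "feature": feature,
                "features": list(features),
                "aic": aic,
                "chosen": chosen,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def stepwise_minimize_aic(
    X: pd.DataFrame,
    y,
    candidates: Sequence[str] | None = None,
    start: str = "full",
) -> tuple[LogisticFit, StepwiseTrace]:
    """Greedy bidirectional stepwise logistic selection minimizing AIC.

    At each step every single addition and single drop is evaluated and
    the move with the largest AIC decrease is taken; the search stops
    when no move decreases the AIC.  A tie between an add and a drop of
    equal decrease prefers the drop (parsimony).  ``start`` is ``full``
    (begin from the complete candidate model, the default since the
    search is expected to discard correlated metabolites) or ``empty``.
    """
    X = pd.DataFrame(X)
    candidates = list(candidates) if candidates is not None else list(X.columns)
    trace = StepwiseTrace()
    if not candidates:
        warnings.warn("empty candidate set; returning intercept-only model")
        fit = fit_logistic(None, y)
        trace.log("start", None, (), fit.aic, True)
        return fit, trace
    if start not in ("full", "empty"):
        raise ValueError("start must be 'full' or 'empty'")
    current = tuple(candidates) if start == "full" else ()
    best = fit_logistic(X, y, current)
    trace.log("start", None, current, best.aic, True)
    while True:
        moves: list[tuple[float, int, str, str | None, LogisticFit]] = []
        # drops first so that equal-decrease ties prefer parsimony
        for f in current:
            sub = tuple(c for c in current if c != f)
            fit = fit_logistic(X, y, sub)
            trace.log("drop", f, sub, fit.aic, False)
            moves.append((fit.aic, 0, "drop", f, fit))
        for f in candidates:
            if f in current:
                continue
            sup = current + (f,)
            fit = fit_logistic(X, y, sup)
            trace.log("add", f, sup, fit.aic, False)
            moves.append((fit.aic, 1, "add", f, fit))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        best_aic, _, move, feature, fit = moves[0]
        if best_aic < best.aic:
            best = fit
            current = fit.features
            trace.log(move, feature, current, best_aic, True)
        else:
            break
    return best, trace


def likelihood_ratio(full: LogisticFit, nested: LogisticFit) -> float:
    """LR statistic 2 * (logLik_full - logLik_nested); >= 0 for nested
    models."""
    return 2.0 * (full.log_lik - nested.log_lik)


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_obese: int
    n_lean: int


def roc_auc(scores, labels) -> RocResult:
    """AUC by the rank-sum (Mann-Whitney) formulation, ties counted
    one half."""
    scores = np.asarray(scores, dtype=float)
    y = _validate_binary(labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return RocResult(float(auc), n1, n0)


# ---------------------------------------------------------------------------
# random-forest permutation importance


def rf_importance(
    X: pd.DataFrame,
    y,
    n_trees: int = 500,
    seed: int = 0,
    top_k: int | None = 31,
    max_features: str | int = "sqrt",
) -> pd.DataFrame:
    """Rank features by mean decrease in out-of-bag accuracy.

    For each bootstrap tree, the accuracy on its out-of-bag samples is
    compared with the accuracy after permuting one feature's OOB
    values; the importance of a feature is the mean accuracy decrease
    over trees.  Output is sorted by descending importance (ties broken
    by feature id) and truncated to ``top_k`` rows.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    X = pd.DataFrame(X)
    y01 = _validate_binary(y)
    Xv = X.to_numpy(dtype=float)
    n, k = Xv.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros((n_trees, k))
    counts = np.zeros(k)
    used_trees = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0 or len(np.unique(y01[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xv[boot], y01[boot])
        base_acc = np.mean(tree.predict(Xv[oob]) == y01[oob])
        for j in range(k):
            perm = rng.permutation(len(oob))
            Xp = Xv[oob].copy()
            Xp[:, j] = Xp[perm, j]
            acc = np.mean(tree.predict(Xp) == y01[oob])
            drops[used_trees, j] = base_acc - acc
        counts += 1
        used_trees += 1
    if used_trees == 0:
        raise ValueError("no usable bootstrap trees (degenerate labels?)")
    importance = drops[:used_trees].mean(axis=0)
    out = pd.DataFrame(
        {"metabolite": list(X.columns), "importance": importance}
    )
    out = out.sort_values(
        ["importance", "metabolite"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimators


class RandomForestImportanceSelector(BaseEstimator, TransformerMixin):
    """Feature selector keeping the top-k metabolites by OOB
    permutation importance."""

    def __init__(
        self,
        n_trees: int = 500,
        top_k: int = 31,
        random_state: int = 0,
        max_features: str | int = "sqrt",
    ):
        self.n_trees = n_trees
        self.top_k = top_k
        self.random_state = random_state
        self.max_features = max_features

    def fit(self, X, y) -> "RandomForestImportanceSelector":
        X = pd.DataFrame(X)
        self.ranking_ = rf_importance(
            X,
            y,
            n_trees=self.n_trees,
            seed=self.random_state,
            top_k=self.top_k,
            max_features=self.max_features,
        )
        self.selected_ = list(self.ranking_["metabolite"])
        self.support_ = np.array(
            [c in set(self.selected_) for c in X.columns]
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "selected_")
        X = pd.DataFrame(X)
        return X[[c for c in X.columns if c in set(self.selected_)]]


class StepwiseLogisticAIC(BaseEstimator, ClassifierMixin):
    """Logistic classifier with bidirectional stepwise-AIC feature
    selection.

    Fitted attributes: ``included_`` (features in the minimal-AIC
    model), ``aic_``, ``log_likelihood_``, ``fit_`` (the underlying
    :class:`LogisticFit`), ``trace_`` (every evaluated model).
    """

    def __init__(self, start: str = "full"):
        self.start = start

    def fit(self, X, y) -> "StepwiseLogisticAIC":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("StepwiseLogisticAIC requires binary labels")
        self.fit_, self.trace_ = stepwise_minimize_aic(X, y, start=self.start)
        self.included_ = list(self.fit_.features)
        self.aic_ = self.fit_.aic
        self.log_likelihood_ = self.fit_.log_lik
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "fit_")
        p = self.fit_.predict_proba(pd.DataFrame(X))
        return np.log(p / (1 - p))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "fit_")
        p1 = self.fit_.predict_proba(pd.DataFrame(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return np.where(p1 >= 0.5, self.classes_[1], self.classes_[0])


def candidate_report(
    X: pd.DataFrame,
    y,
    ranking: pd.DataFrame,
    final_fit: LogisticFit,
) -> pd.DataFrame:
    """Per-candidate report: importance, rank, membership in the final
    model and single-metabolite ROC AUC."""
    X = pd.DataFrame(X)
    rows = []
    final = set(final_fit.features)
    for _, r in ranking.iterrows():
        m = r["metabolite"]
        auc = roc_auc(X[m].to_numpy(), y).auc
        auc = max(auc, 1.0 - auc)  # direction-free separation measure
        rows.append(
            {
                "metabolite": m,
                "importance": r["importance"],
                "rank": int(r["rank"]),
                "in_final_model": m in final,
                "auc_single": auc,
            }
        )
    return pd.DataFrame(rows)
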