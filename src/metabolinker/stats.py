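"""Group statistics for the factorial mouse design.

Per-metabolite fixed-effects ANOVA (line, sex, diet; main effects only,
sequential type-I sums of squares), the recessive obese-vs-lean
grouping (obese inbred line vs pooled lean control and F1 lines), the
two-group comparison that produces the significant-metabolite table,
phenotype summaries with fold ratios, and Bonferroni correction for
pairwise phenotype contrasts.

The ANOVA is computed by explicit nested least squares shared across
all metabolite columns (the design is identical for every response), so
thousand-metabolite calibration runs stay cheap.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .simulate import LEAN_LINES, OBESE_LINE

OBESE, LEAN = "obese", "lean"


# ---------------------------------------------------------------------------
# ANOVA


def _dummy(design: pd.DataFrame, factor: str) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = sorted(design[factor].unique())
    cols = [
        (design[factor] == lvl).to_numpy(dtype=float) for lvl in levels[1:]
    ]
    return np.column_stack(cols) if cols else np.empty((len(design), 0))


def anova_factors(
    log_matrix: pd.DataFrame,
    design: pd.DataFrame,
    factors: Sequence[str] = ("line", "sex", "diet"),
) -> pd.DataFrame:
    """Main-effects-only ANOVA per metabolite.

    Returns a DataFrame indexed by metabolite with ``p_<factor>`` and
    ``F_<factor>`` columns plus the residual df.  Sums of squares are
    sequential (type I) in the order given; for a factor with zero
    between-level sum of squares the p-value is 1 by convention.
    """
    design = design.loc[log_matrix.index]
    for f in factors:
        if design[f].nunique() < 1:
            raise ValueError(f"factor {f!r} has no levels")
    Y = log_matrix.to_numpy(dtype=float)
    n = Y.shape[0]

    blocks = [np.ones((n, 1))]
    dfs = []
    for f in factors:
        d = _dummy(design, f)
        blocks.append(d)
        dfs.append(d.shape[1])
    X_full = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; aliased factors among "
            f"{list(factors)}"
        )

    def rss(X: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        return (resid * resid).sum(axis=0)

    rss_seq = []
    for k in range(len(blocks) + 1):
        if k == 0:
            continue
        rss_seq.append(rss(np.hstack(blocks[:k])))
    rss_full = rss_seq[-1]
    df_resid = n - X_full.shape[1]
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    out = {"df_resid": np.full(Y.shape[1], df_resid)}
    tiny = np.maximum((Y * Y).sum(axis=0), 1.0) * 1e-12
    for i, f in enumerate(factors):
        ss = rss_seq[i] - rss_seq[i + 1]
        df_f = dfs[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df_f) / (rss_full / df_resid)
        p = sps.f.sf(F, df_f, df_resid)
        zero_ss = ss <= tiny
        F = np.where(zero_ss, 0.0, F)
        p = np.where(zero_ss, 1.0, p)
        p = np.where(np.isinf(F), 0.0, p)
        out[f"F_{f}"] = F
        out[f"p_{f}"] = p
    return pd.DataFrame(out, index=log_matrix.columns)


# ---------------------------------------------------------------------------
# recessive grouping and two-group comparison


def recessive_grouping(design: pd.DataFrame) -> pd.Series:
    """Label each sample obese (BFMI) or lean (B6 and F1 pooled),
    pooling sexes and diets."""
    known = {OBESE_LINE: OBESE, **{l: LEAN for l in LEAN_LINES}}
    unknown = set(design["line"]) - set(known)
    if unknown:
        raise ValueError(f"unknown line labels: {sorted(unknown)}")
    return design["line"].map(known).rename("group")


def compare_groups(
    log_matrix: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Obese-vs-lean comparison per metabolite.

    The p-value is a one-way two-group ANOVA on the log concentrations
    (equivalent to the two-sided pooled-variance t-test); means and SDs
    are reported on the raw concentration scale alongside.
    """
    groups = groups.loc[log_matrix.index]
    obese = log_matrix.loc[groups == OBESE]
    lean = log_matrix.loc[groups == LEAN]
    if len(obese) < 2 or len(lean) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(obese)} obese / "
            f"{len(lean)} lean"
        )
    t = sps.ttest_ind(
        obese.to_numpy(), lean.to_numpy(), axis=0, equal_var=True
    )
    raw_obese, raw_lean = np.exp(obese), np.exp(lean)
    return pd.DataFrame(
        {
            "obese_mean": raw_obese.mean(axis=0),
            "obese_sd": raw_obese.std(axis=0, ddof=1),
            "lean_mean": raw_lean.mean(axis=0),
            "lean_sd": raw_lean.std(axis=0, ddof=1),
            "p_value": np.where(
                np.isnan(t.pvalue), 1.0, t.pvalue
            ),  # zero-variance, equal-mean columns: no evidence
            "n_obese": len(obese),
            "n_lean": len(lean),
        },
        index=log_matrix.columns,
    )


def select_significant(
    comparison: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Metabolites with p strictly below alpha, ordered by ascending p
    then id (stable)."""
    sig = comparison[comparison["p_value"] < alpha]
    order = sig.assign(_id=sig.index.astype(str)).sort_values(
        ["p_value", "_id"], kind="mergesort"
    )
    return list(order.index)


class SignificanceSelector(BaseEstimator, TransformerMixin):
    """Feature selector keeping metabolites that differ between groups.

    ``fit(X, y)`` runs the pooled-variance two-group comparison on
    log-scale features X against binary labels y and keeps features
    with p strictly below ``alpha``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y) -> "SignificanceSelector":
        X = pd.DataFrame(X)
        groups = pd.Series(y, index=X.index)
        comp = compare_groups(X, groups.map(_binary_to_group))
        self.p_values_ = comp["p_value"]
        self.selected_ = select_significant(comp, self.alpha)
        self.support_ = np.array([c in set(self.selected_) for c in X.columns])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_")
        X = pd.DataFrame(X)
        return X[[c for c in X.columns if c in set(self.selected_)]]


def _binary_to_group(label) -> str:
    if label in (OBESE, LEAN):
        return label
    return OBESE if label in (1, True, OBESE_LINE) else LEAN


# ---------------------------------------------------------------------------
# phenotype summaries


def fold_ratio(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Ratio of group means rounded half-away-from-zero."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in fold ratio")
    ratio = Decimal(repr(float(numerator))) / Decimal(repr(float(denominator)))
    q = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(q, rounding=ROUND_HALF_UP))


def bonferroni_pairwise(p_values, m: int):
    """Bonferroni adjustment p_adj = min(1, m * p) for m pairwise
    comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    adj = np.minimum(1.0, m * p)
    return float(adj) if adj.ndim == 0 else adj


def phenotype_summary(
    traits: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell (line x sex x diet) mean and SD for each trait, plus
    the main-effects ANOVA p-values per trait."""
    design = design.loc[traits.index]
    cells = (
        traits.join(design[["line", "sex", "diet"]])
        .groupby(["line", "sex", "diet"], sort=True)
        .agg(["mean", "std", "count"])
    )
    anova = anova_factors(traits, design)
    return cells, anova
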