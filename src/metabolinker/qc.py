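"""Metabolite quality control: CV filtering and log transformation.

Per-metabolite coefficients of variation (sample SD / mean, computed on
untransformed concentrations) come from repeated measurements of a
reference sample; metabolites whose CV exceeds the threshold (default
0.2) are excluded, and the retained concentrations are natural-log
transformed to remove skewness before modeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

DEFAULT_CV_THRESHOLD = 0.2


def compute_cv(reference: pd.DataFrame, min_replicates: int = 2) -> pd.Series:
    """Per-metabolite CV = sample (n-1) standard deviation / mean over
    reference replicates (columns = metabolites).

    Missing values are excluded pairwise; a metabolite with fewer than
    ``min_replicates`` non-missing values, or zero mean, is an error.
    """
    cvs = {}
    for mid in reference.columns:
        vals = reference[mid].dropna().to_numpy(dtype=float)
        if len(vals) < min_replicates:
            raise ValueError(
                f"metabolite {mid!r} has {len(vals)} replicates; "
                f"need >= {min_replicates}"
            )
        mean = vals.mean()
        if mean == 0:
            raise ValueError(f"metabolite {mid!r} has zero mean")
        cvs[mid] = vals.std(ddof=1) / mean
    return pd.Series(cvs, name="cv")


def qc_report(
    cv: pd.Series, threshold: float = DEFAULT_CV_THRESHOLD
) -> pd.DataFrame:
    """QC table: metabolite, CV, pass flag (pass iff CV <= threshold)."""
    return pd.DataFrame(
        {
            "metabolite": cv.index,
            "cv": cv.to_numpy(),
            "pass": (cv <= threshold).to_numpy(),
        }
    ).reset_index(drop=True)


def filter_by_cv(
    matrix: pd.DataFrame,
    qc: pd.DataFrame | pd.Series,
    threshold: float = DEFAULT_CV_THRESHOLD,
) -> pd.DataFrame:
    """Drop matrix columns whose CV is strictly greater than the
    threshold (CV exactly equal is retained); column order preserved."""
    cv = qc["cv"].set_axis(qc["metabolite"]) if isinstance(qc, pd.DataFrame) else qc
    missing = set(matrix.columns) - set(cv.index)
    if missing:
        raise ValueError(f"QC report does not cover columns: {sorted(missing)}")
    keep = [m for m in matrix.columns if cv[m] <= threshold]
    return matrix[keep]


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise natural log; missing stays missing; non-positive
    values raise with their coordinates."""
    bad = (matrix <= 0).fillna(False)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-positive concentration at sample {matrix.index[r]!r}, "
            f"metabolite {matrix.columns[c]!r}"
        )
    return np.log(matrix)


class CVFilter(BaseEstimator, TransformerMixin):
    """Feature filter dropping metabolites with high reference-sample CV.

    sklearn-style transformer: ``fit`` takes the reference-replicate
    table (rows = replicate measurements of the reference sample),
    ``transform`` drops failing columns from a study matrix.

    Parameters
    ----------
    threshold : float, default 0.2
        Maximum allowed CV; strictly larger values fail.
    """

    def __init__(self, threshold: float = DEFAULT_CV_THRESHOLD):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "CVFilter":
        self.cv_ = compute_cv(pd.DataFrame(X))
        self.support_ = (self.cv_ <= self.threshold).to_numpy()
        self.n_features_in_ = len(self.cv_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "cv_")
        return filter_by_cv(pd.DataFrame(X), self.cv_, self.threshold)

    def report(self) -> pd.DataFrame:
        check_is_fitted(self, "cv_")
        return qc_report(self.cv_, self.threshold)

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


class LogTransformer(BaseEstimator, TransformerMixin):
    """Stateless natural-log transformer for concentration matrices."""

    def fit(self, X, y=None) -> "LogTransformer":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return log_transform(pd.DataFrame(X))
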