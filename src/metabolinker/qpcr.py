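"""Relative quantification of gene expression by the delta-delta-Ct
method.

Triplicate Ct values are averaged per sample and gene, the target
gene's Ct is normalized against the arithmetic mean of two endogenous
control genes (equivalent to geometric-mean normalization on the linear
scale), and expression is reported relative to a calibrator group whose
mean is normalized to 1:

    dCt_s   = Ct_target,s - mean(Ct_controls,s)
    ddCt_s  = dCt_s - mean over calibrator samples of dCt
    RQ_s    = 2 ** (-ddCt_s)

Group comparisons use a two-tailed pooled-variance t-test on dCt (the
approximately normal log2 scale); RQ is reported for interpretation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_CONTROL_GENES = ("Rps25", "bActin")


def aggregate_triplicates(
    ct_table: pd.DataFrame, max_sd: float = 0.5
) -> pd.DataFrame:
    """Mean Ct per (sample, gene) with replicate-scatter flags.

    Input is long format with columns sample, gene, Ct (and anything
    else, preserved where unambiguous).  A (sample, gene) cell whose
    replicate SD exceeds ``max_sd`` is flagged ``high_sd``; a single
    replicate is passed through flagged ``insufficient replicates``.
    """
    ct_table = pd.DataFrame(ct_table)
    if ct_table["Ct"].isna().all():
        raise ValueError("all replicate Ct values missing")
    rows = []
    for (sample, gene), grp in ct_table.groupby(["sample", "gene"], sort=False):
        vals = grp["Ct"].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"all replicates missing for {sample}/{gene}")
        flag = ""
        if len(vals) == 1:
            flag = "insufficient replicates"
        elif vals.std(ddof=1) > max_sd:
            flag = "high_sd"
        row = {"sample": sample, "gene": gene, "Ct": vals.mean(), "flag": flag}
        if "group" in grp.columns:
            row["group"] = grp["group"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def ddct_rq(
    ct_means: pd.DataFrame,
    target_gene: str,
    control_genes: tuple[str, ...] = DEFAULT_CONTROL_GENES,
    calibrator_group: str | None = None,
) -> pd.DataFrame:
    """Per-sample dCt, ddCt and RQ = 2^-ddCt with calibrator-group
    normalization.

    ``ct_means`` has columns sample, gene, Ct, group (one row per
    sample x gene).  The calibrator defaults to the first group in
    table order; its group mean dCt anchors ddCt so the calibrator's
    geometric mean RQ is 1.
    """
    ct_means = pd.DataFrame(ct_means)
    wide = ct_means.pivot(index="sample", columns="gene", values="Ct")
    groups = ct_means.drop_duplicates("sample").set_index("sample")["group"]
    for g in (target_gene, *control_genes):
        if g not in wide.columns:
            raise ValueError(f"gene {g!r} missing from Ct table")
        missing = wide.index[wide[g].isna()]
        if len(missing):
            raise ValueError(
                f"missing {g} measurement for sample(s) {list(missing)}"
            )
    calibrator_group = calibrator_group or groups.iloc[0]
    if (groups == calibrator_group).sum() == 0:
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    dct = wide[target_gene] - wide[list(control_genes)].mean(axis=1)
    cal_mean = dct[groups == calibrator_group].mean()
    ddct = dct - cal_mean
    rq = np.power(2.0, -ddct)
    out = pd.DataFrame(
        {
            "sample": wide.index,
            "group": groups.loc[wide.index].to_numpy(),
            "dCt": dct.to_numpy(),
            "ddCt": ddct.to_numpy(),
            "RQ": rq.to_numpy(),
        }
    )
    out.attrs["calibrator_group"] = calibrator_group
    return out


def group_rq_summary(rq_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of RQ per group."""
    return (
        rq_table.groupby("group")["RQ"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
    )


def group_ttest(rq_table: pd.DataFrame, group_a: str, group_b: str) -> float:
    """Two-sided pooled-variance t-test on dCt between two groups."""
    a = rq_table.loc[rq_table["group"] == group_a, "dCt"].to_numpy()
    b = rq_table.loc[rq_table["group"] == group_b, "dCt"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0) and np.isclose(
        a.mean(), b.mean()
    ):
        return 1.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def relative_quantification(
    ct_table: pd.DataFrame,
    target_gene: str,
    control_genes: tuple[str, ...] = DEFAULT_CONTROL_GENES,
    calibrator_group: str | None = None,
    max_sd: float = 0.5,
) -> pd.DataFrame:
    """Full pipeline: triplicate aggregation then ddCt RQ."""
    means = aggregate_triplicates(ct_table, max_sd=max_sd)
    return ddct_rq(means, target_gene, control_genes, calibrator_group)
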