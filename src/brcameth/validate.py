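"""Cross-platform and confounder validation of candidate markers.

Covers agreement between the array (beta values) and pyrosequencing
(percent methylation) for the same samples, correlation structure among
candidate loci, rank-sum validation of group differences in independent
samples, and nested logistic regressions testing whether a marker's
association with mutation status survives adjustment for ER status and
grade — the key confounders of breast-tumor methylation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import IndependenceResult, SampleRecord
from .select import rank_sum_p

__all__ = [
    "icc_array_vs_pyro",
    "pairwise_r2",
    "independence_glm",
    "validation_wilcoxon",
]


def icc_array_vs_pyro(
    paired: list[tuple[float, float]], form: str = "absolute"
) -> float:
    """Intraclass correlation between array and pyrosequencing measurements.

    ``paired`` holds (array beta, pyro percent / 100) per sample; pairs with
    a missing member are dropped.  The default is the two-way,
    single-measure, absolute-agreement form (ICC(2,1)), so systematic scale
    shifts between the platforms reduce agreement, which is the property of
    interest when asking whether the platforms are interchangeable;
    ``form="consistency"`` gives the consistency form (ICC(3,1)) instead.
    """
    if form not in ("absolute", "consistency"):
        raise ValueError("form must be 'absolute' or 'consistency'")
    data = np.array(
        [(a, b) for a, b in paired if np.isfinite(a) and np.isfinite(b)], dtype=float
    )
    if len(data) < 3:
        raise ValueError("insufficient pairs: ICC needs at least 3 complete pairs")
    n, k = data.shape  # subjects x raters (k = 2)
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    if form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        # all values identical in every cell: perfect (vacuous) agreement
        return 1.0
    return float((msr - mse) / denom)


def pairwise_r2(pyro: pd.DataFrame, loci: list[str] | None = None) -> pd.DataFrame:
    """Squared Pearson correlation between loci over pairwise-complete samples.

    ``pyro`` is loci x samples with NaN for failed assays.  Pairs with fewer
    than 3 complete observations, and constant loci, yield NaN.
    """
    sub = pyro if loci is None else pyro.loc[list(loci)]
    corr = sub.T.corr(method="pearson", min_periods=3)
    r2 = corr**2
    for l in r2.index:
        vals = sub.loc[l].dropna()
        if len(vals) >= 3 and vals.nunique() > 1:
            r2.loc[l, l] = 1.0
    return r2


def _wald_p(fit, name: str) -> float:
    return float(fit.pvalues[name])


def independence_glm(
    meth: pd.Series,
    mutation: pd.Series,
    er: pd.Series,
    grade: pd.Series,
    locus_id: str = "",
    min_complete: int = 10,
) -> IndependenceResult:
    """Nested logistic regressions of mutation status on methylation.

    Fits mutation ~ methylation, then + ER, then + ER + grade on complete
    cases only, by maximum likelihood, reporting the Wald p-value of each
    coefficient.  A marker that is informative only through its correlation
    with ER shows a small marginal p but a large conditional one.  Perfect
    separation is flagged and the affected p-values reported as NaN.
    """
    df = pd.DataFrame(
        {"meth": meth, "mutation": mutation, "er": er, "grade": grade}
    ).dropna()
    n = len(df)
    if n < min_complete:
        raise ValueError(
            f"independence glm needs >= {min_complete} complete cases, got {n}"
        )
    y = df["mutation"].astype(float)
    if y.nunique() < 2:
        raise ValueError("mutation labels are constant among complete cases")

    def fit_p(cols: list[str]) -> dict[str, float]:
        X = sm.add_constant(df[cols].astype(float))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.any(np.abs(res.params) > 50):
                raise np.linalg.LinAlgError("divergent coefficients")
            return {c: _wald_p(res, c) for c in cols}
        except Exception:
            warnings.warn(
                f"locus {locus_id or '?'}: logistic fit on {cols} did not converge "
                "(possible perfect separation); p-values reported as missing"
            )
            return {c: float("nan") for c in cols}

    p1 = fit_p(["meth"])
    p2 = fit_p(["meth", "er"])
    p3 = fit_p(["meth", "er", "grade"])
    return IndependenceResult(
        locus_id=locus_id,
        p_meth_alone=p1["meth"],
        p_meth_given_er=p2["meth"],
        p_er=p2["er"],
        p_meth_given_er_grade=p3["meth"],
        p_er_given_grade=p3["er"],
        p_grade=p3["grade"],
        n_complete_cases=n,
    )


def validation_wilcoxon(
    pyro: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Rank-sum validation of each locus on the percent-methylation scale.

    ``labels`` maps sample id to 1 (mutated) or 0 (wild-type); missing
    assay values and unlabeled samples are dropped per locus.  Returns a
    table of p-values, group medians and the wild-type-minus-mutated median
    difference.  Loci with an empty group are skipped with a warning.
    """
    labels = labels.reindex(pyro.columns)
    rows = []
    for locus in pyro.index:
        vals = pyro.loc[locus]
        ok = vals.notna() & labels.notna()
        g1 = vals[ok & (labels == 1)].to_numpy()
        g2 = vals[ok & (labels == 0)].to_numpy()
        if len(g1) < 2 or len(g2) < 2:
            warnings.warn(f"locus {locus}: a group is empty/too small after "
                          "dropping missing values; skipped")
            continue
        rows.append(
            {
                "locus_id": locus,
                "n_group1": len(g1),
                "n_group2": len(g2),
                "p_value": rank_sum_p(g1, g2),
                "median_group1": float(np.median(g1)),
                "median_group2": float(np.median(g2)),
                "median_difference": float(np.median(g2) - np.median(g1)),
            }
        )
    return pd.DataFrame(rows).set_index("locus_id") if rows else pd.DataFrame()
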