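"""Differential-methylation probe screen and candidate-panel selection.

Three two-group rank-sum screens are run on the QC-passed beta matrix —
mutation status (pathogenic vs. wild-type), ER status and grade — each
corrected by Benjamini-Hochberg FDR.  Candidate markers of mutation status
are the probes significant only in the mutation contrast (Venn uniqueness),
with an absolute median group difference of at least 5% beta, and not
attributable to a genotype confound at the probed CpG.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    GROUP_PATHOGENIC,
    GROUP_WILDTYPE,
    ProbeTestResult,
    SampleRecord,
    SelectionResult,
)

__all__ = [
    "rank_sum_p",
    "wilcoxon_screen",
    "bh_fdr",
    "venn_unique",
    "effect_size_filter",
    "snp_confound_test",
    "genotype_table",
    "select_probes",
    "CONTRAST_MUTATION",
    "CONTRAST_ER",
    "CONTRAST_GRADE",
]

CONTRAST_MUTATION = "mutation"
CONTRAST_ER = "ER"
CONTRAST_GRADE = "grade"

_EXACT_MAX_N = 8  # exact rank-sum null up to this min group size (no ties)


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one probe.

    Uses the exact null distribution when the smaller group has at most
    eight observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0  # identical distributions carry no rank information
    no_ties = len(np.unique(combined)) == len(combined)
    if min(len(x), len(y)) <= _EXACT_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def wilcoxon_screen(
    beta: pd.DataFrame, labels: pd.Series, contrast: str
) -> list[ProbeTestResult]:
    """Rank-sum screen of every probe between two label groups.

    ``labels`` maps sample id to 1 (group 1: mutated / ER-positive / high
    grade) or 0 (group 2); samples with a missing label are excluded from
    this contrast only.  ``delta_beta`` is median(group 2) - median(group 1),
    matching the wild-type-minus-mutated orientation of the screen.
    """
    labels = labels.reindex(beta.columns)
    valid = labels.notna()
    g1 = beta.columns[valid & (labels == 1)]
    g2 = beta.columns[valid & (labels == 0)]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"contrast {contrast!r}: each group needs >= 2 samples after "
            f"removing missing labels (got {len(g1)} and {len(g2)})"
        )
    m1 = beta[g1].to_numpy()
    m2 = beta[g2].to_numpy()
    med1 = np.median(m1, axis=1)
    med2 = np.median(m2, axis=1)

    if min(len(g1), len(g2)) > _EXACT_MAX_N:
        # vectorized normal approximation across all probes
        res = stats.mannwhitneyu(
            m1, m2, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
        pvals = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    else:
        pvals = np.array([rank_sum_p(m1[i], m2[i]) for i in range(len(beta))])

    return [
        ProbeTestResult(
            probe_id=str(pid),
            contrast=contrast,
            p_value=float(pvals[i]),
            median_group1=float(med1[i]),
            median_group2=float(med2[i]),
            delta_beta=float(med2[i] - med1[i]),
        )
        for i, pid in enumerate(beta.index)
    ]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q_values(results: list[ProbeTestResult]) -> list[ProbeTestResult]:
    """Fill the q_value field of a screen's results (in place; returned)."""
    q = bh_fdr([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    return results


def venn_unique(
    mutation_results: list[ProbeTestResult],
    er_results: list[ProbeTestResult],
    grade_results: list[ProbeTestResult],
    q_cut: float = 0.05,
) -> set[str]:
    """Probes significant in the mutation contrast only.

    A probe qualifies when its mutation-contrast q-value is below ``q_cut``
    and its ER and grade q-values are not (probes absent from a contrast,
    e.g. when that contrast could not be run, count as non-significant
    there).
    """
    sig_mut = {r.probe_id for r in mutation_results if r.q_value < q_cut}
    sig_er = {r.probe_id for r in er_results if r.q_value < q_cut}
    sig_grade = {r.probe_id for r in grade_results if r.q_value < q_cut}
    return sig_mut - sig_er - sig_grade


def effect_size_filter(
    candidates: set[str],
    mutation_results: list[ProbeTestResult],
    min_abs_delta: float = 0.05,
) -> set[str]:
    """Drop candidates whose absolute median group difference is below 5%.

    The boundary is retained: only probes with |delta beta| strictly less
    than ``min_abs_delta`` are excluded.
    """
    by_id = {r.probe_id: r for r in mutation_results}
    missing = candidates - set(by_id)
    if missing:
        raise KeyError(f"candidates without a mutation-contrast result: {sorted(missing)}")
    return {p for p in candidates if abs(by_id[p].delta_beta) >= min_abs_delta}


def snp_confound_test(genotype_counts) -> tuple[float, float, bool]:
    """Pearson chi-squared test of genotype-by-group association.

    ``genotype_counts`` is a 2 x k contingency table (groups x genotypes).
    No continuity correction is applied.  Returns ``(chi2, p, exclude)``
    with ``exclude`` true when p < 0.05 — the genotype distribution differs
    between groups, so the probe's methylation difference may be a genetic
    artifact (e.g. a CG>TG allele abolishing the CpG).
    """
    table = np.asarray(genotype_counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k contingency table with k >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    keep = table.sum(axis=0) > 0
    if not keep.all():
        warnings.warn("dropping all-zero genotype columns from chi-squared test")
        table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 1.0, False
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), bool(p < 0.05)


def genotype_table(
    genotypes: dict[str, int], records: list[SampleRecord]
) -> pd.DataFrame:
    """2 x k genotype-count table (pathogenic vs. wild-type) for one locus."""
    rows = {GROUP_PATHOGENIC: {}, GROUP_WILDTYPE: {}}
    for r in records:
        if r.group in rows and r.sample_id in genotypes:
            g = int(genotypes[r.sample_id])
            rows[r.group][g] = rows[r.group].get(g, 0) + 1
    cols = sorted(set(rows[GROUP_PATHOGENIC]) | set(rows[GROUP_WILDTYPE]))
    return pd.DataFrame(
        [[rows[grp].get(c, 0) for c in cols] for grp in (GROUP_PATHOGENIC, GROUP_WILDTYPE)],
        index=[GROUP_PATHOGENIC, GROUP_WILDTYPE],
        columns=[f"genotype_{c}" for c in cols],
    )


def _contrast_labels(records: list[SampleRecord], contrast: str) -> pd.Series:
    idx = [r.sample_id for r in records]
    if contrast == CONTRAST_MUTATION:
        vals = [
            1.0 if r.group == GROUP_PATHOGENIC
            else 0.0 if r.group == GROUP_WILDTYPE
            else np.nan
            for r in records
        ]
    elif contrast == CONTRAST_ER:
        vals = [np.nan if r.er_status is None else float(r.er_status) for r in records]
    elif contrast == CONTRAST_GRADE:
        vals = [np.nan if r.grade is None else float(r.grade) for r in records]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return pd.Series(vals, index=idx)


def select_probes(
    beta: pd.DataFrame,
    records: list[SampleRecord],
    q_cut: float = 0.05,
    min_abs_delta: float = 0.05,
    snp_genotypes: dict[str, dict[str, int]] | None = None,
) -> tuple[SelectionResult, dict[str, list[ProbeTestResult]]]:
    """Run the full screen: three contrasts, FDR, Venn, effect and SNP filters.

    The mutation contrast compares the known pathogenic and wild-type
    groups; the ER and grade contrasts use every sample with the relevant
    label.  ``snp_genotypes`` optionally maps probe id -> per-sample
    genotype (T-allele count) for loci with known polymorphisms; candidates
    whose genotype distribution differs between groups are excluded.
    """
    results: dict[str, list[ProbeTestResult]] = {}
    for contrast in (CONTRAST_MUTATION, CONTRAST_ER, CONTRAST_GRADE):
        labels = _contrast_labels(records, contrast)
        results[contrast] = attach_q_values(wilcoxon_screen(beta, labels, contrast))

    unique = venn_unique(
        results[CONTRAST_MUTATION], results[CONTRAST_ER], results[CONTRAST_GRADE],
        q_cut=q_cut,
    )
    passing = effect_size_filter(unique, results[CONTRAST_MUTATION], min_abs_delta)

    excluded_snp: dict[str, dict] = {}
    if snp_genotypes:
        for probe_id, genos in snp_genotypes.items():
            if probe_id not in passing:
                continue
            table = genotype_table(genos, records)
            chi2, p, exclude = snp_confound_test(table.to_numpy())
            if exclude:
                excluded_snp[probe_id] = {"chi2": chi2, "p": p}

    selection = SelectionResult(
        significant_by_contrast={
            c: {r.probe_id for r in results[c] if r.q_value < q_cut}
            for c in results
        },
        unique_to_mutation=unique,
        passing_effect_filter=passing,
        excluded_snp_probes=excluded_snp,
    )
    return selection, results
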