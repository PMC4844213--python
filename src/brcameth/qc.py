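"""Sample- and probe-level quality control for methylation array data.

Sample QC flags tumors whose internal-control metrics lie outside the normal
range across the cohort (> 3 SD by default).  Probe QC drops probes whose
detection p-values indicate failed hybridization in more than 20% of
samples.  Both steps are idempotent: re-running them on already-filtered
data changes nothing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import QCReport

__all__ = ["sample_qc", "probe_qc", "apply_qc"]


def sample_qc(control_metrics: pd.DataFrame, sd_threshold: float = 3.0) -> QCReport:
    """Flag samples with outlying control metrics.

    ``control_metrics`` is samples x metrics.  A sample fails if any metric
    lies strictly more than ``sd_threshold`` standard deviations from that
    metric's mean across all samples.  Zero-variance metrics cannot flag
    anything and are skipped with a warning.
    """
    if len(control_metrics) < 3:
        raise ValueError("sample QC requires at least 3 samples")
    passed: list[str] = []
    failed: dict[str, str] = {}
    means = control_metrics.mean(axis=0)
    sds = control_metrics.std(axis=0, ddof=1)

    usable = []
    for metric in control_metrics.columns:
        if sds[metric] == 0 or np.isnan(sds[metric]):
            warnings.warn(f"control metric {metric!r} has zero variance; skipped")
        else:
            usable.append(metric)

    for sid, row in control_metrics.iterrows():
        reasons = [
            m for m in usable
            if abs(row[m] - means[m]) > sd_threshold * sds[m]
        ]
        if reasons:
            failed[str(sid)] = f"metrics outside {sd_threshold} SD: " + ",".join(reasons)
        else:
            passed.append(str(sid))
    return QCReport(passed_samples=passed, failed_samples=failed)


def probe_qc(
    detp: pd.DataFrame, p_cut: float = 0.05, fail_fraction: float = 0.20
) -> QCReport:
    """Drop probes with too many failed detection calls.

    A call fails when its detection p-value is >= ``p_cut``; a probe is
    dropped iff its fraction of failed calls strictly exceeds
    ``fail_fraction`` (a probe failing in exactly 20% of samples is kept).
    """
    if detp.empty:
        raise ValueError("empty detection p-value matrix")
    fail_frac = (detp.to_numpy() >= p_cut).mean(axis=1)
    dropped_mask = fail_frac > fail_fraction
    return QCReport(
        retained_probes=[str(p) for p in detp.index[~dropped_mask]],
        dropped_probes=[str(p) for p in detp.index[dropped_mask]],
    )


def apply_qc(
    beta: pd.DataFrame,
    sample_report: QCReport | None = None,
    probe_report: QCReport | None = None,
) -> pd.DataFrame:
    """Restrict a beta matrix to QC-passing samples and probes."""
    out = beta
    if probe_report is not None:
        out = out.loc[[p for p in out.index if p in set(probe_report.retained_probes)]]
    if sample_report is not None:
        keep = set(sample_report.passed_samples)
        out = out[[s for s in out.columns if s in keep]]
    return out
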