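"""Shared containers for the methylation-based variant classification pipeline.

Matrices (beta values, detection p-values, pyrosequencing percentages,
consensus matrices) are plain :class:`pandas.DataFrame` objects with probe /
locus identifiers as the index and sample identifiers as columns.  The
dataclasses here carry the structured records that flow between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

# Group labels used throughout the sample sheet.
GROUP_PATHOGENIC = "BRCA1"
GROUP_WILDTYPE = "BRCAx"
GROUP_TEST = "test"

VALID_GROUPS = (GROUP_PATHOGENIC, GROUP_WILDTYPE, GROUP_TEST)


@dataclass
class SampleRecord:
    """Per-tumor annotations driving every contrast.

    ``er_status`` is 1 for ER-positive, 0 for ER-negative, None if unknown.
    ``grade`` is dichotomized: 0 for low grade (histological grades 1-2),
    1 for high grade (grade 3), None if unknown.
    """

    sample_id: str
    group: str
    variant_id: Optional[str] = None
    er_status: Optional[int] = None
    grade: Optional[int] = None
    individual_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {VALID_GROUPS}"
            )


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Sample sheet as a DataFrame indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "variant_id": [r.variant_id for r in records],
            "er_status": [r.er_status for r in records],
            "grade": [r.grade for r in records],
            "individual_id": [r.individual_id for r in records],
        }
    )
    return df.set_index("sample_id", drop=False)


def frame_to_records(df: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in df.iterrows():
        def _opt(v):
            if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
                return None
            return v

        er = _opt(row.get("er_status"))
        gr = _opt(row.get("grade"))
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                variant_id=_opt(row.get("variant_id")),
                er_status=None if er is None else int(er),
                grade=None if gr is None else int(gr),
                individual_id=_opt(row.get("individual_id")),
            )
        )
    return records


@dataclass
class Truth:
    """Ground truth of a simulated cohort, for evaluation only."""

    mut_probe_ids: set[str]
    er_probe_ids: set[str]
    grade_probe_ids: set[str]
    pathogenic: dict[str, bool]  # sample_id -> true pathogenicity
    snp_probe_id: Optional[str] = None
    snp_genotypes: dict[str, int] = field(default_factory=dict)  # T-allele count
    failing_probe_ids: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "mut_probe_ids": sorted(self.mut_probe_ids),
            "er_probe_ids": sorted(self.er_probe_ids),
            "grade_probe_ids": sorted(self.grade_probe_ids),
            "pathogenic": {k: bool(v) for k, v in self.pathogenic.items()},
            "snp_probe_id": self.snp_probe_id,
            "snp_genotypes": {k: int(v) for k, v in self.snp_genotypes.items()},
            "failing_probe_ids": sorted(self.failing_probe_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Truth":
        return cls(
            mut_probe_ids=set(d["mut_probe_ids"]),
            er_probe_ids=set(d["er_probe_ids"]),
            grade_probe_ids=set(d["grade_probe_ids"]),
            pathogenic={k: bool(v) for k, v in d["pathogenic"].items()},
            snp_probe_id=d.get("snp_probe_id"),
            snp_genotypes={k: int(v) for k, v in d.get("snp_genotypes", {}).items()},
            failing_probe_ids=set(d.get("failing_probe_ids", [])),
        )


@dataclass
class QCReport:
    passed_samples: list[str] = field(default_factory=list)
    failed_samples: dict[str, str] = field(default_factory=dict)  # id -> reason
    retained_probes: list[str] = field(default_factory=list)
    dropped_probes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "passed_samples": list(self.passed_samples),
            "failed_samples": dict(self.failed_samples),
            "retained_probes": list(self.retained_probes),
            "dropped_probes": list(self.dropped_probes),
        }


@dataclass
class ProbeTestResult:
    """One probe, one contrast, from the rank-sum screen."""

    probe_id: str
    contrast: str  # mutation | ER | grade
    p_value: float
    q_value: float = float("nan")
    median_group1: float = float("nan")
    median_group2: float = float("nan")
    delta_beta: float = float("nan")  # median_group2 - median_group1


@dataclass
class SelectionResult:
    significant_by_contrast: dict[str, set[str]]
    unique_to_mutation: set[str]
    passing_effect_filter: set[str]
    excluded_snp_probes: dict[str, dict] = field(default_factory=dict)

    @property
    def panel(self) -> set[str]:
        """Final candidate marker panel after every filter."""
        return self.passing_effect_filter - set(self.excluded_snp_probes)


@dataclass
class ConsensusResult:
    consensus_matrix: pd.DataFrame  # samples x samples in [0, 1]
    assignments: pd.Series  # sample_id -> cluster label in {1, 2}
    cluster_identity: dict[int, str]  # cluster -> "BRCA1-like"/"BRCAx-like"/"ambiguous"
    test_sample_calls: dict[str, Optional[str]] = field(default_factory=dict)


@dataclass
class IndependenceResult:
    """Nested logistic regression p-values for one locus (confounder check)."""

    locus_id: str
    p_meth_alone: float
    p_meth_given_er: float
    p_er: float
    p_meth_given_er_grade: float
    p_er_given_grade: float
    p_grade: float
    n_complete_cases: int


@dataclass
class LogisticModel:
    """Z-score reference statistics plus fitted logistic coefficients."""

    marker_ids: list[str]
    ref_means: dict[str, float]
    ref_sds: dict[str, float]
    intercept: float
    coefficients: dict[str, float]
    training_n: int
    dropped_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.marker_ids:
            if self.ref_sds[m] <= 0:
                raise ValueError(f"degenerate marker {m}: reference sd must be > 0")
        if set(self.coefficients) != set(self.marker_ids):
            raise ValueError("coefficient set must match marker set")

    def to_dict(self) -> dict:
        return {
            "marker_ids": list(self.marker_ids),
            "ref_means": dict(self.ref_means),
            "ref_sds": dict(self.ref_sds),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "training_n": self.training_n,
            "dropped_markers": list(self.dropped_markers),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            marker_ids=list(d["marker_ids"]),
            ref_means={k: float(v) for k, v in d["ref_means"].items()},
            ref_sds={k: float(v) for k, v in d["ref_sds"].items()},
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            training_n=int(d["training_n"]),
            dropped_markers=list(d.get("dropped_markers", [])),
        )


@dataclass
class TumorPrediction:
    sample_id: str
    variant_id: Optional[str]
    probability: float
    predicted_label: int  # 1 = pathogenic-like at threshold 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.probability < 1.0):
            raise ValueError("probability must lie strictly inside (0, 1)")


@dataclass
class SpliceContext:
    """Raw splice-site strength scores plus the calibration reference.

    ``site_type`` is one of ``donor``, ``acceptor`` or ``de_novo_donor``.
    ``calibration_mean``/``calibration_sd`` describe the distribution of
    scores of wild-type splice junctions against which raw scores are
    standardized.
    """

    site_type: str
    raw_mes_wt: float
    raw_mes_variant: float
    calibration_mean: float
    calibration_sd: float

    def __post_init__(self) -> None:
        if self.site_type not in ("donor", "acceptor", "de_novo_donor"):
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if self.calibration_sd <= 0:
            raise ValueError("calibration_sd must be > 0")


@dataclass
class VariantEvidence:
    variant_id: str
    missense_prior: Optional[float] = None
    splice_contexts: list[SpliceContext] = field(default_factory=list)
    prior_override: Optional[float] = None
    extra_lrs: list[float] = field(default_factory=list)  # e.g. segregation LRs

    def __post_init__(self) -> None:
        if (
            self.missense_prior is None
            and not self.splice_contexts
            and self.prior_override is None
        ):
            raise ValueError(
                f"variant {self.variant_id}: at least one prior source required"
            )


@dataclass
class ClassificationResult:
    variant_id: str
    n_tumors: int
    n_independent: int
    tumor_probabilities: dict[str, float]
    tumor_lrs: dict[str, float]
    combined_lr: float
    prior: float
    posterior: float
    iarc_class: int
    guard_applied: bool = False
    posterior_range: Optional[tuple[float, float]] = None
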