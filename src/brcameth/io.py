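"""Plain-text readers and writers for every pipeline artifact.

Matrices (beta values, detection p-values, consensus) travel as TSV with
probes/loci as rows and samples as columns; sample sheets, pyrosequencing
tables (long format), evidence and result tables as CSV; models, ground
truth and QC reports as JSON; pipeline configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    LogisticModel,
    SampleRecord,
    SpliceContext,
    Truth,
    VariantEvidence,
    frame_to_records,
    records_to_frame,
)

__all__ = [
    "read_matrix", "write_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_truth", "write_truth",
    "read_pyro", "write_pyro",
    "read_evidence", "write_evidence",
    "read_model", "write_model",
    "read_yaml", "write_json",
]


def write_matrix(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(records: list[SampleRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_sample_sheet(path) -> list[SampleRecord]:
    return frame_to_records(pd.read_csv(path))


def write_truth(truth: Truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_truth(path) -> Truth:
    return Truth.from_dict(json.loads(Path(path).read_text()))


def write_pyro(pyro: pd.DataFrame, path) -> None:
    """Long-format CSV: locus_id, sample_id, percent (missing rows omitted)."""
    long = (
        pyro.rename_axis("locus_id")
        .reset_index()
        .melt(id_vars="locus_id", var_name="sample_id", value_name="percent")
        .dropna(subset=["percent"])
    )
    long.to_csv(path, index=False)


def read_pyro(path, sample_ids: list[str] | None = None) -> pd.DataFrame:
    long = pd.read_csv(path)
    wide = long.pivot(index="locus_id", columns="sample_id", values="percent")
    if sample_ids is not None:
        wide = wide.reindex(columns=sample_ids)
    wide.columns.name = None
    return wide


def write_evidence(evidence: list[VariantEvidence], path) -> None:
    payload = []
    for e in evidence:
        payload.append(
            {
                "variant_id": e.variant_id,
                "missense_prior": e.missense_prior,
                "prior_override": e.prior_override,
                "extra_lrs": list(e.extra_lrs),
                "splice_contexts": [
                    {
                        "site_type": c.site_type,
                        "raw_mes_wt": c.raw_mes_wt,
                        "raw_mes_variant": c.raw_mes_variant,
                        "calibration_mean": c.calibration_mean,
                        "calibration_sd": c.calibration_sd,
                    }
                    for c in e.splice_contexts
                ],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_evidence(path) -> list[VariantEvidence]:
    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        out.append(
            VariantEvidence(
                variant_id=d["variant_id"],
                missense_prior=d.get("missense_prior"),
                prior_override=d.get("prior_override"),
                extra_lrs=[float(x) for x in d.get("extra_lrs", [])],
                splice_contexts=[
                    SpliceContext(**c) for c in d.get("splice_contexts", [])
                ],
            )
        )
    return out


def write_model(model: LogisticModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_model(path) -> LogisticModel:
    return LogisticModel.from_dict(json.loads(Path(path).read_text()))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=_default))
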