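"""End-to-end orchestration: simulate -> qc -> select -> cluster -> validate
-> fit/predict -> classify, under a single seeded configuration.

Every stage writes its artifacts to the output directory as plain text and
the run finishes with a manifest (file checksums) and a report (counts at
each stage).  Stage outputs are pure functions of their declared inputs, so
a rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cluster import BRCA1_LIKE, call_test_samples, consensus_cluster
from .classify import classify_variants
from .datatypes import (
    GROUP_PATHOGENIC,
    GROUP_TEST,
    GROUP_WILDTYPE,
    SampleRecord,
    Truth,
)
from .model import fit_logistic, loocv, ppv_npv, predict_samples
from .qc import apply_qc, probe_qc
from .select import select_probes
from .simulate import (
    SimConfig,
    generate_cohort,
    generate_detection_pvalues,
    generate_evidence,
    generate_pyro_panel,
)
from .validate import validation_wilcoxon

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    fail_probe_fraction: float = 0.007
    q_cut: float = 0.05
    min_abs_delta: float = 0.05
    k: int = 2
    n_resamples: int = 100
    subsample_fraction: float = 0.8
    max_markers: int = 4
    min_complete_per_class: int = 5
    guard: bool = False
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "qc": True,
            "select": True,
            "cluster": True,
            "validate": True,
            "fit_predict": True,
            "classify": True,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = io.read_yaml(path)
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.pop("sim", {}).items()})
        stages = {**cls().stages, **raw.pop("stages", {})}
        return cls(sim=sim, stages=stages, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages_run": []}
    sim = config.sim
    if sim.seed != config.seed:
        sim = SimConfig(**{**asdict(sim), "seed": config.seed})

    beta = records = truth = None
    panel: list[str] = []
    pyro = None

    def stage(name):
        return config.stages.get(name, False)

    try:
        if stage("simulate"):
            beta, records, truth = generate_cohort(sim)
            detp, failing = generate_detection_pvalues(
                beta, config.fail_probe_fraction, seed=config.seed
            )
            truth.failing_probe_ids = failing
            io.write_matrix(beta, out / "beta.tsv")
            io.write_matrix(detp, out / "detp.tsv")
            io.write_sample_sheet(records, out / "samples.csv")
            io.write_truth(truth, out / "truth.json")
            evidence = generate_evidence(records, truth, sim)
            io.write_evidence(evidence, out / "evidence.json")
            report["stages_run"].append("simulate")
            report["n_samples"] = beta.shape[1]
            report["n_probes"] = beta.shape[0]
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    needs_data = any(
        stage(s) for s in ("qc", "select", "cluster", "validate", "fit_predict")
    )
    if beta is None and needs_data:
        try:
            beta = io.read_matrix(out / "beta.tsv")
            records = io.read_sample_sheet(out / "samples.csv")
            truth = io.read_truth(out / "truth.json")
        except FileNotFoundError as exc:
            raise PipelineError(f"stage qc failed: missing input artifact: {exc}") from exc

    try:
        if stage("qc"):
            detp = io.read_matrix(out / "detp.tsv")
            probe_report = probe_qc(detp)
            beta = apply_qc(beta, probe_report=probe_report)
            io.write_json(probe_report.to_dict(), out / "qc.json")
            report["stages_run"].append("qc")
            report["probes_retained"] = len(probe_report.retained_probes)
            report["probes_dropped"] = len(probe_report.dropped_probes)
    except Exception as exc:
        raise PipelineError(f"stage qc failed: {exc}") from exc

    try:
        if stage("select"):
            snp_map = (
                {truth.snp_probe_id: truth.snp_genotypes}
                if truth.snp_probe_id and truth.snp_genotypes
                else None
            )
            selection, screen = select_probes(
                beta, records, q_cut=config.q_cut,
                min_abs_delta=config.min_abs_delta, snp_genotypes=snp_map,
            )
            panel = sorted(selection.panel)
            rows = []
            for contrast, results in screen.items():
                for r in results:
                    rows.append(
                        {
                            "probe_id": r.probe_id, "contrast": contrast,
                            "p_value": r.p_value, "q_value": r.q_value,
                            "median_group1": r.median_group1,
                            "median_group2": r.median_group2,
                            "delta_beta": r.delta_beta,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "screen.tsv", sep="\t", index=False)
            io.write_json(
                {
                    "significant_by_contrast": {
                        c: sorted(s) for c, s in selection.significant_by_contrast.items()
                    },
                    "unique_to_mutation": sorted(selection.unique_to_mutation),
                    "passing_effect_filter": sorted(selection.passing_effect_filter),
                    "excluded_snp_probes": selection.excluded_snp_probes,
                    "panel": panel,
                },
                out / "selection.json",
            )
            report["stages_run"].append("select")
            report["n_significant_mutation"] = len(
                selection.significant_by_contrast["mutation"]
            )
            report["n_significant_ER"] = len(selection.significant_by_contrast["ER"])
            report["n_significant_grade"] = len(
                selection.significant_by_contrast["grade"]
            )
            report["n_unique_to_mutation"] = len(selection.unique_to_mutation)
            report["n_panel"] = len(panel)
            report["n_snp_excluded"] = len(selection.excluded_snp_probes)
    except Exception as exc:
        raise PipelineError(f"stage select failed: {exc}") from exc

    if not panel and (stage("cluster") or stage("validate") or stage("fit_predict")):
        import json

        panel = json.loads((out / "selection.json").read_text())["panel"]

    try:
        if stage("cluster") and panel:
            result = consensus_cluster(
                beta.loc[panel], k=config.k, n_resamples=config.n_resamples,
                subsample_fraction=config.subsample_fraction, seed=config.seed,
            )
            calls = call_test_samples(result, records)
            io.write_matrix(result.consensus_matrix, out / "consensus.tsv")
            pd.DataFrame(
                {
                    "sample_id": result.assignments.index,
                    "cluster": result.assignments.to_numpy(),
                    "call": [
                        calls.get(s, "") for s in result.assignments.index
                    ],
                }
            ).to_csv(out / "clusters.csv", index=False)
            report["stages_run"].append("cluster")
            report["n_test_called_brca1_like"] = sum(
                1 for v in calls.values() if v == BRCA1_LIKE
            )
            report["n_test_called"] = sum(1 for v in calls.values() if v)
    except Exception as exc:
        raise PipelineError(f"stage cluster failed: {exc}") from exc

    validated: list[str] = []
    try:
        if stage("validate") and panel:
            pyro = generate_pyro_panel(beta, panel, sim)
            io.write_pyro(pyro, out / "pyro.csv")
            labels = pd.Series(
                {
                    r.sample_id: (
                        1.0 if r.group == GROUP_PATHOGENIC
                        else 0.0 if r.group == GROUP_WILDTYPE
                        else np.nan
                    )
                    for r in records
                }
            )
            vw = validation_wilcoxon(pyro, labels)
            vw.to_csv(out / "validation.tsv", sep="\t")
            validated = sorted(vw.index[vw["p_value"] < 0.05])
            report["stages_run"].append("validate")
            report["n_validated"] = len(validated)
    except Exception as exc:
        raise PipelineError(f"stage validate failed: {exc}") from exc

    predictions = []
    try:
        if stage("fit_predict") and panel:
            if pyro is None:
                pyro = io.read_pyro(out / "pyro.csv", [r.sample_id for r in records])
            markers = validated or panel
            if len(markers) > config.max_markers:
                vw = pd.read_csv(out / "validation.tsv", sep="\t", index_col=0)
                markers = list(
                    vw.loc[[m for m in markers if m in vw.index], "p_value"]
                    .sort_values()
                    .index[: config.max_markers]
                )
            values = pyro.loc[markers].T  # samples x markers, percent scale
            known = [r for r in records if r.group in (GROUP_PATHOGENIC, GROUP_WILDTYPE)]
            train_values = values.loc[[r.sample_id for r in known]]
            train_labels = pd.Series(
                {r.sample_id: float(r.group == GROUP_PATHOGENIC) for r in known}
            )
            model = fit_logistic(
                train_values, train_labels,
                min_complete_per_class=config.min_complete_per_class,
            )
            io.write_model(model, out / "model.json")
            acc, heldout = loocv(
                train_values, train_labels,
                min_complete_per_class=config.min_complete_per_class,
            )
            preds_known, _ = predict_samples(model, train_values)
            ppv, npv = ppv_npv(
                pd.Series({p.sample_id: p.predicted_label for p in preds_known}),
                train_labels,
            )
            test_ids = [r.sample_id for r in records if r.group == GROUP_TEST]
            variant_of = {
                r.sample_id: r.variant_id for r in records if r.variant_id
            }
            predictions, skipped = predict_samples(
                model, values.loc[test_ids], variant_of
            )
            pd.DataFrame(
                [
                    {
                        "sample_id": p.sample_id,
                        "variant_id": p.variant_id,
                        "probability": p.probability,
                        "predicted_label": p.predicted_label,
                    }
                    for p in predictions
                ]
            ).to_csv(out / "predictions.csv", index=False)
            report["stages_run"].append("fit_predict")
            report["markers_in_model"] = model.marker_ids
            report["loocv_accuracy"] = acc
            report["training_ppv"] = ppv
            report["training_npv"] = npv
            report["n_test_predicted"] = len(predictions)
            report["n_test_skipped_missing"] = len(skipped)
    except Exception as exc:
        raise PipelineError(f"stage fit_predict failed: {exc}") from exc

    try:
        if stage("classify") and predictions:
            evidence = io.read_evidence(out / "evidence.json")
            results = classify_variants(
                predictions, records, evidence, guard=config.guard
            )
            pd.DataFrame(
                [
                    {
                        "variant_id": r.variant_id,
                        "n_tumors": r.n_tumors,
                        "n_independent": r.n_independent,
                        "prior": r.prior,
                        "combined_lr": r.combined_lr,
                        "posterior": r.posterior,
                        "iarc_class": r.iarc_class,
                        "guard_applied": r.guard_applied,
                        "posterior_low": r.posterior_range[0] if r.posterior_range else "",
                        "posterior_high": r.posterior_range[1] if r.posterior_range else "",
                    }
                    for r in results
                ]
            ).to_csv(out / "classification.csv", index=False)
            # per-sample log-LR table for plotting the spread by variant
            pd.DataFrame(
                [
                    {
                        "variant_id": r.variant_id,
                        "sample_id": sid,
                        "log_lr": float(np.log(lr)),
                    }
                    for r in results
                    for sid, lr in r.tumor_lrs.items()
                ]
            ).to_csv(out / "log_lrs.csv", index=False)
            report["stages_run"].append("classify")
            report["n_variants_classified"] = len(results)
            report["classes"] = {
                r.variant_id: r.iarc_class for r in results
            }
    except Exception as exc:
        raise PipelineError(f"stage classify failed: {exc}") from exc

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "report.json")
    }
    io.write_json(manifest, out / "manifest.json")
    io.write_json(report, out / "report.json")
    return report
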