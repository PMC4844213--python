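"""Synthetic cohorts with the statistical structure of familial breast-tumor
methylation studies.

The generator emulates a three-group cohort (BRCA1-pathogenic, BRCAx
wild-type, and test-variant tumors) measured on a methylation array:

* beta values drawn from beta distributions parameterized by a per-probe
  mean and a shared concentration, keeping the [0, 1] support;
* a small set of probes carrying a planted mutation-status effect
  (absolute mean shift drawn from ``mut_effect_range``);
* a much larger set of ER-status-associated probes and a handful of
  grade-associated probes — the dominant structure of breast-tumor
  methylation is ER-driven, and ER status is strongly confounded with
  mutation status (``er_mut_log_odds``);
* one SNP-confounded locus where a CG>TG polymorphism (minor allele
  frequency ``snp_maf``) abolishes methylation on the T allele and the T
  allele is overrepresented in the wild-type group, creating a spurious
  group difference;
* a pyrosequencing panel on the percent scale with per-assay
  missing-completely-at-random dropout (30-75% by default, the failure
  range typical of fragmented FFPE-derived DNA);
* per-probe detection p-values with a designated fraction of failing
  probes.

All outputs are bit-identical under a fixed seed.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GROUP_PATHOGENIC,
    GROUP_TEST,
    GROUP_WILDTYPE,
    SampleRecord,
    SpliceContext,
    Truth,
    VariantEvidence,
)

__all__ = [
    "SimConfig",
    "generate_cohort",
    "generate_pyro_panel",
    "generate_detection_pvalues",
    "generate_evidence",
]


@dataclass
class SimConfig:
    """Cohort-generation parameters.

    Defaults mirror a scaled-down genome-wide screen: 20 tumors per group,
    2000 probes of which 20 carry a mutation effect, 200 an ER effect and 5
    a grade effect.  ``mut_effect_range`` is the absolute beta-value shift
    between pathogenic and wild-type tumors; its floor of 0.05 matches the
    minimum group difference considered biologically meaningful downstream.
    """

    n_brca1: int = 20
    n_brcax: int = 20
    n_test: int = 20
    n_probes: int = 2000
    n_mut_probes: int = 20
    n_er_probes: int = 200
    n_grade_probes: int = 5
    mut_effect_range: tuple[float, float] = (0.05, 0.30)
    er_effect_range: tuple[float, float] = (0.05, 0.30)
    grade_effect_range: tuple[float, float] = (0.05, 0.20)
    er_mut_log_odds: float = 2.2
    er_missing_rate: float = 0.05
    grade_missing_rate: float = 0.10
    pyro_dropout_range: tuple[float, float] = (0.30, 0.75)
    pyro_noise_sd: float = 5.0  # percent-methylation scale
    snp_maf: float = 0.2
    include_snp_probe: bool = True
    noise_concentration: float = 40.0
    frac_test_pathogenic: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_brca1", "n_brcax", "n_test", "n_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"degenerate cohort: {name} must be > 0")
        n_special = self.n_mut_probes + self.n_er_probes + self.n_grade_probes
        if n_special + int(self.include_snp_probe) > self.n_probes:
            raise ValueError("planted probe counts exceed total probe count")
        for name in ("mut_effect_range", "er_effect_range", "grade_effect_range",
                     "pyro_dropout_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"{name} must satisfy 0 <= low <= high <= 1")
        if not (0 <= self.snp_maf <= 1):
            raise ValueError("snp_maf must be in [0, 1]")
        if self.noise_concentration <= 0:
            raise ValueError("noise_concentration must be > 0")


def _baseline_means(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal per-probe baseline means, as on real methylation arrays."""
    comp = rng.choice(3, size=n, p=[0.45, 0.45, 0.10])
    means = np.empty(n)
    means[comp == 0] = rng.beta(2, 8, size=(comp == 0).sum())  # unmethylated mode
    means[comp == 1] = rng.beta(8, 2, size=(comp == 1).sum())  # methylated mode
    means[comp == 2] = rng.beta(5, 5, size=(comp == 2).sum())  # intermediate
    return np.clip(means, 0.03, 0.97)


def _signed_shift(rng: np.random.Generator, base: float, lo: float, hi: float) -> float:
    """Draw |shift| from [lo, hi]; orient toward the side with more headroom."""
    mag = rng.uniform(lo, hi)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if base + sign * mag > 0.98 or base + sign * mag < 0.02:
        sign = -sign
    return sign * mag


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, list[SampleRecord], Truth]:
    """Generate a beta-value matrix, sample sheet and ground truth.

    Returns ``(beta, records, truth)`` where ``beta`` is probes x samples in
    [0, 1].  Pathogenic tumors (the BRCA1 group plus the truly pathogenic
    test-variant tumors) carry the planted mutation-probe shifts; ER and
    grade shifts follow each sample's latent ER / grade state, which is then
    partially masked in the sample sheet to emulate missing pathology data.
    """
    rng = np.random.default_rng([int(config.seed), 0xC0])

    n_total = config.n_brca1 + config.n_brcax + config.n_test
    sample_ids = (
        [f"B{i+1:03d}" for i in range(config.n_brca1)]
        + [f"X{i+1:03d}" for i in range(config.n_brcax)]
        + [f"T{i+1:03d}" for i in range(config.n_test)]
    )
    groups = (
        [GROUP_PATHOGENIC] * config.n_brca1
        + [GROUP_WILDTYPE] * config.n_brcax
        + [GROUP_TEST] * config.n_test
    )

    # --- test-variant structure: variants, tumors, individuals -------------
    # Roughly 70% as many variants as test tumors; a few variants contribute
    # two or three tumors, occasionally from the same individual.
    test_ids = sample_ids[config.n_brca1 + config.n_brcax:]
    n_variants = max(1, int(np.ceil(config.n_test * 0.7)))
    variant_names = [f"VUS{i+1:02d}" for i in range(n_variants)]
    variant_truth = {
        v: bool(rng.random() < config.frac_test_pathogenic) for v in variant_names
    }
    # first assign one tumor per variant, then distribute the remainder
    assignment = list(variant_names)
    while len(assignment) < config.n_test:
        assignment.append(variant_names[int(rng.integers(n_variants))])
    assignment = assignment[: config.n_test]
    rng.shuffle(assignment)

    variant_of = dict(zip(test_ids, assignment))
    individual_of: dict[str, str] = {}
    seen_per_variant: dict[str, int] = {}
    for sid in test_ids:
        v = variant_of[sid]
        k = seen_per_variant.get(v, 0)
        # second tumor of a variant shares an individual 25% of the time
        if k >= 1 and rng.random() < 0.25:
            individual_of[sid] = f"IND_{v}_1"
        else:
            individual_of[sid] = f"IND_{v}_{k + 1}"
        seen_per_variant[v] = k + 1

    pathogenic = {}
    for sid, grp in zip(sample_ids, groups):
        if grp == GROUP_PATHOGENIC:
            pathogenic[sid] = True
        elif grp == GROUP_WILDTYPE:
            pathogenic[sid] = False
        else:
            pathogenic[sid] = variant_truth[variant_of[sid]]

    # --- latent ER and grade, confounded with pathogenicity ---------------
    base_logit_er = np.log(0.7 / 0.3)  # ER-positive fraction in wild-type tumors
    er_latent = {}
    grade_latent = {}
    for sid in sample_ids:
        logit = base_logit_er - (config.er_mut_log_odds if pathogenic[sid] else 0.0)
        er = int(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
        er_latent[sid] = er
        p_high = 0.65 if er == 0 else 0.45  # ER-negative tumors skew high grade
        grade_latent[sid] = int(rng.random() < p_high)

    # --- planted probe sets ------------------------------------------------
    probe_ids = np.array([f"cg{i:08d}" for i in range(config.n_probes)])
    n_special = config.n_mut_probes + config.n_er_probes + config.n_grade_probes
    n_special += int(config.include_snp_probe)
    special = rng.choice(config.n_probes, size=n_special, replace=False)
    mut_idx = special[: config.n_mut_probes]
    er_idx = special[config.n_mut_probes: config.n_mut_probes + config.n_er_probes]
    grade_idx = special[
        config.n_mut_probes + config.n_er_probes:
        config.n_mut_probes + config.n_er_probes + config.n_grade_probes
    ]
    snp_idx = int(special[-1]) if config.include_snp_probe else None

    means = _baseline_means(rng, config.n_probes)
    # additive shifts on the mean scale, one per planted probe
    mut_shift = np.array(
        [_signed_shift(rng, means[i], *config.mut_effect_range) for i in mut_idx]
    )
    er_shift = np.array(
        [_signed_shift(rng, means[i], *config.er_effect_range) for i in er_idx]
    )
    grade_shift = np.array(
        [_signed_shift(rng, means[i], *config.grade_effect_range) for i in grade_idx]
    )

    # --- SNP genotypes at the confounded locus -----------------------------
    snp_genotypes: dict[str, int] = {}
    if snp_idx is not None:
        means[snp_idx] = max(means[snp_idx], 0.6)  # a normally methylated CpG
        for sid in sample_ids:
            # T allele enriched in wild-type tumors, depleted in pathogenic ones
            maf = min(2.0 * config.snp_maf, 0.5) if not pathogenic[sid] \
                else 0.3 * config.snp_maf
            snp_genotypes[sid] = int(rng.binomial(2, maf))

    # --- per-sample mean matrix then beta noise -----------------------------
    mean_matrix = np.tile(means[:, None], (1, n_total))
    for j, sid in enumerate(sample_ids):
        if pathogenic[sid]:
            mean_matrix[mut_idx, j] += mut_shift
        if er_latent[sid] == 1:
            mean_matrix[er_idx, j] += er_shift
        if grade_latent[sid] == 1:
            mean_matrix[grade_idx, j] += grade_shift
        if snp_idx is not None:
            # each T allele removes half of the methylatable CpG dosage
            mean_matrix[snp_idx, j] *= 1.0 - 0.5 * snp_genotypes[sid]
    mean_matrix = np.clip(mean_matrix, 0.01, 0.99)

    c = config.noise_concentration
    beta_values = rng.beta(mean_matrix * c, (1.0 - mean_matrix) * c)
    beta = pd.DataFrame(beta_values, index=probe_ids, columns=sample_ids)

    # --- sample sheet with partially masked pathology ----------------------
    records = []
    for sid, grp in zip(sample_ids, groups):
        er: int | None = er_latent[sid]
        gr: int | None = grade_latent[sid]
        if rng.random() < config.er_missing_rate:
            er = None
        if rng.random() < config.grade_missing_rate:
            gr = None
        records.append(
            SampleRecord(
                sample_id=sid,
                group=grp,
                variant_id=variant_of.get(sid),
                er_status=er,
                grade=gr,
                individual_id=individual_of.get(sid, f"IND_{sid}"),
            )
        )

    truth = Truth(
        mut_probe_ids=set(probe_ids[mut_idx]),
        er_probe_ids=set(probe_ids[er_idx]),
        grade_probe_ids=set(probe_ids[grade_idx]),
        pathogenic=pathogenic,
        snp_probe_id=None if snp_idx is None else str(probe_ids[snp_idx]),
        snp_genotypes=snp_genotypes,
    )
    return beta, records, truth


def generate_pyro_panel(
    beta: pd.DataFrame, loci: list[str], config: SimConfig
) -> pd.DataFrame:
    """Pyrosequencing percent-methylation table for ``loci``.

    Percent methylation is 100*beta plus Gaussian noise of sd
    ``config.pyro_noise_sd`` (percent scale), clipped to [0, 100].  Each
    locus loses a fraction of samples drawn from ``pyro_dropout_range``
    (missing completely at random), emulating per-assay QC failure of
    degraded FFPE DNA.  Missing entries are NaN.
    """
    missing = [l for l in loci if l not in beta.index]
    if missing:
        raise KeyError(f"unknown loci: {missing}")
    rng = np.random.default_rng([int(config.seed), 0xA1])
    sub = beta.loc[loci]
    percent = sub.to_numpy() * 100.0
    if config.pyro_noise_sd > 0:
        percent = percent + rng.normal(0.0, config.pyro_noise_sd, size=percent.shape)
    percent = np.clip(percent, 0.0, 100.0)
    lo, hi = config.pyro_dropout_range
    for i in range(len(loci)):
        rate = rng.uniform(lo, hi) if hi > lo else lo
        mask = rng.random(percent.shape[1]) < rate
        percent[i, mask] = np.nan
    return pd.DataFrame(percent, index=list(loci), columns=sub.columns)


DetectionPResult = namedtuple("DetectionPResult", ["detp", "failing_probe_ids"])


def generate_detection_pvalues(
    beta: pd.DataFrame, fail_probe_fraction: float, seed: int
) -> DetectionPResult:
    """Per-probe detection p-values with a planted set of failing probes.

    Failing probes receive p >= 0.05 in more than 20% of samples; all other
    calls are confidently detected (p < 0.01).
    """
    if not (0 <= fail_probe_fraction <= 1):
        raise ValueError("fail_probe_fraction must be in [0, 1]")
    rng = np.random.default_rng([int(seed), 0xDE])
    n_probes, n_samples = beta.shape
    n_fail = int(round(fail_probe_fraction * n_probes))
    fail_rows = rng.choice(n_probes, size=n_fail, replace=False)
    detp = rng.uniform(0.0, 0.01, size=(n_probes, n_samples))
    min_fail = int(np.floor(0.20 * n_samples)) + 1  # strictly more than 20%
    for i in fail_rows:
        k = int(rng.integers(min_fail, n_samples + 1))
        cols = rng.choice(n_samples, size=k, replace=False)
        detp[i, cols] = rng.uniform(0.05, 1.0, size=k)
    frame = pd.DataFrame(detp, index=beta.index, columns=beta.columns)
    return DetectionPResult(frame, set(beta.index[fail_rows]))


# Splice-site strength calibration used for simulated evidence: a plausible
# wild-type donor/acceptor score distribution on the maximum-entropy scale.
_CAL = {"donor": (8.0, 1.5), "acceptor": (8.5, 2.0)}


def generate_evidence(
    records: list[SampleRecord], truth: Truth, config: SimConfig
) -> list[VariantEvidence]:
    """Per-variant bioinformatic evidence records for the test variants.

    Truly pathogenic variants tend to receive supportive priors (a damaging
    splice context or a high missense prior); neutral variants receive low
    missense priors.  Priors are evidence, not labels: a minority of
    variants get a prior discordant with their true status.
    """
    rng = np.random.default_rng([int(config.seed), 0xEB])
    variants: dict[str, bool] = {}
    for r in records:
        if r.group == GROUP_TEST and r.variant_id is not None:
            variants.setdefault(r.variant_id, truth.pathogenic[r.sample_id])

    out = []
    for vid in sorted(variants):
        is_path = variants[vid]
        # 70% of priors point the right way; the rest are uninformative/low
        supportive = rng.random() < 0.7
        if is_path and supportive:
            if rng.random() < 0.5:
                # score-reducing donor variant, z-score below -2 -> strong prior
                mean, sd = _CAL["donor"]
                wt = rng.normal(mean, 0.5)
                var = mean - rng.uniform(2.5, 4.0) * sd
                out.append(
                    VariantEvidence(
                        variant_id=vid,
                        missense_prior=0.02,
                        splice_contexts=[
                            SpliceContext("donor", wt, var, mean, sd)
                        ],
                    )
                )
            else:
                out.append(VariantEvidence(variant_id=vid, missense_prior=0.66))
        elif is_path:
            # pathogenic but with a weak/mid-band splice prior
            mean, sd = _CAL["acceptor"]
            wt = rng.normal(mean, 0.5)
            var = mean - rng.uniform(0.2, 1.2) * sd
            out.append(
                VariantEvidence(
                    variant_id=vid,
                    missense_prior=0.02,
                    splice_contexts=[SpliceContext("acceptor", wt, var, mean, sd)],
                )
            )
        else:
            out.append(
                VariantEvidence(
                    variant_id=vid,
                    missense_prior=float(rng.choice([0.02, 0.02, 0.03])),
                )
            )
    return out
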