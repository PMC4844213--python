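"""Multifactorial likelihood classification of variants.

Per-tumor probabilities from the methylation model are converted to
likelihood ratios (LR = p / (1 - p)), combined across independent tumors
by multiplication (tumors from the same individual are first reduced to a
single contribution), and multiplied into the bioinformatic prior odds to
give a posterior probability of pathogenicity, which maps onto the IARC
five-tier classification.  The prior comes from sequence bioinformatics: a
missense conservation-based prior and/or a splicing prior derived from
calibrated maximum-entropy splice-site score z-scores, with the higher
prior taking precedence.  An optional guard demotes classifications whose
combined LR is too close to 1 (between 0.5 and 2.0) back to the uncertain
class, per ENIGMA BRCA classification guidelines.
"""

from __future__ import annotations

from itertools import groupby
from math import exp, log

import numpy as np

from .datatypes import (
    ClassificationResult,
    SampleRecord,
    SpliceContext,
    TumorPrediction,
    VariantEvidence,
)

__all__ = [
    "prob_to_lr",
    "lr_to_prob",
    "combine_lrs",
    "mes_zscore",
    "splicing_prior",
    "combined_prior",
    "posterior",
    "iarc_class",
    "enigma_guard",
    "classify_variants",
    "IARC_BAND_EDGES",
    "SPLICE_PRIOR_RULES",
]


def prob_to_lr(p: float) -> float:
    """Likelihood ratio in favor of pathogenicity from a model probability."""
    if not (0.0 < p < 1.0):
        raise ValueError("probability must lie strictly in (0, 1)")
    return p / (1.0 - p)


def lr_to_prob(lr: float) -> float:
    """Inverse of :func:`prob_to_lr`."""
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    return lr / (1.0 + lr)


def combine_lrs(
    lrs: list[float],
    individuals: list[str] | None = None,
    reducer=None,
) -> float:
    """Combine per-tumor LRs into one per-variant LR.

    Only tumors from different individuals are independent, so LRs are
    multiplied across individuals; several tumors from the same individual
    are reduced to a single contribution by ``reducer`` (default: geometric
    mean — the natural average on the log-odds scale on which LRs
    combine).  With ``individuals`` omitted, every tumor counts as
    independent.
    """
    if not lrs:
        raise ValueError("cannot combine an empty list of likelihood ratios")
    if any(lr <= 0 for lr in lrs):
        raise ValueError("likelihood ratios must be positive")
    if individuals is None:
        individuals = [str(i) for i in range(len(lrs))]
    if len(individuals) != len(lrs):
        raise ValueError("one individual id per likelihood ratio required")
    if reducer is None:
        reducer = lambda vals: exp(sum(log(v) for v in vals) / len(vals))
    pairs = sorted(zip(individuals, lrs), key=lambda t: t[0])
    total = 1.0
    for _, group in groupby(pairs, key=lambda t: t[0]):
        total *= reducer([lr for _, lr in group])
    return total


def mes_zscore(raw: float, calibration_mean: float, calibration_sd: float) -> float:
    """Standardize a raw splice-site strength score against the wild-type
    junction score distribution."""
    if calibration_sd <= 0:
        raise ValueError("calibration sd must be > 0")
    return (raw - calibration_mean) / calibration_sd


# Splicing-prior rules: per site type, (applies when variant reduces score?,
# strong-band predicate, strong prior, mid-band predicate, mid prior).
# Donor/acceptor rules give the probability that a score-reducing variant
# damages the natural splice junction; the de novo donor rule gives the
# probability that a score-increasing variant creates a new donor.
SPLICE_PRIOR_RULES = {
    "donor": {"reduces": True, "strong": (-np.inf, -2.0), "strong_p": 0.97,
              "mid": (-2.0, 0.0), "mid_p": 0.34},
    "acceptor": {"reduces": True, "strong": (-np.inf, -1.5), "strong_p": 0.97,
                 "mid": (-1.5, 0.5), "mid_p": 0.34},
    "de_novo_donor": {"reduces": False, "strong": (0.0, np.inf), "strong_p": 0.64,
                      "mid": (-2.0, 0.0), "mid_p": 0.30},
}


def splicing_prior(ctx: SpliceContext) -> float | None:
    """Prior probability of a splicing effect from a calibrated score z-score.

    Returns None when the variant does not move the score in the damaging
    direction for its site type, or when the z-score falls outside the
    calibrated bands.
    """
    if ctx.site_type not in SPLICE_PRIOR_RULES:
        raise ValueError(f"unknown site_type {ctx.site_type!r}")
    rule = SPLICE_PRIOR_RULES[ctx.site_type]
    if rule["reduces"] and not (ctx.raw_mes_variant < ctx.raw_mes_wt):
        return None
    if not rule["reduces"] and not (ctx.raw_mes_variant > ctx.raw_mes_wt):
        return None
    z = mes_zscore(ctx.raw_mes_variant, ctx.calibration_mean, ctx.calibration_sd)
    if ctx.site_type == "donor":
        if z < -2.0:
            return 0.97
        if -2.0 <= z < 0.0:
            return 0.34
        return None
    if ctx.site_type == "acceptor":
        if z < -1.5:
            return 0.97
        if -1.5 <= z < 0.5:
            return 0.34
        return None
    # de novo donor
    if z > 0.0:
        return 0.64
    if -2.0 <= z <= 0.0:
        return 0.30
    return None


def combined_prior(evidence: VariantEvidence) -> float:
    """Bioinformatic prior for one variant.

    An explicit override takes precedence; otherwise the higher of the
    missense prior and any splicing prior is used.
    """
    if evidence.prior_override is not None:
        return float(evidence.prior_override)
    candidates = []
    if evidence.missense_prior is not None:
        candidates.append(float(evidence.missense_prior))
    for ctx in evidence.splice_contexts:
        sp = splicing_prior(ctx)
        if sp is not None:
            candidates.append(sp)
    if not candidates:
        raise ValueError(
            f"variant {evidence.variant_id}: no applicable prior source"
        )
    return max(candidates)


def posterior(prior: float, lr: float) -> float:
    """Posterior probability of pathogenicity from prior odds times LR."""
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must lie strictly in (0, 1)")
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    odds = prior / (1.0 - prior) * lr
    return odds / (odds + 1.0)


# IARC five-tier class bands on the posterior probability.  Edges follow the
# published interval notation: 0.001, 0.05 and 0.95 belong to the higher
# class; Class 5 requires strictly more than 0.99.
IARC_BAND_EDGES = {
    "class2_min": 0.001,   # inclusive
    "class3_min": 0.05,    # inclusive
    "class4_min": 0.95,    # inclusive
    "class4_max": 0.99,    # inclusive (Class 5 strictly above)
}


def iarc_class(post: float) -> int:
    """Map a posterior probability in (0, 1) onto IARC classes 1-5."""
    if not (0.0 < post < 1.0):
        raise ValueError("posterior must lie strictly in (0, 1)")
    e = IARC_BAND_EDGES
    if post < e["class2_min"]:
        return 1
    if post < e["class3_min"]:
        return 2
    if post < e["class4_min"]:
        return 3
    if post <= e["class4_max"]:
        return 4
    return 5


def enigma_guard(proposed_class: int, combined_lr: float, enabled: bool = True) -> int:
    """Demote confident classes whose combined LR is too close to 1.

    When enabled, Classes 1/2 require combined LR < 0.5 and Classes 4/5
    require combined LR > 2.0; otherwise the variant stays in the
    uncertain Class 3.
    """
    if proposed_class not in (1, 2, 3, 4, 5):
        raise ValueError("proposed class must be 1-5")
    if not enabled or proposed_class == 3:
        return proposed_class
    if proposed_class in (1, 2) and not (combined_lr < 0.5):
        return 3
    if proposed_class in (4, 5) and not (combined_lr > 2.0):
        return 3
    return proposed_class


def _per_individual_lrs(
    lrs: dict[str, float], individual_of: dict[str, str]
) -> dict[str, list[float]]:
    grouped: dict[str, list[float]] = {}
    for sid, lr in lrs.items():
        grouped.setdefault(individual_of.get(sid, sid), []).append(lr)
    return grouped


def classify_variants(
    predictions: list[TumorPrediction],
    records: list[SampleRecord],
    evidence: list[VariantEvidence],
    guard: bool = False,
) -> list[ClassificationResult]:
    """Full classification of every variant with both predictions and evidence.

    Per-tumor probabilities become LRs; tumors of the same individual are
    reduced by geometric mean; independent contributions are multiplied,
    along with any externally supplied LRs in the evidence record (e.g.
    segregation); prior odds times combined LR gives the posterior and the
    IARC class.  When an individual contributed several tumors the result
    also carries the posterior range over single-tumor-per-individual
    choices.
    """
    by_variant: dict[str, list[TumorPrediction]] = {}
    for p in predictions:
        if p.variant_id is not None:
            by_variant.setdefault(p.variant_id, []).append(p)
    individual_of = {r.sample_id: (r.individual_id or r.sample_id) for r in records}
    evidence_by_id = {e.variant_id: e for e in evidence}

    results = []
    for vid in sorted(by_variant):
        if vid not in evidence_by_id:
            continue
        ev = evidence_by_id[vid]
        preds = by_variant[vid]
        probs = {p.sample_id: p.probability for p in preds}
        lrs = {sid: prob_to_lr(pr) for sid, pr in probs.items()}
        individuals = [individual_of.get(sid, sid) for sid in lrs]
        combined = combine_lrs(list(lrs.values()), individuals)
        for extra in ev.extra_lrs:
            combined *= extra
        prior = combined_prior(ev)
        post = posterior(prior, combined)
        proposed = iarc_class(post)
        final = enigma_guard(proposed, combined, enabled=guard)

        # posterior range across single-tumor-per-individual choices
        grouped = _per_individual_lrs(lrs, individual_of)
        post_range = None
        if any(len(v) > 1 for v in grouped.values()):
            lo = np.prod([min(v) for v in grouped.values()])
            hi = np.prod([max(v) for v in grouped.values()])
            extra_prod = float(np.prod(ev.extra_lrs)) if ev.extra_lrs else 1.0
            post_range = (
                posterior(prior, float(lo) * extra_prod),
                posterior(prior, float(hi) * extra_prod),
            )

        results.append(
            ClassificationResult(
                variant_id=vid,
                n_tumors=len(preds),
                n_independent=len(grouped),
                tumor_probabilities=probs,
                tumor_lrs=lrs,
                combined_lr=combined,
                prior=prior,
                posterior=post,
                iarc_class=final,
                guard_applied=(final != proposed),
                posterior_range=post_range,
            )
        )
    return results
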