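"""Consensus clustering of tumors on the selected marker panel.

Samples are repeatedly clustered by k-means (k = 2) on random subsamples of
the cohort; the consensus matrix records how often each pair of samples
co-clusters among the resamples containing both.  The final partition is a
hierarchical (average-linkage) cut of 1 - consensus.  Each cluster is then
labelled by the majority mutation status of its known-status members, and
each test-variant tumor inherits its cluster's label.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .datatypes import (
    ConsensusResult,
    GROUP_PATHOGENIC,
    GROUP_TEST,
    GROUP_WILDTYPE,
    SampleRecord,
)

__all__ = ["consensus_cluster", "call_test_samples"]

_MAX_REDRAWS = 10

BRCA1_LIKE = "BRCA1-like"
BRCAX_LIKE = "BRCAx-like"
AMBIGUOUS = "ambiguous"


def consensus_cluster(
    beta_subset: pd.DataFrame,
    k: int = 2,
    n_resamples: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus k-means clustering of samples (columns of ``beta_subset``).

    Each resample draws ``subsample_fraction`` of the samples without
    replacement, runs k-means (Euclidean distance on beta values, 10
    seeded restarts, best inertia kept) and records co-cluster events.
    A resample producing an empty cluster is redrawn a bounded number of
    times.  With one resample at fraction 1 this reduces to a plain
    k-means assignment.
    """
    if beta_subset.shape[0] < 2:
        raise ValueError("need at least 2 probes to cluster on")
    n = beta_subset.shape[1]
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for k={k}")
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")

    X = beta_subset.T.to_numpy()  # samples x probes
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("degenerate input: all samples identical; no cluster structure")

    rng = np.random.default_rng([int(seed), 0xCC])
    m = max(k, int(round(subsample_fraction * n)))
    co_count = np.zeros((n, n))
    both_count = np.zeros((n, n))

    done = 0
    while done < n_resamples:
        labels = None
        idx = None
        for _ in range(_MAX_REDRAWS):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            km = KMeans(
                n_clusters=k,
                n_init=10,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X[idx])
            if len(np.unique(km.labels_)) == k:
                labels = km.labels_
                break
        if labels is None:
            raise ValueError(
                "degenerate input: k-means could not form k distinct clusters"
            )
        same = labels[:, None] == labels[None, :]
        both_count[np.ix_(idx, idx)] += 1
        co_count[np.ix_(idx, idx)] += same
        done += 1

    with np.errstate(invalid="ignore"):
        consensus = np.where(both_count > 0, co_count / np.maximum(both_count, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(assign)) < k:
        warnings.warn("consensus tree yields fewer than k clusters")

    sample_ids = list(beta_subset.columns)
    return ConsensusResult(
        consensus_matrix=pd.DataFrame(consensus, index=sample_ids, columns=sample_ids),
        assignments=pd.Series(assign, index=sample_ids, name="cluster"),
        cluster_identity={},
    )


def call_test_samples(
    result: ConsensusResult, records: list[SampleRecord]
) -> dict[str, str | None]:
    """Label clusters by known-status majority and call the test tumors.

    Each cluster is labelled BRCA1-like or BRCAx-like by the majority of
    its known-status members; an exact tie makes the cluster ambiguous and
    its test members uncalled.  A cluster containing no known-status sample
    leaves all of its test members uncalled (None).  Fills
    ``result.cluster_identity`` and ``result.test_sample_calls`` and
    returns the per-test-sample calls.
    """
    by_id = {r.sample_id: r for r in records}
    clusters = sorted(result.assignments.unique())
    known_in_any = False
    identity: dict[int, str | None] = {}
    for c in clusters:
        members = result.assignments.index[result.assignments == c]
        n_path = sum(1 for s in members if by_id[s].group == GROUP_PATHOGENIC)
        n_wt = sum(1 for s in members if by_id[s].group == GROUP_WILDTYPE)
        if n_path + n_wt == 0:
            identity[int(c)] = None
        elif n_path > n_wt:
            identity[int(c)] = BRCA1_LIKE
            known_in_any = True
        elif n_wt > n_path:
            identity[int(c)] = BRCAX_LIKE
            known_in_any = True
        else:
            identity[int(c)] = AMBIGUOUS
            known_in_any = True
    if not known_in_any:
        raise ValueError("no cluster contains a known-status sample")

    calls: dict[str, str | None] = {}
    for sid, c in result.assignments.items():
        if by_id[sid].group == GROUP_TEST:
            label = identity[int(c)]
            calls[sid] = label if label in (BRCA1_LIKE, BRCAX_LIKE) else None
    result.cluster_identity = {c: (v if v is not None else "uncalled") for c, v in identity.items()}
    result.test_sample_calls = calls
    return calls
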