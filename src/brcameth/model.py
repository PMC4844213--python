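"""Z-scored multi-marker logistic model of mutation status.

Marker values (beta values or pyrosequencing percentages) are standardized
against reference statistics computed from the known-status training
samples, combined in a maximum-likelihood logistic regression, evaluated by
leave-one-out cross-validation and PPV/NPV, and applied to test-variant
tumors to give each tumor a probability of having arisen on a pathogenic
background.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .datatypes import LogisticModel, TumorPrediction

__all__ = [
    "zscore_transform",
    "fit_logistic",
    "train_model",
    "loocv",
    "ppv_npv",
    "predict_prob",
    "predict_samples",
    "PROB_CLAMP",
]

PROB_CLAMP = 1e-12  # keeps downstream likelihood ratios finite


def zscore_transform(values, ref_mean: float, ref_sd: float):
    """Standardize marker values against stored reference statistics.

    Missing values stay missing.  ``ref_sd`` must be positive.
    """
    if ref_sd <= 0:
        raise ValueError("degenerate marker: reference sd must be > 0")
    return (np.asarray(values, dtype=float) - ref_mean) / ref_sd


def _reference_stats(values: pd.DataFrame) -> tuple[dict[str, float], dict[str, float]]:
    means = {m: float(values[m].mean()) for m in values.columns}
    sds = {m: float(values[m].std(ddof=1)) for m in values.columns}
    return means, sds


def _complete_case_markers(
    values: pd.DataFrame,
    labels: pd.Series,
    min_complete_per_class: int,
) -> tuple[list[str], list[str]]:
    """Greedily drop the most-missing marker until complete cases suffice.

    Mirrors the practical constraint that with per-assay dropout, adding a
    marker can cost more complete cases than it is worth; markers are
    removed in order of missingness until each class retains at least
    ``min_complete_per_class`` complete cases.
    """
    markers = list(values.columns)
    dropped: list[str] = []
    while markers:
        complete = values[markers].notna().all(axis=1)
        y = labels[complete]
        if len(y) and min((y == 1).sum(), (y == 0).sum()) >= min_complete_per_class:
            return markers, dropped
        worst = max(markers, key=lambda m: values[m].isna().sum())
        markers.remove(worst)
        dropped.append(worst)
        warnings.warn(
            f"marker {worst!r} dropped: too few complete cases with it included"
        )
    raise ValueError("no marker subset leaves enough complete cases per class")


def _ml_logit(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum-likelihood logistic fit; ridge-stabilized on separation."""
    X = sm.add_constant(z, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 30):
            raise np.linalg.LinAlgError("divergent fit")
        return float(params[0]), params[1:]
    except Exception:
        warnings.warn("logistic fit unstable (possible perfect separation); "
                      "falling back to a ridge-stabilized fit")
        clf = LogisticRegression(penalty="l2", C=1.0, solver="lbfgs", max_iter=1000)
        clf.fit(z, y)
        return float(clf.intercept_[0]), clf.coef_[0].astype(float)


def fit_logistic(
    values: pd.DataFrame,
    labels: pd.Series,
    ref_means: dict[str, float] | None = None,
    ref_sds: dict[str, float] | None = None,
    min_complete_per_class: int = 5,
) -> LogisticModel:
    """Fit the z-scored logistic model on known-status samples.

    ``values`` is samples x markers on the raw measurement scale (NaN for
    missing); ``labels`` is 1 for pathogenic, 0 for wild-type.  Reference
    means/sds default to the training samples' own statistics and are
    stored in the model so that later samples are standardized against the
    training distribution rather than their own.
    """
    labels = labels.reindex(values.index).astype(float)
    if labels.isna().any():
        values = values.loc[labels.notna()]
        labels = labels.dropna()
    if labels.nunique() < 2:
        raise ValueError("labels are all one class; cannot fit")

    markers, dropped = _complete_case_markers(values, labels, min_complete_per_class)
    complete = values[markers].notna().all(axis=1)
    sub = values.loc[complete, markers]
    y = labels[complete].to_numpy()

    if ref_means is None or ref_sds is None:
        ref_means, ref_sds = _reference_stats(sub)
    for m in markers:
        if ref_sds[m] <= 0:
            raise ValueError(f"degenerate marker {m}: zero reference sd")

    z = np.column_stack(
        [zscore_transform(sub[m], ref_means[m], ref_sds[m]) for m in markers]
    )
    intercept, coefs = _ml_logit(z, y)
    return LogisticModel(
        marker_ids=markers,
        ref_means={m: ref_means[m] for m in markers},
        ref_sds={m: ref_sds[m] for m in markers},
        intercept=intercept,
        coefficients=dict(zip(markers, coefs)),
        training_n=int(len(y)),
        dropped_markers=dropped,
    )


train_model = fit_logistic  # alias: fitting includes the z-score reference


def predict_prob(model: LogisticModel, marker_values) -> float:
    """Probability of pathogenicity for one sample.

    ``marker_values`` maps marker id to raw value; every model marker must
    be present (complete-case prediction).  The probability is clamped away
    from 0 and 1 so that the derived likelihood ratio stays finite.
    """
    eta = model.intercept
    for m in model.marker_ids:
        v = marker_values.get(m) if hasattr(marker_values, "get") else marker_values[m]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise KeyError(f"missing marker {m!r} for prediction")
        z = (float(v) - model.ref_means[m]) / model.ref_sds[m]
        eta += model.coefficients[m] * z
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP))


def predict_samples(
    model: LogisticModel,
    values: pd.DataFrame,
    variant_of: dict[str, str] | None = None,
) -> tuple[list[TumorPrediction], dict[str, str]]:
    """Predict every sample in ``values`` (samples x markers).

    Samples missing any model marker are skipped, with the reason recorded.
    Returns (predictions, skipped) where ``skipped`` maps sample id to the
    reason.
    """
    predictions: list[TumorPrediction] = []
    skipped: dict[str, str] = {}
    for sid, row in values.iterrows():
        missing = [m for m in model.marker_ids if pd.isna(row.get(m, np.nan))]
        if missing:
            skipped[str(sid)] = f"missing markers: {','.join(missing)}"
            continue
        p = predict_prob(model, row)
        predictions.append(
            TumorPrediction(
                sample_id=str(sid),
                variant_id=(variant_of or {}).get(str(sid)),
                probability=p,
                predicted_label=int(p >= 0.5),
            )
        )
    return predictions, skipped


def loocv(
    values: pd.DataFrame,
    labels: pd.Series,
    min_complete_per_class: int = 5,
    refit_reference: bool = True,
) -> tuple[float, pd.Series]:
    """Leave-one-out cross-validation of the z-scored logistic model.

    Each fold refits the model without one complete-case sample and
    predicts it at threshold 0.5.  By default the z-score reference
    statistics are recomputed inside each fold (no information from the
    held-out sample leaks into its standardization); pass
    ``refit_reference=False`` to standardize every fold against the full
    training set instead.  An unfittable fold counts as incorrect.
    Returns (accuracy, held-out probabilities indexed by sample).
    """
    labels = labels.reindex(values.index).astype(float)
    keep = labels.notna()
    values, labels = values.loc[keep], labels[keep]

    markers, _ = _complete_case_markers(values, labels, min_complete_per_class)
    complete = values[markers].notna().all(axis=1)
    sub = values.loc[complete, markers]
    y = labels[complete]

    fixed_ref = None if refit_reference else _reference_stats(sub)

    probs = {}
    correct = 0
    for sid in sub.index:
        train = sub.drop(index=sid)
        try:
            if fixed_ref is None:
                m = fit_logistic(train, y.drop(index=sid),
                                 min_complete_per_class=min(
                                     min_complete_per_class,
                                     int(min((y.drop(index=sid) == 1).sum(),
                                             (y.drop(index=sid) == 0).sum()))))
            else:
                m = fit_logistic(train, y.drop(index=sid),
                                 ref_means=fixed_ref[0], ref_sds=fixed_ref[1],
                                 min_complete_per_class=min_complete_per_class)
            p = predict_prob(m, sub.loc[sid])
        except Exception as exc:  # fold unfittable -> counted incorrect
            warnings.warn(f"LOOCV fold for {sid} unfittable: {exc}")
            probs[sid] = np.nan
            continue
        probs[sid] = p
        if int(p >= 0.5) == int(y[sid]):
            correct += 1
    n = len(sub)
    return correct / n, pd.Series(probs, name="loocv_probability")


def ppv_npv(predicted: pd.Series, truth: pd.Series) -> tuple[float, float]:
    """Positive and negative predictive value of binary predictions.

    Returns NaN for a value whose denominator is empty (no predicted
    positives or no predicted negatives).
    """
    pred = pd.Series(predicted).astype(int)
    tru = pd.Series(truth).reindex(pred.index).astype(int)
    tp = int(((pred == 1) & (tru == 1)).sum())
    fp = int(((pred == 1) & (tru == 0)).sum())
    tn = int(((pred == 0) & (tru == 0)).sum())
    fn = int(((pred == 0) & (tru == 1)).sum())
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    return ppv, npv
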