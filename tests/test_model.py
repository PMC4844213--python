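"""Z-scored logistic prediction model, LOOCV and predictive values."""

import numpy as np
import pandas as pd
import pytest

from brcameth import (
    LogisticModel,
    fit_logistic,
    loocv,
    ppv_npv,
    predict_prob,
    predict_samples,
    zscore_transform,
)
from brcameth.model import PROB_CLAMP

from oracles import newton_raphson_logistic


def _sim_logistic(rng, n=200, beta=(0.3, 1.2, -0.8), scale=10.0):
    """Marker matrix plus labels from a known logistic generative model."""
    z = rng.normal(size=(n, len(beta) - 1))
    eta = beta[0] + z @ np.array(beta[1:])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    # raw values on an arbitrary measurement scale
    values = pd.DataFrame(
        z * scale + 50.0, index=[f"s{i}" for i in range(n)],
        columns=[f"m{j}" for j in range(len(beta) - 1)],
    )
    labels = pd.Series(y, index=values.index)
    return values, labels


# ------------------------------------------------------------- z-scores

def test_zscore_reference_points():
    assert zscore_transform([3.0], 3.0, 2.0)[0] == 0.0
    assert zscore_transform([5.0], 3.0, 2.0)[0] == 1.0
    with pytest.raises(ValueError, match="degenerate marker"):
        zscore_transform([1.0], 0.0, 0.0)


def test_zscore_training_column_standardized(rng):
    x = rng.uniform(20, 80, size=50)
    z = zscore_transform(x, x.mean(), x.std(ddof=1))
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_zscore_preserves_missing():
    z = zscore_transform([1.0, np.nan], 0.0, 1.0)
    assert np.isnan(z[1])


# ------------------------------------------------------------- fitting

def test_fit_matches_newton_raphson_oracle(rng):
    values, labels = _sim_logistic(rng, n=150)
    model = fit_logistic(values, labels)
    z = np.column_stack(
        [
            (values[m] - model.ref_means[m]) / model.ref_sds[m]
            for m in model.marker_ids
        ]
    )
    X = np.column_stack([np.ones(len(z)), z])
    beta_ref, _ = newton_raphson_logistic(X, labels.to_numpy())
    assert model.intercept == pytest.approx(beta_ref[0], abs=1e-6)
    for j, m in enumerate(model.marker_ids):
        assert model.coefficients[m] == pytest.approx(beta_ref[j + 1], abs=1e-6)


def test_null_fit_recovers_class_balance(rng):
    values, _ = _sim_logistic(rng, n=2000)
    labels = pd.Series(
        (rng.random(len(values)) < 0.7).astype(float), index=values.index
    )
    model = fit_logistic(values, labels)
    balance = labels.mean()
    assert model.intercept == pytest.approx(np.log(balance / (1 - balance)), abs=0.15)
    for c in model.coefficients.values():
        assert abs(c) < 0.2


def test_symmetric_single_marker_zero_intercept():
    values = pd.DataFrame({"m": [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]},
                          index=[f"s{i}" for i in range(6)])
    labels = pd.Series([0, 0, 0, 1, 1, 1], index=values.index, dtype=float)
    with pytest.warns(UserWarning, match="ridge"):
        model = fit_logistic(values, labels, min_complete_per_class=3)
    assert model.intercept == pytest.approx(0.0, abs=0.2)


def test_coefficient_recovery_within_two_se(rng):
    values, labels = _sim_logistic(rng, n=400, beta=(0.0, 1.5))
    model = fit_logistic(values, labels)
    z = ((values["m0"] - model.ref_means["m0"]) / model.ref_sds["m0"]).to_numpy()
    X = np.column_stack([np.ones(len(z)), z])
    _, se = newton_raphson_logistic(X, labels.to_numpy())
    assert abs(model.coefficients["m0"] - 1.5) < 2 * se[1]


def test_all_one_class_rejected(rng):
    values, _ = _sim_logistic(rng, n=30)
    labels = pd.Series(1.0, index=values.index)
    with pytest.raises(ValueError, match="one class"):
        fit_logistic(values, labels)


def test_missingness_drives_marker_removal(rng):
    """A marker with heavy dropout is removed so complete cases suffice,
    mirroring marker removal forced by per-assay missing data."""
    values, labels = _sim_logistic(rng, n=40, beta=(0.2, 1.0, -0.5, 0.8))
    values.iloc[:30, 2] = np.nan  # m2 missing for 30/40 samples
    with pytest.warns(UserWarning, match="dropped"):
        model = fit_logistic(values, labels, min_complete_per_class=8)
    assert "m2" in model.dropped_markers
    assert "m2" not in model.marker_ids


# ------------------------------------------------------------- prediction

def test_predict_prob_reference_points():
    model = LogisticModel(
        marker_ids=["m"], ref_means={"m": 10.0}, ref_sds={"m": 2.0},
        intercept=0.0, coefficients={"m": 1.0}, training_n=10,
    )
    assert predict_prob(model, {"m": 10.0}) == pytest.approx(0.5)
    # strictly increasing in a positive-coefficient marker
    probs = [predict_prob(model, {"m": v}) for v in np.linspace(0, 20, 9)]
    assert np.all(np.diff(probs) > 0)
    with pytest.raises(KeyError, match="missing marker"):
        predict_prob(model, {})


def test_predict_prob_clamped():
    model = LogisticModel(
        marker_ids=["m"], ref_means={"m": 0.0}, ref_sds={"m": 1.0},
        intercept=0.0, coefficients={"m": 100.0}, training_n=10,
    )
    assert predict_prob(model, {"m": 10.0}) == 1.0 - PROB_CLAMP
    assert predict_prob(model, {"m": -10.0}) == PROB_CLAMP


def test_predict_samples_skips_incomplete(rng):
    values, labels = _sim_logistic(rng, n=60)
    model = fit_logistic(values, labels)
    values.iloc[0, 0] = np.nan
    preds, skipped = predict_samples(model, values)
    assert len(preds) == 59
    assert "s0" in skipped and "missing markers" in skipped["s0"]


def test_calibration_slope_near_one(rng):
    import statsmodels.api as sm

    train_v, train_l = _sim_logistic(rng, n=600)
    test_v, test_l = _sim_logistic(rng, n=600)
    model = fit_logistic(train_v, train_l)
    preds, _ = predict_samples(model, test_v)
    p = np.array([pr.probability for pr in preds])
    logit_p = np.log(p / (1 - p))
    fit = sm.Logit(test_l.to_numpy(), sm.add_constant(logit_p)).fit(disp=0)
    assert fit.params[1] == pytest.approx(1.0, abs=0.25)


# ------------------------------------------------------------- LOOCV

def test_loocv_perfectly_separated_accuracy_one():
    values = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0, 20.0, 21.0, 22.0, 23.0]},
                          index=[f"s{i}" for i in range(8)])
    labels = pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=values.index, dtype=float)
    with pytest.warns(UserWarning):
        acc, probs = loocv(values, labels, min_complete_per_class=3)
    assert acc == 1.0


def test_loocv_equals_definitional_oracle(rng):
    values, labels = _sim_logistic(rng, n=40, beta=(0.2, 1.0))
    acc, probs = loocv(values, labels, min_complete_per_class=5)
    # literal per-sample exclusion using the same fitter
    for sid in list(values.index)[:8]:
        m = fit_logistic(values.drop(index=sid), labels.drop(index=sid))
        assert probs[sid] == pytest.approx(predict_prob(m, values.loc[sid]),
                                           abs=1e-10)
    manual_acc = np.mean(
        [int(probs[s] >= 0.5) == int(labels[s]) for s in values.index]
    )
    assert acc == pytest.approx(manual_acc)


def test_loocv_null_labels_near_chance(rng):
    values, _ = _sim_logistic(rng, n=60)
    labels = pd.Series(
        rng.permutation([0.0, 1.0] * 30), index=values.index
    )
    acc, _ = loocv(values, labels)
    assert 0.2 <= acc <= 0.8  # no better than chance, generous band


# ------------------------------------------------------------- PPV / NPV

def test_ppv_npv_values():
    pred = pd.Series([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    truth = pd.Series([1, 1, 1, 0, 0, 0, 0, 0, 1, 1])
    ppv, npv = ppv_npv(pred, truth)
    assert ppv == pytest.approx(0.75)
    assert npv == pytest.approx(4 / 6)
    ppv, npv = ppv_npv(pd.Series([1, 1]), pd.Series([1, 1]))
    assert ppv == 1.0 and np.isnan(npv)
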