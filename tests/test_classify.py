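"""Likelihood ratios, priors, posterior odds and IARC classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brcameth import (
    SampleRecord,
    SpliceContext,
    TumorPrediction,
    VariantEvidence,
    classify_variants,
    combine_lrs,
    combined_prior,
    enigma_guard,
    iarc_class,
    lr_to_prob,
    mes_zscore,
    posterior,
    prob_to_lr,
    splicing_prior,
)


# ------------------------------------------------------------- LR basics

def test_prob_to_lr_reference_points():
    assert prob_to_lr(0.5) == pytest.approx(1.0)
    assert prob_to_lr(0.8778) == pytest.approx(7.18, abs=0.005)
    for bad in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            prob_to_lr(bad)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
def test_lr_round_trip(p):
    assert lr_to_prob(prob_to_lr(p)) == pytest.approx(p, rel=1e-12)


def test_combine_lrs_independent_product():
    assert combine_lrs([7.0]) == pytest.approx(7.0)
    assert combine_lrs([19.6, 27.24], ["i1", "i2"]) == pytest.approx(533.904)


def test_combine_lrs_same_individual_geometric_mean():
    assert combine_lrs([4.0, 9.0], ["i1", "i1"]) == pytest.approx(6.0)
    # mixed: geometric mean within individual, product across
    assert combine_lrs([4.0, 9.0, 2.0], ["i1", "i1", "i2"]) == pytest.approx(12.0)
    # alternative within-individual reducer
    assert combine_lrs([4.0, 9.0], ["i1", "i1"], reducer=min) == pytest.approx(4.0)


def test_combine_lrs_order_invariant(rng):
    lrs = list(rng.uniform(0.1, 20.0, size=6))
    inds = ["a", "a", "b", "c", "c", "c"]
    perm = rng.permutation(6)
    assert combine_lrs(lrs, inds) == pytest.approx(
        combine_lrs([lrs[i] for i in perm], [inds[i] for i in perm])
    )


def test_combine_lrs_errors():
    with pytest.raises(ValueError):
        combine_lrs([])
    with pytest.raises(ValueError):
        combine_lrs([1.0, -2.0])


# ------------------------------------------------------------- MES / priors

def test_mes_zscore_reference_and_linearity(rng):
    assert mes_zscore(8.0, 8.0, 1.5) == 0.0
    assert mes_zscore(11.0, 8.0, 1.5) == pytest.approx(2.0)
    raw, mean, sd = 6.2, 8.0, 1.5
    for a in (0.5, 2.0, 7.3):
        assert mes_zscore(a * raw, a * mean, a * sd) == pytest.approx(
            mes_zscore(raw, mean, sd)
        )
    with pytest.raises(ValueError):
        mes_zscore(1.0, 0.0, 0.0)


def _ctx(site, z_variant, reduces=True, mean=8.0, sd=1.0):
    wt = mean + 0.5
    var = mean + z_variant * sd
    if reduces and var >= wt:
        wt = var + 1.0
    if not reduces and var <= wt:
        wt = var - 1.0
    return SpliceContext(site, wt, var, mean, sd)


@pytest.mark.parametrize(
    "site,z,reduces,expected",
    [
        ("donor", -2.5, True, 0.97),
        ("donor", -1.0, True, 0.34),
        ("donor", 0.2, True, None),        # score reduced but z above band
        ("acceptor", -2.0, True, 0.97),
        ("acceptor", -1.0, True, 0.34),
        ("acceptor", 0.4, True, 0.34),     # acceptor mid band extends to 0.5
        ("acceptor", 0.6, True, None),
        ("de_novo_donor", 0.5, False, 0.64),
        ("de_novo_donor", -1.0, False, 0.30),
        ("de_novo_donor", -3.0, False, None),
    ],
)
def test_splicing_prior_bands(site, z, reduces, expected):
    assert splicing_prior(_ctx(site, z, reduces)) == expected


def test_splicing_prior_requires_damaging_direction():
    # donor variant that increases the score: no damage prior
    ctx = SpliceContext("donor", 6.0, 7.0, 8.0, 1.0)
    assert splicing_prior(ctx) is None
    # de novo donor requires an increased score
    ctx = SpliceContext("de_novo_donor", 9.0, 8.5, 8.0, 1.0)
    assert splicing_prior(ctx) is None
    with pytest.raises(ValueError, match="site_type"):
        SpliceContext("branch_point", 8.0, 7.0, 8.0, 1.0)


def test_combined_prior_max_rule_and_override():
    splice = _ctx("donor", -1.0)  # 0.34
    ev = VariantEvidence("v1", missense_prior=0.02, splice_contexts=[splice])
    assert combined_prior(ev) == pytest.approx(0.34)
    assert combined_prior(VariantEvidence("v2", missense_prior=0.02)) == 0.02
    ev3 = VariantEvidence("v3", missense_prior=0.02, prior_override=0.66)
    assert combined_prior(ev3) == 0.66
    # splicing prior inapplicable and no other source -> error
    ctx = SpliceContext("donor", 6.0, 7.0, 8.0, 1.0)
    with pytest.raises(ValueError, match="no applicable prior"):
        combined_prior(VariantEvidence("v4", splice_contexts=[ctx]))


# ------------------------------------------------------------- posterior

def test_posterior_worked_examples():
    assert posterior(0.34, 533.904) == pytest.approx(0.99638, abs=5e-6)
    assert posterior(0.66, 25.218) == pytest.approx(0.97998, abs=5e-6)
    assert posterior(0.5, 1.0) == pytest.approx(0.5)
    for prior in (0.02, 0.34, 0.97):
        assert posterior(prior, 1.0) == pytest.approx(prior)
    with pytest.raises(ValueError):
        posterior(0.0, 2.0)
    with pytest.raises(ValueError):
        posterior(0.5, 0.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.floats(min_value=1e-6, max_value=1 - 1e-6),
    st.floats(min_value=1e-4, max_value=1e4),
    st.floats(min_value=1e-4, max_value=1e4),
)
def test_posterior_sequential_update_equivalence(prior, lr1, lr2):
    joint = posterior(prior, lr1 * lr2)
    stepwise = posterior(posterior(prior, lr1), lr2)
    assert abs(joint - stepwise) < 1e-12


def test_posterior_monotone(rng):
    priors = np.sort(rng.uniform(0.01, 0.99, size=20))
    posts = [posterior(p, 3.0) for p in priors]
    assert np.all(np.diff(posts) > 0)
    lrs = np.sort(rng.uniform(0.01, 100, size=20))
    posts = [posterior(0.3, lr) for lr in lrs]
    assert np.all(np.diff(posts) > 0)


# ------------------------------------------------------------- IARC classes

@pytest.mark.parametrize(
    "post,expected",
    [
        (0.99638, 5), (0.0005, 1), (0.5, 3),
        (0.0009, 1), (0.001, 2), (0.049, 2), (0.05, 3),
        (0.949, 3), (0.95, 4), (0.99, 4), (0.9901, 5),
    ],
)
def test_iarc_class_bands_and_edges(post, expected):
    assert iarc_class(post) == expected


def test_iarc_partition_of_unit_interval():
    grid = np.linspace(1e-9, 1 - 1e-9, 20001)
    classes = np.array([iarc_class(p) for p in grid])
    assert set(classes) == {1, 2, 3, 4, 5}
    assert np.all(np.diff(classes) >= 0)  # monotone single-valued partition


def test_enigma_guard():
    assert enigma_guard(2, 1.1, enabled=True) == 3
    assert enigma_guard(5, 533.9, enabled=True) == 5
    assert enigma_guard(4, 1.43, enabled=True) == 3
    assert enigma_guard(1, 0.2, enabled=True) == 1
    for cls in (1, 2, 3, 4, 5):
        assert enigma_guard(cls, 1.0, enabled=False) == cls


# ------------------------------------------------------------- integration

def test_classify_variants_end_to_end():
    records = [
        SampleRecord("t1", "test", variant_id="vA", individual_id="i1"),
        SampleRecord("t2", "test", variant_id="vA", individual_id="i2"),
        SampleRecord("t3", "test", variant_id="vB", individual_id="i3"),
        SampleRecord("t4", "test", variant_id="vB", individual_id="i3"),
    ]
    preds = [
        TumorPrediction("t1", "vA", lr_to_prob(19.6), 1),
        TumorPrediction("t2", "vA", lr_to_prob(27.24), 1),
        TumorPrediction("t3", "vB", lr_to_prob(4.0), 1),
        TumorPrediction("t4", "vB", lr_to_prob(9.0), 1),
    ]
    evidence = [
        VariantEvidence("vA", prior_override=0.34),
        VariantEvidence("vB", missense_prior=0.02),
    ]
    results = {r.variant_id: r for r in classify_variants(preds, records, evidence)}

    a = results["vA"]
    assert a.n_independent == 2
    assert a.combined_lr == pytest.approx(533.904)
    assert a.posterior == pytest.approx(0.99638, abs=5e-6)
    assert a.iarc_class == 5
    assert a.posterior_range is None

    b = results["vB"]  # same individual twice -> geometric mean, range reported
    assert b.n_independent == 1
    assert b.combined_lr == pytest.approx(6.0)
    assert b.posterior_range == pytest.approx(
        (posterior(0.02, 4.0), posterior(0.02, 9.0))
    )
    # internal consistency of the posterior with prior and combined LR
    odds = b.prior / (1 - b.prior) * b.combined_lr
    assert abs(b.posterior - odds / (1 + odds)) < 1e-9


def test_classify_applies_guard_and_extra_lrs():
    records = [SampleRecord("t1", "test", variant_id="v", individual_id="i1")]
    preds = [TumorPrediction("t1", "v", lr_to_prob(1.4), 1)]
    evidence = [VariantEvidence("v", prior_override=0.97)]
    (res,) = classify_variants(preds, records, evidence, guard=True)
    assert res.iarc_class == 3 and res.guard_applied  # LR 1.4 fails the >2 rule
    (res_off,) = classify_variants(preds, records, evidence, guard=False)
    assert res_off.iarc_class == 4 and not res_off.guard_applied
    # an external segregation LR multiplies into the combined LR
    evidence = [VariantEvidence("v", prior_override=0.97, extra_lrs=[10.0])]
    (res2,) = classify_variants(preds, records, evidence, guard=True)
    assert res2.combined_lr == pytest.approx(14.0)
    assert res2.iarc_class in (4, 5) and not res2.guard_applied
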