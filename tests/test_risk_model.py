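"""Logistic fitting (with independent oracles), odds ratios, AUROC and
quintile calibration."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from ihcdx.risk import (
    PUBLISHED_MODEL,
    LogisticModel,
    adjusted_odds_ratios,
    auroc,
    calibrate_quintiles,
    fit_logistic,
    predict_prob,
)
from ihcdx.synthetic import default_cohort_config, generate_cohort


def _simulate(rng, n, beta=(-2.4, 0.006, 0.005)):
    r1 = rng.normal(180, 55, n)
    r2 = rng.normal(125, 70, n)
    p = expit(beta[0] + beta[1] * r1 + beta[2] * r2)
    y = (rng.random(n) < p).astype(int)
    return r1, r2, y


def test_predict_prob_midpoint():
    model = LogisticModel(0.0, 0.0, 0.0)
    assert predict_prob(model, 150.0, 150.0) == pytest.approx(0.5)


def test_published_model_at_origin():
    expected = math.exp(-2.4106) / (1 + math.exp(-2.4106))
    assert predict_prob(PUBLISHED_MODEL, 0.0, 0.0) == pytest.approx(expected, abs=1e-6)
    assert expected == pytest.approx(0.0824, abs=5e-4)


def test_published_model_at_group_means():
    prob = predict_prob(PUBLISHED_MODEL, 196.1, 145.2)
    direct = math.exp(-2.4106 + 0.00619 * 196.1 + 0.00543 * 145.2)
    assert prob == pytest.approx(direct / (1 + direct), abs=1e-9)
    assert prob == pytest.approx(0.40, abs=0.01)


def test_published_adjusted_odds_ratios():
    aors = adjusted_odds_ratios(PUBLISHED_MODEL).set_index("marker")
    assert round(aors.loc["TGFBR1", "aOR"], 3) == 1.006
    assert round(aors.loc["TGFBR2", "aOR"], 3) == 1.005


def test_zero_coefficient_gives_unit_odds_ratio():
    model = LogisticModel(0.0, 0.0, 0.0, cov=np.eye(3) * 1e-6)
    aors = adjusted_odds_ratios(model)
    assert (aors["aOR"] == 1.0).all()


def test_fit_recovers_known_parameters_within_3_se(rng):
    r1, r2, y = _simulate(rng, 5000)
    model = fit_logistic(r1, r2, y)
    assert model.converged
    truth = np.array([-2.4, 0.006, 0.005])
    se = np.sqrt(np.diag(model.cov))
    assert np.all(np.abs(model.coef - truth) < 3 * se)


def test_fit_matches_direct_likelihood_maximization(rng):
    """IRLS solution vs independent numerical maximization of the
    log-likelihood (Nelder-Mead refinement via BFGS), tolerance 1e-6."""
    r1, r2, y = _simulate(rng, 400)
    model = fit_logistic(r1, r2, y)
    X = np.column_stack([np.ones_like(r1), r1, r2])

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    opt = minimize(nll, x0=np.zeros(3), method="BFGS", options={"gtol": 1e-10})
    assert np.allclose(model.coef, opt.x, atol=1e-6)


def test_fit_matches_statsmodels(rng):
    statsmodels = pytest.importorskip("statsmodels.api")
    r1, r2, y = _simulate(rng, 600)
    model = fit_logistic(r1, r2, y)
    X = np.column_stack([np.ones_like(r1), r1, r2])
    sm_fit = statsmodels.Logit(y, X).fit(disp=0)
    assert np.allclose(model.coef, sm_fit.params, atol=1e-6)
    assert np.allclose(np.sqrt(np.diag(model.cov)), sm_fit.bse, rtol=1e-4)


def test_fit_constant_outcome_rejected():
    with pytest.raises(ValueError):
        fit_logistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 1, 1])


def test_fit_rank_deficient_design_rejected():
    r1 = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        fit_logistic(r1, 2 * r1, [0, 1, 0, 1])


def test_fit_flags_perfect_separation():
    r1 = np.array([10.0, 20.0, 30.0, 200.0, 210.0, 220.0])
    r2 = np.array([40.0, 12.0, 33.0, 190.0, 260.0, 205.0])
    y = np.array([0, 0, 0, 1, 1, 1])
    model = fit_logistic(r1, r2, y)
    assert not model.converged
    assert model.note
    with pytest.raises(ValueError):
        adjusted_odds_ratios(model)


def test_wald_ci_coverage_of_slope(rng):
    """Nominal 95% coverage of the beta1 Wald interval over repeated fits
    (60 reps at n = 600; binomial 3-sigma band)."""
    hits = 0
    reps = 60
    for _ in range(reps):
        r1, r2, y = _simulate(rng, 600)
        model = fit_logistic(r1, r2, y)
        se = math.sqrt(model.cov[1, 1])
        if abs(model.beta1 - 0.006) < 1.96 * se:
            hits += 1
    coverage = hits / reps
    assert abs(coverage - 0.95) < 3 * math.sqrt(0.95 * 0.05 / reps)


def test_auroc_perfect_and_tied():
    labels = ["CIRRHOSIS"] * 3 + ["HCC"] * 3
    assert auroc([4.0, 5.0, 6.0, 1.0, 2.0, 3.0], labels) == 1.0
    assert auroc([2.0] * 6, labels) == 0.5


def test_auroc_requires_both_classes():
    with pytest.raises(ValueError):
        auroc([1.0, 2.0], ["HCC", "HCC"])


def test_auroc_equals_pairwise_oracle(rng):
    """O(n^2) oracle: count of event>non-event pairs with half credit for
    ties, over all pairs."""
    n = 200
    scores = np.round(rng.uniform(0, 10, n), 1)  # coarse grid forces ties
    labels = np.where(rng.random(n) < 0.4, "CIRRHOSIS", "HCC")
    ev = scores[labels == "CIRRHOSIS"]
    ne = scores[labels == "HCC"]
    wins = sum((e > x) + 0.5 * (e == x) for e in ev for x in ne)
    assert auroc(scores, labels) == pytest.approx(wins / (len(ev) * len(ne)))


def test_auroc_monotone_transform_invariance(rng):
    scores = rng.normal(0, 1, 300)
    labels = np.where(rng.random(300) < 0.5, "CIRRHOSIS", "HCC")
    assert auroc(scores, labels) == pytest.approx(auroc(expit(scores), labels))


def test_calibration_well_specified_simulation(rng):
    """When predictions equal the true event rates, the quintile line is
    near-identity at large n."""
    n = 50_000
    probs = rng.uniform(0.05, 0.95, n)
    labels = np.where(rng.random(n) < probs, "CIRRHOSIS", "HCC")
    cal = calibrate_quintiles(probs, labels)
    assert cal.slope == pytest.approx(1.0, abs=0.05)
    assert cal.intercept == pytest.approx(0.0, abs=0.03)
    assert (cal.table["n"].max() - cal.table["n"].min()) <= 1


def test_calibration_constant_predictions_degenerate():
    cal = calibrate_quintiles([0.4] * 10, ["HCC"] * 5 + ["CIRRHOSIS"] * 5)
    assert math.isnan(cal.slope)


def test_calibration_exact_line_gives_r2_one():
    # five distinct prediction levels whose observed rates match exactly
    probs = np.repeat([0.0, 0.25, 0.5, 0.75, 1.0], 4)
    labels = np.concatenate(
        [
            ["HCC"] * 4,
            ["CIRRHOSIS", "HCC", "HCC", "HCC"],
            ["CIRRHOSIS", "CIRRHOSIS", "HCC", "HCC"],
            ["CIRRHOSIS", "CIRRHOSIS", "CIRRHOSIS", "HCC"],
            ["CIRRHOSIS"] * 4,
        ]
    )
    cal = calibrate_quintiles(probs, labels)
    assert cal.slope == pytest.approx(1.0)
    assert cal.intercept == pytest.approx(0.0, abs=1e-12)
    assert cal.r_squared == pytest.approx(1.0)


def test_calibration_requires_five_samples():
    with pytest.raises(ValueError):
        calibrate_quintiles([0.5] * 4, ["HCC"] * 4)


def test_model_json_round_trip(tmp_path):
    path = tmp_path / "model.json"
    model = LogisticModel(-2.0, 0.01, 0.02, cov=np.eye(3) * 0.1, converged=True, n_iter=7)
    model.to_json(path)
    back = LogisticModel.from_json(path)
    assert back.coef == pytest.approx(model.coef)
    assert np.allclose(back.cov, model.cov)


def test_published_model_separates_simulated_cohorts():
    """Sanity: under the reported group normals the published risk score
    ranks cirrhosis above HCC clearly better than chance."""
    cfg = default_cohort_config(seed=55)
    for key, g in list(cfg.groups.items()):
        cfg.groups[key] = type(g)(g.label, 4000, g.mean, g.sd)
    wide = generate_cohort(cfg).pivot_table(
        index=["patient_id", "region"], columns="marker", values="h_score"
    ).reset_index()
    probs = predict_prob(PUBLISHED_MODEL, wide["TGFBR1"], wide["TGFBR2"])
    value = auroc(probs, wide["region"].to_numpy())
    assert 0.60 < value < 0.72
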