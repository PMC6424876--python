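"""PACE aggregation (gEUp, sigmoid, MLE) and the LKB benchmark."""

import numpy as np
import pytest
from scipy.stats import norm

from pace import (
    DoseMap,
    GridSpec,
    LKBModel,
    PaceModel,
    fit_lkb,
    fit_pace,
    geud,
    geup,
    lkb_probability,
    pace_loglik,
    pace_probability,
    wilks_profile_ci,
)
from pace.lkb import geud_batch
from pace.model import geup_batch


# ---------------------------------------------------------------------------
# gEUp (Eq. 3 analogue)
# ---------------------------------------------------------------------------

def test_geup_hand_example():
    # ((1*0.04^2 + 3*0.36^2)/4)^0.5 = sqrt(0.0976)
    val = geup(np.array([0.04, 0.36]), np.array([1.0, 3.0]), nu=0.5)
    assert val == pytest.approx(np.sqrt(0.0976), rel=1e-10)


def test_geup_uniform_probability_fixed_point():
    p = np.full(10, 0.37)
    w = np.linspace(0.1, 5.0, 10)
    for nu in (0.05, 0.5, 1.0):
        assert geup(p, w, nu) == pytest.approx(0.37, rel=1e-9)


def test_geup_nu_one_is_weighted_mean(rng):
    p = rng.uniform(0, 1, 20)
    w = rng.uniform(0, 2, 20)
    w[3] = 0.0
    assert geup(p, w, 1.0) == pytest.approx(np.average(p, weights=w), rel=1e-10)


def test_geup_invariant_under_w_rescaling(rng):
    p = rng.uniform(0, 1, 15)
    w = rng.uniform(0.1, 2, 15)
    for c in (1e-6, 3.7, 1e6):
        assert geup(p, c * w, 0.23) == pytest.approx(geup(p, w, 0.23), rel=1e-9)


def test_geup_bounded_by_p_range_and_small_nu_limit(rng):
    p = rng.uniform(0.1, 0.9, 30)
    w = rng.uniform(0.5, 1.5, 30)
    sel = w > 0
    for nu in (0.05, 0.3, 1.0):
        g = geup(p, w, nu)
        assert p[sel].min() - 1e-12 <= g <= p[sel].max() + 1e-12
    # one high-probability voxel dominates as nu decreases
    p2 = np.full(30, 0.1)
    p2[7] = 0.9
    vals = [geup(p2, w, nu) for nu in (1.0, 0.5, 0.2, 0.05)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_geup_rejects_zero_total_weight():
    with pytest.raises(ValueError, match="zero"):
        geup(np.array([0.5, 0.5]), np.zeros(2), 0.5)


# ---------------------------------------------------------------------------
# Sigmoids
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fn,loc_kw", [(pace_probability, 0.5), (lkb_probability, 30.0)])
def test_sigmoid_midpoint_and_phi1(fn, loc_kw):
    slope = 0.35
    assert fn(loc_kw, slope, loc_kw) == pytest.approx(0.5, abs=1e-12)
    assert fn(loc_kw * (1 + slope), slope, loc_kw) == pytest.approx(
        norm.cdf(1.0), rel=1e-10
    )


def test_sigmoids_strictly_increasing():
    g = np.linspace(0.01, 0.99, 50)
    out = pace_probability(g, 0.4, 0.5)
    assert np.all(np.diff(out) > 0)
    d = np.linspace(1.0, 80.0, 50)
    assert np.all(np.diff(lkb_probability(d, 0.25, 36.0)) > 0)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def test_pace_loglik_hand_summed():
    # 3 patients, single voxel each: gEUp equals that voxel's P
    p_maps = np.array([[0.2], [0.5], [0.8]])
    w_maps = np.ones((3, 1))
    y = np.array([0, 1, 1])
    mu, tp50 = 0.4, 0.5
    pis = [pace_probability(p, mu, tp50) for p in (0.2, 0.5, 0.8)]
    hand = np.log(1 - pis[0]) + np.log(pis[1]) + np.log(pis[2])
    got = pace_loglik((1.0, mu, tp50), p_maps, w_maps, y)
    assert got == pytest.approx(hand, rel=1e-10)


def test_loglik_all_half_is_minus_n_log2():
    p_maps = np.full((8, 4), 0.5)
    w_maps = np.ones((8, 4))
    y = np.array([0, 1] * 4)
    got = pace_loglik((1.0, 0.4, 0.5), p_maps, w_maps, y)
    assert got == pytest.approx(-8 * np.log(2), rel=1e-10)


def test_fallback_probability_used_for_zero_w_patients():
    p_maps = np.array([[0.3], [0.7], [0.5]])
    w_maps = np.array([[1.0], [1.0], [0.0]])  # patient 2 undefined
    y = np.array([0, 1, 1])
    got = pace_loglik((1.0, 0.4, 0.5), p_maps, w_maps, y, fallback_probability=0.25)
    base = pace_loglik((1.0, 0.4, 0.5), p_maps[:2], w_maps[:2], y[:2])
    assert got == pytest.approx(base + np.log(0.25), rel=1e-9)


# ---------------------------------------------------------------------------
# gEUD / LKB
# ---------------------------------------------------------------------------

def test_geud_hand_example():
    # ((4^2 + 16^2)/2)^0.5 = sqrt(136)
    assert geud(np.array([4.0, 16.0]), 0.5) == pytest.approx(np.sqrt(136.0), rel=1e-12)


def test_geud_identities(rng):
    d = rng.uniform(0.1, 3.0, 40)
    assert geud(d, 1.0) == pytest.approx(d.mean(), rel=1e-12)
    assert geud(np.full(10, 1.7), 0.3) == pytest.approx(1.7, rel=1e-10)
    for n in (0.05, 0.3, 1.0):
        assert d.min() - 1e-12 <= geud(d, n) <= d.max() + 1e-12
    with pytest.raises(ValueError):
        geud(d, 0.0)


def test_geud_constant_on_identical_dvh_family(rng):
    """After DVH equalization gEUD is the same number for every map, any n."""
    from pace import equalize_dvh, generate_dose_maps

    grid = GridSpec((12, 12))
    maps = equalize_dvh(generate_dose_maps(grid, 6, rng))
    for n in (0.05, 0.2, 1.0):
        vals = geud_batch(np.stack([m.roi_values() for m in maps]), n)
        assert np.allclose(vals, vals[0], rtol=1e-12)


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

def _pace_training_set(n, seed, m=60, nu=0.1, mu=0.35, tp50=0.5):
    """Outcomes sampled from a PACE model with known true backbone maps."""
    r = np.random.default_rng(seed)
    p_maps = r.uniform(0.01, 0.99, size=(n, m))
    w_maps = r.uniform(0.5, 1.5, size=(n, m))
    g = geup_batch(p_maps, w_maps, nu)
    pi = pace_probability(g, mu, tp50)
    y = (r.uniform(size=n) < pi).astype(int)
    return p_maps, w_maps, y


def test_fit_pace_duplicated_cohort_doubles_loglik():
    p, w, y = _pace_training_set(150, seed=3)
    fit1 = fit_pace(p, w, y, compute_ci=False)
    fit2 = fit_pace(
        np.vstack([p, p]), np.vstack([w, w]), np.concatenate([y, y]),
        compute_ci=False,
    )
    assert fit2.nu == pytest.approx(fit1.nu, rel=1e-3)
    assert fit2.tp50 == pytest.approx(fit1.tp50, rel=1e-3)
    assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-4)


def test_fit_pace_beats_prevalence_baseline():
    p, w, y = _pace_training_set(200, seed=4)
    fit = fit_pace(p, w, y, compute_ci=False)
    prev = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    base = y.sum() * np.log(prev) + (len(y) - y.sum()) * np.log(1 - prev)
    assert fit.loglik >= base - 1e-6


def test_fit_lkb_duplicated_cohort_doubles_loglik(rng):
    doses = rng.uniform(0.5, 3.0, size=(120, 50))
    g = geud_batch(doses, 0.2)
    pi = lkb_probability(g, 0.3, float(np.median(g)))
    y = (rng.uniform(size=120) < pi).astype(int)
    fit1 = fit_lkb(doses, y, compute_ci=False)
    fit2 = fit_lkb(np.vstack([doses, doses]), np.tile(y, 2), compute_ci=False)
    assert fit2.n == pytest.approx(fit1.n, rel=1e-3)
    assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-4)


# ---------------------------------------------------------------------------
# Wilks profile intervals
# ---------------------------------------------------------------------------

def test_profile_ci_matches_quadratic_likelihood_oracle():
    """For a Gaussian (quadratic) profile the Wilks interval is theta +- 1.96 SE."""
    theta0, se = 2.0, 0.3

    def profile_nll(v):
        return 0.5 * ((v - theta0) / se) ** 2

    (lo, hi), flags = wilks_profile_ci(profile_nll, theta0, 0.0, (0.0, 10.0))
    assert lo == pytest.approx(theta0 - 1.959964 * se, rel=1e-2)
    assert hi == pytest.approx(theta0 + 1.959964 * se, rel=1e-2)
    assert flags == (False, False)


def test_profile_ci_widens_with_level():
    def profile_nll(v):
        return 0.5 * ((v - 1.0) / 0.2) ** 2

    (lo1, hi1), _ = wilks_profile_ci(profile_nll, 1.0, 0.0, (0.0, 5.0), level=0.90)
    (lo2, hi2), _ = wilks_profile_ci(profile_nll, 1.0, 0.0, (0.0, 5.0), level=0.99)
    assert lo2 < lo1 < hi1 < hi2


def test_profile_ci_flat_profile_hits_bounds_with_flags():
    (lo, hi), flags = wilks_profile_ci(lambda v: 0.0, 0.5, 0.0, (0.1, 0.9))
    assert (lo, hi) == (0.1, 0.9)
    assert flags == (True, True)


# ---------------------------------------------------------------------------
# End-to-end prediction composition
# ---------------------------------------------------------------------------

def test_predict_composes_the_three_stages(small_s2g_cohort):
    cohort = small_s2g_cohort
    doses = cohort.dose_matrix()
    model = PaceModel.fit(doses, cohort.outcomes, grid=cohort.grid)
    test_map = cohort.dose_maps[0]
    direct = model.predict(test_map)
    # manual chaining: backbone maps -> gEUp -> sigmoid
    from pace import predict_batch

    p, _, w = predict_batch(model.backbone, test_map.roi_values()[None, :])
    g = geup(p[0], w[0], model.params.nu)
    manual = pace_probability(g, model.params.mu, model.params.tp50)
    assert direct == pytest.approx(manual, rel=1e-10)
    # scaling W by a positive constant cannot change the prediction
    g2 = geup(p[0], 17.0 * w[0], model.params.nu)
    assert g2 == pytest.approx(g, rel=1e-9)


def test_prediction_at_tp50_geup_is_half(small_s2g_cohort):
    cohort = small_s2g_cohort
    model = PaceModel.fit(cohort.dose_matrix(), cohort.outcomes, grid=cohort.grid)
    assert pace_probability(model.params.tp50, model.params.mu, model.params.tp50) == pytest.approx(0.5)


def test_lkb_model_predictions_monotone_in_geud(small_s2g_cohort):
    cohort = small_s2g_cohort
    doses = cohort.dose_matrix()
    model = LKBModel.fit(doses, cohort.outcomes)
    g = geud_batch(doses, model.params.n)
    probs = model.predict_batch(doses)
    order = np.argsort(g)
    assert np.all(np.diff(probs[order]) >= -1e-12)
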