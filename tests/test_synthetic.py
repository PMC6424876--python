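"""Synthetic generator: dose maps, DVH equalization, RS maps, g2EUD, labelling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pace import (
    DoseMap,
    GridSpec,
    RSMap,
    S2GParams,
    SimulationConfig,
    choose_threshold,
    equalize_dvh,
    g2eud,
    g2eud_batch,
    generate_dose_map,
    generate_dose_maps,
    label_outcomes,
    make_rs_map,
    simulate_cohort,
)
from pace.lkb import geud
from pace.synthetic import _gaussian_bumps


# ---------------------------------------------------------------------------
# Dose-map generation
# ---------------------------------------------------------------------------

def test_single_central_peak_has_unit_maximum():
    g = GridSpec((17, 17))
    L = g.roi_size
    vals = _gaussian_bumps(g, centers=[[8.0, 8.0]], sigmas=[0.2 * L], heights=[1.0])
    full = g.from_roi(vals)
    assert full[8, 8] == pytest.approx(1.0)
    assert full.max() == pytest.approx(1.0)


def test_two_gaussian_map_matches_per_voxel_loop_oracle(grid16):
    centers = np.array([[3.0, 4.0], [11.0, 9.0]])
    sigmas = np.array([2.5, 4.0])
    heights = np.array([0.7, 1.2])
    vals = grid16.from_roi(_gaussian_bumps(grid16, centers, sigmas, heights))
    # independent brute-force voxel loop
    oracle = np.zeros((16, 16))
    for i in range(16):
        for j in range(16):
            for c, s, h in zip(centers, sigmas, heights):
                d2 = (i - c[0]) ** 2 + (j - c[1]) ** 2
                oracle[i, j] += h * np.exp(-d2 / (2 * s**2))
    assert np.allclose(vals, oracle)
    assert vals.mean() == pytest.approx(oracle.mean())


def test_generated_peaks_respect_parameter_ranges(grid16, rng):
    # heights 0.5-1.5 AU and widths 0.1-0.3 L imply hard bounds on the map
    for _ in range(20):
        dm = generate_dose_map(grid16, rng)
        v = dm.roi_values()
        assert v.min() >= 0
        assert v.max() <= 4 * 1.5  # at most 4 peaks of height 1.5
        assert v.max() >= 0.1  # at least one peak of height >= 0.5 nearby


def test_generation_is_bit_reproducible(grid16):
    a = generate_dose_maps(grid16, 5, np.random.default_rng(7))
    b = generate_dose_maps(grid16, 5, np.random.default_rng(7))
    for x, y in zip(a, b):
        assert np.array_equal(x.values, y.values)


# ---------------------------------------------------------------------------
# DVH equalization
# ---------------------------------------------------------------------------

def test_equalize_dvh_hand_ranks():
    mask = np.array([[True, True, True], [False] * 3, [False] * 3])
    g = GridSpec((3, 3), roi_mask=mask)
    dm = DoseMap(g, g.from_roi(np.array([5.0, 1.0, 3.0]), fill=0.0))
    (out,) = equalize_dvh([dm], d_max=1.0)
    assert np.allclose(out.roi_values(), [1.0, 1 / 3, 2 / 3])


def test_equalized_maps_share_exact_sorted_values_and_order(grid16, rng):
    maps = generate_dose_maps(grid16, 4, rng)
    eq = equalize_dvh(maps, d_max=2.0)
    ref = np.sort(eq[0].roi_values())
    for dm, orig in zip(eq, maps):
        v = dm.roi_values()
        assert np.array_equal(np.sort(v), ref)  # identical DVH, exactly
        # spatial ordering by dose preserved
        assert np.array_equal(np.argsort(v, kind="stable"),
                              np.argsort(orig.roi_values(), kind="stable"))
    # uniform differential DVH on (0, d_max]
    assert ref[0] == pytest.approx(2.0 / grid16.n_roi)
    assert ref[-1] == pytest.approx(2.0)


def test_equalize_uniform_map_is_fixed_point(grid8):
    m = grid8.n_roi
    v = (np.arange(m, dtype=float) + 1) / m
    rng = np.random.default_rng(3)
    v = rng.permutation(v)
    dm = DoseMap(grid8, grid8.from_roi(v))
    (out,) = equalize_dvh([dm], d_max=1.0)
    assert np.allclose(out.roi_values(), v)


def test_equalize_rejects_constant_map(grid8):
    dm = DoseMap(grid8, np.ones(grid8.shape))
    with pytest.raises(ValueError, match="constant"):
        equalize_dvh([dm])


# ---------------------------------------------------------------------------
# RS maps
# ---------------------------------------------------------------------------

def test_homogeneous_rs_is_all_ones(grid8):
    rs = make_rs_map(grid8, "homogeneous")
    assert np.all(rs.roi_values() == 1.0)


def test_s2g_symmetric_under_center_exchange(grid16):
    p = S2GParams(centers=((0.25, 0.25), (0.75, 0.75)), sigma_fracs=(0.1, 0.1))
    rs = make_rs_map(grid16, "s2g", p).weights
    # the point reflection through the grid center swaps the two equal bumps
    assert np.allclose(rs, rs[::-1, ::-1], atol=1e-12)


def test_s2g_matches_direct_two_gaussian_formula(grid8):
    p = S2GParams(centers=((0.2, 0.3), (0.7, 0.6)), sigma_fracs=(0.12, 0.2),
                  amplitudes=(0.8, 1.1))
    rs = make_rs_map(grid8, "s2g", p).weights
    lo, hi = grid8.roi_bbox()
    L = grid8.roi_size
    oracle = np.zeros((8, 8))
    for i in range(8):
        for j in range(8):
            for c, s, h in zip(p.centers, p.sigma_fracs, p.amplitudes):
                cx = lo + np.asarray(c) * (hi - lo)
                d2 = (i - cx[0]) ** 2 + (j - cx[1]) ** 2
                oracle[i, j] += h * np.exp(-d2 / (2 * (s * L) ** 2))
    assert np.allclose(rs, oracle)


def test_unknown_rs_kind_errors(grid8):
    with pytest.raises(ValueError, match="kind"):
        make_rs_map(grid8, "striped")


# ---------------------------------------------------------------------------
# g2EUD
# ---------------------------------------------------------------------------

def _tiny(doses, weights):
    mask = np.ones((2, 2), bool)
    mask[1, :] = False
    g = GridSpec((2, 2), roi_mask=mask)
    dm = DoseMap(g, g.from_roi(np.asarray(doses, float), fill=0.0))
    rs = RSMap(g, g.from_roi(np.asarray(weights, float), fill=0.0))
    return dm, rs


def test_g2eud_hand_example():
    dm, rs = _tiny([4.0, 16.0], [1.0, 3.0])
    # ((1*4^2 + 3*16^2)/4)^0.5 = (784/4)^0.5 = sqrt(196) = 14
    assert g2eud(dm, rs, n=0.5) == pytest.approx(np.sqrt(196.0), rel=1e-12)


def test_g2eud_uniform_dose_fixed_point(grid8):
    dm = DoseMap(grid8, np.full(grid8.shape, 2.7))
    rs = make_rs_map(grid8, "s2g")
    for n in (0.05, 0.3, 1.0, 2.0):
        assert g2eud(dm, rs, n) == pytest.approx(2.7, rel=1e-10)


def test_g2eud_with_homogeneous_rs_equals_geud(grid8, rng):
    dm = generate_dose_map(grid8, rng)
    rs = make_rs_map(grid8, "homogeneous")
    for n in (0.05, 0.1, 0.5, 1.0):
        assert g2eud(dm, rs, n) == geud(dm, n)  # exact equality


def test_g2eud_n1_is_rs_weighted_mean(grid8, rng):
    dm = generate_dose_map(grid8, rng)
    rs = make_rs_map(grid8, "s2g")
    d, w = dm.roi_values(), rs.roi_values()
    assert g2eud(dm, rs, 1.0) == pytest.approx(np.average(d, weights=w), rel=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.01, 5.0), min_size=4, max_size=4),
    st.integers(0, 3),
    st.floats(0.05, 2.0),
)
def test_g2eud_monotone_in_each_voxel_dose(doses, bump_idx, n):
    w = np.array([1.0, 0.5, 2.0, 0.1])
    d = np.array(doses)
    base = g2eud_batch(d[None, :], w, n)[0]
    d2 = d.copy()
    d2[bump_idx] += 0.5
    assert g2eud_batch(d2[None, :], w, n)[0] >= base - 1e-12


def test_g2eud_errors():
    dm, rs = _tiny([1.0, 2.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        g2eud(dm, rs, n=0.0)


# ---------------------------------------------------------------------------
# Outcome labelling
# ---------------------------------------------------------------------------

def test_label_outcomes_strict_threshold():
    assert np.array_equal(label_outcomes(np.array([0.2, 0.9]), 0.5), [0, 1])
    assert np.array_equal(label_outcomes(np.full(4, 0.5), 0.5), [0, 0, 0, 0])


def test_choose_threshold_small_case_and_limits():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    th = choose_threshold(g, 0.5)
    assert 2.0 <= th <= 3.0
    assert label_outcomes(g, th).sum() == 2
    th_low = choose_threshold(g, 1e-9)
    assert th_low >= g.max() - 1e-9
    assert label_outcomes(g, th_low).sum() == 0
    with pytest.raises(ValueError):
        choose_threshold(np.ones(5), 0.5)


@pytest.mark.parametrize("rate,n_maps", [(0.25, 1000), (0.18, 98)])
def test_event_rate_matches_target_within_one_count(rate, n_maps, rng):
    g = rng.lognormal(0.0, 0.5, size=n_maps)
    th = choose_threshold(g, rate)
    events = label_outcomes(g, th).sum()
    assert abs(events - rate * n_maps) <= 1.0 + 1e-9


def test_simulate_cohort_is_reproducible_and_consistent():
    cfg = SimulationConfig(grid_shape=(12, 12), n_maps=30, event_rate=0.3)
    a = simulate_cohort(cfg, seed=5)
    b = simulate_cohort(cfg, seed=5)
    assert np.array_equal(a.dose_matrix(), b.dose_matrix())
    assert np.array_equal(a.outcomes, b.outcomes)
    assert np.array_equal(a.outcomes, label_outcomes(a.g2euds, a.threshold))
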