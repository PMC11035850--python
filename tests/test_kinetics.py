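"""Forward-model numerics: convolution kernels, compartment solutions,
frame averaging, and their independent oracles (quadrature, dense search,
stiff ODE integration)."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from ventclear import kinetics as K
from ventclear.tac_io import FrameSchedule, TimeActivityCurve


def test_feng_input_boundaries(feng_params, fine_grid):
    c = K.feng_input(feng_params, fine_grid)
    assert np.all(c[fine_grid <= feng_params.t0] == 0.0)
    # continuous at t0 and decaying to zero at long times
    assert abs(K.feng_input(feng_params, feng_params.t0 + 1e-9)) < 1e-5
    assert K.feng_input(feng_params, 1e4) == pytest.approx(0.0, abs=1e-30)


def test_feng_peak_matches_dense_grid_search(feng_params):
    tg = np.arange(0.0, 5.0, 1e-4)
    c = K.feng_input(feng_params, tg)
    i = int(np.argmax(c))
    # frozen oracle values from the dt=1e-4 grid search over the default input
    assert tg[i] == pytest.approx(0.7935, abs=2e-4)
    assert c[i] == pytest.approx(98.274362, rel=1e-5)


def test_convolve_exp_closed_forms(fine_grid):
    ones = np.ones_like(fine_grid)
    k = 0.018
    out = K.convolve_exp(fine_grid, ones, k)
    np.testing.assert_allclose(out, (1 - np.exp(-k * fine_grid)) / k, rtol=1e-10, atol=1e-12)
    assert out[-1] < 1 / 0.018  # monotone approach to the 55.56 asymptote
    np.testing.assert_allclose(K.convolve_exp(fine_grid, ones, 0.0), fine_grid,
                               rtol=0, atol=1e-10)


def test_convolve_exp_matches_quadrature(fine_grid, feng_curve):
    k = 0.1
    out = K.convolve_exp(fine_grid, feng_curve, k)

    def interp(s):
        return np.interp(s, fine_grid, feng_curve)

    for t_eval in (1.0, 5.0, 30.0, 60.0):
        ref = quad(lambda s: interp(s) * np.exp(-k * (t_eval - s)), 0, t_eval,
                   limit=400)[0]
        i = int(round(t_eval / (fine_grid[1] - fine_grid[0])))
        assert out[i] == pytest.approx(ref, rel=2e-6)


@pytest.mark.parametrize("k", [0.5e-2, 0.99e-2, 1.01e-2, 5e-2])
def test_convolve_exp_accurate_across_series_branch(fine_grid, k):
    # k*dt straddles the series-expansion threshold; both branches must hit
    # the constant-input closed form (1 - e^(-kt)) / k
    out = K.convolve_exp(fine_grid, np.ones_like(fine_grid), k)
    np.testing.assert_allclose(out[1:], (1 - np.exp(-k * fine_grid[1:])) / k,
                               rtol=1e-9)


def test_convolve_exp_rejects_nonuniform_grid():
    with pytest.raises(ValueError, match="uniform"):
        K.convolve_exp(np.array([0.0, 0.1, 0.3]), np.ones(3), 0.1)


def test_frame_average_constant_linear_and_quadrature(fine_grid, feng_curve, schedule):
    np.testing.assert_allclose(
        K.frame_average(fine_grid, np.full_like(fine_grid, 3.7), schedule), 3.7,
        rtol=1e-12)
    # f(t) = t over frame [0, 10] s averages to the 5-s midpoint value
    first = K.frame_average(fine_grid, fine_grid, schedule)[0]
    assert first == pytest.approx(5.0 / 60.0, rel=1e-12)

    avg = K.frame_average(fine_grid, feng_curve, schedule)

    def interp(s):
        return np.interp(s, fine_grid, feng_curve)

    for i in (3, 7, 12, 21):
        a, b = schedule.frames[i][0] / 60.0, schedule.frames[i][1] / 60.0
        ref = quad(interp, a, b, limit=400)[0] / (b - a)
        assert avg[i] == pytest.approx(ref, rel=2e-6)

    with pytest.raises(ValueError, match="outside grid"):
        K.frame_average(fine_grid[:100], feng_curve[:100], schedule)


def test_ventricle_model_limits_and_linearity(fine_grid, feng_curve, schedule):
    zero = K.ventricle_model(fine_grid, feng_curve, feng_curve,
                             K.VentricleParams(0.0, 0.02, 0.0), schedule)
    np.testing.assert_array_equal(zero.activity, 0.0)

    # constant input: frames approach k1_blood / k_clearance = 1/3
    ones = np.ones_like(fine_grid)
    tac = K.ventricle_model(fine_grid, ones, None, K.VentricleParams(0.006, 0.018), schedule)
    expect = 0.006 / 0.018 * (1 - np.exp(-0.018 * 3375 / 60))  # value at last frame centre
    assert tac.activity[-1] == pytest.approx(expect, rel=1e-3)

    # dual model equals the sum of two blood-only evaluations
    c1 = K.convolve_exp(fine_grid, feng_curve, 0.3)
    dual = K.ventricle_model(fine_grid, feng_curve, c1,
                             K.VentricleParams(0.006, 0.018, 0.002), schedule)
    b1 = K.ventricle_model(fine_grid, feng_curve, None,
                           K.VentricleParams(0.006, 0.018), schedule)
    b2 = K.ventricle_model(fine_grid, c1, None,
                           K.VentricleParams(0.002, 0.018), schedule)
    np.testing.assert_allclose(dual.activity, b1.activity + b2.activity,
                               rtol=0, atol=1e-9)

    with pytest.raises(ValueError, match="tissue input"):
        K.ventricle_model(fine_grid, feng_curve, None,
                          K.VentricleParams(0.006, 0.018, 0.001), schedule)


def test_forward_models_superposition_in_input(fine_grid, feng_curve, schedule):
    rng = np.random.default_rng(5)
    other = np.abs(rng.normal(size=feng_curve.shape)).cumsum() / len(feng_curve)
    p = K.VentricleParams(0.006, 0.018)
    mixed = K.ventricle_model(fine_grid, 2.0 * feng_curve + 0.5 * other, None, p, schedule)
    parts = (2.0 * K.ventricle_model(fine_grid, feng_curve, None, p, schedule).activity
             + 0.5 * K.ventricle_model(fine_grid, other, None, p, schedule).activity)
    np.testing.assert_allclose(mixed.activity, parts, rtol=0, atol=1e-9)


def test_ventricle_nonnegative_and_monotone_in_clearance(fine_grid, feng_curve, schedule):
    last_vals = []
    for kc in (0.002, 0.01, 0.02, 0.05, 0.2):
        tac = K.ventricle_model(fine_grid, feng_curve, None,
                                K.VentricleParams(0.006, kc), schedule)
        assert np.all(tac.activity >= 0)
        last_vals.append(tac.activity[-1])
    assert np.all(np.diff(last_vals) <= 1e-15)  # faster clearance never raises the tail


def test_two_tissue_collapses_and_repeated_root(fine_grid, feng_curve, schedule):
    # k3 = k4 = 0 collapses to the one-tissue model
    tac, c1 = K.two_tissue_model(fine_grid, feng_curve,
                                 K.TwoTissueParams(0.3, 0.3, 0.0, 0.0), schedule)
    one = 0.3 * K.convolve_exp(fine_grid, feng_curve, 0.3)
    np.testing.assert_allclose(c1, one, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(tac.activity, K.frame_average(fine_grid, one, schedule),
                               rtol=1e-10, atol=1e-12)

    zero, c1z = K.two_tissue_model(fine_grid, feng_curve,
                                   K.TwoTissueParams(0.0, 0.3, 0.05, 0.03), schedule)
    np.testing.assert_array_equal(zero.activity, 0.0)
    np.testing.assert_array_equal(c1z, 0.0)

    # k3 = 0, k2 = k4: exactly repeated eigenvalue; compare with a tiny split
    rep, c1r = K.two_tissue_model(fine_grid, feng_curve,
                                  K.TwoTissueParams(0.3, 0.1, 0.0, 0.1), schedule)
    near, c1n = K.two_tissue_model(fine_grid, feng_curve,
                                   K.TwoTissueParams(0.3, 0.1, 1e-9, 0.1), schedule)
    np.testing.assert_allclose(rep.activity, near.activity, rtol=1e-5)


@pytest.mark.parametrize("seed", [0, 1])
def test_models_match_rk45_oracle(fine_grid, feng_curve, schedule, seed):
    rng = np.random.default_rng(seed)
    K1, k2, k3, k4 = 10 ** rng.uniform(-1.5, 0.0), *(10 ** rng.uniform(-2.5, -0.3, 3))
    k1b, k1t, kc = 10 ** rng.uniform(-3, -1.5, 3)
    tt = K.TwoTissueParams(K1, k2, k3, k4)
    tot, c1 = K.two_tissue_model(fine_grid, feng_curve, tt, schedule)

    def rhs(s, y):
        cp = np.interp(s, fine_grid, feng_curve)
        return [K1 * cp - (k2 + k3) * y[0] + k4 * y[1], k3 * y[0] - k4 * y[1]]

    sol = solve_ivp(rhs, (0, fine_grid[-1]), [0, 0], method="RK45", rtol=1e-9,
                    atol=1e-12, dense_output=True)
    ref = sol.sol(fine_grid).sum(axis=0)
    # reconstruct the fine-grid total from the same eigen-decomposition
    s_ = k2 + k3 + k4
    sq = np.sqrt(s_ * s_ - 4 * k2 * k4)
    a1, a2 = (s_ - sq) / 2, (s_ + sq) / 2
    totf = (K1 / sq) * ((k4 - a1) * K.convolve_exp(fine_grid, feng_curve, a1)
                        + (a2 - k4) * K.convolve_exp(fine_grid, feng_curve, a2)) \
        + (K1 * k3 / sq) * (K.convolve_exp(fine_grid, feng_curve, a1)
                            - K.convolve_exp(fine_grid, feng_curve, a2))
    assert np.max(np.abs(totf - ref)) / np.max(np.abs(ref)) < 1e-6

    vp = K.VentricleParams(k1b, kc, k1t)
    vent = K.ventricle_model(fine_grid, feng_curve, c1, vp, schedule)

    def rhs_v(s, y):
        return [k1b * np.interp(s, fine_grid, feng_curve)
                + k1t * np.interp(s, fine_grid, c1) - kc * y[0]]

    sol_v = solve_ivp(rhs_v, (0, fine_grid[-1]), [0.0], method="RK45", rtol=1e-9,
                      atol=1e-13, dense_output=True)
    ref_frames = K.frame_average(fine_grid, sol_v.sol(fine_grid)[0], schedule)
    assert np.max(np.abs(vent.activity - ref_frames)) / np.max(np.abs(ref_frames)) < 1e-6


def test_upsample_idif_preserves_frame_means(fine_grid, feng_curve, schedule):
    frames = K.frame_average(fine_grid, feng_curve, schedule)
    tac = TimeActivityCurve(schedule, frames, "idif")
    up = K.upsample_idif(tac, fine_grid)
    back = K.frame_average(fine_grid, up, schedule)
    np.testing.assert_allclose(back, frames, rtol=1e-9, atol=1e-9)
    assert up[0] == 0.0
    # plain midpoint interpolation flattens the peak relative to the corrected form
    plain = K.upsample_idif(tac, fine_grid, mean_correction=False)
    assert plain.max() < up.max()
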