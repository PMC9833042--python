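"""Inverse fits: transition-point A-Ci estimation, Michaelis-Menten K_C,
initial slopes and percent-difference summaries."""

import numpy as np
import pandas as pd
import pytest

import rubiscotherm as rt
from rubiscotherm import DomainError, FitError, GasExchangeCurve, InputError


def _fit_cell(truth, cell, replicate=0):
    curve = rt.generate_aci_curve(truth, cell, replicate)
    kin = truth.kinetics[cell.split(":")[0]]
    return curve, rt.fit_aci_ethier(curve, kin)


@pytest.mark.parametrize("cell", ["10C:10", "10C:30", "30C:10", "30C:30"])
def test_noiseless_round_trip_is_exact(noiseless_truth, cell):
    """Forward-generate with the reference truth, invert, recover exactly."""
    ct = noiseless_truth.cells[cell]
    _, fit = _fit_cell(noiseless_truth, cell)
    assert fit.params.v_cmax == pytest.approx(ct.v_cmax, rel=1e-6)
    assert fit.params.j_max == pytest.approx(ct.j_max, rel=1e-6)
    assert fit.params.g_m == pytest.approx(ct.g_m, rel=1e-6)
    assert fit.gm_rubisco == pytest.approx(fit.gm_rubp, rel=1e-6)
    assert fit.criterion < 1e-8


@pytest.mark.parametrize("cell", ["10C:10", "30C:30"])
def test_transition_brackets_true_crossover(noiseless_truth, cell):
    """The chosen transition C_i separates the truly Rubisco-limited from
    the truly regeneration-limited records of the generating model."""
    ct = noiseless_truth.cells[cell]
    curve, fit = _fit_cell(noiseless_truth, cell)
    p = rt.parameters_from_kinetics(
        noiseless_truth.kinetics[cell.split(":")[0]], ct.t_leaf,
        v_cmax=ct.v_cmax, j_max=ct.j_max, r_d=ct.r_d, g_m=ct.g_m,
    )
    tags = {ci: rt.assimilation_ci(p, ci).limitation for ci in curve.c_i}
    rub = [ci for ci, tag in tags.items() if tag == rt.RUBISCO]
    reg = [ci for ci, tag in tags.items() if tag == rt.RUBP_REGENERATION and ci > max(rub)]
    if reg:
        assert max(rub) <= fit.transition_ci <= min(reg)


def test_estimates_invariant_to_record_order(noiseless_truth):
    curve, fit = _fit_cell(noiseless_truth, "10C:10")
    rng = np.random.default_rng(9)
    perm = rng.permutation(curve.n_records)
    shuffled = GasExchangeCurve(
        c_a=curve.c_a[perm], c_i=curve.c_i[perm], a_net=curve.a_net[perm],
        g_s=curve.g_s[perm], t_leaf=curve.t_leaf[perm], pressure=curve.pressure[perm],
        r_d=curve.r_d, growth_label=curve.growth_label, meas_label=curve.meas_label,
    )
    refit = rt.fit_aci_ethier(shuffled, noiseless_truth.kinetics["10C"])
    assert refit.params.v_cmax == pytest.approx(fit.params.v_cmax, rel=1e-9)
    assert refit.params.j_max == pytest.approx(fit.params.j_max, rel=1e-9)
    assert refit.params.g_m == pytest.approx(fit.params.g_m, rel=1e-9)


def test_estimates_robust_to_duplicated_records(noiseless_truth):
    """Duplicated steps (the repeated 400 settings) only reweight points;
    on noiseless data the recovered parameters are unchanged."""
    ct = noiseless_truth.cells["10C:10"]
    curve, _ = _fit_cell(noiseless_truth, "10C:10")
    dup = slice(0, 2)
    doubled = GasExchangeCurve(
        c_a=np.concatenate([curve.c_a, curve.c_a[dup]]),
        c_i=np.concatenate([curve.c_i, curve.c_i[dup]]),
        a_net=np.concatenate([curve.a_net, curve.a_net[dup]]),
        g_s=np.concatenate([curve.g_s, curve.g_s[dup]]),
        t_leaf=np.concatenate([curve.t_leaf, curve.t_leaf[dup]]),
        pressure=np.concatenate([curve.pressure, curve.pressure[dup]]),
        r_d=curve.r_d,
    )
    fit = rt.fit_aci_ethier(doubled, noiseless_truth.kinetics["10C"])
    assert fit.params.v_cmax == pytest.approx(ct.v_cmax, rel=1e-6)
    assert fit.params.g_m == pytest.approx(ct.g_m, rel=1e-6)


def test_short_curve_is_rejected():
    with pytest.raises(InputError):
        GasExchangeCurve(
            c_a=[400, 300, 200, 150, 100],
            c_i=[280, 210, 140, 105, 70],
            a_net=[15, 13, 10, 8, 5],
            g_s=[0.2] * 5, t_leaf=[25.0] * 5, pressure=[101.325] * 5,
        )


def test_curve_requires_ci_below_ca_when_assimilating():
    with pytest.raises(InputError):
        GasExchangeCurve(
            c_a=[400, 300, 200, 150, 100, 50],
            c_i=[420, 210, 140, 105, 70, 35],
            a_net=[15, 13, 10, 8, 5, 1],
            g_s=[0.2] * 6, t_leaf=[25.0] * 6, pressure=[101.325] * 6,
        )


def _mm_curve(vmax, kc21, gamma, c_c, r_d=0.0):
    a_net = vmax * (c_c - gamma) / (c_c + kc21) - r_d
    n = len(c_c)
    return GasExchangeCurve(
        c_a=np.asarray(c_c) * 20.0, c_i=np.asarray(c_c) * 10.0, a_net=a_net,
        g_s=np.full(n, 0.2), t_leaf=np.full(n, 27.4),
        pressure=np.full(n, 101.325), r_d=r_d, rubisco_sites=14.4,
    )


def test_mm_fit_noiseless_round_trip():
    """Exact recovery of the in vivo K_C21%O2 and the vmax term."""
    c_c = np.array([3.0, 5.0, 8.0, 12.0, 20.0, 35.0, 60.0, 110.0, 180.0])
    gamma = 1.83
    curve = _mm_curve(108.1, 54.9, gamma, c_c)
    fit = rt.fit_mm_kc21(curve, g_m=1.0, gamma_star=gamma, c_c=c_c)
    assert fit.kc21_apparent == pytest.approx(54.9, rel=1e-6)
    assert fit.vmax_term == pytest.approx(108.1, rel=1e-6)
    assert fit.rmse == pytest.approx(0.0, abs=1e-9)


def test_mm_fit_normalise_by_sites_reports_in_vivo_kcat():
    c_c = np.array([3.0, 5.0, 8.0, 12.0, 20.0, 35.0, 60.0, 110.0, 180.0])
    curve = _mm_curve(47.664, 22.5, 1.8, c_c)  # vmax = 3.31 s-1 x 14.4 sites
    fit = rt.fit_mm_kc21(curve, g_m=1.0, gamma_star=1.8, c_c=c_c,
                         normalise_by_sites=True)
    assert fit.vmax_term == pytest.approx(3.31, rel=1e-6)


def test_mm_fit_degenerate_curve_raises():
    gamma = 10.0
    c_c = np.full(6, gamma)
    curve = _mm_curve(100.0, 50.0, gamma, c_c)
    with pytest.raises(FitError):
        rt.fit_mm_kc21(curve, g_m=1.0, gamma_star=gamma, c_c=c_c)


def test_mm_fit_rejects_nonpositive_cc():
    c_c = np.array([-1.0, 5.0, 8.0, 12.0, 20.0, 35.0])
    curve = _mm_curve(100.0, 50.0, 2.0, np.abs(c_c) + 1)
    with pytest.raises(InputError):
        rt.fit_mm_kc21(curve, g_m=1.0, gamma_star=2.0, c_c=c_c)


def test_mm_fit_recovery_under_noise_is_unbiased():
    """Additive noise of sd 0.2 on A leaves the K_C estimate unbiased
    (|median bias| < 5% over seeded replicates)."""
    c_c = np.array([3.0, 5.0, 8.0, 12.0, 20.0, 35.0, 60.0, 110.0, 180.0, 300.0])
    gamma = 1.83
    rng = np.random.default_rng(1)
    estimates = []
    for _ in range(50):
        curve = _mm_curve(108.1, 54.9, gamma, c_c)
        noisy = GasExchangeCurve(
            c_a=curve.c_a, c_i=curve.c_i,
            a_net=curve.a_net + rng.normal(0.0, 0.2, c_c.size),
            g_s=curve.g_s, t_leaf=curve.t_leaf, pressure=curve.pressure,
            r_d=0.0,
        )
        estimates.append(
            rt.fit_mm_kc21(noisy, g_m=1.0, gamma_star=gamma, c_c=c_c).kc21_apparent
        )
    assert abs(np.median(estimates) / 54.9 - 1.0) < 0.05


def test_initial_slope_exact_on_collinear_points():
    fit = rt.initial_slope([10.0, 20.0, 30.0], [1.0, 2.0, 3.0], c_c_max=50.0)
    assert fit.slope == pytest.approx(0.1, rel=1e-12)
    assert fit.se == pytest.approx(0.0, abs=1e-12)


def test_initial_slope_matches_low_c_chord_of_mm_curve():
    vmax, kc21, gamma = 108.1, 54.9, 0.0
    c_c = np.linspace(0.5, 0.1 * kc21, 8)
    a = vmax * (c_c - gamma) / (c_c + kc21)
    fit = rt.initial_slope(c_c, a, c_c_max=0.1 * kc21)
    # low-C chord of the MM curve: derivative vmax (kc21+gamma)/(c+kc21)^2
    assert abs(fit.slope / (vmax * (kc21 + gamma) / kc21**2) - 1.0) < 0.10


def test_initial_slope_needs_three_points():
    with pytest.raises(InputError):
        rt.initial_slope([10.0, 20.0, 30.0], [1.0, 2.0, 3.0], c_c_max=25.0)


def test_percent_difference_against_hand_arithmetic():
    assert rt.percent_difference(14.4, 8.9, "reduction") == pytest.approx(
        100 * (14.4 - 8.9) / 14.4, rel=1e-15
    )
    assert rt.percent_difference(24.6, 19.8, "excess") == pytest.approx(
        100 * (24.6 - 19.8) / 19.8, rel=1e-15
    )
    assert rt.percent_difference(3.7, 3.7, "reduction") == 0.0
    assert rt.percent_difference(3.7, 3.7, "excess") == 0.0
    with pytest.raises(DomainError):
        rt.percent_difference(0.0, 1.0, "reduction")
    with pytest.raises(DomainError):
        rt.percent_difference(1.0, 0.0, "excess")
    with pytest.raises(InputError):
        rt.percent_difference(1.0, 2.0, "ratio")


def test_summarize_groups_means_and_se():
    df = pd.DataFrame(
        {
            "growth_label": ["10C"] * 3 + ["30C"] * 3,
            "meas_label": ["30"] * 6,
            "v_cmax": [100.0, 110.0, 120.0, 90.0, 100.0, 110.0],
        }
    )
    out = rt.summarize_groups(df, ["v_cmax"])
    cold = out[out.growth_label == "10C"].iloc[0]
    assert cold["n"] == 3
    assert cold["v_cmax_mean"] == pytest.approx(110.0)
    assert cold["v_cmax_se"] == pytest.approx(10.0 / np.sqrt(3))
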