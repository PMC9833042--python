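"""Arrhenius temperature responses, derived constants and unit bridging."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rubiscotherm as rt
from rubiscotherm import DomainError, InputError, TemperatureResponse


@given(
    e_a=st.floats(-100.0, 100.0),
    value_25=st.floats(1e-3, 1e3),
)
def test_arrhenius_identity_at_25(e_a, value_25):
    """The exponent vanishes at the 25 degC anchor for any activation energy."""
    tr = TemperatureResponse(value_25, e_a)
    assert rt.arrhenius_value(tr, 25.0) == pytest.approx(value_25, rel=1e-15)


def test_arrhenius_matches_closed_form():
    # Independent one-line recomputation of the Celsius Arrhenius form.
    tr = TemperatureResponse(11.8, 54.8)
    t = 35.0
    expected = 11.8 * math.exp((t - 25) * 54.8e3 / (298 * 8.314 * (273 + t)))
    got = rt.arrhenius_value(tr, t)
    assert got == pytest.approx(expected, rel=1e-14)
    assert got == pytest.approx(24.197, abs=5e-3)


@pytest.mark.parametrize("e_a,increasing", [(54.8, True), (-23.7, False)])
def test_arrhenius_monotonic_in_temperature(e_a, increasing):
    tr = TemperatureResponse(10.0, e_a)
    grid = rt.arrhenius_value(tr, np.linspace(-10.0, 60.0, 71))
    diffs = np.diff(grid)
    assert np.all(diffs > 0) if increasing else np.all(diffs < 0)


def test_arrhenius_out_of_range_temperature():
    tr = TemperatureResponse(1.0, 50.0)
    with pytest.raises(DomainError):
        rt.arrhenius_value(tr, 75.0)
    with pytest.raises(DomainError):
        rt.arrhenius_value(tr, -20.0)


def test_cold_warm_kc_divergence_at_35(kinetics_table):
    """Cold-grown K_C overtakes warm-grown K_C by ~25-26% at 35 degC."""
    ratio = rt.arrhenius_value(kinetics_table["10C"].k_c, 35.0) / rt.arrhenius_value(
        kinetics_table["30C"].k_c, 35.0
    )
    assert 1.25 <= ratio <= 1.26


@pytest.mark.parametrize("label", ["10C", "20C", "30C"])
@pytest.mark.parametrize("parameter", ["kcat_co2", "s_co", "k_c", "k_o"])
def test_fit_arrhenius_noiseless_round_trip(kinetics_table, label, parameter):
    """Forward-generate from every reference constant, then invert exactly."""
    tr = getattr(kinetics_table[label], parameter)
    temps = np.array([10.0, 15.0, 20.0, 25.0, 30.0, 35.0])
    fit = rt.fit_arrhenius(temps, rt.arrhenius_value(tr, temps))
    assert fit.response.value_25 == pytest.approx(tr.value_25, rel=1e-6)
    assert fit.response.e_a == pytest.approx(tr.e_a, rel=1e-6)
    assert fit.rmse == pytest.approx(0.0, abs=1e-8)


def test_fit_arrhenius_constant_values_gives_zero_ea():
    fit = rt.fit_arrhenius([10.0, 20.0, 30.0, 40.0], [2.5, 2.5, 2.5, 2.5])
    assert fit.response.e_a == pytest.approx(0.0, abs=1e-8)
    assert fit.response.value_25 == pytest.approx(2.5, rel=1e-10)


def test_fit_arrhenius_input_validation():
    with pytest.raises(InputError):
        rt.fit_arrhenius([10.0, 20.0], [1.0, 2.0])
    with pytest.raises(InputError):
        rt.fit_arrhenius([10.0, 10.0, 10.0], [1.0, 1.0, 1.0])
    with pytest.raises(InputError):
        rt.fit_arrhenius([10.0, 20.0, 30.0], [1.0, -2.0, 3.0])


def test_kinetics_at_temperature(kinetics_table):
    at25 = rt.kinetics_at_temperature(kinetics_table["10C"], 25.0)
    assert (at25.kcat_co2, at25.s_co, at25.k_c, at25.k_o) == pytest.approx(
        (3.31, 75.1, 11.8, 275.6)
    )
    at35 = rt.kinetics_at_temperature(kinetics_table["30C"], 35.0)
    assert at35.k_c == pytest.approx(19.36, abs=0.05)
    assert at35.k_c > 0 and at35.k_o > 0


def test_kc_apparent_o2_matches_hand_arithmetic():
    assert rt.kc_apparent_o2(11.8, 275.6, 0.0) == 11.8
    assert rt.kc_apparent_o2(11.8, 275.6, 253.0) == pytest.approx(
        11.8 * (1 + 253.0 / 275.6), rel=1e-15
    )
    assert rt.kc_apparent_o2(11.8, 275.6, 253.0) == pytest.approx(22.63, abs=5e-3)
    assert rt.kc_apparent_o2(11.4, 259.7, 253.0) == pytest.approx(22.51, abs=5e-3)
    with pytest.raises(DomainError):
        rt.kc_apparent_o2(11.8, 0.0, 253.0)


def test_gamma_star_from_sco():
    assert rt.gamma_star_from_sco(78.0, 253.0) == pytest.approx(0.5 * 253 / 78, rel=1e-15)
    assert rt.gamma_star_from_sco(78.0, 253.0) == pytest.approx(1.62, abs=5e-3)
    assert rt.gamma_star_from_sco(123.4, 0.0) == 0.0
    # monotone: higher specificity -> lower compensation point
    assert rt.gamma_star_from_sco(90.0, 253.0) < rt.gamma_star_from_sco(70.0, 253.0)
    with pytest.raises(DomainError):
        rt.gamma_star_from_sco(0.0, 253.0)


def test_dissolved_o2_near_published_value():
    """21% O2 at 1 atm and 25 degC dissolves to roughly 253 uM."""
    o2 = rt.dissolved_concentration(210000.0, 101.325, 25.0, "o2")
    assert abs(o2 - 253.0) / 253.0 < 0.10


def test_dissolved_concentration_linearity_and_bounds():
    assert rt.dissolved_concentration(0.0, 101.325, 20.0, "co2") == 0.0
    one = rt.dissolved_concentration(400.0, 101.325, 20.0, "co2")
    two = rt.dissolved_concentration(800.0, 101.325, 20.0, "co2")
    assert two == pytest.approx(2 * one, rel=1e-12)
    with pytest.raises(DomainError):
        rt.dissolved_concentration(400.0, 101.325, 55.0, "co2")
    with pytest.raises(DomainError):
        rt.dissolved_concentration(400.0, 101.325, 25.0, "n2")


def test_solubility_decreases_with_temperature():
    sol = rt.default_solubility()
    grid = np.linspace(0.0, 40.0, 41)
    for gas in ("co2", "o2"):
        coefs = np.array([sol.coefficient(gas, t) for t in grid])
        assert np.all(np.diff(coefs) < 0)
        assert np.all(coefs > 0)


def test_mole_fraction_dissolved_round_trip():
    conc = rt.dissolved_concentration(400.0, 98.0, 17.3, "co2")
    back = rt.mole_fraction_from_dissolved(conc, 98.0, 17.3, "co2")
    assert back == pytest.approx(400.0, rel=1e-12)


def test_temperature_response_validation():
    with pytest.raises(DomainError):
        TemperatureResponse(-1.0, 50.0)
    with pytest.raises(DomainError):
        TemperatureResponse(1.0, 50.0, se_25=-0.1)
    # negative activation energy is legitimate (specificity factor)
    TemperatureResponse(75.1, -23.7)


def test_rubisco_kinetics_requires_ko_above_kc():
    tr = lambda v: TemperatureResponse(v, 50.0)
    with pytest.raises(DomainError):
        rt.RubiscoKinetics(kcat_co2=tr(3.3), s_co=tr(75.0), k_c=tr(300.0), k_o=tr(11.8))
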