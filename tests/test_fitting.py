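import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utrisim.fitting import (
    BimorphConstants,
    extract_voltage_steps,
    fit_modulus,
    fit_vb,
    linear_fit,
    stage_to_seconds,
    stress_strain,
    vb_area,
)
from utrisim.synth import gen_growth_curve, gen_voltage_trace


# ---------------------------------------------------------------------------
# von Bertalanffy
# ---------------------------------------------------------------------------


def test_vb_area_boundary_values():
    assert vb_area(5.0, A_inf=2.0, r=0.1, t0=5.0) == 0.0
    assert vb_area(1e9, A_inf=2.0, r=0.1, t0=0.0) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        vb_area(1.0, A_inf=1.0, r=-1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    A_inf=st.floats(1e-9, 1e3),
    r=st.floats(1e-8, 10.0),
    t0=st.floats(-10.0, 10.0),
)
def test_vb_area_satisfies_growth_ode(A_inf, r, t0):
    # dA/dt = r*(A_inf - A), checked against the analytic derivative
    t = t0 + np.linspace(0.1, 3.0, 7) / r
    A = vb_area(t, A_inf, r, t0)
    dAdt = A_inf * r * np.exp(-r * (t - t0))
    np.testing.assert_allclose(dAdt, r * (A_inf - A), rtol=1e-9)


def test_initial_slope_is_rate_times_asymptote():
    A_inf, r, t0 = 1.8e-7, 3.6e-6, 0.0
    eps = 1e-3
    slope = (vb_area(t0 + eps, A_inf, r, t0) - vb_area(t0, A_inf, r, t0)) / eps
    assert slope == pytest.approx(r * A_inf, rel=1e-6)


def test_fit_recovers_exact_parameters_from_noiseless_curve():
    t, A, _, truth = gen_growth_curve(noise=0.0)
    fit = fit_vb(t, A)
    assert fit.A_inf == pytest.approx(truth["A_inf"], rel=1e-6)
    assert fit.r == pytest.approx(truth["r"], rel=1e-6)
    assert fit.t0 == pytest.approx(truth["t0"], rel=1e-4)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_fit_parameter_recovery_under_noise():
    # 100 replicates at 1% relative noise on the 8-stage series
    a_errs, r_errs = [], []
    for seed in range(100):
        t, A, _, truth = gen_growth_curve(noise=0.01, seed=seed)
        fit = fit_vb(t, A)
        a_errs.append(fit.A_inf / truth["A_inf"] - 1)
        r_errs.append(fit.r / truth["r"] - 1)
    a_errs = np.array(a_errs)
    r_errs = np.array(r_errs)
    assert abs(a_errs.mean()) < 0.02           # bias below 2%
    assert np.sqrt((a_errs**2).mean()) < 0.05  # RMSE below 5%
    assert np.sqrt((r_errs**2).mean()) < 0.05


def test_fit_input_validation():
    with pytest.raises(ValueError):
        fit_vb([0, 1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        fit_vb([0, 2, 1, 3], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# linear fits
# ---------------------------------------------------------------------------


def test_linear_fit_exact_line():
    x = np.arange(10.0)
    slope, intercept, r2 = linear_fit(x, 2 * x + 1)
    assert (slope, intercept) == (pytest.approx(2.0), pytest.approx(1.0))
    assert r2 == pytest.approx(1.0)


def test_linear_fit_scale_equivariance():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 10, 20)
    y = 3 * x + rng.normal(0, 1, 20)
    s1, i1, r1 = linear_fit(x, y)
    s2, i2, r2 = linear_fit(x, 7.5 * y)
    assert s2 == pytest.approx(7.5 * s1)
    assert i2 == pytest.approx(7.5 * i1)
    assert r2 == pytest.approx(r1)


def test_linear_fit_errors():
    with pytest.raises(ValueError):
        linear_fit([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        linear_fit([1, 2], [1, 2])


# ---------------------------------------------------------------------------
# rheometry
# ---------------------------------------------------------------------------


def test_clean_staircase_amplitudes_recovered_exactly():
    trace, truth = gen_voltage_trace(E=640.0, noise=0.0, n_steps=10, seed=0)
    dv = extract_voltage_steps(trace, 10)
    np.testing.assert_allclose(dv, truth["plateaus"], rtol=1e-9)


def test_flat_trace_yields_zero_steps():
    dv = extract_voltage_steps(np.zeros(20000), n_steps=3)
    np.testing.assert_allclose(dv, 0.0, atol=1e-15)


def test_trace_too_short_rejected():
    with pytest.raises(ValueError):
        extract_voltage_steps(np.zeros(1000), n_steps=5)


def test_noisy_extraction_mean_error_within_two_percent():
    errs = []
    for seed in range(30):
        trace, truth = gen_voltage_trace(E=640.0, noise=0.05, seed=seed)
        dv = extract_voltage_steps(trace, truth["n_steps"])
        errs.append(np.mean(np.abs(dv - truth["plateaus"]) / truth["plateaus"].max()))
    assert np.mean(errs) < 0.02


def test_force_and_tip_displacement_from_printed_constants():
    consts = BimorphConstants()
    series = stress_strain(
        np.array([1.0]), np.array([5e-6]), A0=2e-5, L0=2e-3, constants=consts
    )
    assert series.force[0] == pytest.approx(2.62e-3 * 6.5 / 22, rel=1e-12)
    assert series.tip_displacement[0] == pytest.approx(
        2.62e-3 * 6.5 / 22 / 645, rel=1e-12
    )


def test_zero_voltage_probe_is_pure_base_strain():
    series = stress_strain(np.array([0.0]), np.array([4e-6]), A0=2e-5, L0=2e-3)
    assert series.stress[0] == 0.0
    assert series.strain[0] == pytest.approx(4e-6 / 2e-3)
    assert series.valid[0]


def test_negative_gel_compression_flagged_invalid():
    # voltage implying a tip yield larger than the base displacement
    series = stress_strain(np.array([10.0]), np.array([1e-9]), A0=2e-5, L0=2e-3)
    assert not series.valid[0]
    with pytest.raises(ValueError):
        fit_modulus(series)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(scale=st.floats(0.1, 10.0))
def test_stress_strain_linear_in_voltage(scale):
    dv = np.array([0.2, 0.4, 0.6])
    base = np.array([2e-6, 4e-6, 6e-6])
    a = stress_strain(dv, base, A0=2e-5, L0=2e-3)
    b = stress_strain(scale * dv, base, A0=2e-5, L0=2e-3)
    np.testing.assert_allclose(b.stress, scale * a.stress, rtol=1e-12)
    np.testing.assert_allclose(b.force, scale * a.force, rtol=1e-12)
    np.testing.assert_allclose(b.tip_displacement, scale * a.tip_displacement, rtol=1e-12)


def test_modulus_recovered_from_clean_synthetic_gel():
    trace, truth = gen_voltage_trace(E=640.0, noise=0.0, seed=0)
    dv = extract_voltage_steps(trace, truth["n_steps"])
    series = stress_strain(
        dv, truth["step"] * np.arange(1, truth["n_steps"] + 1),
        truth["A0"], truth["L0"],
    )
    E, sigma0, r2 = fit_modulus(series)
    assert E == pytest.approx(640.0, rel=1e-6)
    assert abs(sigma0) < 1e-8
    assert r2 == pytest.approx(1.0)


def test_modulus_within_five_percent_at_two_percent_noise():
    for seed in range(10):
        trace, truth = gen_voltage_trace(E=640.0, noise=0.02, seed=seed)
        dv = extract_voltage_steps(trace, truth["n_steps"])
        series = stress_strain(
            dv, truth["step"] * np.arange(1, truth["n_steps"] + 1),
            truth["A0"], truth["L0"],
        )
        E, _, r2 = fit_modulus(series)
        assert abs(E / 640.0 - 1) < 0.05
        assert r2 > 0.98


def test_offset_only_gel_has_zero_slope():
    trace, truth = gen_voltage_trace(E=0.0, sigma0=5.0, noise=0.0, seed=0)
    dv = extract_voltage_steps(trace, truth["n_steps"])
    series = stress_strain(
        dv, truth["step"] * np.arange(1, truth["n_steps"] + 1),
        truth["A0"], truth["L0"],
    )
    E, sigma0, _ = fit_modulus(series)
    assert abs(E) < 1e-6
    assert sigma0 == pytest.approx(5.0, rel=1e-9)


# ---------------------------------------------------------------------------
# stage-time mapping
# ---------------------------------------------------------------------------


def test_stage_to_seconds_mapping():
    assert stage_to_seconds("E15.5") == pytest.approx(15.5 * 86400)
    assert stage_to_seconds("P2") == pytest.approx(21.5 * 86400)
    assert stage_to_seconds("P0") == pytest.approx(19.5 * 86400)
    with pytest.raises(ValueError):
        stage_to_seconds("Q3")
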