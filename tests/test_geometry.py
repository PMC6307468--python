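"""Closed-form estimator tests against an independent quadrature oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from cablemorph.geometry import (
    ArcObservation,
    DerivedMorphometrics,
    EllipseSpec,
    HalfEllipseSpec,
    auxiliary_h,
    bulb_area,
    ellipse_perimeter_ramanujan,
    equivalent_spherical_diameter,
    half_ellipse_perimeter,
    perimeter_from_arc,
    ridge_width,
    total_ridge_count,
)


def ellipse_arc_quadrature(a: float, b: float) -> float:
    """Oracle: adaptive quadrature of the elliptic arc-length integrand."""
    e2 = 1.0 - (min(a, b) / max(a, b)) ** 2
    val, _ = quad(lambda t: math.sqrt(1.0 - e2 * math.sin(t) ** 2),
                  0.0, math.pi / 2.0, epsabs=1e-12, epsrel=1e-12)
    return 4.0 * max(a, b) * val


@pytest.mark.parametrize("eps, expected", [
    (1.0, 0.0),
    (0.0, 1.0),
    (0.5, (0.5 / 1.5) ** 2),
])
def test_auxiliary_h_values(eps, expected):
    assert auxiliary_h(eps) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("eps", [-0.1, 1.1, 2.0])
def test_auxiliary_h_domain(eps):
    with pytest.raises(ValueError):
        auxiliary_h(eps)


def test_round_filament_perimeter_is_pi_w():
    """A round cross-section has circumference pi * W exactly."""
    assert ellipse_perimeter_ramanujan(
        EllipseSpec(W=1.0, epsilon=1.0)) == pytest.approx(math.pi, rel=1e-15)


def test_flat_filament_perimeter_is_about_2w():
    """A fully collapsed cross-section approaches the ribbon perimeter 2W."""
    p = ellipse_perimeter_ramanujan(EllipseSpec(W=1.0, epsilon=0.0))
    assert p == pytest.approx(2.0, rel=1e-3)


def test_intermediate_flattening_matches_quadrature():
    p = ellipse_perimeter_ramanujan(EllipseSpec(W=2.0, epsilon=0.5))
    oracle = ellipse_arc_quadrature(1.0, 0.5)
    assert p == pytest.approx(oracle, rel=1e-5)


@settings(derandomize=True, max_examples=60)
@given(eps=st.floats(min_value=0.0, max_value=1.0),
       w=st.floats(min_value=0.1, max_value=1e4))
def test_ramanujan_tracks_true_arc_length(eps, w):
    """Relative error stays below 1e-5 except near the degenerate flat
    limit, where the truncation error peaks at 4e-4 (P = 1.9992 W vs 2W)."""
    p = ellipse_perimeter_ramanujan(EllipseSpec(W=w, epsilon=eps))
    oracle = ellipse_arc_quadrature(w / 2.0, max(eps, 1e-12) * w / 2.0)
    tol = 1e-5 if eps >= 0.2 else 5e-4
    assert p == pytest.approx(oracle, rel=tol)


def test_perimeter_monotone_and_bounded_in_flattening():
    w = 3.0
    eps = np.linspace(0.0, 1.0, 101)
    p = np.array([ellipse_perimeter_ramanujan(EllipseSpec(W=w, epsilon=e))
                  for e in eps])
    assert np.all(np.diff(p) >= 0)
    assert np.all(p >= 2.0 * w * (1.0 - 1e-3))
    assert np.all(p <= math.pi * w * (1.0 + 1e-3))


def test_half_ellipse_semicircle_case_exact():
    """H = W/2 reduces to a semicircle: arc pi*r plus base 2r."""
    assert half_ellipse_perimeter(
        HalfEllipseSpec(W=2.0, H=1.0)) == pytest.approx(math.pi + 2.0,
                                                        rel=1e-15)


def test_half_ellipse_collapsed_ribbon():
    p = half_ellipse_perimeter(HalfEllipseSpec(W=1.0, H=0.0))
    assert p == pytest.approx(2.0, rel=1e-3)


def test_half_ellipse_matches_quadrature_for_deflated_filament():
    """Air-dried thick-filament shape: half-ellipse arc plus flat base."""
    spec = HalfEllipseSpec(W=3.71, H=0.87, unit="um")
    p = half_ellipse_perimeter(spec)
    oracle = 0.5 * ellipse_arc_quadrature(3.71e3 / 2.0, 0.87e3) + 3.71e3
    assert p == pytest.approx(oracle, rel=1e-5)
    assert p == pytest.approx(8.132e3, rel=1e-3)


def test_half_ellipse_rejects_height_over_half_width():
    with pytest.raises(ValueError):
        HalfEllipseSpec(W=1.0, H=0.51)


@pytest.mark.parametrize("n_obs, expected", [(12, 24), (1, 2), (27, 54)])
def test_total_ridge_count_doubles_one_sided_count(n_obs, expected):
    assert total_ridge_count(n_obs) == expected


def test_total_ridge_count_rejects_nonpositive():
    with pytest.raises(ValueError):
        total_ridge_count(0)


@pytest.mark.parametrize("P, N, unit, expected_nm", [
    (12.5, 61, "um", 204.918),   # thick filament: ~205 nm
    (7.3, 52, "um", 140.385),    # extracted filament: ~140 nm
    (42.0, 1, "nm", 42.0),       # identity
])
def test_ridge_width(P, N, unit, expected_nm):
    assert ridge_width(P, N, unit=unit) == pytest.approx(expected_nm, rel=1e-4)


def test_ridge_width_rejects_zero_count():
    with pytest.raises(ValueError):
        ridge_width(1.0, 0)


@pytest.mark.parametrize("P, unit, expected_nm", [
    (math.pi, "nm", 1.0),
    (12.5, "um", 3978.87),
    (7.85, "um", 2498.77),
    (1.56, "um", 496.56),
])
def test_equivalent_spherical_diameter(P, unit, expected_nm):
    d = equivalent_spherical_diameter(P, unit=unit)
    assert d == pytest.approx(expected_nm, rel=1e-4)


@settings(derandomize=True, max_examples=40)
@given(x=st.floats(min_value=1e-3, max_value=1e6))
def test_desd_inverts_multiplication_by_pi(x):
    assert equivalent_spherical_diameter(math.pi * x) == pytest.approx(
        x, rel=1e-12)


@pytest.mark.parametrize("L, theta, expected", [
    (math.pi, math.pi, 2.0 * math.pi),  # half circle of unit radius
    (5.0, 2.0 * math.pi, 5.0),          # full outline unchanged
    (3.125, math.pi / 2.0, 12.5),       # quarter arc: 4x
])
def test_perimeter_from_arc(L, theta, expected):
    p = perimeter_from_arc(ArcObservation(L_arc=L, theta=theta))
    assert p == pytest.approx(expected, rel=1e-12)


@settings(derandomize=True, max_examples=40)
@given(L=st.floats(min_value=1e-3, max_value=1e6),
       theta=st.floats(min_value=1e-3, max_value=2.0 * math.pi))
def test_arc_extrapolation_scale_equivariant(L, theta):
    p1 = perimeter_from_arc(ArcObservation(L_arc=L, theta=theta))
    p2 = perimeter_from_arc(ArcObservation(L_arc=2 * L, theta=theta))
    assert p2 == pytest.approx(2.0 * p1, rel=1e-12)


def test_arc_rejects_bad_angles():
    with pytest.raises(ValueError):
        ArcObservation(L_arc=1.0, theta=0.0)
    with pytest.raises(ValueError):
        ArcObservation(L_arc=1.0, theta=7.0)


@pytest.mark.parametrize("d, expected", [
    (124.0, 12076.28),   # thick-filament bulb: ~12e3 nm^2
    (103.0, 8332.29),    # thin-filament bulb: ~8e3 nm^2
    (0.0, 0.0),
])
def test_bulb_area(d, expected):
    assert bulb_area(d) == pytest.approx(expected, abs=0.5)


def test_bulb_area_rejects_negative():
    with pytest.raises(ValueError):
        bulb_area(-1.0)


def test_unit_tags_convert_consistently():
    assert ridge_width(12.5, 61, unit="um") == pytest.approx(
        ridge_width(12500.0, 61, unit="nm"))
    with pytest.raises(ValueError):
        ridge_width(12.5, 61, unit="furlong")


def test_ellipse_spec_defaults_to_round_with_warning(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="cablemorph.geometry"):
        spec = EllipseSpec(W=1.0)
    assert spec.epsilon == 1.0
    assert any("flattening" in r.message for r in caplog.records)


def test_derived_morphometrics_enforces_internal_consistency():
    DerivedMorphometrics(P=math.pi * 10.0, d_ESD=10.0)
    with pytest.raises(ValueError):
        DerivedMorphometrics(P=10.0, d_ESD=10.0)
    with pytest.raises(ValueError):
        DerivedMorphometrics(P=100.0, N_R=10, delta_R=11.0)
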