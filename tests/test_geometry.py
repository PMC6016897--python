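import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from valvegeom import (
    BoundaryCurve,
    CuspParameters,
    DomainError,
    FitError,
    boundary_height,
    fit_sine_boundary,
    flatten,
    load_boundary_points,
    make_cusp,
    radius_from_width,
    surface_point,
    unflatten,
)
from .conftest import REF_HEIGHT, REF_N_CUSPS, REF_WIDTH

cusp_strategy = st.builds(
    make_cusp,
    st.floats(5.0, 60.0),
    st.floats(2.0, 30.0),
    st.integers(2, 6),
)


@pytest.mark.parametrize(
    "width, n, expected, tol",
    [
        (REF_WIDTH, 3, 9.65, 5e-3),  # reference valve, 3 significant figures
        (2 * math.pi, 2, 2.0, 1e-12),
        (15.0, 3, 7.16197243913529, 1e-12),
    ],
)
def test_radius_from_width(width, n, expected, tol):
    """r = W·n/(2π): one cusp's annulus arc equals its flattened width."""
    r = radius_from_width(width, n)
    assert r == pytest.approx(expected, abs=tol)
    # round trip: arc length of one cusp at radius r is the width again
    assert r * (2 * math.pi / n) == pytest.approx(width, rel=1e-12)


@pytest.mark.parametrize("width, n", [(0.0, 3), (-1.0, 3), (5.0, 1), (5.0, 2.5)])
def test_radius_from_width_rejects_invalid(width, n):
    with pytest.raises(DomainError):
        radius_from_width(width, n)


def test_make_cusp_reference_instance(reference_cusp):
    assert reference_cusp.radius == pytest.approx(9.65, abs=5e-3)
    assert reference_cusp.max_height == REF_HEIGHT
    assert reference_cusp.angular_extent == pytest.approx(2 * math.pi / 3, rel=1e-15)
    assert reference_cusp.wavenumber == pytest.approx(1.5, rel=1e-12)
    assert reference_cusp.width == pytest.approx(REF_WIDTH, rel=1e-12)


def test_make_cusp_four_cusp_instance():
    c = make_cusp(10.0, 5.0, 4)
    assert c.radius == pytest.approx(6.3661977236758134, rel=1e-14)
    assert c.angular_extent == pytest.approx(math.pi / 2, rel=1e-15)
    assert c.wavenumber == 2.0


def test_wavenumber_closure_enforced():
    """k·(2π/n) must equal π: the free edge returns to zero at the far commissure."""
    with pytest.raises(DomainError):
        CuspParameters(radius=9.65, max_height=14.2, n_cusps=3, wavenumber=1.5 * (1 + 1e-4))
    # exactly closed wavenumber is accepted
    CuspParameters(radius=9.65, max_height=14.2, n_cusps=3, wavenumber=1.5)


def test_published_wavenumber_constant_is_rounded_half_n():
    """The published factor 9650π/20211 is n/2 = 1.5 rounded through the width."""
    k_published = 9650 * math.pi / 20211
    assert abs(k_published - 1.5) / 1.5 < 5e-5


@pytest.mark.parametrize("max_height, n", [(-1.0, 3), (5.0, 0)])
def test_make_cusp_rejects_invalid(max_height, n):
    with pytest.raises(DomainError):
        make_cusp(10.0, max_height, n)


def test_boundary_height_pinned_and_peaked(reference_cusp):
    h = reference_cusp.max_height
    ext = reference_cusp.angular_extent
    assert boundary_height(reference_cusp, 0.0) == 0.0
    assert boundary_height(reference_cusp, ext) == pytest.approx(0.0, abs=1e-12 * h)
    assert boundary_height(reference_cusp, ext / 2) == pytest.approx(h, rel=1e-12)
    assert boundary_height(reference_cusp, math.pi / 6) == pytest.approx(10.041, abs=5e-4)
    with pytest.raises(DomainError):
        boundary_height(reference_cusp, ext + 0.1)
    with pytest.raises(DomainError):
        boundary_height(reference_cusp, -0.1)


def test_surface_point_values(reference_cusp):
    r = reference_cusp.radius
    p = surface_point(reference_cusp, 0.0, 0.7)
    assert p == pytest.approx([r, 0.0, 0.0], abs=1e-12)
    peak = surface_point(reference_cusp, math.pi / 3, 1.0)
    assert peak == pytest.approx([r / 2, r * math.sqrt(3) / 2, REF_HEIGHT], rel=1e-12)
    with pytest.raises(DomainError):
        surface_point(reference_cusp, 0.1, 1.5)


def test_flatten_examples(reference_cusp):
    x, z = flatten(reference_cusp, reference_cusp.angular_extent, 0.0)
    assert x == pytest.approx(REF_WIDTH, rel=1e-12)
    assert flatten(reference_cusp, 0.0, 3.0) == (0.0, 3.0)
    x, z = flatten(reference_cusp, math.pi / 3, 7.0)
    assert x == pytest.approx(10.1055, abs=1e-4)  # the fitted peak abscissa W/2
    assert z == 7.0


@settings(derandomize=True, max_examples=50)
@given(cusp=cusp_strategy, frac=st.floats(0.0, 1.0))
def test_arc_length_and_symmetry_properties(cusp, frac):
    """n cusp widths tile the annulus; the free edge is symmetric about the midline."""
    x, _ = flatten(cusp, cusp.angular_extent, 0.0)
    assert x * cusp.n_cusps == pytest.approx(2 * math.pi * cusp.radius, rel=1e-12)
    theta = frac * cusp.angular_extent
    assert boundary_height(cusp, theta) == pytest.approx(
        boundary_height(cusp, cusp.angular_extent - theta), abs=1e-12 * cusp.max_height
    )


@settings(derandomize=True, max_examples=50)
@given(cusp=cusp_strategy, frac=st.floats(0.0, 1.0), zfrac=st.floats(0.0, 1.0))
def test_surface_point_on_cylinder_and_flatten_roundtrip(cusp, frac, zfrac):
    theta = frac * cusp.angular_extent
    p = surface_point(cusp, theta, zfrac)
    assert math.hypot(p[0], p[1]) == pytest.approx(cusp.radius, rel=1e-9)
    x, z = flatten(cusp, theta, p[2])
    theta_back, z_back = unflatten(cusp, x, z)
    assert theta_back == pytest.approx(theta, rel=1e-12, abs=1e-15)
    assert z_back == z


def test_fit_recovers_three_point_instance():
    """The minimal peak-and-endpoints sample determines the sine exactly."""
    fit = fit_sine_boundary([(0.0, 0.0), (10.1055, 1.0), (20.211, 0.0)])
    assert fit.amplitude == pytest.approx(1.0, abs=1e-9)
    assert fit.width == pytest.approx(20.211, abs=1e-9)
    assert fit.residual_rms < 1e-12


def test_fit_recovers_noiseless_samples_free_and_fixed_width():
    x = np.linspace(0.0, REF_WIDTH, 50)
    z = REF_HEIGHT * np.sin(np.pi * x / REF_WIDTH)
    free = fit_sine_boundary(np.column_stack([x, z]))
    assert free.amplitude == pytest.approx(REF_HEIGHT, rel=1e-9)
    assert free.width == pytest.approx(REF_WIDTH, rel=1e-9)
    fixed = fit_sine_boundary(np.column_stack([x, z]), width_fixed=REF_WIDTH)
    assert fixed.amplitude == pytest.approx(REF_HEIGHT, rel=1e-12)
    assert fixed.width_se is None


def test_fit_rejects_degenerate_input():
    with pytest.raises(FitError):
        fit_sine_boundary([(0.0, 0.0), (1.0, 1.0)])  # too few points
    with pytest.raises(FitError):
        fit_sine_boundary([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])  # flat: W unidentifiable


def test_boundary_curve_shape():
    curve = BoundaryCurve(width=20.0, amplitude=5.0)
    assert curve.height_flat(0.0) == pytest.approx(0.0, abs=1e-12)
    assert curve.height_flat(10.0) == pytest.approx(5.0, rel=1e-12)
    x = np.linspace(0.0, 20.0, 11)
    np.testing.assert_allclose(curve.height_flat(x), curve.height_flat(20.0 - x), atol=1e-12)
    cusp = curve.as_cusp(3)
    assert cusp.width == pytest.approx(20.0, rel=1e-12)


def test_load_boundary_points_formats(tmp_path):
    path = tmp_path / "pts.txt"
    path.write_text(
        "# flattened free-edge samples (mm)\n"
        "x_mm, z_mm\n"
        "0.0, 0.0\n"
        "10.1055 1.0\n"
        "20.211,0.0\n"
    )
    pts = load_boundary_points(path)
    np.testing.assert_allclose(pts, [[0, 0], [10.1055, 1], [20.211, 0]])
    bad = tmp_path / "bad.txt"
    bad.write_text("# only comments\n")
    with pytest.raises(FitError):
        load_boundary_points(bad)
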