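"""Parametric geometry of a semilunar valve cusp on a cylindrical shell.

A fully open semilunar cusp is modelled as one n-th of a circular cylinder
of radius ``r`` (the valve annulus), bounded below by the annulus plane
``z = 0`` and above by a sine-shaped free edge.  In the flattened
(developed) plane the free edge is ``z(x) = h·sin(πx/W)`` where ``W`` is
the cusp width (arc length along the annulus between the commissures) and
``h`` the maximum cusp height.  The cylinder development ``x = r·θ`` is an
isometry, so lengths and areas measured on the flattened cusp equal those
on the 3-D surface.

All lengths are in millimetres; angles in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CuspParameters",
    "BoundaryCurve",
    "SineFitResult",
    "radius_from_width",
    "make_cusp",
    "boundary_height",
    "surface_point",
    "flatten",
    "unflatten",
    "fit_sine_boundary",
    "load_boundary_points",
]

#: relative tolerance for the wavenumber closure invariant k·(2π/n) = π
_K_CLOSURE_RTOL = 1e-6


class DomainError(ValueError):
    """An argument lies outside the operation's mathematical domain."""


class FitError(ValueError):
    """Boundary-curve fitting failed or the input is degenerate."""


@dataclass(frozen=True)
class CuspParameters:
    """Complete specification of one cylindrical-shell cusp.

    Parameters
    ----------
    radius : float
        Cylinder (annulus) radius r > 0, mm.
    max_height : float
        Maximum cusp height h > 0, mm; the free edge reaches this at the
        cusp midline.
    n_cusps : int
        Number of identical cusps tiling the annulus (>= 2); a tricuspid
        valve has 3, so each cusp spans one third of the cylinder.
    wavenumber : float, optional
        Factor k multiplying θ inside the free-edge sine.  Defaults to
        n_cusps / 2, the exact value for which the edge returns to zero at
        the far commissure; a caller may pass a rounded published value,
        which must satisfy k·(2π/n) = π to relative 1e-6.
    """

    radius: float
    max_height: float
    n_cusps: int
    wavenumber: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise DomainError(f"radius must be positive, got {self.radius}")
        if not (self.max_height > 0 and math.isfinite(self.max_height)):
            raise DomainError(f"max_height must be positive, got {self.max_height}")
        if int(self.n_cusps) != self.n_cusps or self.n_cusps < 2:
            raise DomainError(f"n_cusps must be an integer >= 2, got {self.n_cusps}")
        object.__setattr__(self, "n_cusps", int(self.n_cusps))
        if math.isnan(self.wavenumber):
            object.__setattr__(self, "wavenumber", self.n_cusps / 2.0)
        closure = self.wavenumber * self.angular_extent
        if abs(closure - math.pi) > _K_CLOSURE_RTOL * math.pi:
            raise DomainError(
                "wavenumber does not close the free edge at the far commissure: "
                f"k·(2π/n) = {closure!r}, expected π to relative {_K_CLOSURE_RTOL:g}"
            )

    @property
    def angular_extent(self) -> float:
        """Angular span 2π/n of one cusp, radians."""
        return 2.0 * math.pi / self.n_cusps

    @property
    def width(self) -> float:
        """Flattened cusp width W = r·(2π/n), mm (annulus arc length)."""
        return self.radius * self.angular_extent


@dataclass(frozen=True)
class BoundaryCurve:
    """Sine free edge of a cusp, in flattened and angular coordinates.

    The flattened form is ``z(x) = amplitude·sin(πx/width)`` on
    ``x ∈ [0, width]``; through the development ``x = r·θ`` the same curve
    reads ``z(θ) = amplitude·sin(π·r·θ/width)``.
    """

    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and math.isfinite(self.width)):
            raise DomainError(f"width must be positive, got {self.width}")
        if not (self.amplitude >= 0 and math.isfinite(self.amplitude)):
            raise DomainError(f"amplitude must be nonnegative, got {self.amplitude}")

    def height_flat(self, x):
        """Edge height z(x) over the flattened coordinate x ∈ [0, W], mm."""
        x = np.asarray(x, dtype=float)
        _check_range(x, 0.0, self.width, "x")
        out = self.amplitude * np.sin(np.pi * x / self.width)
        return float(out) if out.ndim == 0 else out

    def height_angular(self, theta, radius: float):
        """Edge height z(θ) for a cusp of the given annulus radius, mm."""
        theta = np.asarray(theta, dtype=float)
        return self.height_flat(radius * theta)

    def as_cusp(self, n_cusps: int) -> CuspParameters:
        """Cusp whose free edge is this curve (amplitude must be > 0)."""
        return make_cusp(self.width, self.amplitude, n_cusps)


@dataclass(frozen=True)
class SineFitResult:
    """Least-squares sine-edge fit with basic diagnostics.

    ``amplitude_se``/``width_se`` are standard errors from the residual
    variance and the Jacobian at the optimum (``width_se`` is None when the
    width was held fixed); ``residual_rms`` is in mm.
    """

    curve: BoundaryCurve
    residual_rms: float
    n_points: int
    amplitude_se: float
    width_se: float | None

    @property
    def amplitude(self) -> float:
        return self.curve.amplitude

    @property
    def width(self) -> float:
        return self.curve.width


def _check_range(value: np.ndarray, lo: float, hi: float, name: str) -> None:
    # tolerate float round-off at interval endpoints
    tol = 1e-9 * max(abs(lo), abs(hi), 1.0)
    if np.any(value < lo - tol) or np.any(value > hi + tol):
        raise DomainError(f"{name} outside [{lo:g}, {hi:g}]")


def radius_from_width(width: float, n_cusps: int) -> float:
    """Annulus radius from the cusp width via the arc-length relation x = rθ.

    One cusp subtends 2π/n, so its arc length (= flattened width W) is
    r·2π/n and r = W·n/(2π).  For the reference human pulmonary valve
    (W = 20.211 mm, n = 3) this gives r ≈ 9.65 mm.
    """
    if not (width > 0 and math.isfinite(width)):
        raise DomainError(f"width must be positive, got {width}")
    if int(n_cusps) != n_cusps or n_cusps < 2:
        raise DomainError(f"n_cusps must be an integer >= 2, got {n_cusps}")
    return width * n_cusps / (2.0 * math.pi)


def make_cusp(width: float, max_height: float, n_cusps: int = 3) -> CuspParameters:
    """Construct cusp parameters from measured width and maximum height.

    The wavenumber is taken as k = π·r/W = n/2 exactly, so the free edge is
    pinned to zero at both commissures by construction.
    """
    r = radius_from_width(width, n_cusps)
    k = math.pi * r / (r * 2.0 * math.pi / n_cusps)  # = n/2, kept explicit
    return CuspParameters(radius=r, max_height=max_height, n_cusps=int(n_cusps), wavenumber=k)


def boundary_height(cusp: CuspParameters, theta):
    """Free-edge height h·sin(kθ) above the annulus at angle θ, mm.

    Zero at the commissures θ = 0 and θ = 2π/n, maximal (= h) at the cusp
    midline θ = π/n.
    """
    theta = np.asarray(theta, dtype=float)
    _check_range(theta, 0.0, cusp.angular_extent, "theta")
    out = cusp.max_height * np.sin(cusp.wavenumber * theta)
    out = np.maximum(out, 0.0)  # clip sine round-off at the far commissure
    return float(out) if out.ndim == 0 else out


def surface_point(cusp: CuspParameters, theta, zfrac):
    """Point(s) of the cusp surface (r·cosθ, r·sinθ, zfrac·h·sin(kθ)).

    ``zfrac ∈ [0, 1]`` runs from the annulus to the local free edge, so the
    (θ, zfrac) parameter domain is a fixed rectangle.  Returns an array of
    shape ``(..., 3)``; every point lies on the cylinder x² + y² = r².
    """
    theta = np.asarray(theta, dtype=float)
    zfrac = np.asarray(zfrac, dtype=float)
    _check_range(zfrac, 0.0, 1.0, "zfrac")
    z = zfrac * boundary_height(cusp, theta)
    pts = np.stack(
        np.broadcast_arrays(
            cusp.radius * np.cos(theta), cusp.radius * np.sin(theta), z
        ),
        axis=-1,
    )
    return pts


def flatten(cusp: CuspParameters, theta, z):
    """Develop a surface point (θ, z) onto the plane: (x, z) with x = r·θ.

    The cylinder is developable, so this map is an isometry: arc lengths
    and areas on the shell equal their flattened counterparts.
    """
    theta = np.asarray(theta, dtype=float)
    _check_range(theta, 0.0, cusp.angular_extent, "theta")
    x = cusp.radius * theta
    x = float(x) if x.ndim == 0 else x
    return x, z


def unflatten(cusp: CuspParameters, x, z):
    """Inverse development: (x, z) back to (θ = x/r, z)."""
    x = np.asarray(x, dtype=float)
    _check_range(x, 0.0, cusp.width, "x")
    theta = x / cusp.radius
    theta = float(theta) if theta.ndim == 0 else theta
    return theta, z


def fit_sine_boundary(points, width_fixed: float | None = None) -> SineFitResult:
    """Least-squares fit of the free edge z(x) = A·sin(πx/W) to sampled points.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        Columns (x, z) in mm; n >= 3.
    width_fixed : float, optional
        Hold W at this value and solve the then-linear problem for A.
        When omitted both A and W are estimated by bounded nonlinear least
        squares, with A profiled out analytically at the starting point.

    Returns
    -------
    SineFitResult
        Fitted curve plus residual RMS and parameter standard errors.

    Notes
    -----
    With W free the objective has spurious minima at W/m (the sine aliases);
    the optimizer is started at W₀ = 2·x_peak, twice the abscissa of the
    largest sampled height, which lies in the correct basin whenever the
    samples cover the cusp.  Noiseless samples of a true sine are recovered
    to relative 1e-9 or better.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be an (n, 2) array of (x, z)")
    if pts.shape[0] < 3:
        raise FitError(f"need at least 3 boundary points, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise FitError("boundary points must be finite")
    x, z = pts[:, 0], pts[:, 1]

    if width_fixed is not None:
        w = float(width_fixed)
        if not (w > 0 and math.isfinite(w)):
            raise DomainError(f"width_fixed must be positive, got {w}")
        _check_range(x, 0.0, w, "x")
        s = np.sin(np.pi * x / w)
        gram = float(s @ s)
        if gram == 0.0:
            raise FitError("all sample abscissae sit at edge zeros; amplitude unidentifiable")
        amp = float(s @ z) / gram
        resid = amp * s - z
        dof = max(len(x) - 1, 1)
        sigma2 = float(resid @ resid) / dof
        return SineFitResult(
            curve=BoundaryCurve(width=w, amplitude=amp),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            n_points=len(x),
            amplitude_se=math.sqrt(sigma2 / gram),
            width_se=None,
        )

    if np.allclose(z, 0.0):
        raise FitError("all heights are zero: width is unidentifiable")

    x_span = float(np.max(x) - np.min(x))
    if x_span <= 0:
        raise FitError("degenerate abscissae: zero x-range")
    x_peak = float(x[np.argmax(z)])
    w0 = 2.0 * x_peak if x_peak > 0 else 2.0 * x_span
    a0 = float(np.max(z))
    if a0 <= 0:
        a0 = float(np.max(np.abs(z)))

    def residual(p):
        a, w = p
        return a * np.sin(np.pi * x / w) - z

    sol = least_squares(
        residual,
        x0=[a0, w0],
        bounds=([0.0, 1e-6 * x_span], [np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    amp, w = float(sol.x[0]), float(sol.x[1])
    resid = sol.fun
    dof = max(len(x) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        a_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        w_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        a_se = w_se = math.nan
    return SineFitResult(
        curve=BoundaryCurve(width=w, amplitude=amp),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=len(x),
        amplitude_se=a_se,
        width_se=w_se,
    )


def load_boundary_points(path) -> np.ndarray:
    """Read a two-column (x, z) boundary point table in mm.

    Accepts whitespace- or comma-delimited text, '#' comments, and an
    optional single header row (auto-detected).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    rows = []
    for ln in lines:
        if not ln or ln.startswith("#"):
            continue
        parts = [p for p in ln.replace(",", " ").split() if p]
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            if not rows:  # header row
                continue
            raise FitError(f"unparseable data line in {path}: {ln!r}")
    if not rows or any(len(r) < 2 for r in rows):
        raise FitError(f"{path} does not contain two numeric columns")
    return np.asarray(rows, dtype=float)[:, :2]
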