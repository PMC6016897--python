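"""Derived scalar morphometrics of the modelled valve.

Given cusp parameters this module computes the annulus circumference and
diameter, the area of one cusp (closed form and independent mesh
quadrature), the total valve area (n cusps) and the effective orifice
("valve flap") area obtained from the literature flap-to-valve area ratio,
and compares them against a published cadaveric reference table by
descriptive z-scores.

Because the cylindrical shell is developable, the cusp area is exactly the
flattened area under the sine free edge:

    A_cusp = ∫₀^W h·sin(πx/W) dx = 2·h·W/π.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .geometry import CuspParameters, DomainError, boundary_height

__all__ = [
    "MeasurementReport",
    "ring_circumference",
    "annulus_diameter",
    "cusp_area_closed_form",
    "cusp_area_quadrature",
    "flattened_area_quadrature",
    "valve_areas",
    "compare_to_reference",
    "load_reference_tables",
    "yang_reference",
    "DEFAULT_FLAP_TO_VALVE_RATIO",
]

#: flap (orifice) to total valve area ratio 1 : 1.55 from cadaveric literature
DEFAULT_FLAP_TO_VALVE_RATIO = 1.55


@dataclass(frozen=True)
class MeasurementReport:
    """Scalar metrics of one modelled valve (lengths mm, areas mm²).

    ``orifice_area`` is the "valve flap" area: total cusp area divided by
    the flap-to-valve ratio (the two names denote the same quantity).
    """

    cusp_area: float
    annulus_diameter: float
    annulus_circumference: float
    valve_area: float
    orifice_area: float
    flap_to_valve_ratio: float
    n_cusps: int

    def __post_init__(self) -> None:
        rel = lambda a, b: abs(a - b) / max(abs(b), 1e-300)
        if rel(self.valve_area, self.n_cusps * self.cusp_area) > 1e-12:
            raise DomainError("valve_area must equal n_cusps x cusp_area")
        if rel(self.orifice_area, self.valve_area / self.flap_to_valve_ratio) > 1e-12:
            raise DomainError("orifice_area must equal valve_area / ratio")
        if rel(self.annulus_circumference, math.pi * self.annulus_diameter) > 1e-12:
            raise DomainError("circumference must equal pi x diameter")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        """Fixed-width table, 4 decimal places (full precision kept in fields)."""
        rows = [
            ("cusp area (mm^2)", self.cusp_area),
            ("annulus diameter (mm)", self.annulus_diameter),
            ("annulus circumference (mm)", self.annulus_circumference),
            ("valve area (mm^2)", self.valve_area),
            ("orifice (flap) area (mm^2)", self.orifice_area),
            ("flap-to-valve ratio", self.flap_to_valve_ratio),
        ]
        width = max(len(name) for name, _ in rows)
        lines = [f"{name:<{width}}  {value:12.4f}" for name, value in rows]
        lines.append(f"{'number of cusps':<{width}}  {self.n_cusps:12d}")
        return "\n".join(lines)


def ring_circumference(cusp: CuspParameters) -> float:
    """Annulus (valve ring) circumference 2πr, mm."""
    return 2.0 * math.pi * cusp.radius


def annulus_diameter(cusp: CuspParameters) -> float:
    """Annulus diameter 2r, mm."""
    return 2.0 * cusp.radius


def cusp_area_closed_form(cusp: CuspParameters) -> float:
    """Exact cusp surface area 2·h·W/π, mm².

    The shell is developable, so the 3-D area equals the flattened area
    under the free edge, ∫₀^W h·sin(πx/W) dx = 2hW/π.
    """
    return 2.0 * cusp.max_height * cusp.width / math.pi


def cusp_area_quadrature(cusp: CuspParameters, n_theta: int, n_z: int) -> float:
    """Cusp area by triangulated-mesh summation (independent of the closed form).

    Builds the structured (n_theta x n_z) surface mesh and sums triangle
    areas; converges to ``cusp_area_closed_form`` at second order in the
    angular resolution.
    """
    from .mesh import build_cusp_mesh  # local import: mesh builds on geometry

    if n_theta < 2 or n_z < 2:
        raise DomainError("quadrature needs n_theta >= 2 and n_z >= 2")
    return build_cusp_mesh(cusp, n_theta, n_z).area()


def flattened_area_quadrature(cusp: CuspParameters) -> float:
    """Flattened cusp area by adaptive 1-D quadrature of r·h·sin(kθ) dθ, mm².

    Developability oracle: equals the 3-D surface area.
    """
    val, _ = quad(lambda t: cusp.radius * boundary_height(cusp, t), 0.0, cusp.angular_extent)
    return val


def valve_areas(
    cusp: CuspParameters, flap_to_valve_ratio: float = DEFAULT_FLAP_TO_VALVE_RATIO
) -> MeasurementReport:
    """Full measurement report for a valve of n identical cusps.

    valve_area = n·cusp_area; orifice_area = valve_area / ratio.
    """
    if not (flap_to_valve_ratio > 0 and math.isfinite(flap_to_valve_ratio)):
        raise DomainError(f"flap_to_valve_ratio must be positive, got {flap_to_valve_ratio}")
    a_cusp = cusp_area_closed_form(cusp)
    a_valve = cusp.n_cusps * a_cusp
    return MeasurementReport(
        cusp_area=a_cusp,
        annulus_diameter=annulus_diameter(cusp),
        annulus_circumference=ring_circumference(cusp),
        valve_area=a_valve,
        orifice_area=a_valve / flap_to_valve_ratio,
        flap_to_valve_ratio=flap_to_valve_ratio,
        n_cusps=cusp.n_cusps,
    )


def load_reference_tables() -> dict:
    """Bundled literature reference values (cadaveric morphometrics)."""
    with resources.files("valvegeom.data").joinpath("reference.json").open("rt") as fh:
        return json.load(fh)


def yang_reference() -> dict:
    """Cadaveric mean ± SD comparison row (Yang's measurements)."""
    return load_reference_tables()["yang_cadaveric"]


def compare_to_reference(report: MeasurementReport, reference: dict | None = None) -> pd.DataFrame:
    """Descriptive z-scores of a report against a mean ± SD reference table.

    Parameters
    ----------
    report : MeasurementReport
    reference : dict, optional
        Mapping metric name -> {"mean": float, "sd": float}; metric names
        must be report field names.  Defaults to the bundled cadaveric row.

    Returns
    -------
    pandas.DataFrame
        Columns ``metric, value, ref_mean, ref_sd, z, within_1sd``; the
        z-scores are descriptive only, no inference is implied.
    """
    if reference is None:
        reference = yang_reference()
    values = report.to_dict()
    rows = []
    for metric, ref in reference.items():
        if metric not in values:
            raise KeyError(f"reference metric {metric!r} not in report")
        mean, sd = float(ref["mean"]), float(ref["sd"])
        if sd <= 0:
            raise DomainError(f"reference SD for {metric!r} must be positive, got {sd}")
        z = (values[metric] - mean) / sd
        rows.append(
            {
                "metric": metric,
                "value": values[metric],
                "ref_mean": mean,
                "ref_sd": sd,
                "z": z,
                "within_1sd": bool(abs(z) <= 1.0),
            }
        )
    return pd.DataFrame(rows)
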