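"""Synthetic morphometric cohorts and noisy free-edge point clouds.

Published pulmonary-valve morphometrics report per-cusp width and height
as mean ± SD over a cadaveric population.  This module draws synthetic
per-cusp measurements from independent normal distributions with those
parameters (truncated at zero, since lengths are positive) and generates
noisy samples of the sine free edge, so the fitting and measurement
pipeline can be exercised end to end without any deposited data.

All randomness flows through an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CuspParameters, DomainError
from .measure import load_reference_tables

__all__ = ["MorphometricDistribution", "sample_cohort", "sample_boundary_points", "cohort_measurements"]

CUSP_LABELS = ("left", "right", "anterior")


@dataclass(frozen=True)
class MorphometricDistribution:
    """Per-cusp width/height mean ± SD (mm) for the three pulmonary cusps.

    ``params`` maps label ('left' | 'right' | 'anterior') to a dict with
    keys width_mean, width_sd, height_mean, height_sd.
    """

    params: dict

    def __post_init__(self) -> None:
        for label in CUSP_LABELS:
            if label not in self.params:
                raise DomainError(f"missing cusp label {label!r}")
            p = self.params[label]
            missing = {"width_mean", "width_sd", "height_mean", "height_sd"} - set(p)
            if missing:
                raise DomainError(f"{label}: missing parameters {sorted(missing)}")
            if p["width_mean"] <= 0 or p["height_mean"] <= 0:
                raise DomainError(f"{label}: means must be positive")
            if p["width_sd"] < 0 or p["height_sd"] < 0:
                raise DomainError(f"{label}: SDs must be nonnegative")

    @classmethod
    def default(cls) -> "MorphometricDistribution":
        """Bundled literature per-cusp mean ± SD values."""
        return cls(params=load_reference_tables()["cusp_morphometrics"])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated at zero by resampling nonpositive values."""
    if sd == 0.0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0.0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0.0
    return out


def sample_cohort(
    dist: MorphometricDistribution | None = None, n: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` synthetic width/height measurements per cusp label.

    Returns a DataFrame with columns ``cusp, width_mm, height_mm`` and
    3n rows (n per label); draws are independent across and within cusps,
    and bit-for-bit reproducible for a given seed.
    """
    if dist is None:
        dist = MorphometricDistribution.default()
    if int(n) != n or n < 1:
        raise DomainError(f"n must be a positive integer, got {n}")
    rng = np.random.default_rng(seed)
    frames = []
    for label in CUSP_LABELS:
        p = dist.params[label]
        frames.append(
            pd.DataFrame(
                {
                    "cusp": label,
                    "width_mm": _truncated_normal(rng, p["width_mean"], p["width_sd"], int(n)),
                    "height_mm": _truncated_normal(rng, p["height_mean"], p["height_sd"], int(n)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def sample_boundary_points(
    cusp: CuspParameters, n_points: int, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Noisy flattened samples (x, z) of the cusp free edge.

    x is uniform on [0, W]; z = h·sin(πx/W) plus additive Gaussian noise of
    standard deviation ``noise_sd`` (mm).
    """
    if int(n_points) != n_points or n_points < 3:
        raise DomainError(f"n_points must be an integer >= 3, got {n_points}")
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be nonnegative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, cusp.width, size=int(n_points))
    z = cusp.max_height * np.sin(np.pi * x / cusp.width)
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=int(n_points))
    return np.column_stack([x, z])


def cohort_measurements(
    cohort: pd.DataFrame, n_cusps: int = 3, flap_to_valve_ratio: float = 1.55
) -> pd.DataFrame:
    """Per-sample derived metrics for a cohort table.

    Treats each (width, height) row as one symmetric valve and appends the
    derived radius, annulus diameter/circumference, cusp area, valve area
    and orifice area columns.
    """
    from .geometry import make_cusp
    from .measure import valve_areas

    rows = []
    for _, rec in cohort.iterrows():
        cusp = make_cusp(float(rec["width_mm"]), float(rec["height_mm"]), n_cusps)
        rep = valve_areas(cusp, flap_to_valve_ratio)
        rows.append(
            {
                "cusp": rec["cusp"],
                "width_mm": rec["width_mm"],
                "height_mm": rec["height_mm"],
                "radius_mm": cusp.radius,
                "annulus_diameter_mm": rep.annulus_diameter,
                "annulus_circumference_mm": rep.annulus_circumference,
                "cusp_area_mm2": rep.cusp_area,
                "valve_area_mm2": rep.valve_area,
                "orifice_area_mm2": rep.orifice_area,
            }
        )
    return pd.DataFrame(rows)
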