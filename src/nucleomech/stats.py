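"""Hertz-model indentation fit and simple linear correlation.

These back the two statistical procedures used around the simulator: the
spherical-indenter Hertz fit that calibrates hydrogel Young's moduli from
depth-force curves, and ordinary least-squares regression with Pearson's r
for trend analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class HertzCurve:
    """Depth-force indentation curve from a spherical probe.

    depths: µm, non-negative and strictly increasing; forces: pN;
    probe_radius: µm; sample_poisson: Poisson's ratio of the indented gel.
    """

    depths: np.ndarray
    forces: np.ndarray
    probe_radius: float
    sample_poisson: float = 0.5

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        f = np.asarray(self.forces, dtype=float)
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "forces", f)
        if d.ndim != 1 or f.shape != d.shape:
            raise ValueError("depths and forces must be 1-D arrays of equal length")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("depths must be non-negative and strictly increasing")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if not 0 <= self.sample_poisson <= 0.5:
            raise ValueError("sample_poisson must be in [0, 0.5]")


def hertz_force(E: float, depths, probe_radius: float, poisson: float = 0.5) -> np.ndarray:
    """Forward Hertz model F = (4/3)·E/(1−ν²)·√R·δ^{3/2} (pN, spherical probe)."""
    d = np.asarray(depths, dtype=float)
    return (4.0 / 3.0) * E / (1.0 - poisson**2) * np.sqrt(probe_radius) * d**1.5


def hertz_fit(curve: HertzCurve) -> float:
    """Least-squares Young's modulus E (Pa) for a depth-force curve.

    The model is linear in E, so the fit is the closed-form projection
    E = Σ F·g / Σ g² with g(δ) = (4/3)√R·δ^{3/2}/(1−ν²); it recovers a
    noise-free forward curve exactly and can never return a negative
    modulus for non-negative forces.
    """
    mask = curve.depths > 0
    if mask.sum() < 3:
        raise ValueError("need at least 3 points with positive depth")
    if np.all(curve.forces == 0):
        raise ValueError("all forces are zero; no modulus information")
    g = hertz_force(1.0, curve.depths[mask], curve.probe_radius, curve.sample_poisson)
    return float(np.dot(curve.forces[mask], g) / np.dot(g, g))


class LinearCorrelation(NamedTuple):
    slope: float
    intercept: float
    r: float
    p: float


def linear_correlation(x, y) -> LinearCorrelation:
    """OLS slope/intercept with Pearson r and its two-sided p-value.

    The p-value comes from the t distribution with n − 2 degrees of
    freedom.  Requires n >= 3 and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return LinearCorrelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
    )
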