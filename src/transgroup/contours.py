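"""Radial frequency pattern (RFP) contours.

A contour is described in polar coordinates as a base radius plus a sum of
sinusoidal radius modulations,

    r(theta) = r0 + sum_i A_i * sin(f_i * theta + phi_i),

with integer frequencies ``f_i`` so that the curve closes after one
revolution.  The polar origin may be offset from the display center (the
``center`` field) after centroid alignment; the analytic description is the
single source of truth and polygonal samplings are derived from it on
demand.

This module generates random contours, selects a geometrically compatible
partner contour for a two-contour display, tests point inclusion (the
contour is star-shaped about its polar origin by construction, so the
radial test is exact), and computes coarse shape descriptors (minimum-area
bounding rectangle).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Polygon

from ._rng import as_rng

#: Default number of sinusoidal components per contour.
N_COMPONENTS = 10
#: Inclusive integer frequency range, cycles per revolution.
FREQ_RANGE = (2, 4)
#: Amplitude range, degrees of visual angle.
AMP_RANGE = (0.03, 0.1)
#: Base radius added to the modulation sum, degrees.
BASE_RADIUS = 1.0
#: Default polygonal sampling density.
N_SAMPLES = 4096


class DegenerateContourPairError(ValueError):
    """Two contours coincide (r1 == r2 everywhere within tolerance)."""


class NoCompatiblePartnerError(RuntimeError):
    """No candidate contour intersected the reference contour acceptably."""


class PointOnContourError(ValueError):
    """A query point lies on the contour within tolerance; inclusion is ambiguous."""


@dataclass(frozen=True)
class FourierComponent:
    """One sinusoidal radius modulation."""

    frequency: int
    amplitude: float
    phase: float

    def __post_init__(self):
        if self.frequency < 1 or self.frequency != int(self.frequency):
            raise ValueError(f"frequency must be a positive integer, got {self.frequency}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class RadialFrequencyContour:
    """Closed RFP contour: base radius, components, and polar-origin offset."""

    components: tuple[FourierComponent, ...]
    base_radius: float = BASE_RADIUS
    center: tuple[float, float] = (0.0, 0.0)

    # -- analytic evaluation ------------------------------------------------
    def radius(self, theta):
        """Radius about the polar origin at angle(s) *theta*."""
        theta = np.asarray(theta, dtype=float)
        f, a, ph = _component_arrays(self.components)
        return self.base_radius + np.sin(theta[..., None] * f + ph) @ a

    def radius_deriv(self, theta):
        """dr/dtheta at angle(s) *theta*."""
        theta = np.asarray(theta, dtype=float)
        f, a, ph = _component_arrays(self.components)
        return np.cos(theta[..., None] * f + ph) @ (a * f)

    def point(self, theta):
        """Cartesian point(s) on the contour, display-centered coordinates."""
        r = self.radius(theta)
        return np.stack(
            [self.center[0] + r * np.cos(theta), self.center[1] + r * np.sin(theta)],
            axis=-1,
        )

    def points(self, n: int = N_SAMPLES) -> np.ndarray:
        """Sample the contour as an (n, 2) open polygon (last != first)."""
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        return self.point(theta)

    def tangent_angle(self, theta):
        """Local tangent direction in degrees, axial convention [0, 180)."""
        r = self.radius(theta)
        dr = self.radius_deriv(theta)
        dx = dr * np.cos(theta) - r * np.sin(theta)
        dy = dr * np.sin(theta) + r * np.cos(theta)
        return np.degrees(np.arctan2(dy, dx)) % 180.0

    def arc_table(self, n: int = 8192) -> tuple[np.ndarray, np.ndarray]:
        """Return (theta grid, cumulative arc length) over one revolution.

        The grid has n+1 points covering [0, 2*pi]; cumulative length starts
        at 0 and ends at the perimeter.  Tables are cached per contour.
        """
        return _arc_table_cached(self, n)

    def perimeter(self, n: int = 8192) -> float:
        return float(self.arc_table(n)[1][-1])

    def max_extent(self, n: int = N_SAMPLES) -> float:
        """Largest distance of any contour point from the display center."""
        return float(np.max(np.linalg.norm(self.points(n), axis=1)))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "base_radius": self.base_radius,
            "center": list(self.center),
            "components": [
                {"frequency": c.frequency, "amplitude": c.amplitude, "phase": c.phase}
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadialFrequencyContour":
        return cls(
            components=tuple(
                FourierComponent(int(c["frequency"]), float(c["amplitude"]), float(c["phase"]))
                for c in d["components"]
            ),
            base_radius=float(d["base_radius"]),
            center=(float(d["center"][0]), float(d["center"][1])),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "RadialFrequencyContour":
        return cls.from_dict(json.loads(s))


@lru_cache(maxsize=4096)
def _component_arrays(components: tuple[FourierComponent, ...]):
    f = np.array([c.frequency for c in components], dtype=float)
    a = np.array([c.amplitude for c in components], dtype=float)
    ph = np.array([c.phase for c in components], dtype=float)
    return f, a, ph


@lru_cache(maxsize=512)
def _arc_table_cached(contour: "RadialFrequencyContour", n: int):
    theta = np.linspace(0.0, 2 * np.pi, n + 1)
    speed = np.hypot(contour.radius(theta), contour.radius_deriv(theta))
    # trapezoid rule on the speed gives arc length
    seg = 0.5 * (speed[1:] + speed[:-1]) * np.diff(theta)
    return theta, np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class CompatibilityReport:
    """Geometric compatibility metrics for a superimposed contour pair."""

    intersection_angles: tuple[float, ...]  # crossing angles, degrees in (0, 90]
    min_segment_length: float  # shortest along-contour arc between crossings, degrees
    radial_distance_min: float
    radial_distance_max: float
    radial_distance_mean: float

    @property
    def n_intersections(self) -> int:
        return len(self.intersection_angles)


@dataclass(frozen=True)
class BoundingBox:
    """Minimum-area enclosing rectangle of a contour."""

    width: float  # long side, degrees
    height: float  # short side, degrees
    orientation: float  # long-axis direction, degrees in [0, 180)
    aspect_ratio: float  # width / height, >= 1


def generate_contour(
    rng_seed,
    n_components: int = N_COMPONENTS,
    freq_range: tuple[int, int] = FREQ_RANGE,
    amp_range: tuple[float, float] = AMP_RANGE,
    base_radius: float = BASE_RADIUS,
) -> RadialFrequencyContour:
    """Draw a random RFP contour.

    Integer frequencies are drawn uniformly from ``freq_range`` (inclusive),
    amplitudes uniformly from ``amp_range``, phases uniformly from [0, 2*pi).
    The (practically impossible) event of a non-positive radius triggers a
    redraw.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rng = as_rng(rng_seed)
    probe = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    while True:
        comps = tuple(
            FourierComponent(
                frequency=int(rng.integers(freq_range[0], freq_range[1] + 1)),
                amplitude=float(rng.uniform(*amp_range)),
                phase=float(rng.uniform(0.0, 2 * np.pi)),
            )
            for _ in range(n_components)
        )
        contour = RadialFrequencyContour(components=comps, base_radius=base_radius)
        if np.all(contour.radius(probe) > 0.0):
            return contour


def mean_radius(contour: RadialFrequencyContour, n: int = 2**15) -> float:
    """Angular mean (1/2pi) * integral of r(theta) over one revolution.

    Computed by the rectangle rule on a uniform grid, which is spectrally
    exact for trigonometric polynomials whenever ``n`` exceeds the highest
    component frequency; for integer frequencies the result equals the base
    radius to rounding error.
    """
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return float(np.mean(contour.radius(theta)))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polygon given as an (n, 2) open ring."""
    return np.asarray(Polygon(points).centroid.coords[0])


def align_centroid(
    contour: RadialFrequencyContour, n_samples: int = N_SAMPLES
) -> RadialFrequencyContour:
    """Translate the contour so its polygonal area centroid sits at the origin.

    The shape is unchanged; only the polar-origin offset ``center`` moves.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    poly = Polygon(contour.points(n_samples))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate contour polygon")
    cx, cy = poly.centroid.coords[0]
    return replace(contour, center=(contour.center[0] - cx, contour.center[1] - cy))


def find_intersections(
    c1: RadialFrequencyContour,
    c2: RadialFrequencyContour,
    n_grid: int = 4096,
    tol: float = 1e-8,
    refine: bool = True,
) -> list[tuple[float, np.ndarray]]:
    """All angles where the two radius functions cross.

    Both contours must share the same polar origin (call before centroid
    alignment).  Sign changes of r1 - r2 on a dense grid are refined by
    bisection to ``tol`` (or located by linear interpolation when
    ``refine`` is off, e.g. while scoring large candidate pools).  Returns
    (theta, cartesian point) pairs sorted by angle; raises for an
    (effectively) identical pair.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)

    def diff(t):
        return c1.radius(t) - c2.radius(t)

    d = diff(theta)
    if np.max(np.abs(d)) < 1e-10:
        raise DegenerateContourPairError("contours are identical within tolerance")

    roots: list[float] = []
    sign = np.sign(d)
    # exact zeros on the grid (rare) count as roots directly
    for i in np.flatnonzero(sign == 0):
        roots.append(float(theta[i]))
    step = 2 * np.pi / n_grid
    for i in np.flatnonzero(sign * np.roll(sign, -1) < 0):
        a = theta[i]
        if refine:
            roots.append(float(brentq(diff, a, a + step, xtol=tol)))
        else:
            d1, d2 = d[i], d[(i + 1) % n_grid]
            roots.append(a + step * d1 / (d1 - d2))
    roots = sorted(r % (2 * np.pi) for r in roots)
    # merge duplicates from wrap-around / grid zeros
    out: list[tuple[float, np.ndarray]] = []
    for r in roots:
        if out and abs(r - out[-1][0]) < 10 * tol:
            continue
        out.append((r, c1.point(r)))
    if len(out) >= 2 and (out[0][0] + 2 * np.pi - out[-1][0]) < 10 * tol:
        out.pop()
    return out


def crossing_angles(
    c1: RadialFrequencyContour, c2: RadialFrequencyContour, thetas
) -> np.ndarray:
    """Acute angles in degrees between the tangent directions at crossings."""
    t = np.atleast_1d(np.asarray(thetas, dtype=float))

    def tangent_vecs(c):
        r, dr = c.radius(t), c.radius_deriv(t)
        v = np.stack([dr * np.cos(t) - r * np.sin(t), dr * np.sin(t) + r * np.cos(t)], axis=-1)
        return v / np.linalg.norm(v, axis=-1, keepdims=True)

    cosang = np.abs(np.sum(tangent_vecs(c1) * tangent_vecs(c2), axis=-1))
    return np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))


def crossing_angle(
    c1: RadialFrequencyContour, c2: RadialFrequencyContour, theta: float
) -> float:
    """Acute angle in degrees between the two tangent directions at a crossing."""
    return float(crossing_angles(c1, c2, theta)[0])


def _arc_lengths_between(c: RadialFrequencyContour, thetas: np.ndarray) -> np.ndarray:
    """Along-contour arc lengths between consecutive crossing angles (circular)."""
    grid, cum = c.arc_table()
    s = np.interp(np.sort(thetas), grid, cum)
    per = cum[-1]
    return np.diff(np.concatenate([s, [s[0] + per]]))


def compatibility_report(
    c1: RadialFrequencyContour,
    c2: RadialFrequencyContour,
    n_grid: int = 4096,
    refine: bool = True,
) -> CompatibilityReport:
    """Score the geometric compatibility of a superimposed contour pair."""
    inters = find_intersections(c1, c2, n_grid=n_grid, refine=refine)
    thetas = np.array([t for t, _ in inters])
    angles = tuple(float(a) for a in crossing_angles(c1, c2, thetas)) if len(thetas) else ()
    if len(thetas) >= 2:
        min_seg = min(
            float(np.min(_arc_lengths_between(c1, thetas))),
            float(np.min(_arc_lengths_between(c2, thetas))),
        )
    else:
        min_seg = float("inf") if len(thetas) == 0 else 0.0
    grid = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    dr = np.abs(c1.radius(grid) - c2.radius(grid))
    return CompatibilityReport(
        intersection_angles=angles,
        min_segment_length=min_seg,
        radial_distance_min=float(dr.min()),
        radial_distance_max=float(dr.max()),
        radial_distance_mean=float(dr.mean()),
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def score_candidates(
    reports: Sequence[CompatibilityReport],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Compatibility score per candidate: weighted sum of z-scored metrics.

    Larger minimum inter-crossing segment and larger mean radial separation
    are better; crossing angles closer to perpendicular are better.
    """
    seg = _zscore(np.array([r.min_segment_length for r in reports]))
    sep = _zscore(np.array([r.radial_distance_mean for r in reports]))
    ang = _zscore(
        np.array([np.mean(np.abs(90.0 - np.array(r.intersection_angles))) for r in reports])
    )
    return weights[0] * seg + weights[1] * sep - weights[2] * ang


def select_partner(
    c1: RadialFrequencyContour,
    rng_seed,
    n_candidates: int = 100,
    min_segment: float = 0.35,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    **generate_kwargs,
) -> tuple[RadialFrequencyContour, CompatibilityReport]:
    """Generate candidate contours and return the most compatible partner.

    Candidates that do not intersect ``c1`` in at least two points, or whose
    shortest inter-crossing segment falls below ``min_segment`` (degrees of
    arc; default one average element spacing) are infeasible.  Among feasible
    candidates the weighted z-score of the compatibility metrics is
    maximized; ties break to the first (lowest-index) candidate.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = as_rng(rng_seed)
    feasible: list[tuple[int, RadialFrequencyContour, CompatibilityReport]] = []
    for i in range(n_candidates):
        cand = generate_contour(rng, **generate_kwargs)
        try:
            # linear-interpolated crossings on a coarser grid are plenty for scoring
            rep = compatibility_report(c1, cand, n_grid=1024, refine=False)
        except DegenerateContourPairError:
            continue
        if rep.n_intersections >= 2 and rep.min_segment_length >= min_segment:
            feasible.append((i, cand, rep))
    if not feasible:
        raise NoCompatiblePartnerError(
            f"none of {n_candidates} candidates intersected the reference contour "
            f"with minimum segment length >= {min_segment}; enlarge the pool"
        )
    scores = score_candidates([rep for _, _, rep in feasible], weights)
    best = int(np.argmax(scores))  # argmax returns the first maximum: ties -> first index
    _, cand, rep = feasible[best]
    return cand, rep


def point_inside(
    contour: RadialFrequencyContour, point, tol: float = 1e-9
) -> bool:
    """Radial inclusion test, exact for star-shaped RFP contours.

    ``point`` is expressed relative to the display center; it is referred to
    the contour's polar origin before comparing its radius with r(theta).
    Points on the contour (within ``tol``) raise, since inclusion is
    ambiguous there; the stimulus generator avoids that band by construction.
    """
    p = np.asarray(point, dtype=float) - np.asarray(contour.center)
    rho = float(np.hypot(p[0], p[1]))
    r = float(contour.radius(np.arctan2(p[1], p[0])))
    if abs(rho - r) < tol:
        raise PointOnContourError(f"point at radius {rho} lies on the contour (r={r})")
    return rho < r


def min_bounding_rect(
    contour: RadialFrequencyContour, n_samples: int = N_SAMPLES
) -> BoundingBox:
    """Minimum-area enclosing rectangle of the sampled contour polygon."""
    rect = Polygon(contour.points(n_samples)).minimum_rotated_rectangle
    corners = np.asarray(rect.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if l1 >= l2:
        long_len, short_len, long_vec = l1, l2, e1
    else:
        long_len, short_len, long_vec = l2, l1, e2
    orientation = float(np.degrees(np.arctan2(long_vec[1], long_vec[0])) % 180.0)
    return BoundingBox(
        width=float(long_len),
        height=float(short_len),
        orientation=orientation,
        aspect_ratio=float(long_len / short_len),
    )


def axial_difference(a: float, b: float) -> float:
    """Difference between two axial orientations, degrees in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)
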