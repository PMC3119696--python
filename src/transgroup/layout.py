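"""Element placement for two-contour grouping displays.

Local elements are placed exactly on both latent contours at (jittered)
equidistant arc-length positions, the background is filled by dart throwing
until contour elements are no longer detectable from local density alone
(the proximity cue), and one background element per display is replaced by
the task target with a prescribed inside/outside allocation over the batch.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import ranksums

from ._rng import as_rng
from .contours import RadialFrequencyContour, point_inside

#: Display half-width, degrees; the rendered image is 3.8 x 3.8 degrees.
DISPLAY_HALFWIDTH = 1.9
#: Default average along-contour element spacing, degrees.
AVG_SPACING = 0.35
#: Jitter half-range as a fraction of the average spacing (0.42 keeps
#: realized spacings inside the 58%..142% band).
JITTER_FRAC = 0.42
#: Allowed consecutive-spacing band relative to the average spacing.
SPACING_BAND = (0.58, 1.42)
#: Minimum element distance to contour intersection points, and the minimum
#: background dart separation, as fractions of the average spacing.
CLEARANCE_FRAC = 0.5
#: Radial eccentricity band for the target square center, degrees.
TARGET_ECC_BAND = (0.75, 1.35)
#: Radial no-go margin around each contour for target placement, degrees.
TARGET_CONTOUR_MARGIN = 0.05

TARGET_CLASSES = ("inside_both", "outside_both", "mixed")


class LayoutConstraintError(RuntimeError):
    """Placement constraints could not be satisfied for this contour pair."""


class TargetAssignmentError(RuntimeError):
    """No background element satisfies the required target class for a display."""


@dataclass(frozen=True)
class Element:
    """One local display element."""

    position: tuple[float, float]
    role: str  # contour1 | contour2 | background | target
    arc_angle: float | None = None  # polar angle on its contour (contour roles)
    tangent: float | None = None  # local tangent, degrees axial (contour roles)

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class ElementLayout:
    """All elements of one stimulus set."""

    elements: list[Element]
    avg_spacing: float = AVG_SPACING
    display_halfwidth: float = DISPLAY_HALFWIDTH
    target_index: int | None = None
    target_class: str | None = None

    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.elements], dtype=float).reshape(-1, 2)

    def indices(self, *roles: str) -> np.ndarray:
        return np.array(
            [i for i, e in enumerate(self.elements) if e.role in roles], dtype=int
        )

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "avg_spacing": self.avg_spacing,
            "display_halfwidth": self.display_halfwidth,
            "target_index": self.target_index,
            "target_class": self.target_class,
            "elements": [
                {
                    "position": list(e.position),
                    "role": e.role,
                    "arc_angle": e.arc_angle,
                    "tangent": e.tangent,
                }
                for e in self.elements
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElementLayout":
        return cls(
            elements=[
                Element(
                    position=tuple(e["position"]),
                    role=e["role"],
                    arc_angle=e["arc_angle"],
                    tangent=e["tangent"],
                )
                for e in d["elements"]
            ],
            avg_spacing=float(d["avg_spacing"]),
            display_halfwidth=float(d["display_halfwidth"]),
            target_index=d["target_index"],
            target_class=d["target_class"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ElementLayout":
        return cls.from_dict(json.loads(s))


def place_on_contour(
    contour: RadialFrequencyContour,
    role: str,
    avg_spacing: float,
    intersections: Sequence[np.ndarray],
    rng_seed,
    jitter_frac: float = JITTER_FRAC,
    spacing_band: tuple[float, float] = SPACING_BAND,
    clearance_frac: float = CLEARANCE_FRAC,
    max_attempts: int = 1000,
    max_rotations: int = 40,
) -> list[Element]:
    """Place elements on a contour at jittered equidistant arc positions.

    ``floor(perimeter / avg_spacing)`` elements are laid out equidistantly
    in arc length (with a random rotational offset) and uniform arc-length
    jitter in +-``jitter_frac * avg_spacing`` is added per element.  Jitter
    draws that violate the consecutive-spacing band or come closer than
    ``clearance_frac * avg_spacing`` to any contour intersection point are
    resampled per element (rejection, not clipping, to avoid biasing the
    spacing distribution toward the band edges).  Some rotational offsets
    admit no solution at all (an element trapped against two crossings), so
    the whole offset is redrawn when per-element resampling stalls.
    """
    rng = as_rng(rng_seed)
    grid, cum = contour.arc_table()
    perimeter = float(cum[-1])
    if not (0 < avg_spacing < perimeter):
        raise ValueError("avg_spacing must be positive and below the contour perimeter")
    n = int(perimeter // avg_spacing)
    if n < 3:
        raise LayoutConstraintError("contour too short for the requested spacing")
    gap = perimeter / n
    jmax = jitter_frac * avg_spacing
    inter_pts = np.asarray(list(intersections), dtype=float).reshape(-1, 2)
    clearance = clearance_frac * avg_spacing

    def positions_for(arc: np.ndarray):
        theta = np.interp(arc % perimeter, cum, grid)
        return theta, contour.point(theta)

    solution = None
    per_element_cap = max(1, max_attempts // max_rotations)
    for _ in range(max_rotations):
        base = (rng.uniform(0.0, perimeter) + gap * np.arange(n)) % perimeter
        base.sort()
        jitter = rng.uniform(-jmax, jmax, n)
        attempts = np.zeros(n, dtype=int)
        while True:
            arc = base + jitter
            gaps = np.diff(np.concatenate([arc, [arc[0] + perimeter]]))
            ratio = gaps / avg_spacing
            bad = np.zeros(n, dtype=bool)
            # a bad gap implicates both neighbours
            for kind in (ratio < spacing_band[0], ratio > spacing_band[1]):
                idx = np.flatnonzero(kind)
                bad[idx] = True
                bad[(idx + 1) % n] = True
            if inter_pts.size:
                _, pts = positions_for(arc)
                d = np.linalg.norm(pts[:, None, :] - inter_pts[None, :, :], axis=2)
                bad |= d.min(axis=1) < clearance
            if not bad.any():
                solution = base + jitter
                break
            attempts[bad] += 1
            if np.any(attempts > per_element_cap):
                break  # this rotation looks infeasible; redraw the offset
            jitter[bad] = rng.uniform(-jmax, jmax, int(bad.sum()))
        if solution is not None:
            break
    if solution is None:
        raise LayoutConstraintError(
            f"could not satisfy spacing/clearance constraints on contour "
            f"role={role!r}; intersections too dense for spacing {avg_spacing}"
        )

    theta, pts = positions_for(solution)
    tangents = contour.tangent_angle(theta)
    return [
        Element(
            position=(float(p[0]), float(p[1])),
            role=role,
            arc_angle=float(t % (2 * np.pi)),
            tangent=float(tg),
        )
        for p, t, tg in zip(pts, theta, tangents)
    ]


def nearest_neighbor_distances(positions: np.ndarray, subset: np.ndarray) -> np.ndarray:
    """Distance from each subset element to its nearest other element (any role)."""
    d = np.linalg.norm(positions[subset][:, None, :] - positions[None, :, :], axis=2)
    d[np.arange(len(subset)), subset] = np.inf
    return d.min(axis=1)


def rank_proximity_test(contour_nn: np.ndarray, background_nn: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two NN-distance samples."""
    return float(ranksums(np.asarray(contour_nn), np.asarray(background_nn)).pvalue)


def proximity_pvalue(layout: ElementLayout) -> float:
    """p-value of the proximity-cue test for a layout.

    Nearest-neighbour distances of contour-role elements are compared with
    those of background-role elements by a two-sided rank-sum test; a high
    p-value means local density alone does not give away the contours.
    """
    pos = layout.positions()
    ci = layout.indices("contour1", "contour2")
    bi = layout.indices("background", "target")
    if len(ci) < 5 or len(bi) < 5:
        raise ValueError(
            f"need >= 5 contour and >= 5 background elements, got {len(ci)}/{len(bi)}"
        )
    return rank_proximity_test(
        nearest_neighbor_distances(pos, ci), nearest_neighbor_distances(pos, bi)
    )


def fill_background(
    layout: ElementLayout,
    rng_seed,
    p_threshold: float = 0.3,
    min_background: int | None = None,
    max_darts: int = 10_000,
    clearance_frac: float = CLEARANCE_FRAC,
) -> ElementLayout:
    """Fill the display with background elements until the proximity cue is gone.

    Uniform darts over the display square are accepted when at least
    ``clearance_frac * avg_spacing`` away from every existing element;
    filling stops as soon as the proximity test exceeds ``p_threshold``
    (with at least ``min_background`` background elements present, so that
    an underpowered early test cannot leave the display visibly empty; the
    default floor fills the off-contour area at roughly the contour element
    density).
    """
    rng = as_rng(rng_seed)
    hw = layout.display_halfwidth
    min_dist = clearance_frac * layout.avg_spacing
    elements = list(layout.elements)
    pos = layout.positions()
    n_bg = len(layout.indices("background"))
    if min_background is None:
        # fill the free area at one element per (1.2 * avg_spacing)^2
        footprint = (1.2 * layout.avg_spacing) ** 2
        min_background = max(5, int((2 * hw) ** 2 / footprint) - len(elements))
    for _ in range(max_darts):
        cand = rng.uniform(-hw, hw, 2)
        if np.min(np.linalg.norm(pos - cand, axis=1)) < min_dist:
            continue
        elements.append(Element(position=(float(cand[0]), float(cand[1])), role="background"))
        pos = np.vstack([pos, cand])
        n_bg += 1
        if n_bg >= min_background:
            trial = replace(layout, elements=elements)
            if proximity_pvalue(trial) > p_threshold:
                return trial
    raise LayoutConstraintError(
        f"background fill did not pass the proximity test within {max_darts} darts"
    )


def classify_target_point(
    point,
    contour1: RadialFrequencyContour,
    contour2: RadialFrequencyContour,
) -> str:
    in1 = point_inside(contour1, point)
    in2 = point_inside(contour2, point)
    if in1 and in2:
        return "inside_both"
    if not in1 and not in2:
        return "outside_both"
    return "mixed"


def _target_candidates(
    layout: ElementLayout,
    contour1: RadialFrequencyContour,
    contour2: RadialFrequencyContour,
    ecc_band: tuple[float, float],
    margin: float,
) -> dict[str, list[int]]:
    """Background elements eligible as target, keyed by inside/outside class."""
    out: dict[str, list[int]] = {c: [] for c in TARGET_CLASSES}
    for i in layout.indices("background"):
        p = layout.elements[i].xy
        ecc = float(np.linalg.norm(p))
        if not (ecc_band[0] <= ecc <= ecc_band[1]):
            continue
        ambiguous = False
        for c in (contour1, contour2):
            rel = p - np.asarray(c.center)
            rho = float(np.hypot(rel[0], rel[1]))
            if abs(rho - float(c.radius(np.arctan2(rel[1], rel[0])))) <= margin:
                ambiguous = True
                break
        if ambiguous:
            continue
        out[classify_target_point(p, contour1, contour2)].append(int(i))
    return out


def assign_targets(
    batch: Sequence,
    rng_seed,
    ecc_band: tuple[float, float] = TARGET_ECC_BAND,
    margin: float = TARGET_CONTOUR_MARGIN,
    max_retries: int = 20,
) -> Sequence:
    """Replace one background element per display by the target square.

    ``batch`` items must expose ``layout``, ``contour1`` and ``contour2``
    attributes (e.g. :class:`transgroup.stimset.StimulusSet`); layouts are
    updated in place.  Over the batch the target class is stratified exactly
    25% inside both contours, 25% outside both, 50% inside one but outside
    the other; per display the element is drawn at random among eligible
    background elements (eccentricity band, off-contour margin, class).
    """
    n = len(batch)
    if n % 4 != 0:
        raise ValueError("batch size must be divisible by 4")
    rng = as_rng(rng_seed)
    quota_template = {"inside_both": n // 4, "outside_both": n // 4, "mixed": n // 2}
    candidates = [
        _target_candidates(s.layout, s.contour1, s.contour2, ecc_band, margin)
        for s in batch
    ]
    for i, cand in enumerate(candidates):
        if not any(cand.values()):
            raise TargetAssignmentError(
                f"display {i}: no background element is eligible as target"
            )

    assignment: list[str] | None = None
    for _ in range(max_retries):
        quota = dict(quota_template)
        trial: list[str | None] = [None] * n
        # scarcest displays first: fewest feasible classes, then fewest candidates
        order = sorted(
            range(n),
            key=lambda i: (
                sum(1 for c in TARGET_CLASSES if candidates[i][c]),
                sum(len(v) for v in candidates[i].values()),
            ),
        )
        ok = True
        for i in order:
            feas = [c for c in TARGET_CLASSES if candidates[i][c] and quota[c] > 0]
            if not feas:
                ok = False
                break
            weights = np.array([quota[c] for c in feas], dtype=float)
            choice = str(rng.choice(feas, p=weights / weights.sum()))
            trial[i] = choice
            quota[choice] -= 1
        if ok:
            assignment = [c for c in trial if c is not None]
            break
    if assignment is None:
        infeasible = [
            i
            for i in range(n)
            if sum(1 for c in TARGET_CLASSES if candidates[i][c]) < len(TARGET_CLASSES)
        ]
        raise TargetAssignmentError(
            "could not stratify target classes 25/25/50 over the batch; "
            f"displays with restricted candidate classes: {infeasible}"
        )

    for s, cand, cls in zip(batch, candidates, assignment):
        idx = int(rng.choice(cand[cls]))
        elements = list(s.layout.elements)
        elements[idx] = replace(elements[idx], role="target")
        s.layout = replace(
            s.layout, elements=elements, target_index=idx, target_class=cls
        )
    return batch


def spacing_ratios(layout: ElementLayout, contour: RadialFrequencyContour, role: str) -> np.ndarray:
    """Consecutive along-contour arc-length gaps divided by the average spacing."""
    grid, cum = contour.arc_table()
    thetas = np.sort(
        [e.arc_angle for e in layout.elements if e.role == role and e.arc_angle is not None]
    )
    s = np.interp(thetas, grid, cum)
    gaps = np.diff(np.concatenate([s, [s[0] + cum[-1]]]))
    return gaps / layout.avg_spacing
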