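"""Whole stimulus sets: two compatible latent contours plus an element layout.

One *stimulus set* is the unit the experiment works with: a first random
radial-frequency contour, a compatible partner selected from a pool of
random candidates, elements placed on both contours, a proximity-balanced
background, and (after batch-level stratification) one target element.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import as_rng, child_seed
from . import contours as ct
from . import layout as lay


@dataclass
class StimulusSet:
    """One generated stimulus set (two latent contours + element layout)."""

    set_id: int
    contour1: ct.RadialFrequencyContour
    contour2: ct.RadialFrequencyContour
    intersections: list[tuple[float, np.ndarray]]
    layout: lay.ElementLayout
    report: ct.CompatibilityReport | None = None

    def intersection_points(self) -> np.ndarray:
        return np.array([p for _, p in self.intersections]).reshape(-1, 2)

    def to_dict(self) -> dict:
        return {
            "set_id": self.set_id,
            "contour1": self.contour1.to_dict(),
            "contour2": self.contour2.to_dict(),
            "intersections": [
                {"theta": float(t), "point": [float(p[0]), float(p[1])]}
                for t, p in self.intersections
            ],
            "layout": self.layout.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSet":
        return cls(
            set_id=int(d["set_id"]),
            contour1=ct.RadialFrequencyContour.from_dict(d["contour1"]),
            contour2=ct.RadialFrequencyContour.from_dict(d["contour2"]),
            intersections=[
                (float(i["theta"]), np.asarray(i["point"], dtype=float))
                for i in d["intersections"]
            ],
            layout=lay.ElementLayout.from_dict(d["layout"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "StimulusSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def generate_stimulus_set(
    rng_seed,
    set_id: int = 0,
    avg_spacing: float = lay.AVG_SPACING,
    n_candidates: int = 100,
    max_retries: int = 25,
) -> StimulusSet:
    """Generate one complete (target-less) stimulus set.

    The first contour is drawn, a compatible partner selected among
    ``n_candidates`` random contours sharing the same polar origin, the
    pair translated rigidly so the first contour's centroid sits at the
    display center, elements placed on both contours and the background
    filled.  Contour pairs whose placement constraints cannot be satisfied
    (or that poke outside the display) are discarded and redrawn.
    """
    rng = as_rng(rng_seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            c1 = ct.generate_contour(rng)
            c2, report = ct.select_partner(c1, rng, n_candidates=n_candidates, min_segment=avg_spacing)
            inters = ct.find_intersections(c1, c2)
            # rigid translation of the whole pair: centroid of contour 1 -> origin
            shift = ct.polygon_centroid(c1.points())
            c1 = ct.RadialFrequencyContour(c1.components, c1.base_radius, tuple(c1.center - shift))
            c2 = ct.RadialFrequencyContour(c2.components, c2.base_radius, tuple(c2.center - shift))
            inters = [(t, p - shift) for t, p in inters]
            pts = [p for _, p in inters]

            e1 = lay.place_on_contour(c1, "contour1", avg_spacing, pts, rng)
            e2 = lay.place_on_contour(c2, "contour2", avg_spacing, pts, rng)
            elements = e1 + e2
            pos = np.array([e.position for e in elements])
            if np.any(np.abs(pos) > lay.DISPLAY_HALFWIDTH):
                raise lay.LayoutConstraintError("contour elements outside display")
            layout = lay.ElementLayout(elements=elements, avg_spacing=avg_spacing)
            layout = lay.fill_background(layout, rng)
            # a display must offer at least one eligible target element
            cand = lay._target_candidates(
                layout, c1, c2, lay.TARGET_ECC_BAND, lay.TARGET_CONTOUR_MARGIN
            )
            if sum(len(v) for v in cand.values()) == 0:
                raise lay.LayoutConstraintError("no eligible target candidates")
            return StimulusSet(set_id, c1, c2, inters, layout, report)
        except (lay.LayoutConstraintError, ct.NoCompatiblePartnerError) as err:
            last_err = err
    raise lay.LayoutConstraintError(
        f"failed to generate a valid stimulus set after {max_retries} attempts"
    ) from last_err


def generate_batch(
    n_sets: int,
    rng_seed,
    avg_spacing: float = lay.AVG_SPACING,
    n_candidates: int = 100,
    assign: bool = True,
) -> list[StimulusSet]:
    """Generate a batch of stimulus sets with stratified target assignment.

    With ``assign`` (default), ``n_sets`` must be divisible by 4 and targets
    are allocated 25% inside both contours / 25% outside both / 50% mixed.
    """
    rng = as_rng(rng_seed)
    batch = [
        generate_stimulus_set(
            child_seed(rng), set_id=i, avg_spacing=avg_spacing, n_candidates=n_candidates
        )
        for i in range(n_sets)
    ]
    if assign:
        lay.assign_targets(batch, rng)
    return batch
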