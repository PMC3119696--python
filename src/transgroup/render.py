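"""Display rendering: Gaussian-blob previews and Gabor test displays.

Luminance is normalized to [0, 1] on a 0.5 background (no gamma; hardware
calibration is out of scope).  Coordinates are degrees of visual angle with
the origin at the display center, x rightward and y upward; pixel (0, 0) is
the top-left corner and pixel centers sit at half-integer offsets, so the
degree-to-pixel conversion flips y.

Preview displays render every element as an isotropic Gaussian blob whose
peak is high (0.77) for "lit" elements and low (0.64) otherwise; which
elements are lit defines the preview condition.  The postsaccadic test
display renders oriented Gabor patches: elements of the displayed contour
are aligned with the local contour tangent (plus orientation jitter), all
other elements are randomly oriented, and the target element is replaced by
a small luminance-defined square.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from ._rng import as_rng
from .layout import ElementLayout

#: Display size in degrees.
SIZE_DEG = 3.8
#: Default pixels per degree: an 800-px-wide frame spanning 17 degrees.
PPD = 800.0 / 17.0
#: Background luminance.
BACKGROUND = 0.5
#: Peak luminance increments over the background.
PEAK_HIGH = 0.27  # lit elements: 0.5 + 0.27 = 0.77
PEAK_LOW = 0.14  # unlit elements: 0.5 + 0.14 = 0.64
#: Gaussian blob standard deviation, degrees.
GAUSS_SD = 0.05
#: Gabor envelope standard deviation, degrees; carrier frequency, cyc/deg.
GABOR_SD = 0.06
GABOR_SF = 10.0
#: Orientation jitter half-range for displayed-contour Gabors, degrees.
ORIENT_JITTER = 22.5
#: Target square: border/core widths in pixels and luminances.
TARGET_BORDER_PX = 2
TARGET_CORE_PX = 3
TARGET_BORDER_LUM = 0.75
TARGET_CORE_LUM = 0.25

#: The five preview conditions; the fixation display is condition-less.
CONDITIONS = ("uniform", "random", "localized", "same", "different")


@dataclass(frozen=True)
class ConditionSpec:
    """Which elements are lit in a preview display."""

    name: str
    lit_set: frozenset[int]


@dataclass
class DisplayImage:
    """Normalized-luminance image with its degree-to-pixel scale."""

    pixels: np.ndarray  # (n, n) float in [0, 1]
    ppd: float = PPD
    size_deg: float = SIZE_DEG

    @property
    def n_px(self) -> int:
        return self.pixels.shape[0]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) degree coordinates of pixel centers: x per column, y per row."""
        n = self.n_px
        half = self.size_deg / 2.0
        x = (np.arange(n) + 0.5) / self.ppd - half
        y = half - (np.arange(n) + 0.5) / self.ppd
        return x, y

    def deg_to_px(self, point) -> tuple[int, int]:
        """Nearest (row, col) pixel for a point in degrees."""
        x, y = float(point[0]), float(point[1])
        half = self.size_deg / 2.0
        col = int(np.clip(round(x * self.ppd + half * self.ppd - 0.5), 0, self.n_px - 1))
        row = int(np.clip(round((half - y) * self.ppd - 0.5), 0, self.n_px - 1))
        return row, col

    def quantized(self) -> np.ndarray:
        """8-bit representation, as written to PNG."""
        return np.round(np.clip(self.pixels, 0.0, 1.0) * 255.0).astype(np.uint8)

    def to_png(self, path) -> None:
        Image.fromarray(self.quantized(), mode="L").save(Path(path), format="PNG")

    @classmethod
    def from_png(cls, path, ppd: float = PPD, size_deg: float = SIZE_DEG) -> "DisplayImage":
        arr = np.asarray(Image.open(Path(path)).convert("L"), dtype=float) / 255.0
        return cls(pixels=arr, ppd=ppd, size_deg=size_deg)


def blank_image(ppd: float = PPD, size_deg: float = SIZE_DEG) -> DisplayImage:
    n = int(round(size_deg * ppd))
    return DisplayImage(pixels=np.full((n, n), BACKGROUND), ppd=ppd, size_deg=size_deg)


def assign_condition(sset, condition_name: str, postsac_stimulus: int = 1, rng_seed=None) -> ConditionSpec:
    """Choose the lit element subset implementing a preview condition.

    ``sset`` is a stimulus set exposing ``layout``, ``contour1`` and
    ``contour2``.  Uniform lights every element; Same lights the elements of
    the contour shown postsaccadically and Different those of the other
    contour; Random lights half of all elements; Localized half of the
    elements lying within the maximal radius of both latent contours; the
    fixation display lights none.
    """
    layout: ElementLayout = sset.layout
    n = layout.n_elements
    if condition_name == "fixation":
        return ConditionSpec("fixation", frozenset())
    if condition_name == "uniform":
        return ConditionSpec("uniform", frozenset(range(n)))
    if condition_name in ("same", "different"):
        shown = postsac_stimulus if condition_name == "same" else 3 - postsac_stimulus
        return ConditionSpec(condition_name, frozenset(int(i) for i in layout.indices(f"contour{shown}")))
    rng = as_rng(rng_seed)
    if condition_name == "random":
        lit = rng.choice(n, size=n // 2, replace=False)
        return ConditionSpec("random", frozenset(int(i) for i in lit))
    if condition_name == "localized":
        max_radius = max(sset.contour1.max_extent(), sset.contour2.max_extent())
        ecc = np.linalg.norm(layout.positions(), axis=1)
        pool = np.flatnonzero(ecc <= max_radius)
        lit = rng.choice(pool, size=len(pool) // 2, replace=False)
        return ConditionSpec("localized", frozenset(int(i) for i in lit))
    raise ValueError(f"unknown condition {condition_name!r}")


def _add_profiles(img: DisplayImage, centers: np.ndarray, profile_fn, radius_deg: float) -> None:
    """Accumulate per-element luminance profiles into img.pixels (in place)."""
    x, y = img.pixel_centers()
    n = img.n_px
    rad_px = int(np.ceil(radius_deg * img.ppd)) + 1
    for k, (cx, cy) in enumerate(centers):
        row, col = img.deg_to_px((cx, cy))
        r0, r1 = max(0, row - rad_px), min(n, row + rad_px + 1)
        c0, c1 = max(0, col - rad_px), min(n, col + rad_px + 1)
        dx = x[c0:c1][None, :] - cx
        dy = y[r0:r1][:, None] - cy
        img.pixels[r0:r1, c0:c1] += profile_fn(k, dx, dy)


def render_gaussian(
    layout: ElementLayout,
    spec: ConditionSpec,
    ppd: float = PPD,
    sigma: float = GAUSS_SD,
    peak_high: float = PEAK_HIGH,
    peak_low: float = PEAK_LOW,
) -> DisplayImage:
    """Render a preview display of Gaussian blobs.

    Overlapping profiles sum on the 0.5 background before clipping to
    [0, 1]; with the spacing constraints the overlap of neighbouring
    Gaussians is negligible at 0.05 degree scale.
    """
    img = blank_image(ppd)
    centers = layout.positions()
    peaks = np.array(
        [peak_high if i in spec.lit_set else peak_low for i in range(layout.n_elements)]
    )

    def profile(k, dx, dy):
        return peaks[k] * np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))

    _add_profiles(img, centers, profile, radius_deg=4 * sigma)
    img.pixels = np.clip(img.pixels, 0.0, 1.0)
    return img


def assign_orientations(
    layout: ElementLayout,
    postsac_stimulus: int,
    rng_seed,
    jitter_deg: float = ORIENT_JITTER,
) -> np.ndarray:
    """Gabor orientation (degrees, axial) for every element of a test display.

    Elements of the displayed contour take their stored local tangent plus
    uniform jitter in +-``jitter_deg``; every other element (background and
    the latent other contour) is uniformly random in [0, 180).  The target
    element gets NaN (it is rendered as a square, not a Gabor).
    """
    rng = as_rng(rng_seed)
    ori = rng.uniform(0.0, 180.0, layout.n_elements)
    for i in layout.indices(f"contour{postsac_stimulus}"):
        ori[i] = (layout.elements[i].tangent + rng.uniform(-jitter_deg, jitter_deg)) % 180.0
    if layout.target_index is not None:
        ori[layout.target_index] = np.nan
    return ori


def render_gabor(
    layout: ElementLayout,
    postsac_stimulus: int,
    rng_seed=None,
    orientations: np.ndarray | None = None,
    ppd: float = PPD,
    sigma: float = GABOR_SD,
    sf: float = GABOR_SF,
    peak: float = PEAK_HIGH,
    with_target: bool = True,
) -> DisplayImage:
    """Render the postsaccadic test display (oriented Gabors + target square).

    The carrier is in cosine phase so the element center attains the full
    0.77 peak.  ``orientations`` (from :func:`assign_orientations`) may be
    passed explicitly; otherwise they are drawn from ``rng_seed``.
    """
    if orientations is None:
        orientations = assign_orientations(layout, postsac_stimulus, rng_seed)
    img = blank_image(ppd)
    centers = layout.positions()
    keep = np.ones(layout.n_elements, dtype=bool)
    if layout.target_index is not None:
        keep[layout.target_index] = False

    def profile(k, dx, dy):
        if not keep[k]:
            return 0.0
        a = np.radians(orientations[k])
        # carrier varies perpendicular to the element's orientation axis
        w = -np.sin(a) * dx + np.cos(a) * dy
        env = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
        return peak * env * np.cos(2.0 * np.pi * sf * w)

    _add_profiles(img, centers, profile, radius_deg=4 * sigma)
    img.pixels = np.clip(img.pixels, 0.0, 1.0)
    if with_target and layout.target_index is not None:
        img = render_target(img, layout.elements[layout.target_index].position)
    return img


def render_target(image: DisplayImage, position) -> DisplayImage:
    """Draw the target square centered on the pixel nearest ``position``.

    The square is 7 x 7 px (about 0.15 degrees at the default scale): a
    2-px-wide border at 0.75 luminance around a 3 x 3 px core at 0.25.
    """
    side = TARGET_CORE_PX + 2 * TARGET_BORDER_PX
    half = side // 2
    row, col = image.deg_to_px(position)
    if row - half < 0 or col - half < 0 or row + half >= image.n_px or col + half >= image.n_px:
        raise ValueError("target square would exceed the image bounds")
    px = image.pixels.copy()
    px[row - half : row + half + 1, col - half : col + half + 1] = TARGET_BORDER_LUM
    core = TARGET_CORE_PX // 2
    px[row - core : row + core + 1, col - core : col + core + 1] = TARGET_CORE_LUM
    return replace(image, pixels=px)
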