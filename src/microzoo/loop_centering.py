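"""Automatic cryoloop centering from on-axis microscope images.

The sequence mirrors standard microbeam practice: background-subtract,
blur and binarize the microscope frame; search for the loop by large
horizontal translations if nothing is visible; align the loop tip (the
leftmost silhouette pixel) with the beam horizontally and the silhouette
centre of gravity with the beam height, repeating at 0/45/90 degrees; fit
the silhouette pixel count at four angles to a period-180 cosine to find
the **face angle** (the spindle angle at which the largest loop face is
perpendicular to the beam); finally circumscribe the silhouette with a
rectangle and divide it by the raster beam size to define the scan grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Protocol

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu

from .geometry import rot2d
from .virtual_beamline import MicroscopeImage

__all__ = [
    "BinaryImage",
    "CenteringResult",
    "RasterArea",
    "DegenerateSilhouetteError",
    "EmptyMaskError",
    "binarize",
    "search_loop",
    "center_tip",
    "silhouette_counts",
    "find_face_angle",
    "define_raster_area",
    "center_loop",
]


class DegenerateSilhouetteError(ValueError):
    """The four silhouette counts carry no angular modulation."""


class EmptyMaskError(ValueError):
    """A binarized image contains no true pixels where some are required."""


class GoniometerLike(Protocol):
    """The stage interface the centering routines drive."""

    def capture(self, omega: float) -> MicroscopeImage: ...
    def translate_lab(self, d_y_lab: float, d_z: float, omega: float) -> None: ...


@dataclass(frozen=True)
class BinaryImage:
    """Thresholded silhouette mask plus the settings that produced it."""

    mask: np.ndarray
    pixel_size: float
    beam_center: tuple[float, float]
    omega: float
    blur_sigma: float
    threshold: float


@dataclass(frozen=True)
class CenteringResult:
    """Outcome of loop centering.

    ``translation`` is the total sample-frame offset applied (um);
    ``face_angle`` is reported in [0, 180) degrees.
    """

    translation: tuple[float, float, float]
    face_angle: float | None
    converged: bool
    iterations: int

    def __post_init__(self) -> None:
        if self.face_angle is not None:
            object.__setattr__(self, "face_angle",
                               float(np.mod(self.face_angle, 180.0)))


@dataclass(frozen=True)
class RasterArea:
    """A rectangular raster grid in lab coordinates at a fixed omega.

    ``origin_y_lab``/``origin_z`` locate the centre of the top-left grid
    (micrometres relative to the beam position); rows step downwards by
    ``step_v`` and columns step toward +Z by ``step_h``.
    """

    origin_y_lab: float
    origin_z: float
    n_h: int
    n_v: int
    step_h: float
    step_v: float
    omega: float

    def __post_init__(self) -> None:
        if self.n_h < 1 or self.n_v < 1:
            raise ValueError("grid counts must be >= 1")
        if self.step_h <= 0 or self.step_v <= 0:
            raise ValueError("grid steps must be positive")

    @property
    def width(self) -> float:
        return self.n_h * self.step_h

    @property
    def height(self) -> float:
        return self.n_v * self.step_v

    def grid_lab(self) -> tuple[np.ndarray, np.ndarray]:
        """(y_lab, z) arrays of shape (n_v, n_h) for every grid centre."""
        i = np.arange(self.n_v)[:, None]
        j = np.arange(self.n_h)[None, :]
        y = self.origin_y_lab - i * self.step_v + 0.0 * j
        z = self.origin_z + j * self.step_h + 0.0 * i
        return y, z

    def grid_centers_stage(self) -> np.ndarray:
        """(n_v, n_h, 3) stage-frame coordinates of the grid centres.

        The raster plane is assumed to pass through the rotation axis, so
        each lab point (0, y, z) maps back through the spindle rotation.
        """
        y, z = self.grid_lab()
        r = rot2d(-self.omega)
        out = np.empty(y.shape + (3,))
        out[..., 0] = r[0, 1] * y
        out[..., 1] = r[1, 1] * y
        out[..., 2] = z
        return out


# ---------------------------------------------------------------------------


def binarize(
    image: MicroscopeImage,
    background: MicroscopeImage,
    blur_sigma: float = 2.0,
    threshold: float | None = None,
    min_threshold: float = 10.0,
) -> BinaryImage:
    """Blur the background-subtracted frame and threshold it.

    ``threshold=None`` picks Otsu's threshold on the blurred difference,
    floored at ``min_threshold`` grey levels so residual noise on an
    object-free frame never counts as foreground.
    """
    if image.pixels.shape != background.pixels.shape:
        raise ValueError("image and background shapes differ")
    if image.pixel_size != background.pixel_size:
        raise ValueError("image and background pixel sizes differ")
    diff = gaussian_filter(image.pixels - background.pixels, blur_sigma)
    if threshold is None:
        if diff.max() - diff.min() < 1e-9:
            return BinaryImage(np.zeros_like(diff, dtype=bool),
                               image.pixel_size, image.beam_center,
                               image.omega, blur_sigma, math.inf)
        threshold = max(float(threshold_otsu(diff)), min_threshold)
    mask = diff > threshold
    return BinaryImage(mask, image.pixel_size, image.beam_center,
                       image.omega, blur_sigma, float(threshold))


def search_loop(
    stage: GoniometerLike,
    background: MicroscopeImage | Callable[[float], MicroscopeImage],
    *,
    image_width_um: float | None = None,
    translation_factor: float = 1.5,
    max_iterations: int = 2,
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    blur_sigma: float = 2.0,
    threshold: float | None = None,
    min_pixels: int = 20,
) -> tuple[bool, float]:
    """Find the loop, translating horizontally when nothing is in view.

    Binarized frames at ``angles`` are inspected; if none shows at least
    ``min_pixels`` true pixels the stage is translated along the rotation
    axis toward the loop-tip side (-Z) by ``translation_factor`` times
    the image width and the inspection is repeated, at most
    ``max_iterations`` times.  Returns ``(found,
    total_horizontal_translation_um)`` (signed); not finding the loop is
    a normal outcome.
    """
    bg = background if callable(background) else (lambda _om: background)
    total = 0.0
    for attempt in range(max_iterations + 1):
        for om in angles:
            b = binarize(stage.capture(om), bg(om), blur_sigma, threshold)
            if int(b.mask.sum()) >= min_pixels:
                return True, total
        if attempt == max_iterations:
            break
        if image_width_um is None:
            img = stage.capture(angles[0])
            image_width_um = img.pixels.shape[1] * img.pixel_size
        step = -translation_factor * image_width_um
        stage.translate_lab(0.0, step, angles[0])
        total += step
    return False, total


def _tip_and_cog(mask: np.ndarray, beam_center) -> tuple[int, int, float]:
    """Leftmost true-pixel column (tie: row nearest the beam row), CoG row."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("no true pixels in binarized image")
    tip_col = int(cols.min())
    tie_rows = rows[cols == tip_col]
    tip_row = int(tie_rows[np.argmin(np.abs(tie_rows - beam_center[0]))])
    return tip_col, tip_row, float(rows.mean())


def center_tip(
    stage: GoniometerLike,
    background: MicroscopeImage | Callable[[float], MicroscopeImage],
    *,
    angles: tuple[float, ...] = (0.0, 45.0, 90.0),
    blur_sigma: float = 2.0,
    threshold: float | None = None,
) -> CenteringResult:
    """Align the loop tip with the beam, iterating over ``angles``.

    At each angle the horizontal translation matches the leftmost true
    pixel's column to the beam column, and the vertical translation
    matches the true-pixel centre of gravity to the beam row.  Because the
    vertical corrections at 0 and 90 degrees address orthogonal
    sample-frame components, the noise-free sequence converges exactly.
    """
    bg = background if callable(background) else (lambda _om: background)
    total = np.zeros(3)
    for om in angles:
        img = stage.capture(om)
        b = binarize(img, bg(om), blur_sigma, threshold)
        tip_col, _tip_row, cog_row = _tip_and_cog(b.mask, b.beam_center)
        px = b.pixel_size
        d_z = (b.beam_center[1] - tip_col) * px
        d_y = (cog_row - b.beam_center[0]) * px
        stage.translate_lab(d_y, d_z, om)
        total[2] += d_z
        total[:2] += rot2d(-om) @ np.array([0.0, d_y])
    return CenteringResult(translation=tuple(total), face_angle=None,
                           converged=True, iterations=len(angles))


def silhouette_counts(
    stage: GoniometerLike,
    background: MicroscopeImage | Callable[[float], MicroscopeImage],
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    *,
    blur_sigma: float = 2.0,
    threshold: float | None = None,
) -> list[int]:
    """True-pixel counts of the binarized silhouette at each angle."""
    bg = background if callable(background) else (lambda _om: background)
    return [int(binarize(stage.capture(om), bg(om), blur_sigma,
                         threshold).mask.sum()) for om in angles]


def find_face_angle(
    counts,
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
) -> float:
    """Face angle from silhouette pixel counts via a period-180 cosine fit.

    Fits ``N(theta) = A + B cos(2 (theta - phi))`` by least squares (exact
    for noise-free cosine data), takes the fitted minimising angle -- where
    the loop looks smallest from the X-ray viewpoint -- and returns that
    angle plus 90 degrees, reduced to [0, 180).  The result is invariant
    under uniform scaling of the counts.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or len(c) != len(angles) or len(c) < 3:
        raise ValueError("need one count per angle, at least three")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    th = np.deg2rad(np.asarray(angles, dtype=float))
    design = np.column_stack([np.ones_like(th), np.cos(2 * th), np.sin(2 * th)])
    (a, cc, ss), *_ = np.linalg.lstsq(design, c, rcond=None)
    amp = math.hypot(cc, ss)
    if amp <= 1e-12 * max(abs(a), 1.0):
        raise DegenerateSilhouetteError(
            "silhouette counts show no angular modulation; face angle undefined")
    phi_max = math.degrees(0.5 * math.atan2(ss, cc))   # fitted maximum
    phi_min = phi_max + 90.0                           # loop looks smallest
    return float(np.mod(phi_min + 90.0, 180.0))


def define_raster_area(
    binary: BinaryImage,
    beam: tuple[float, float],
    user_loop_size: float | None = None,
) -> RasterArea:
    """Circumscribe the silhouette and divide it by the raster beam size.

    The bounding rectangle of true pixels is converted to micrometres;
    grid counts are the ceil-divided widths and the grid step equals the
    beam size.  ``user_loop_size`` caps the horizontal extent, measured
    from the loop tip (the leftmost column).  The vertical range always
    comes from the found silhouette edge.
    """
    beam_h, beam_v = beam
    if beam_h <= 0 or beam_v <= 0:
        raise ValueError("beam sizes must be positive")
    rows, cols = np.nonzero(binary.mask)
    if rows.size == 0:
        raise EmptyMaskError("cannot define a raster area on an empty mask")
    px = binary.pixel_size
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    width = (c1 - c0 + 1) * px
    if user_loop_size is not None:
        width = min(width, float(user_loop_size))
    height = (r1 - r0 + 1) * px
    n_h = max(1, math.ceil(width / beam_h - 1e-9))
    n_v = max(1, math.ceil(height / beam_v - 1e-9))
    bc_r, bc_c = binary.beam_center
    z_left = (c0 - 0.5 - bc_c) * px          # left edge of leftmost pixel
    y_top = (bc_r - (r0 - 0.5)) * px         # top edge of topmost pixel
    return RasterArea(origin_y_lab=y_top - beam_v / 2.0,
                      origin_z=z_left + beam_h / 2.0,
                      n_h=n_h, n_v=n_v, step_h=float(beam_h),
                      step_v=float(beam_v), omega=binary.omega)


def center_loop(
    stage: GoniometerLike,
    background: MicroscopeImage | Callable[[float], MicroscopeImage],
    beam: tuple[float, float] = (10.0, 15.0),
    *,
    user_loop_size: float | None = None,
    blur_sigma: float = 2.0,
    threshold: float | None = None,
    search: bool = True,
    shift_half_loop: bool = True,
) -> tuple[CenteringResult, RasterArea | None]:
    """Full centering sequence: search, tip centering, face angle, raster area.

    After the face angle is found the tip is re-centred at that angle and
    the circumscribing raster grid is defined there.  When a user loop
    size is given the stage is finally moved left along the rotation axis
    by half that size, so the scanned stretch of the loop brackets the
    beam position; the returned area is expressed in the moved frame.
    Returns ``(result, None)`` with ``converged=False`` if no loop is
    found.
    """
    bg = background if callable(background) else (lambda _om: background)
    kw = dict(blur_sigma=blur_sigma, threshold=threshold)
    if search:
        found, _shift = search_loop(stage, bg, **kw)
        if not found:
            return CenteringResult((0.0, 0.0, 0.0), None, False, 0), None
    tip = center_tip(stage, bg, **kw)
    counts = silhouette_counts(stage, bg, **kw)
    face = find_face_angle(counts)
    extra = center_tip(stage, bg, angles=(face,), **kw)
    b = binarize(stage.capture(face), bg(face), blur_sigma, threshold)
    area = define_raster_area(b, beam, user_loop_size)
    total = np.asarray(tip.translation) + np.asarray(extra.translation)
    if user_loop_size is not None and shift_half_loop:
        stage.translate_lab(0.0, -user_loop_size / 2.0, face)
        total[2] -= user_loop_size / 2.0
        area = replace(area, origin_z=area.origin_z - user_loop_size / 2.0)
    result = CenteringResult(translation=tuple(total), face_angle=face,
                             converged=True,
                             iterations=tip.iterations + extra.iterations)
    return result, area
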