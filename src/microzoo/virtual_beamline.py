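"""A virtual microfocus beamline: ground-truth samples and simulated measurements.

This module generates everything the decision-making code consumes so the
whole pipeline can run with no hardware:

* on-axis microscope images of a cryoloop silhouette rotating about the
  horizontal goniometer axis (:func:`capture_image`),
* per-grid diffraction responses of a raster scan, i.e. the number of
  low-resolution spots a spot finder would count (:func:`raster_response`),
* synthetic detector frames with injected Bragg spots for exercising the
  spot finder itself (:func:`make_diffraction_frame`).

The loop is modelled as a thin elliptical annulus (plus a stem) lying in a
plane that contains the rotation axis; crystals are axis-aligned boxes in
the sample frame.  Both choices keep every projected overlap analytic, so
each simulated response can be checked against independent brute-force
oracles.  Image noise is additive Gaussian and spot-count noise is Poisson,
both seeded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import rot2d

__all__ = [
    "CrystalTruth",
    "LoopTruth",
    "VirtualSample",
    "Camera",
    "MicroscopeImage",
    "VirtualGoniometer",
    "make_sample",
    "capture_image",
    "silhouette_mask",
    "raster_response",
    "scenario_fig4",
    "make_random_sample",
    "make_diffraction_frame",
]


# ---------------------------------------------------------------------------
# ground-truth types


@dataclass(frozen=True)
class CrystalTruth:
    """An axis-aligned box crystal in the sample frame.

    ``center`` and ``half_extents`` are ``(x, y, z)`` in micrometres with z
    along the rotation axis, y vertical at omega = 0 and x along the beam
    at omega = 0 (the "depth" direction).  ``diffraction_power`` is the
    expected spot count for a beam footprint fully inside the crystal.
    """

    center: tuple[float, float, float]
    half_extents: tuple[float, float, float]
    diffraction_power: float = 50.0

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.half_extents) != 3:
            raise ValueError("center and half_extents must be 3-vectors")
        if any(h <= 0 for h in self.half_extents):
            raise ValueError("crystal half_extents must be positive")
        if self.diffraction_power < 0:
            raise ValueError("diffraction_power must be >= 0")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - np.asarray(self.half_extents)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.half_extents)


@dataclass(frozen=True)
class LoopTruth:
    """A thin elliptical cryoloop ring in a plane containing the rotation axis.

    ``plane_normal_angle`` (degrees) orients the loop-plane normal within
    the sample-frame X-Y plane; the silhouette seen along the beam is
    largest at omega = -plane_normal_angle (mod 180), which is the
    ground-truth face angle.  ``tip_position`` is the leftmost point of the
    ring (the loop tip); the ring centre sits ``outer_radius`` further
    along +Z.  The ring is ``thickness`` micrometres thick along its normal
    and elliptical in-plane with axis ratio ``aspect`` (in-plane semi-axis
    = radius * aspect).
    """

    plane_normal_angle: float = 0.0
    outer_radius: float = 300.0
    inner_radius: float = 240.0
    tip_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    aspect: float = 0.85
    thickness: float = 10.0
    stem_width: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.aspect <= 0 or self.thickness <= 0 or self.stem_width <= 0:
            raise ValueError("aspect, thickness and stem_width must be positive")

    @property
    def ring_center(self) -> np.ndarray:
        """Sample-frame centre of the ring (tip + outer_radius along +Z)."""
        c = np.asarray(self.tip_position, dtype=float).copy()
        c[2] += self.outer_radius
        return c

    @property
    def face_angle(self) -> float:
        """Ground-truth face angle in [0, 180) degrees."""
        return float(np.mod(-self.plane_normal_angle, 180.0))

    def normal(self) -> np.ndarray:
        p = np.deg2rad(self.plane_normal_angle)
        return np.array([np.cos(p), np.sin(p), 0.0])

    def in_plane(self) -> np.ndarray:
        p = np.deg2rad(self.plane_normal_angle)
        return np.array([-np.sin(p), np.cos(p), 0.0])


@dataclass(frozen=True)
class VirtualSample:
    """Ground truth for one pin: loop geometry plus a list of crystals.

    ``loop`` may be ``None`` to model an empty pin.  ``noise_level`` is the
    Gaussian sigma of the microscope image noise (grey levels),
    ``background_level`` / ``contrast`` the background and silhouette grey
    levels of the rendered images.
    """

    loop: LoopTruth | None = field(default_factory=LoopTruth)
    crystals: tuple[CrystalTruth, ...] = ()
    noise_level: float = 2.0
    background_level: float = 40.0
    contrast: float = 130.0
    seed: int = 0


@dataclass(frozen=True)
class Camera:
    """On-axis microscope geometry: pixel grid, scale and beam position."""

    shape: tuple[int, int] = (256, 352)
    pixel_size: float = 4.0  # um / pixel
    beam_center: tuple[float, float] | None = None  # (row, col); None = centre

    def __post_init__(self) -> None:
        if self.shape[0] < 64 or self.shape[1] < 64:
            raise ValueError("camera shape must be at least 64x64")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        bc = self.beam_center
        if bc is None:
            bc = ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)
        if not (0 <= bc[0] < self.shape[0] and 0 <= bc[1] < self.shape[1]):
            raise ValueError("beam_center must lie inside the image")
        object.__setattr__(self, "beam_center", (float(bc[0]), float(bc[1])))

    @property
    def width_um(self) -> float:
        return self.shape[1] * self.pixel_size


@dataclass(frozen=True)
class MicroscopeImage:
    """A grayscale microscope frame with its geometry and capture angle."""

    pixels: np.ndarray
    pixel_size: float
    beam_center: tuple[float, float]
    omega: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        r, c = self.beam_center
        if not (0 <= r < self.pixels.shape[0] and 0 <= c < self.pixels.shape[1]):
            raise ValueError("beam_center outside image bounds")


# ---------------------------------------------------------------------------
# sample construction and validation


def _crystal_inside_loop(crystal: CrystalTruth, loop: LoopTruth) -> bool:
    """Crystal centre inside the loop's elliptical bounding volume.

    Depth (along the loop-plane normal) is allowed up to half the outer
    radius: frozen crystals sit in the solvent film around the ring plane.
    """
    c = np.asarray(crystal.center, dtype=float)
    rel = c - loop.ring_center
    dz = rel[2]
    du = float(rel[:2] @ loop.in_plane()[:2])
    dn = float(rel[:2] @ loop.normal()[:2])
    r = loop.outer_radius
    in_ellipse = (dz / r) ** 2 + (du / (r * loop.aspect)) ** 2 <= 1.0
    return bool(in_ellipse and abs(dn) <= r / 2.0)


def make_sample(
    loop: LoopTruth | dict | None = None,
    crystals: tuple | list = (),
    *,
    noise_level: float = 2.0,
    background_level: float = 40.0,
    contrast: float = 130.0,
    seed: int = 0,
    empty: bool = False,
) -> VirtualSample:
    """Build and validate a :class:`VirtualSample` from a description.

    ``loop`` and each crystal may be given either as the dataclass or as a
    keyword dict (the JSON sample-spec form).  Crystals must lie within the
    loop's bounding volume.  Construction is purely geometric, so two
    identical specs with the same seed yield bit-identical samples.
    """
    if empty:
        return VirtualSample(loop=None, crystals=(), noise_level=noise_level,
                             background_level=background_level, contrast=contrast,
                             seed=seed)
    if loop is None:
        loop = LoopTruth()
    elif isinstance(loop, dict):
        loop = LoopTruth(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in loop.items()})
    xtals = []
    for i, c in enumerate(crystals):
        if isinstance(c, dict):
            c = CrystalTruth(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in c.items()})
        if not _crystal_inside_loop(c, loop):
            raise ValueError(f"crystal {i} lies outside the loop volume")
        xtals.append(c)
    return VirtualSample(loop=loop, crystals=tuple(xtals),
                         noise_level=noise_level,
                         background_level=background_level,
                         contrast=contrast, seed=seed)


def sample_from_json(path) -> VirtualSample:
    """Load a sample spec from a JSON document (see :func:`make_sample`)."""
    with open(path) as fh:
        spec = json.load(fh)
    if spec.get("empty"):
        return make_sample(empty=True)
    return make_sample(
        loop=spec.get("loop"),
        crystals=spec.get("crystals", ()),
        noise_level=spec.get("noise_level", 2.0),
        background_level=spec.get("background_level", 40.0),
        contrast=spec.get("contrast", 130.0),
        seed=spec.get("seed", 0),
    )


# ---------------------------------------------------------------------------
# microscope rendering


def _loop_mask(
    loop: LoopTruth,
    omega: float,
    y_um: np.ndarray,
    z_um: np.ndarray,
    offset: np.ndarray,
) -> np.ndarray:
    """Boolean silhouette of the loop on a lab-frame (y, z) pixel grid.

    Exact projection of the thin elliptical annulus: a pixel ray at lab
    (y, z) hits ring material iff |z - cz| <= r_out and |y - cy| falls
    between k*b_min - m and k*b_max + m, where k is the foreshortening of
    the in-plane axis, b_min/b_max the in-plane chord limits at that z and
    m the projected half-thickness of the ring slab.
    """
    phi = np.deg2rad(loop.plane_normal_angle + omega)
    k = abs(np.cos(phi))          # foreshortening of the in-plane direction
    m = 0.5 * loop.thickness * abs(np.sin(phi))  # projected slab half-height
    c = loop.ring_center + offset
    c_lab_y = float(rot2d(omega) @ c[:2] @ np.array([0.0, 1.0]))
    dz = z_um - c[2]
    dy = np.abs(y_um - c_lab_y)
    r_o, r_i, a = loop.outer_radius, loop.inner_radius, loop.aspect
    with np.errstate(invalid="ignore"):
        bmax = a * np.sqrt(np.clip(r_o ** 2 - dz ** 2, 0.0, None))
        bmin = a * np.sqrt(np.clip(r_i ** 2 - dz ** 2, 0.0, None))
    ring = (np.abs(dz) <= r_o) & (dy <= k * bmax + m) & (dy >= k * bmin - m)
    stem = (dz >= 0.7 * r_o) & (dy <= 0.5 * loop.stem_width * k + m)
    return ring | stem


def _pixel_grids(camera: Camera) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(camera.shape[0], dtype=float)[:, None]
    cols = np.arange(camera.shape[1], dtype=float)[None, :]
    bc_r, bc_c = camera.beam_center
    y_um = (bc_r - rows) * camera.pixel_size
    z_um = (cols - bc_c) * camera.pixel_size
    return y_um, z_um


def silhouette_mask(
    sample: VirtualSample,
    omega: float,
    camera: Camera,
    offset=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Ground-truth boolean silhouette of the sample loop (no noise, no blur)."""
    y_um, z_um = _pixel_grids(camera)
    if sample.loop is None:
        return np.zeros(camera.shape, dtype=bool)
    return _loop_mask(sample.loop, omega, y_um, z_um, np.asarray(offset, float))


def capture_image(
    sample: VirtualSample,
    omega: float,
    camera: Camera,
    rng: np.random.Generator | int | None = None,
    offset=(0.0, 0.0, 0.0),
) -> MicroscopeImage:
    """Render an on-axis microscope frame at spindle angle ``omega``.

    ``offset`` is the goniometer translation in sample-frame micrometres.
    ``rng=None`` renders noise-free; an integer seeds a private generator,
    so a fixed (sample, omega, seed) always yields an identical image.
    """
    mask = silhouette_mask(sample, omega, camera, offset)
    pixels = np.full(camera.shape, sample.background_level, dtype=float)
    pixels[mask] += sample.contrast
    if rng is not None and sample.noise_level > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        pixels += rng.normal(0.0, sample.noise_level, size=camera.shape)
    return MicroscopeImage(pixels=pixels, pixel_size=camera.pixel_size,
                           beam_center=camera.beam_center, omega=float(omega))


# ---------------------------------------------------------------------------
# raster diffraction response


def _interval_overlap(lo1, hi1, lo2, hi2):
    return np.clip(np.minimum(hi1, hi2) - np.maximum(lo1, lo2), 0.0, None)


def raster_response(
    sample: VirtualSample,
    grid_centers,
    omega: float,
    beam: tuple[float, float] = (10.0, 15.0),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Spot counts for beam footprints centred on sample-frame points.

    For each grid point the beam is a top-hat rectangle ``beam = (h, v)``
    micrometres in the lab (z, y) plane, extruded along the beam direction
    at angle ``omega``.  The expected count for a grid is the sum over
    crystals of ``diffraction_power`` times the fraction of the footprint
    whose rays intersect the crystal; because crystals are axis-aligned
    boxes, that fraction factorises into two 1-D overlaps.  With ``rng``
    the realised counts are Poisson draws; with ``rng=None`` the float
    expectations are returned.
    """
    h, v = beam
    if h <= 0 or v <= 0:
        raise ValueError("beam sizes must be positive")
    g = np.atleast_2d(np.asarray(grid_centers, dtype=float))
    if g.shape[-1] != 3:
        raise ValueError("grid_centers must be (N, 3) sample-frame points")
    w = np.deg2rad(omega)
    so, co = np.sin(w), np.cos(w)
    g_lab_y = g[:, 0] * so + g[:, 1] * co
    expected = np.zeros(len(g))
    for xt in sample.crystals:
        cx, cy, cz = xt.center
        hx, hy, hz = xt.half_extents
        c_lab_y = cx * so + cy * co
        half_y = hx * abs(so) + hy * abs(co)
        fz = _interval_overlap(g[:, 2] - h / 2, g[:, 2] + h / 2,
                               cz - hz, cz + hz) / h
        fy = _interval_overlap(g_lab_y - v / 2, g_lab_y + v / 2,
                               c_lab_y - half_y, c_lab_y + half_y) / v
        expected += xt.diffraction_power * fz * fy
    if rng is None:
        return expected
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.poisson(expected)


# ---------------------------------------------------------------------------
# virtual goniometer: stateful stage wrapping the pure renderers


class VirtualGoniometer:
    """Motorised stage + microscope + detector response for one sample.

    Keeps the accumulated translation (sample-frame micrometres) exactly as
    a real centring stage riding on the spindle would, and exposes the
    three measurements the planners drive: microscope captures, background
    captures and raster responses.  All randomness derives from ``seed``
    and an internal call counter, so a full run is reproducible.
    """

    def __init__(self, sample: VirtualSample, camera: Camera | None = None,
                 seed: int = 0):
        self.sample = sample
        self.camera = camera or Camera()
        self.offset = np.zeros(3)  # sample-frame translation (x, y, z) um
        self._seed = int(seed) % (2 ** 31)
        self._count = 0

    def _rng(self) -> np.random.Generator:
        self._count += 1
        return np.random.default_rng((self._seed, self._count))

    # -- measurements -------------------------------------------------
    def capture(self, omega: float, noise: bool = True) -> MicroscopeImage:
        rng = self._rng() if noise else None
        return capture_image(self.sample, omega, self.camera, rng=rng,
                             offset=self.offset)

    def background(self, omega: float = 0.0, noise: bool = True) -> MicroscopeImage:
        bare = dataclasses.replace(self.sample, loop=None, crystals=())
        rng = self._rng() if noise else None
        return capture_image(bare, omega, self.camera, rng=rng)

    def response(self, points_stage, omega: float,
                 beam: tuple[float, float] = (10.0, 15.0),
                 noise: bool = True) -> np.ndarray:
        """Raster response at stage-frame points (= sample frame + offset)."""
        pts = np.atleast_2d(np.asarray(points_stage, dtype=float)) - self.offset
        rng = self._rng() if noise else None
        return raster_response(self.sample, pts, omega, beam, rng=rng)

    # -- motion -------------------------------------------------------
    def translate_lab(self, d_y_lab: float, d_z: float, omega: float) -> None:
        """Apply a lab-frame vertical/horizontal move at the current omega."""
        self.offset[2] += d_z
        self.offset[:2] += rot2d(-omega) @ np.array([0.0, d_y_lab])

    def stage_position(self, point_sample) -> np.ndarray:
        """Stage-frame (goniometer) coordinates of a sample-frame point."""
        return np.asarray(point_sample, dtype=float) + self.offset


# ---------------------------------------------------------------------------
# canned scenarios


def scenario_fig4() -> VirtualSample:
    """A nine-crystal loop exercising every mixed-scheme category.

    With a 10 x 15 um beam (10 um horizontal / 15 um vertical grid), a
    vertical-gap multiplier of 3 and helical size limits 20-100 um, the
    construction guarantees:

    * C1 shares no rotation-axis interval with any other crystal
      (helical full rotation),
    * C2 and C3 overlap others along the axis but every vertical gap is
      at least 3 vertical beam widths, with sizes inside [20, 100]
      (partial helical),
    * C4 and C5 are likewise separated but shorter than 20 um along the
      axis (small wedge),
    * C6, C7 and C8 sit closer than 3 vertical beam widths to a
      neighbour, and C9 is separated but longer than 100 um (clustered).
    """
    loop = LoopTruth(plane_normal_angle=0.0, outer_radius=350.0,
                     inner_radius=300.0, tip_position=(0.0, 0.0, 0.0),
                     aspect=1.0)
    P = 50.0
    xt = [
        CrystalTruth((0.0, 50.0, 70.0), (5.0, 10.0, 30.0), P),    # C1
        CrystalTruth((0.0, 100.0, 190.0), (5.0, 10.0, 40.0), P),  # C2
        CrystalTruth((0.0, 220.0, 210.0), (5.0, 10.0, 40.0), P),  # C3
        CrystalTruth((0.0, -10.5, 155.0), (5.0, 9.5, 4.0), P),    # C4
        CrystalTruth((0.0, 319.5, 245.0), (5.0, 9.5, 4.0), P),    # C5
        CrystalTruth((0.0, 10.0, 330.0), (5.0, 10.0, 30.0), P),   # C6
        CrystalTruth((0.0, 60.0, 350.0), (5.0, 10.0, 30.0), P),   # C7
        CrystalTruth((0.0, 109.5, 370.0), (5.0, 9.5, 30.0), P),   # C8
        CrystalTruth((0.0, 209.0, 445.0), (5.0, 10.0, 65.0), P),  # C9
    ]
    return make_sample(loop=loop, crystals=xt, noise_level=2.0, seed=4)


def make_random_sample(
    seed: int,
    n_crystals: int = 1,
    *,
    crystal_depth_range: tuple[float, float] = (-20.0, 20.0),
    hz_range: tuple[float, float] = (15.0, 50.0),
    axis_separation: float = 30.0,
    power: float = 50.0,
) -> VirtualSample:
    """A random loop with ``n_crystals`` crystals, for recovery tests.

    The loop orientation is uniform in [0, 180); crystals are placed
    inside the ring with rotation-axis half-extents drawn from
    ``hz_range`` and mutually separated by at least ``axis_separation``
    micrometres along the axis (so segmentation keeps them apart); set
    the separation to zero for densely loaded loops.
    """
    rng = np.random.default_rng(seed)
    r_out = rng.uniform(220.0, 300.0)
    r_in = r_out - rng.uniform(50.0, 80.0)
    phi = rng.uniform(0.0, 180.0)
    loop = LoopTruth(plane_normal_angle=phi, outer_radius=r_out,
                     inner_radius=r_in, tip_position=(0.0, 0.0, 0.0),
                     aspect=rng.uniform(0.8, 1.0))
    u = loop.in_plane()
    n = loop.normal()
    crystals: list[CrystalTruth] = []
    z_intervals: list[tuple[float, float]] = []
    guard = 0
    while len(crystals) < n_crystals and guard < 5000:
        guard += 1
        hz = rng.uniform(*hz_range)
        hy = rng.uniform(7.5, 15.0)
        hx = rng.uniform(4.0, 10.0)
        dz = rng.uniform(-0.6 * r_out, 0.6 * r_out)
        du = rng.uniform(-0.5, 0.5) * r_in * loop.aspect
        dn = rng.uniform(*crystal_depth_range)
        if (dz / r_out) ** 2 + (du / (r_out * loop.aspect)) ** 2 > 0.8 ** 2:
            continue
        z = loop.ring_center[2] + dz
        if axis_separation > 0 and any(
                z - hz < hi + axis_separation and z + hz > lo - axis_separation
                for lo, hi in z_intervals):
            continue
        cxy = du * u[:2] + dn * n[:2]
        crystals.append(CrystalTruth((float(cxy[0]), float(cxy[1]), float(z)),
                                     (hx, hy, hz), power))
        z_intervals.append((z - hz, z + hz))
    return make_sample(loop=loop, crystals=crystals, noise_level=2.0,
                       seed=int(rng.integers(0, 2 ** 31)))


# ---------------------------------------------------------------------------
# synthetic detector frames for the spot finder


def make_diffraction_frame(
    geometry,
    spots,
    *,
    background: float = 5.0,
    spot_sigma: float = 1.2,
    rng: np.random.Generator | int | None = None,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render a detector frame with Gaussian spots on a Poisson background.

    ``geometry`` is a :class:`microzoo.spot_finding.DetectorGeometry`;
    ``spots`` is a sequence of ``(row, col, peak_counts)``.  No diffraction
    physics beyond radial position is modelled: the spot's d-spacing is
    whatever its radius implies under the detector geometry.
    """
    if shape is None:
        shape = geometry.shape
    frame = np.zeros(shape, dtype=float)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    for r0, c0, peak in spots:
        frame += peak * np.exp(-(((rows - r0) ** 2 + (cols - c0) ** 2)
                                 / (2.0 * spot_sigma ** 2)))
    if rng is None:
        return frame + background
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.poisson(frame + background).astype(float)
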