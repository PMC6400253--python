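"""Per-crystal data-collection planning from raster heat maps.

Three decision layers sit on top of the heat map:

* **Segmentation** — contiguous grids scoring above a threshold are one
  crystal: repeatedly take the best unassigned grid and flood-fill its
  8-connected above-threshold neighbourhood (equivalent to connected-
  component labelling, emitted in descending peak-score order).
* **Helical planning** — for each crystal take the leftmost/rightmost
  member grids along the rotation axis, rotate to the start/end scan
  angles, and locate each edge in 3-D from a vertical 1-D diffraction
  scan; the two 3-D edge points form the *helical vector*.
* **Mixed-scheme categorisation** — crystals are put into exactly one of
  four groups by their overlaps along the rotation axis and their size:
  helical full rotation (no overlap), partial helical (overlapped but
  vertically clear of every overlapping neighbour by a configurable
  multiple of the vertical beam size), small wedge (too short for
  helical) and clustered (too close vertically, or longer than the
  maximum helical size).

The serial-rotation (SS-ROX) planner derives the per-line oscillation
range from the loop length, scan step and rotation width per frame.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .spot_finding import HeatMap

__all__ = [
    "Category",
    "CrystalRegion",
    "HelicalVector",
    "SchemeAssignment",
    "MixedParams",
    "SSROXPlan",
    "EdgeNotFoundError",
    "segment_crystals",
    "region_edges",
    "helical_scan_angles",
    "locate_edge_3d",
    "plan_helical_vector",
    "categorize",
    "split_clustered",
    "plan_ssrox",
]


class EdgeNotFoundError(RuntimeError):
    """A vertical edge scan produced no score above threshold."""


class Category(str, enum.Enum):
    HELICAL_FULL = "helical_full"
    PARTIAL_HELICAL = "partial_helical"
    SMALL_WEDGE = "small_wedge"
    CLUSTERED = "clustered"


@dataclass(frozen=True)
class CrystalRegion:
    """A connected set of heat-map grids regarded as one crystal.

    Intervals are cell-edge extents in micrometres; ``size_along_axis``
    is the crystal length along the rotation axis (z interval width,
    i.e. column span plus one grid step).
    """

    members: frozenset
    member_coords: dict
    member_scores: dict
    rows: tuple[int, int]
    cols: tuple[int, int]
    z_interval: tuple[float, float]
    y_interval: tuple[float, float]
    best: tuple[int, int]
    peak_score: int
    step_h: float
    step_v: float

    @property
    def size_along_axis(self) -> float:
        return self.z_interval[1] - self.z_interval[0]

    @property
    def center(self) -> np.ndarray:
        pts = np.array([self.member_coords[m] for m in sorted(self.members)])
        return pts.mean(axis=0)

    def overlaps_axis(self, other: "CrystalRegion") -> bool:
        """Do the two regions share any grid column along the rotation axis?"""
        return (self.cols[0] <= other.cols[1]) and (other.cols[0] <= self.cols[1])

    def vertical_gap(self, other: "CrystalRegion") -> float:
        """Gap between the vertical intervals in um (0 when they overlap)."""
        return max(other.y_interval[0] - self.y_interval[1],
                   self.y_interval[0] - other.y_interval[1], 0.0)


@dataclass(frozen=True)
class HelicalVector:
    """Start/end 3-D stage coordinates of a crystal for helical collection."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    start_omega: float
    end_omega: float

    def __post_init__(self) -> None:
        if np.allclose(self.start, self.end):
            raise ValueError("helical vector must have distinct endpoints")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))


@dataclass(frozen=True)
class MixedParams:
    """User parameters of the mixed-scheme categoriser.

    ``vertical_gap_multiplier`` times the vertical beam size is the
    minimum clearance between vertically stacked crystals for quasi-3D
    edge scanning to see one crystal at a time.
    """

    min_helical: float = 20.0           # um
    max_helical: float = 100.0          # um
    vertical_gap_multiplier: float = 3.0
    vertical_beam_size: float = 15.0    # um
    full_wedge: float = 60.0            # deg per helical full rotation crystal
    partial_wedge: float = 40.0         # deg per partial helical crystal
    small_wedge: float = 5.0            # deg per small-wedge crystal

    def __post_init__(self) -> None:
        if not (0 < self.min_helical < self.max_helical):
            raise ValueError("need 0 < min_helical < max_helical")
        if self.vertical_gap_multiplier <= 0 or self.vertical_beam_size <= 0:
            raise ValueError("gap multiplier and beam size must be positive")


@dataclass(frozen=True)
class SchemeAssignment:
    region: CrystalRegion
    category: Category
    wedge_total_osc: float
    collection_points: tuple = ()
    vector: HelicalVector | None = None

    def __post_init__(self) -> None:
        if self.wedge_total_osc <= 0:
            raise ValueError("wedge_total_osc must be positive")


@dataclass(frozen=True)
class SSROXPlan:
    """Serial-rotation raster plan: one rotation scan per horizontal line."""

    n_lines: int
    frames_per_line: int
    osc_per_frame: float
    scan_step: float
    line_positions: tuple  # vertical offsets (um) below the top edge

    @property
    def total_osc_per_line(self) -> float:
        return self.frames_per_line * self.osc_per_frame

    @property
    def total_frames(self) -> int:
        return self.n_lines * self.frames_per_line


# ---------------------------------------------------------------------------
# segmentation


def _region_from_members(heatmap: HeatMap, members: set) -> CrystalRegion:
    rows = [m[0] for m in members]
    cols = [m[1] for m in members]
    r0, r1 = min(rows), max(rows)
    c0, c1 = min(cols), max(cols)
    best = max(members, key=lambda m: (heatmap.scores[m], -m[0], -m[1]))
    sh, sv = heatmap.step_h, heatmap.step_v
    # lab-vertical position of a grid: project the stage (x, y) back through
    # the spindle rotation at which the raster was taken
    w = np.deg2rad(heatmap.omega)
    so, co = np.sin(w), np.cos(w)
    y_lab = [heatmap.coords[m][0] * so + heatmap.coords[m][1] * co
             for m in members]
    z_centers = [heatmap.coords[m][2] for m in members]
    y0 = min(y_lab) - sv / 2.0
    y1 = max(y_lab) + sv / 2.0
    z0 = min(z_centers) - sh / 2.0
    z1 = max(z_centers) + sh / 2.0
    return CrystalRegion(
        members=frozenset(members),
        member_coords={m: tuple(np.asarray(heatmap.coords[m], dtype=float))
                       for m in members},
        member_scores={m: int(heatmap.scores[m]) for m in members},
        rows=(r0, r1), cols=(c0, c1),
        z_interval=(float(z0), float(z1)),
        y_interval=(float(y0), float(y1)),
        best=best, peak_score=int(heatmap.scores[best]),
        step_h=sh, step_v=sv)


def segment_crystals(heatmap: HeatMap, threshold: float = 15.0) -> list[CrystalRegion]:
    """Region-grow crystals from the heat map.

    Take the globally best unassigned grid scoring strictly above
    ``threshold``, flood-fill its 8-connected above-threshold
    neighbourhood into one region, and repeat.  The result equals the
    above-threshold connected components, ordered by descending peak
    score (ties by best-grid row then column).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    good = heatmap.scores > threshold
    unassigned = good.copy()
    regions: list[CrystalRegion] = []
    n_v, n_h = unassigned.shape
    while unassigned.any():
        flat = np.where(unassigned, heatmap.scores, -1)
        seed = np.unravel_index(int(np.argmax(flat)), flat.shape)
        stack = [seed]
        members: set = set()
        unassigned[seed] = False
        while stack:
            i, j = stack.pop()
            members.add((i, j))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ni, nj = i + di, j + dj
                    if 0 <= ni < n_v and 0 <= nj < n_h and unassigned[ni, nj]:
                        unassigned[ni, nj] = False
                        stack.append((ni, nj))
        regions.append(_region_from_members(heatmap, members))
    regions.sort(key=lambda r: (-r.peak_score, r.best[0], r.best[1]))
    return regions


def region_edges(region: CrystalRegion) -> tuple[tuple[int, int], tuple[int, int]]:
    """Leftmost and rightmost member grids along the rotation axis.

    Ties within the extreme column are broken by maximal score (the peak
    grid wins where available), then minimal row.
    """
    if not region.members:
        raise ValueError("region has no members")
    c_min = min(m[1] for m in region.members)
    c_max = max(m[1] for m in region.members)

    def pick(col):
        cands = [m for m in region.members if m[1] == col]
        cands.sort(key=lambda m: (-region.member_scores[m], m[0]))
        return cands[0]

    return pick(c_min), pick(c_max)


# ---------------------------------------------------------------------------
# helical planning


def helical_scan_angles(total_osc: float, face_angle: float) -> tuple[float, float]:
    """Start/end spindle angles for edge scans of a wedge centred on the face.

    The start-edge scan runs at ``face - total_osc/2`` and the end-edge
    scan at ``face + total_osc/2``; for total oscillations beyond 180
    degrees both offsets clamp to +/-90 degrees from the face angle.
    """
    if total_osc <= 0:
        raise ValueError("total_osc must be positive")
    half = min(total_osc / 2.0, 90.0)
    return face_angle - half, face_angle + half


def _scan_direction(omega: float) -> np.ndarray:
    """Sample-frame direction of the lab vertical axis at spindle angle omega."""
    w = np.deg2rad(omega)
    return np.array([np.sin(w), np.cos(w), 0.0])


def locate_edge_3d(
    edge_coord,
    omega: float,
    scores: Sequence[float],
    step: float,
    *,
    offsets: Sequence[float] | None = None,
    threshold: float = 0.0,
) -> np.ndarray:
    """3-D stage coordinate of a crystal edge from a vertical 1-D scan.

    ``scores`` are diffraction scores measured at positions displaced from
    ``edge_coord`` along the lab vertical direction at ``omega`` (by
    ``offsets`` micrometres, default centred multiples of ``step``).  The
    best-scoring position wins; ties take the lowest index.  If no score
    exceeds ``threshold`` the edge was not seen and the caller may fall
    back to the 2-D position.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("scores must be a nonempty 1-D sequence")
    if offsets is None:
        offsets = (np.arange(s.size) - (s.size - 1) / 2.0) * step
    offsets = np.asarray(offsets, dtype=float)
    best = int(np.argmax(s))
    if s[best] <= threshold:
        raise EdgeNotFoundError("no vertical-scan score above threshold")
    return np.asarray(edge_coord, dtype=float) + offsets[best] * _scan_direction(omega)


def _refine_edge_axis(p0, sign, face_angle, scan, step_h, refine_step,
                      threshold):
    """Fine 1-D scan along the rotation axis to pin down a crystal edge.

    The heat map localises the edge only to its grid column; a small-beam
    scan at the face angle over +/- one grid step around the edge grid
    finds the outermost scoring position in the ``sign`` direction.  The
    returned point sits half a fine step inside that position, so the
    subsequent vertical scan still grazes the crystal.
    """
    k = int(round(step_h / refine_step))
    offs = np.arange(-k, k + 1) * refine_step
    pts = p0[None, :] + offs[:, None] * np.array([0.0, 0.0, 1.0])[None, :]
    scores = np.asarray(scan(pts, face_angle), dtype=float)
    good = np.nonzero(scores > threshold)[0]
    if good.size == 0:
        return p0
    idx = good.max() if sign > 0 else good.min()
    edge_off = offs[idx] - sign * refine_step / 2.0
    return p0 + np.array([0.0, 0.0, edge_off])


def plan_helical_vector(
    region: CrystalRegion,
    face_angle: float,
    total_osc: float,
    scan: Callable[[np.ndarray, float], np.ndarray],
    *,
    scan_step: float = 5.0,
    scan_half_range: float = 40.0,
    threshold: float = 0.0,
    refine_step: float = 2.0,
    refine: bool = True,
) -> HelicalVector:
    """Determine the helical vector of one crystal via edge scans.

    ``scan(points, omega) -> scores`` performs a diffraction scan at
    stage-frame points.  Each region edge is first localised along the
    rotation axis by a fine-beam 1-D scan at the face angle (step
    ``refine_step`` micrometres; the heat-map grid only fixes the edge to
    one grid step), then scanned along the lab vertical at its wedge-end
    angle and replaced by the best-scoring 3-D position.
    """
    left, right = region_edges(region)
    om_start, om_end = helical_scan_angles(total_osc, face_angle)
    n = int(2 * round(scan_half_range / scan_step)) + 1
    offsets = (np.arange(n) - (n - 1) / 2.0) * scan_step
    ends = []
    for grid, om, sign in ((left, om_start, -1.0), (right, om_end, +1.0)):
        p0 = np.asarray(region.member_coords[grid], dtype=float)
        if refine:
            p0 = _refine_edge_axis(p0, sign, face_angle, scan,
                                   region.step_h, refine_step, threshold)
        pts = p0[None, :] + offsets[:, None] * _scan_direction(om)[None, :]
        scores = np.asarray(scan(pts, om), dtype=float)
        ends.append(locate_edge_3d(p0, om, scores, scan_step,
                                   offsets=offsets, threshold=threshold))
    return HelicalVector(start=tuple(ends[0]), end=tuple(ends[1]),
                         start_omega=float(om_start), end_omega=float(om_end))


# ---------------------------------------------------------------------------
# mixed-scheme categorisation


def categorize(
    regions: Sequence[CrystalRegion],
    params: MixedParams | None = None,
) -> list[SchemeAssignment]:
    """Assign each crystal region to exactly one mixed-scheme category.

    Per region: if no other region shares its rotation-axis interval it
    is a helical-full candidate; if every axis-overlapping neighbour is
    vertically clear by at least ``vertical_gap_multiplier`` times the
    vertical beam size it is a partial-helical candidate; otherwise it is
    clustered.  Size gates then demote helical candidates shorter than
    ``min_helical`` to small wedges and longer than ``max_helical`` to
    clustered.  The outcome is independent of region order.
    """
    params = params or MixedParams()
    min_gap = params.vertical_gap_multiplier * params.vertical_beam_size
    out: list[SchemeAssignment] = []
    for r in regions:
        neighbours = [o for o in regions if o is not r and r.overlaps_axis(o)]
        if not neighbours:
            cat = Category.HELICAL_FULL
        elif all(r.vertical_gap(o) >= min_gap for o in neighbours):
            cat = Category.PARTIAL_HELICAL
        else:
            cat = Category.CLUSTERED
        if cat in (Category.HELICAL_FULL, Category.PARTIAL_HELICAL):
            if r.size_along_axis < params.min_helical:
                cat = Category.SMALL_WEDGE
            elif r.size_along_axis > params.max_helical:
                cat = Category.CLUSTERED
        if cat is Category.HELICAL_FULL:
            wedge, points = params.full_wedge, ()
        elif cat is Category.PARTIAL_HELICAL:
            wedge, points = params.partial_wedge, ()
        elif cat is Category.SMALL_WEDGE:
            wedge, points = params.small_wedge, (r.best,)
        else:
            wedge, points = params.small_wedge, tuple(split_clustered(r))
        out.append(SchemeAssignment(region=r, category=cat,
                                    wedge_total_osc=wedge,
                                    collection_points=points))
    return out


def split_clustered(region: CrystalRegion) -> list[tuple[int, int]]:
    """Collection grids inside a clustered region.

    Grids one pixel apart vertically and horizontally are treated as
    separate crystals: members on the stride-2 lattice anchored at the
    region's best grid are kept, so no two returned grids are
    8-adjacent.
    """
    if not region.members:
        raise ValueError("region has no members")
    r0, c0 = region.best
    picks = sorted(m for m in region.members
                   if (m[0] - r0) % 2 == 0 and (m[1] - c0) % 2 == 0)
    return picks


# ---------------------------------------------------------------------------
# SS-ROX


def plan_ssrox(
    loop_h_len: float,
    loop_v_len: float,
    scan_step: float,
    osc_per_frame: float,
    v_line_spacing: float,
) -> SSROXPlan:
    """Serial-rotation raster plan over the loop extent at the face angle.

    Frames per line = ceil(horizontal length / scan step); the total
    oscillation per line is that frame count times the rotation width per
    frame; lines tile the vertical extent at ``v_line_spacing``.
    """
    if min(loop_h_len, loop_v_len, scan_step, osc_per_frame, v_line_spacing) <= 0:
        raise ValueError("all SS-ROX plan inputs must be positive")
    frames = max(1, math.ceil(loop_h_len / scan_step - 1e-9))
    n_lines = max(1, math.ceil(loop_v_len / v_line_spacing - 1e-9))
    positions = tuple((i + 0.5) * v_line_spacing for i in range(n_lines))
    return SSROXPlan(n_lines=n_lines, frames_per_line=frames,
                     osc_per_frame=float(osc_per_frame),
                     scan_step=float(scan_step), line_positions=positions)
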