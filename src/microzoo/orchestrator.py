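"""Unattended multi-sample sequencing over the virtual beamline.

Reads per-sample parameter rows (mode, wedge geometry, beam size, dose
budget, spot window, loop size, collection cap ...), then drives each pin
through the common preparation — mount, loop centering, face-angle
search, 2-D raster scan, spot scoring — followed by the scheme-specific
planning and a simulated collection, emitting one record per wedge plus a
timestamped run log.  A pin whose loop is not found yields a ``no_loop``
record and the run continues: unattended operation never stops on a bad
pin.  The goniometer position of a found loop is remembered and reused as
the starting position for the next pin of the same puck.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dose_planner, loop_centering, scheme_planner, spot_finding
from .scheme_planner import Category, MixedParams
from .virtual_beamline import Camera, VirtualGoniometer, VirtualSample

__all__ = [
    "ZooParams",
    "RasterGrid",
    "CollectionRecord",
    "RunResult",
    "PlanError",
    "MODES",
    "load_plan",
    "build_raster_grid",
    "run_sample",
    "run_zoo",
    "write_report",
    "read_report",
]

MODES = ("single", "multi", "helical", "ssrox", "mixed")

TIMING_JITTER_S = 0.002  # trigger/motion synchronisation jitter bound


class PlanError(ValueError):
    """A plan file row failed validation; the message names row and field."""


@dataclass(frozen=True)
class ZooParams:
    """One plan-file row: everything needed to process one group of pins."""

    mode: str = "multi"
    puck_id: str = "CPS1974"
    pins: tuple[int, ...] = (1,)
    total_osc: float = 5.0          # deg per wedge
    osc_width: float = 0.1          # deg per frame
    raster_exposure: float = 0.02   # s per raster frame
    beam_h: float = 10.0            # um
    beam_v: float = 15.0            # um
    dose_budget: float = dose_planner.DEFAULT_DOSE_BUDGET  # MGy per wedge
    exposure_per_frame: float = 0.05  # s, user-preferred collection exposure
    camera_distance: float = 200.0  # mm
    loop_size: float = 600.0        # um
    spot_min: int = 15
    spot_max: int = 100
    data_directory: str = "./data"
    data_name: str = "multi"
    max_collections: int = 100
    mixed: MixedParams = field(default_factory=MixedParams)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise PlanError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.osc_width <= 0 or self.total_osc <= 0:
            raise PlanError("oscillation width and total must be positive")
        n = self.total_osc / self.osc_width
        if abs(n - round(n)) > 1e-6:
            raise PlanError("osc_width must divide total_osc")
        if self.max_collections < 1:
            raise PlanError("max_collections must be >= 1")
        if self.beam_h <= 0 or self.beam_v <= 0:
            raise PlanError("beam sizes must be positive")
        if self.spot_min > self.spot_max:
            raise PlanError("spot window must satisfy min <= max")

    @property
    def frames_per_wedge(self) -> int:
        return int(round(self.total_osc / self.osc_width))


@dataclass(frozen=True)
class RasterGrid:
    """A raster area plus the scan timing that acquires it."""

    area: loop_centering.RasterArea
    frame_rate: float               # Hz
    serpentine: bool = True

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def scan_speed(self) -> float:
        """Goniometer translation speed along a line, um/s."""
        return self.area.step_h * self.frame_rate

    @property
    def total_frames(self) -> int:
        return self.area.n_h * self.area.n_v

    @property
    def position_error_bound(self) -> float:
        """Worst-case positional error (um) from trigger timing jitter."""
        return TIMING_JITTER_S * self.scan_speed


@dataclass
class CollectionRecord:
    """One simulated collection (or a terminal status) for one crystal."""

    sample_id: str
    crystal_id: str
    scheme: str
    status: str = "collected"
    start_omega: float | None = None
    end_omega: float | None = None
    n_frames: int | None = None
    exposure: dose_planner.ExposurePlan | None = None
    grid: list | None = None        # [row, col] on the heat map
    vector: dict | None = None      # helical vector as plain lists

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CollectionRecord":
        d = dict(d)
        if d.get("exposure") is not None:
            d["exposure"] = dose_planner.ExposurePlan(**d["exposure"])
        return cls(**d)


@dataclass
class RunResult:
    """Records plus the run log and intermediate products, for inspection."""

    records: list
    log: list
    heatmap: spot_finding.HeatMap | None = None
    centering: loop_centering.CenteringResult | None = None
    assignments: list | None = None


# ---------------------------------------------------------------------------
# plan files

_TABLE_HEADERS = {
    "mode": "mode",
    "puck id": "puck_id",
    "pin id": "pins",
    "total oscillation per wedge": "total_osc",
    "oscillation width": "osc_width",
    "exposure time for raster scan": "raster_exposure",
    "beam size": "beam",
    "dose per wedge": "dose_budget",
    "exposure time for data collection": "exposure_per_frame",
    "camera distance": "camera_distance",
    "loop size": "loop_size",
    "no. of spots for good crystals": "spot_window",
    "data directory": "data_directory",
    "data name": "data_name",
    "maximum no. of data collections per loop": "max_collections",
}

_MODE_ALIASES = {
    "single": "single", "normal": "single", "normal rotation": "single",
    "multi": "multi", "small wedge": "multi", "small-wedge": "multi",
    "multiple small-wedge": "multi",
    "helical": "helical",
    "ssrox": "ssrox", "ss-rox": "ssrox",
    "mixed": "mixed",
}


def _canon_header(h: str) -> str:
    h = re.sub(r"\(.*?\)", "", str(h)).strip().lower()
    return re.sub(r"\s+", " ", h)


def _parse_pins(value) -> tuple[int, ...]:
    if isinstance(value, (list, tuple)):
        return tuple(int(v) for v in value)
    s = str(value).strip()
    m = re.fullmatch(r"(\d+)\s*[-–]\s*(\d+)", s)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        return tuple(range(a, b + 1))
    return tuple(int(p) for p in re.split(r"[,;]\s*", s))


def _parse_beam(value) -> tuple[float, float]:
    if isinstance(value, (list, tuple)):
        return float(value[0]), float(value[1])
    nums = re.findall(r"[\d.]+", str(value))
    if len(nums) < 2:
        raise ValueError("beam size needs horizontal and vertical values")
    return float(nums[0]), float(nums[1])


def _parse_window(value) -> tuple[int, int]:
    if isinstance(value, (list, tuple)):
        return int(value[0]), int(value[1])
    nums = re.findall(r"\d+", str(value))
    if len(nums) < 2:
        raise ValueError("spot window needs lower and upper bounds")
    return int(nums[0]), int(nums[1])


def _row_to_params(row: dict, row_idx: int) -> ZooParams:
    kw: dict = {}
    for key, value in row.items():
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        name = _TABLE_HEADERS.get(_canon_header(key), key if key in
                                  ZooParams.__dataclass_fields__ else None)
        if name is None:
            continue
        try:
            if name == "mode":
                mode = _MODE_ALIASES.get(str(value).strip().lower())
                if mode is None:
                    raise ValueError(f"unknown mode {value!r}")
                kw["mode"] = mode
            elif name == "pins":
                kw["pins"] = _parse_pins(value)
            elif name == "beam":
                kw["beam_h"], kw["beam_v"] = _parse_beam(value)
            elif name == "spot_window":
                kw["spot_min"], kw["spot_max"] = _parse_window(value)
            elif name in ("puck_id", "data_directory", "data_name"):
                kw[name] = str(value)
            elif name == "max_collections":
                kw[name] = int(value)
            elif name == "mixed":
                kw[name] = MixedParams(**value) if isinstance(value, dict) else value
            else:
                kw[name] = float(value)
        except (TypeError, ValueError) as exc:
            raise PlanError(f"row {row_idx}: field {key!r}: {exc}") from exc
    try:
        return ZooParams(**kw)
    except PlanError as exc:
        raise PlanError(f"row {row_idx}: {exc}") from exc


def load_plan(path) -> list[ZooParams]:
    """Read a plan file (CSV with the standard headers, or JSON list)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            rows = [rows]
    else:
        df = pd.read_csv(path)
        rows = df.to_dict(orient="records")
    if not rows:
        raise PlanError("plan file contains no rows")
    return [_row_to_params(r, i) for i, r in enumerate(rows)]


# ---------------------------------------------------------------------------
# raster timing


def build_raster_grid(area: loop_centering.RasterArea,
                      frame_rate: float = 50.0,
                      serpentine: bool = True) -> RasterGrid:
    """Attach scan timing to a raster area.

    The grid step equals the beam size (set upstream); the translation
    speed is step times frame rate — e.g. a 10 um grid at 50 Hz scans at
    500 um/s.
    """
    return RasterGrid(area=area, frame_rate=float(frame_rate),
                      serpentine=serpentine)


# ---------------------------------------------------------------------------
# per-sample sequencing


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def _acquisition_order_scores(gonio, grid: RasterGrid, beam, noise=True):
    """Raster scores in serpentine acquisition order (flat list)."""
    pts = grid.area.grid_centers_stage()
    order = []
    for i in range(grid.area.n_v):
        cols = range(grid.area.n_h)
        if grid.serpentine and i % 2 == 1:
            cols = reversed(list(cols))
        order.extend((i, j) for j in cols)
    flat = np.array([pts[i, j] for i, j in order])
    scores = gonio.response(flat, grid.area.omega, beam, noise=noise)
    return np.rint(scores).astype(int)


def _beam_params(params: ZooParams,
                 flux_density: float = 1e10) -> dose_planner.BeamParams:
    return dose_planner.BeamParams.from_flux_density(
        flux_density, params.beam_h, params.beam_v)


def _wedge_record(sample_id, crystal_id, scheme, face, total_osc, params,
                  beam, *, grid=None, vector=None, n_frames=None,
                  vector_length=None) -> CollectionRecord:
    n = n_frames or max(1, int(round(total_osc / params.osc_width)))
    if vector is not None:
        plan = dose_planner.suggest_exposure(
            "helical", beam, params.dose_budget, n_frames=n,
            vector_length=vector_length)
    else:
        plan = dose_planner.suggest_exposure(
            "stationary", beam, params.dose_budget, n_frames=n)
    start, end = face - total_osc / 2.0, face + total_osc / 2.0
    return CollectionRecord(
        sample_id=sample_id, crystal_id=crystal_id, scheme=scheme,
        start_omega=float(start), end_omega=float(end), n_frames=n,
        exposure=plan, grid=grid, vector=vector)


def _vector_dict(vec: scheme_planner.HelicalVector) -> dict:
    return {"start": [float(v) for v in vec.start],
            "end": [float(v) for v in vec.end],
            "start_omega": float(vec.start_omega),
            "end_omega": float(vec.end_omega)}


def run_sample(
    params: ZooParams,
    sample: VirtualSample | None,
    *,
    sample_id: str = "pin1",
    camera: Camera | None = None,
    seed: int = 0,
    gonio: VirtualGoniometer | None = None,
    frame_rate: float = 50.0,
    segment_threshold: float | None = None,
) -> RunResult:
    """Run one pin through its full collection sequence.

    Returns collection records, the run log and intermediate products.
    ``sample=None`` (or an empty pin) exercises the loop-not-found path.
    ``gonio`` may be supplied to keep a previous pin's stage position.
    """
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(f"{_now()} {msg}")

    if sample is None:
        sample = VirtualSample(loop=None, crystals=())
    if gonio is None:
        gonio = VirtualGoniometer(sample, camera, seed=seed)
    else:
        gonio.sample = sample
    say(f"{sample_id}: mounted (mode={params.mode})")

    background = gonio.background(0.0)
    result, area = loop_centering.center_loop(
        gonio, background, beam=(params.beam_h, params.beam_v),
        user_loop_size=params.loop_size)
    if not result.converged or area is None:
        say(f"{sample_id}: loop not found; skipping pin")
        rec = CollectionRecord(sample_id=sample_id, crystal_id="-",
                               scheme=params.mode, status="no_loop")
        return RunResult(records=[rec], log=log, centering=result)
    face = result.face_angle
    say(f"{sample_id}: centered, face angle {face:.1f} deg")

    grid = build_raster_grid(area, frame_rate)
    say(f"{sample_id}: raster {area.n_v}x{area.n_h} grids, "
        f"{grid.scan_speed:.0f} um/s, jitter position error "
        f"<= {grid.position_error_bound:.2f} um")
    scores = _acquisition_order_scores(gonio, grid,
                                       (params.beam_h, params.beam_v))
    heatmap = spot_finding.assemble_heatmap(
        scores, area, serpentine=grid.serpentine,
        provenance={"spot_min": params.spot_min, "spot_max": params.spot_max})
    say(f"{sample_id}: heat map max score {int(heatmap.scores.max())}")

    beam = _beam_params(params)
    threshold = segment_threshold if segment_threshold is not None \
        else float(params.spot_min)
    records: list[CollectionRecord] = []
    assignments = None

    def scan(points, omega):
        return gonio.response(points, omega, (2.0, 5.0))

    if params.mode in ("single", "multi"):
        picks = spot_finding.select_crystal_grids(
            heatmap, params.spot_min, params.spot_max,
            min_distance=max(params.beam_h, params.beam_v))
        if params.mode == "single":
            picks = picks[:1]
        for k, (i, j) in enumerate(picks):
            if len(records) >= params.max_collections:
                say(f"{sample_id}: collection cap reached")
                break
            records.append(_wedge_record(
                sample_id, f"xtal{k:03d}", "small_wedge", face,
                params.total_osc, params, beam, grid=[int(i), int(j)]))
    elif params.mode == "helical":
        regions = scheme_planner.segment_crystals(heatmap, threshold)
        for k, region in enumerate(regions):
            if len(records) >= params.max_collections:
                break
            try:
                vec = scheme_planner.plan_helical_vector(
                    region, face, params.total_osc, scan, threshold=threshold)
            except scheme_planner.EdgeNotFoundError:
                say(f"{sample_id}: crystal {k} lost at vertical scan; skipped")
                records.append(CollectionRecord(
                    sample_id=sample_id, crystal_id=f"xtal{k:03d}",
                    scheme="helical", status="edge_not_found"))
                continue
            records.append(_wedge_record(
                sample_id, f"xtal{k:03d}", "helical", face, params.total_osc,
                params, beam, vector=_vector_dict(vec),
                vector_length=vec.length))
    elif params.mode == "ssrox":
        plan = scheme_planner.plan_ssrox(
            area.width, area.height, params.beam_h, params.osc_width,
            params.beam_v)
        exposure = dose_planner.suggest_exposure(
            "ssrox", beam, params.dose_budget,
            n_frames=plan.frames_per_line, scan_step=plan.scan_step)
        records.append(CollectionRecord(
            sample_id=sample_id, crystal_id="loop", scheme="ssrox",
            start_omega=float(face - plan.total_osc_per_line / 2.0),
            end_omega=float(face + plan.total_osc_per_line / 2.0),
            n_frames=plan.total_frames, exposure=exposure))
        say(f"{sample_id}: ssrox {plan.n_lines} lines x "
            f"{plan.frames_per_line} frames, {plan.total_osc_per_line:.1f} "
            f"deg per line")
    elif params.mode == "mixed":
        regions = scheme_planner.segment_crystals(heatmap, threshold)
        assignments = scheme_planner.categorize(regions, params.mixed)
        for k, asg in enumerate(assignments):
            if len(records) >= params.max_collections:
                break
            cid = f"xtal{k:03d}"
            if asg.category in (Category.HELICAL_FULL, Category.PARTIAL_HELICAL):
                try:
                    vec = scheme_planner.plan_helical_vector(
                        asg.region, face, asg.wedge_total_osc, scan,
                        threshold=threshold)
                except scheme_planner.EdgeNotFoundError:
                    records.append(CollectionRecord(
                        sample_id=sample_id, crystal_id=cid,
                        scheme=asg.category.value, status="edge_not_found"))
                    continue
                records.append(_wedge_record(
                    sample_id, cid, asg.category.value, face,
                    asg.wedge_total_osc, params, beam,
                    vector=_vector_dict(vec), vector_length=vec.length))
            else:
                for p, (i, j) in enumerate(asg.collection_points):
                    if len(records) >= params.max_collections:
                        break
                    records.append(_wedge_record(
                        sample_id, f"{cid}.{p}", asg.category.value, face,
                        asg.wedge_total_osc, params, beam,
                        grid=[int(i), int(j)]))
    say(f"{sample_id}: {len(records)} record(s)")
    return RunResult(records=records, log=log, heatmap=heatmap,
                     centering=result, assignments=assignments)


def run_zoo(
    plan: list[ZooParams],
    samples: dict,
    *,
    camera: Camera | None = None,
    seed: int = 0,
) -> RunResult:
    """Process every pin of every plan row; samples maps (puck, pin) -> sample.

    The stage position of the previous successfully found loop carries
    over to the next pin of the same puck, mimicking the saved loop
    position that shortens subsequent searches.
    """
    records: list[CollectionRecord] = []
    log: list[str] = []
    for r, params in enumerate(plan):
        saved_offset = None
        for pin in params.pins:
            sample = samples.get((params.puck_id, pin))
            sid = f"{params.puck_id}-{pin:02d}"
            gonio = VirtualGoniometer(
                sample if sample is not None else VirtualSample(loop=None),
                camera, seed=(seed + 1000 * r + pin) % (2 ** 31))
            if saved_offset is not None:
                gonio.offset = saved_offset.copy()
            res = run_sample(params, sample, sample_id=sid, camera=camera,
                             seed=seed, gonio=gonio)
            if res.centering is not None and res.centering.converged:
                saved_offset = gonio.offset.copy()
            records.extend(res.records)
            log.extend(res.log)
    return RunResult(records=records, log=log)


# ---------------------------------------------------------------------------
# reports


def write_report(records, path, log=None) -> None:
    """Write collection records (and optionally the run log) as JSON."""
    doc = {"records": [r.to_dict() for r in records]}
    if log is not None:
        doc["log"] = list(log)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_report(path) -> list:
    """Read records back; ``read(write(r)) == r``."""
    with open(path) as fh:
        doc = json.load(fh)
    return [CollectionRecord.from_dict(d) for d in doc["records"]]
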