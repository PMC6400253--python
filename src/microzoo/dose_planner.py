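"""Absorbed-dose estimation and exposure-condition suggestion.

A transparent thin-crystal absorption model: the dose deposited by a
top-hat beam is

    dose [Gy] = fluence [ph / m^2] * E_photon [J] * (mu_en / rho) [m^2 / kg]

with fluence = flux * transmission * time / beam area.  The model is
linear in flux, transmission and exposure time, which makes inverting it
for a user dose budget exact.  Photoelectron escape from micron-sized
irradiated volumes is deliberately not modelled; instead an empirical
radiation-damage propagation length can smear a computed dose profile
with a Gaussian of that sigma (:func:`spread_damage`).

For translating schemes (helical, serial rotation) neighbouring frames
re-irradiate overlapping crystal volume; :func:`helical_dose_profile`
accumulates per-frame top-hat footprints along the travel axis on a
0.1 um sampling, whose interior plateau equals the per-frame dose times
the number of overlapping footprints.

The default budget, when none is given, is 10 MGy per wedge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "BeamParams",
    "DoseModelParams",
    "ExposurePlan",
    "DoseBudgetError",
    "DEFAULT_DOSE_BUDGET",
    "stationary_dose",
    "helical_dose_profile",
    "translation_dose_profile",
    "spread_damage",
    "suggest_exposure",
    "estimate_plan_dose",
]

DEFAULT_DOSE_BUDGET = 10.0  # MGy

_KEV_TO_J = 1.602176634e-16
_PROFILE_DX = 0.1  # um sampling of accumulated dose profiles


class DoseBudgetError(ValueError):
    """The requested dose budget cannot be met; names the binding constraint."""


@dataclass(frozen=True)
class BeamParams:
    """X-ray beam at the sample position.

    ``flux`` is photons/s through the full (unattenuated) beam;
    ``transmission`` is the attenuator setting actually applied.
    """

    size_h: float = 10.0        # um
    size_v: float = 15.0        # um
    flux: float = 1.5e12        # ph/s at transmission 1
    photon_energy: float = 12.398  # keV (1.0 Angstrom)
    transmission: float = 1.0

    def __post_init__(self) -> None:
        if self.size_h <= 0 or self.size_v <= 0:
            raise ValueError("beam sizes must be positive")
        if self.flux < 0:
            raise ValueError("flux must be >= 0")
        if not (0 < self.transmission <= 1):
            raise ValueError("transmission must be in (0, 1]")
        if self.photon_energy <= 0:
            raise ValueError("photon energy must be positive")

    @classmethod
    def from_flux_density(cls, flux_density: float, size_h: float,
                          size_v: float, photon_energy: float = 12.398,
                          transmission: float = 1.0) -> "BeamParams":
        """Build from a flux density in photons um^-2 s^-1."""
        return cls(size_h=size_h, size_v=size_v,
                   flux=flux_density * size_h * size_v,
                   photon_energy=photon_energy, transmission=transmission)

    @property
    def area_m2(self) -> float:
        return self.size_h * self.size_v * 1e-12


@dataclass(frozen=True)
class DoseModelParams:
    """Material constants of the absorption model.

    ``mu_en_over_rho`` defaults to a typical aqueous protein crystal near
    12.4 keV.  ``density`` does not enter the thin-sample dose (energy per
    unit mass) but is kept for completeness.  ``propagation_length`` is
    the Gaussian sigma by which deposited dose effectively spreads
    through radiation-damage propagation.
    """

    mu_en_over_rho: float = 0.25     # m^2 / kg
    density: float = 1200.0          # kg / m^3
    propagation_length: float = 0.0  # um

    def __post_init__(self) -> None:
        if self.mu_en_over_rho <= 0 or self.density <= 0:
            raise ValueError("material constants must be positive")
        if self.propagation_length < 0:
            raise ValueError("propagation length must be >= 0")


@dataclass(frozen=True)
class ExposurePlan:
    """Exposure conditions meeting a dose budget for one scheme."""

    exposure_time: float        # s per frame
    transmission: float
    estimated_dose: float       # MGy, peak over the crystal
    scheme: str
    dose_budget: float          # MGy

    def __post_init__(self) -> None:
        if self.estimated_dose > self.dose_budget * (1 + 1e-6):
            raise ValueError("estimated dose exceeds the budget")


# ---------------------------------------------------------------------------


def stationary_dose(beam: BeamParams, exposure_total: float,
                    model: DoseModelParams | None = None) -> float:
    """Peak dose (MGy) for a stationary top-hat beam over ``exposure_total`` s."""
    if exposure_total < 0:
        raise ValueError("exposure_total must be >= 0")
    model = model or DoseModelParams()
    fluence = beam.flux * beam.transmission * exposure_total / beam.area_m2
    dose_gy = fluence * beam.photon_energy * _KEV_TO_J * model.mu_en_over_rho
    return dose_gy / 1e6


def translation_dose_profile(
    travel_length: float,
    beam_width_along_travel: float,
    per_frame_dose: float,
    n_frames: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated dose along a uniformly translating top-hat beam.

    The beam centre advances ``travel_length / n_frames`` per frame
    (frame i centred at ``(i + 1/2)`` steps); each frame deposits
    ``per_frame_dose`` inside its footprint.  Returns positions (um,
    0 at travel start) and the dose profile sampled every 0.1 um.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if beam_width_along_travel <= 0:
        raise ValueError("beam width must be positive")
    w = beam_width_along_travel
    step = travel_length / n_frames
    lo = -w
    hi = travel_length + w
    x = np.arange(lo, hi + _PROFILE_DX / 2, _PROFILE_DX)
    bump = np.zeros(x.size + 1)
    for i in range(n_frames):
        c = (i + 0.5) * step
        a = np.searchsorted(x, c - w / 2.0, side="left")
        b = np.searchsorted(x, c + w / 2.0, side="right")
        bump[a] += per_frame_dose
        bump[b] -= per_frame_dose
    profile = np.cumsum(bump[:-1])
    return x, profile


def helical_dose_profile(
    vector,
    beam: BeamParams,
    frame_time: float,
    n_frames: int,
    model: DoseModelParams | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Dose profile along a helical vector and its peak (MGy).

    The beam centre translates uniformly from the vector start to its end
    over ``n_frames`` frames; each frame contributes the stationary
    per-frame dose inside its top-hat footprint.  The footprint width
    along the travel direction interpolates between the horizontal and
    vertical beam sizes according to the travel direction's inclination
    to the rotation axis.
    """
    model = model or DoseModelParams()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    start = np.asarray(vector.start, dtype=float)
    end = np.asarray(vector.end, dtype=float)
    travel = end - start
    length = float(np.linalg.norm(travel))
    if length <= 0:
        raise ValueError("zero-length helical vector")
    # fraction of travel along the rotation axis selects the beam width
    fz = abs(travel[2]) / length
    width = fz * beam.size_h + (1 - fz) * beam.size_v
    per_frame = stationary_dose(beam, frame_time, model)
    x, profile = translation_dose_profile(length, width, per_frame, n_frames)
    return x, profile, float(profile.max())


def spread_damage(
    positions: np.ndarray,
    profile: np.ndarray,
    model: DoseModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve a dose profile with the damage-propagation Gaussian.

    The support is extended by six sigma on both sides so the integrated
    dose is conserved; a zero propagation length returns the input
    unchanged.
    """
    sigma = model.propagation_length
    if sigma == 0:
        return positions, profile
    dx = float(positions[1] - positions[0])
    pad = int(math.ceil(6 * sigma / dx))
    ext = np.pad(profile, pad)
    out = gaussian_filter1d(ext, sigma / dx, mode="constant", truncate=8.0)
    x = np.arange(-pad, profile.size + pad) * dx + positions[0]
    return x, out


# ---------------------------------------------------------------------------
# inversion


def _peak_dose_per_second(scheme: str, beam: BeamParams,
                          model: DoseModelParams, *, n_frames: int,
                          vector_length: float | None,
                          scan_step: float | None) -> float:
    """Peak dose rate (MGy per second of per-frame exposure)."""
    if scheme == "stationary":
        # the whole wedge irradiates the same volume
        return stationary_dose(beam, float(n_frames), model)
    if scheme == "helical":
        if vector_length is None or vector_length <= 0:
            raise ValueError("helical scheme needs a positive vector length")
        vec = _Line(vector_length)
        _, _, peak = helical_dose_profile(vec, beam, 1.0, n_frames, model)
        return peak
    if scheme == "ssrox":
        if scan_step is None or scan_step <= 0:
            raise ValueError("ssrox scheme needs a positive scan step")
        per_frame = stationary_dose(beam, 1.0, model)
        _, profile = translation_dose_profile(n_frames * scan_step,
                                              beam.size_h, per_frame, n_frames)
        return float(profile.max())
    raise ValueError(f"unknown dose scheme {scheme!r}")


class _Line:
    """Minimal stand-in vector along the rotation axis of a given length."""

    def __init__(self, length: float):
        self.start = (0.0, 0.0, 0.0)
        self.end = (0.0, 0.0, float(length))


def suggest_exposure(
    scheme: str,
    beam: BeamParams,
    budget: float = DEFAULT_DOSE_BUDGET,
    *,
    n_frames: int = 1,
    vector_length: float | None = None,
    scan_step: float | None = None,
    model: DoseModelParams | None = None,
    solve_for: str = "time",
    min_exposure: float = 0.0,
    max_exposure: float | None = None,
) -> ExposurePlan:
    """Exposure conditions whose peak dose meets ``budget`` MGy exactly.

    With ``solve_for="time"`` the maximal per-frame exposure time at the
    beam's transmission is returned; with ``solve_for="transmission"``
    the maximal transmission at the beam's nominal 1 s exposure (capped
    at 1).  Because the dose model is linear the returned plan
    re-estimates to the budget exactly when unconstrained.
    """
    if budget <= 0:
        raise DoseBudgetError("dose budget must be positive")
    model = model or DoseModelParams()
    rate = _peak_dose_per_second(scheme, beam, model, n_frames=n_frames,
                                 vector_length=vector_length,
                                 scan_step=scan_step)
    if rate <= 0:
        raise DoseBudgetError("beam delivers no dose; check flux/transmission")
    if solve_for == "time":
        t = budget / rate
        if t < min_exposure:
            raise DoseBudgetError(
                f"budget {budget} MGy requires {t:.3g} s/frame, below the "
                f"minimum exposure time {min_exposure} s")
        if max_exposure is not None and t > max_exposure:
            t = max_exposure
        dose = rate * t
        return ExposurePlan(exposure_time=float(t),
                            transmission=beam.transmission,
                            estimated_dose=float(dose), scheme=scheme,
                            dose_budget=float(budget))
    if solve_for == "transmission":
        # rate scales linearly with transmission; rescale to transmission 1
        rate_full = rate / beam.transmission
        tr = min(1.0, budget / rate_full)
        dose = rate_full * tr
        return ExposurePlan(exposure_time=1.0, transmission=float(tr),
                            estimated_dose=float(dose), scheme=scheme,
                            dose_budget=float(budget))
    raise ValueError("solve_for must be 'time' or 'transmission'")


def estimate_plan_dose(
    plan: ExposurePlan,
    beam: BeamParams,
    *,
    n_frames: int = 1,
    vector_length: float | None = None,
    scan_step: float | None = None,
    model: DoseModelParams | None = None,
) -> float:
    """Re-estimate the peak dose (MGy) a plan would deposit (round-trip check)."""
    model = model or DoseModelParams()
    b = replace(beam, transmission=plan.transmission)
    rate = _peak_dose_per_second(plan.scheme, b, model, n_frames=n_frames,
                                 vector_length=vector_length,
                                 scan_step=scan_step)
    return rate * plan.exposure_time
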