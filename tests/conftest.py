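import numpy as np
import pytest

from microzoo import loop_centering as lc
from microzoo import spot_finding as sf
from microzoo import virtual_beamline as vb


@pytest.fixture(scope="session")
def camera():
    return vb.Camera(shape=(288, 384), pixel_size=4.0)


@pytest.fixture(scope="session")
def fig4_pipeline(camera):
    """Centering + raster + heat map for the nine-crystal scenario, run once."""
    sample = vb.scenario_fig4()
    gonio = vb.VirtualGoniometer(sample, camera, seed=1)
    background = gonio.background(0.0)
    result, area = lc.center_loop(gonio, background, beam=(10.0, 15.0),
                                  user_loop_size=600.0)
    pts = area.grid_centers_stage().reshape(-1, 3)
    scores = gonio.response(pts, result.face_angle, (10.0, 15.0))
    heatmap = sf.assemble_heatmap(scores, area)
    return {"sample": sample, "gonio": gonio, "centering": result,
            "area": area, "heatmap": heatmap}


@pytest.fixture(scope="session")
def small_detector():
    return sf.DetectorGeometry(pixel_size=0.5, beam_center=(32.0, 32.0),
                               camera_distance=80.0, wavelength=1.0,
                               shape=(64, 64))


def simple_heatmap(scores, step_h=10.0, step_v=15.0, omega=0.0):
    """Heat map at omega with grid (0, 0) centred at the origin."""
    scores = np.asarray(scores, dtype=int)
    n_v, n_h = scores.shape
    area = lc.RasterArea(origin_y_lab=0.0, origin_z=0.0, n_h=n_h, n_v=n_v,
                         step_h=step_h, step_v=step_v, omega=omega)
    return sf.assemble_heatmap(scores.ravel(), area)
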