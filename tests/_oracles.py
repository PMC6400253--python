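"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by a deliberately different route from
the library code (ray sampling instead of analytic overlap, pure-Python
per-pixel scans instead of vectorised bincounts, direct per-frame box
addition instead of cumulative difference arrays), so agreement is a
meaningful check and not a tautology.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def ray_overlap_fraction(grid_center, omega, beam, crystal, dx=0.1):
    """Fraction of the beam footprint whose rays hit a crystal box.

    Samples the top-hat footprint on a ``dx`` micrometre raster; each
    sample casts a ray along the beam direction at spindle angle
    ``omega`` and tests 2-D line/rectangle intersection in the sample
    frame (slab method).  Independent of the analytic 1-D overlap
    factorisation used by the implementation.
    """
    h, v = beam
    gx, gy, gz = grid_center
    w = math.radians(omega)
    so, co = math.sin(w), math.cos(w)
    g_lab_y = gx * so + gy * co
    nz = max(2, int(round(h / dx)))
    ny = max(2, int(round(v / dx)))
    z = gz + (np.arange(nz) + 0.5) / nz * h - h / 2
    y = g_lab_y + (np.arange(ny) + 0.5) / ny * v - v / 2
    cx, cy, cz = crystal.center
    hx, hy, hz = crystal.half_extents
    in_z = (z >= cz - hz) & (z <= cz + hz)
    # ray through lab (x_lab, y_lab): sample point p0 + t*d
    # p0 = R(-w) @ (0, y_lab), d = R(-w) @ (1, 0)
    dxs, dys = co, -so
    p0x = so * y
    p0y = co * y
    eps = 1e-12
    t_lo = np.full(y.shape, -np.inf)
    t_hi = np.full(y.shape, np.inf)
    hit = np.ones(y.shape, dtype=bool)
    for p0, d, c, half in ((p0x, dxs, cx, hx), (p0y, dys, cy, hy)):
        if abs(d) < eps:
            hit &= np.abs(p0 - c) <= half
        else:
            t1 = (c - half - p0) / d
            t2 = (c + half - p0) / d
            t_lo = np.maximum(t_lo, np.minimum(t1, t2))
            t_hi = np.minimum(t_hi, np.maximum(t1, t2))
    hit &= t_lo <= t_hi
    return float(in_z.mean() * hit.mean())


def expected_response(grid_center, omega, beam, crystals, dx=0.1):
    return sum(c.diffraction_power
               * ray_overlap_fraction(grid_center, omega, beam, c, dx)
               for c in crystals)


# ---------------------------------------------------------------------------


def brute_find_spots(frame, geometry, *, adc_threshold=10.0, min_snr=6.0,
                     min_pix=3, max_pix=100, bin_width=1.0, n_iterations=2):
    """Pure-Python per-pixel spot finder mirroring the algorithm definition.

    Radial bins, a median/MAD first background pass, ``n_iterations``
    mean/sigma refinements over unflagged pixels, SNR + ADC gating, BFS
    8-connected agglomeration and pixel-count gating.  Returns a list of
    (centroid_row, centroid_col, n_pixels) sorted by centroid.
    """
    frame = np.asarray(frame, dtype=float)
    H, W = frame.shape
    bc_r, bc_c = geometry.beam_center
    binned: dict[int, list] = {}
    bin_of = {}
    for i in range(H):
        for j in range(W):
            b = int(math.hypot(i - bc_r, j - bc_c) / bin_width)
            binned.setdefault(b, []).append((i, j))
            bin_of[(i, j)] = b

    med, sig = {}, {}
    for b, pix in binned.items():
        vals = [frame[p] for p in pix]
        m = statistics.median(vals)
        med[b] = m
        sig[b] = 1.4826 * statistics.median([abs(v - m) for v in vals])

    def flag(mean, sigma):
        return {(i, j) for i in range(H) for j in range(W)
                if frame[i, j] > mean[bin_of[(i, j)]]
                + min_snr * sigma[bin_of[(i, j)]]}

    signal = flag(med, sig)
    mean, sigma = med, sig
    for _ in range(n_iterations):
        mean, sigma = {}, {}
        for b, pix in binned.items():
            vals = [frame[p] for p in pix if p not in signal]
            if not vals:
                mean[b], sigma[b] = 0.0, 0.0
                continue
            m = sum(vals) / len(vals)
            var = sum(v * v for v in vals) / len(vals) - m * m
            mean[b] = m
            sigma[b] = math.sqrt(max(var, 0.0))
        new_signal = flag(mean, sigma)
        if new_signal == signal:
            break
        signal = new_signal

    candidates = {(i, j) for i in range(H) for j in range(W)
                  if frame[i, j] > mean[bin_of[(i, j)]]
                  + min_snr * sigma[bin_of[(i, j)]]
                  and frame[i, j] > adc_threshold}
    seen = set()
    spots = []
    for p in sorted(candidates):
        if p in seen:
            continue
        comp = [p]
        seen.add(p)
        queue = [p]
        while queue:
            i, j = queue.pop()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    q = (i + di, j + dj)
                    if q in candidates and q not in seen:
                        seen.add(q)
                        comp.append(q)
                        queue.append(q)
        if not (min_pix <= len(comp) <= max_pix):
            continue
        wsum = rsum = csum = 0.0
        for (i, j) in comp:
            wgt = max(frame[i, j] - mean[bin_of[(i, j)]], 0.0)
            wsum += wgt
            rsum += i * wgt
            csum += j * wgt
        if wsum <= 0:
            continue
        spots.append((rsum / wsum, csum / wsum, len(comp)))
    spots.sort()
    return spots


# ---------------------------------------------------------------------------


def direct_translation_profile(travel_length, width, per_frame, n_frames,
                               dx=0.02):
    """Accumulated translating-beam dose by direct per-frame box addition."""
    lo, hi = -width, travel_length + width
    x = np.arange(lo, hi + dx / 2, dx)
    profile = np.zeros_like(x)
    step = travel_length / n_frames
    for i in range(n_frames):
        c = (i + 0.5) * step
        profile[(x >= c - width / 2) & (x < c + width / 2)] += per_frame
    return x, profile


def greedy_selection(scored_grids, coords, min_score, max_score,
                     min_distance):
    """Independent greedy picker over (score, row, col) triples."""
    cand = [(score, i, j) for (i, j), score in scored_grids.items()
            if min_score <= score <= max_score]
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    out = []
    for _s, i, j in cand:
        p = np.asarray(coords[(i, j)])
        if all(np.linalg.norm(p - np.asarray(coords[q])) >= min_distance
               for q in out):
            out.append((i, j))
    return out
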