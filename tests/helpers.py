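"""Analytic stroke factories shared by the unit and acceptance tests.

Strokes are built directly from disk-stamped centerlines so their length,
width, orientation, and junction count are known exactly.
"""

from __future__ import annotations

import numpy as np

import fibroscope as fs
from fibroscope.stainseg import CollagenMask

MPP = 0.25


def stamp_stroke(
    canvas: tuple[int, int],
    segments: list[tuple[tuple[float, float], tuple[float, float]]],
    half_width_px: float,
    mpp: float = MPP,
) -> CollagenMask:
    """Rasterize line segments as disk-stamped strokes of known half-width."""
    h, w = canvas
    m = np.zeros((h, w), dtype=bool)
    r = int(np.ceil(half_width_px))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    disk = np.stack([dr.ravel(), dc.ravel()], axis=1)[
        (dr.ravel() ** 2 + dc.ravel() ** 2) <= half_width_px**2 + 1e-9
    ]
    for (r0, c0), (r1, c1) in segments:
        n = max(int(np.hypot(r1 - r0, c1 - c0) * 3), 2)
        t = np.linspace(0.0, 1.0, n)
        centers = np.column_stack([r0 + t * (r1 - r0), c0 + t * (c1 - c0)])
        px = (np.round(centers).astype(int)[:, None, :] + disk[None, :, :]).reshape(-1, 2)
        ok = (px[:, 0] >= 0) & (px[:, 0] < h) & (px[:, 1] >= 0) & (px[:, 1] < w)
        m[tuple(px[ok].T)] = True
    return CollagenMask(m, mpp)


def bar_mask(
    angle_deg: float,
    length_px: float = 120.0,
    half_width_px: float = 3.0,
    canvas: tuple[int, int] = (256, 256),
    mpp: float = MPP,
) -> CollagenMask:
    """A single straight bar through the canvas center at a known angle."""
    h, w = canvas
    cr, cc = h / 2.0, w / 2.0
    th = np.deg2rad(angle_deg)
    dr, dc = -np.sin(th), np.cos(th)  # image rows grow downward
    a = (cr - dr * length_px / 2, cc - dc * length_px / 2)
    b = (cr + dr * length_px / 2, cc + dc * length_px / 2)
    return stamp_stroke(canvas, [(a, b)], half_width_px, mpp)


def measure_single(mask: CollagenMask) -> fs.FiberRecord:
    graph = fs.skeletonize_mask(mask)
    records = fs.decompose_fibers(graph, mask)
    assert len(records) == 1, f"expected one fiber, got {len(records)}"
    return records[0]
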