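"""Rendering of synthetic larva silhouettes.

Each frame is an 8-bit grayscale image of one larva in a circular well:
a bright elongated head blob plus a tapering tail drawn along a
constant-curvature arc whose head-to-tip chord reproduces the trace's
tail angle exactly (total arc turn = 2 x tail angle), so the pixel
geometry is invertible by the midline tracker.

Conventions: world coordinates in mm with the origin at the well centre,
x to the right, y up (mathematical); image origin top-left with the row
axis flipped (row = (radius - y) * px_per_mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from skimage.draw import disk

from .errors import GenerationError

__all__ = ["WellGeometry", "render_frame", "render_frames", "mm_to_px", "px_to_mm"]

#: body proportions of a 5-dpf larva (mm)
TAIL_LENGTH_MM = 3.2
HEAD_RADIUS_MM = 0.45
TAIL_RADIUS_MM = (0.22, 0.06)  # taper start -> tip


@dataclass(frozen=True)
class WellGeometry:
    """Circular arena geometry and pixel scale."""

    diameter_mm: float = 15.0
    px_per_mm: float = 20.0
    margin_px: int = 4

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def side_px(self) -> int:
        return int(np.ceil(self.diameter_mm * self.px_per_mm)) + 2 * self.margin_px


def mm_to_px(x_mm, y_mm, well: WellGeometry):
    """World (mm, y up) -> image (row, col) float coordinates."""
    col = (np.asarray(x_mm) + well.radius_mm) * well.px_per_mm + well.margin_px
    row = (well.radius_mm - np.asarray(y_mm)) * well.px_per_mm + well.margin_px
    return row, col


def px_to_mm(row, col, well: WellGeometry):
    """Image (row, col) -> world (x, y) in mm."""
    x = (np.asarray(col) - well.margin_px) / well.px_per_mm - well.radius_mm
    y = well.radius_mm - (np.asarray(row) - well.margin_px) / well.px_per_mm
    return x, y


def _midline_mm(x: float, y: float, heading_deg: float, tail_angle_deg: float,
                n: int = 60) -> np.ndarray:
    """(n, 2) arc points head -> tail tip.

    Constant-curvature arc starting at the head, tangent to the backward
    direction, total turn -2 x tail angle, so the head->tip chord sits at
    exactly ``tail_angle`` from straight-behind (positive = fish's left).
    """
    phi0 = np.radians(heading_deg + 180.0)
    turn = np.radians(-2.0 * tail_angle_deg)
    s = np.linspace(0.0, TAIL_LENGTH_MM, n)
    phi = phi0 + turn * s / TAIL_LENGTH_MM
    if abs(turn) < 1e-9:
        pts = np.stack([x + s * np.cos(phi0), y + s * np.sin(phi0)], axis=1)
    else:
        k = turn / TAIL_LENGTH_MM
        pts = np.stack([x + (np.sin(phi) - np.sin(phi0)) / k,
                        y - (np.cos(phi) - np.cos(phi0)) / k], axis=1)
    return pts


def render_frame(x_mm: float, y_mm: float, heading_deg: float,
                 tail_angle_deg: float, well: WellGeometry = WellGeometry(),
                 ) -> np.ndarray:
    """Render one frame (uint8); raises if the fish leaves the well."""
    pts = _midline_mm(x_mm, y_mm, heading_deg, tail_angle_deg)
    # the head must stay trackable inside the arena; a wall-hugging tail
    # may overhang the nominal wall line (the wall itself is not drawn)
    if math.hypot(x_mm, y_mm) > well.radius_mm - HEAD_RADIUS_MM:
        raise GenerationError("fish head outside the well")
    img = np.zeros((well.side_px, well.side_px), dtype=np.uint8)
    shape = img.shape
    row, col = mm_to_px(x_mm, y_mm, well)
    rr, cc = disk((row, col), HEAD_RADIUS_MM * well.px_per_mm, shape=shape)
    img[rr, cc] = 255
    radii = np.linspace(TAIL_RADIUS_MM[0], TAIL_RADIUS_MM[1], len(pts))
    rows, cols = mm_to_px(pts[:, 0], pts[:, 1], well)
    for r, c, rad in zip(rows, cols, radii):
        rr, cc = disk((r, c), max(rad * well.px_per_mm, 1.0), shape=shape)
        img[rr, cc] = 255
    return img


def render_frames(trace: pd.DataFrame, well: WellGeometry = WellGeometry(),
                  rng: np.random.Generator | int | None = None,
                  noise_sd: float = 2.0) -> np.ndarray:
    """Render a trace into an image stack (n_frames, side, side) uint8.

    Optional additive Gaussian pixel noise (``noise_sd`` gray levels)
    emulates sensor noise; the background stays dark.
    """
    rng = np.random.default_rng(rng)
    frames = np.empty((len(trace), well.side_px, well.side_px), dtype=np.uint8)
    for i, (_, f) in enumerate(trace.iterrows()):
        img = render_frame(f["x_mm"], f["y_mm"], f["heading_deg"],
                           f["tail_angle_deg"], well)
        if noise_sd > 0:
            noisy = img.astype(np.float32) + rng.normal(0, noise_sd, img.shape)
            img = np.clip(noisy, 0, 255).astype(np.uint8)
        frames[i] = img
    return frames
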