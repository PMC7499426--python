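"""Midline tracking of larva silhouettes.

A simplified single-animal tracker: background subtraction and a fixed
fractional threshold segment the larva, the mask's skeleton is pruned to
its longest geodesic path, the head end is identified as the wider end
(local mask width from the distance transform), the path is resampled to
10 tail points, and the per-frame tail angle is the signed angle between
the heading and the head-to-tail-tip vector (0 for a straight body,
positive toward the fish's left).

Frames where segmentation or midline extraction fails are flagged, never
fatal; the per-session flagged fraction is the tracker's error rate.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, map_coordinates
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

from .io import FLAG_COLUMN, TRACE_COLUMNS
from .render import WellGeometry, px_to_mm

__all__ = ["Midline", "TrackerParams", "segment_larva", "extract_midline",
           "compute_tail_angle", "track_stack"]

N_TAIL_POINTS = 10


@dataclass(frozen=True)
class TrackerParams:
    """Segmentation and midline settings."""

    threshold_frac: float = 0.5      # of the frame's max background-subtracted contrast
    min_contrast: float = 40.0       # gray levels; below: no larva in frame
    min_area_mm2: float = 0.5
    max_area_mm2: float = 8.0
    min_path_mm: float = 1.5         # shortest acceptable midline
    #: arc range (mm) for the heading-tangent fit; starts past the head
    #: blob, whose skeleton stub is unreliable
    head_fit_mm: tuple[float, float] = (0.45, 2.2)


@dataclass
class Midline:
    """Tracked midline of one frame (all coordinates in mm)."""

    head_xy: tuple[float, float]
    heading_deg: float
    tail_points: list[tuple[float, float]] = field(default_factory=list)
    quality: str = "ok"              # "ok" | "suspect"


def segment_larva(frame: np.ndarray, background: np.ndarray,
                  px_per_mm: float,
                  params: TrackerParams = TrackerParams()) -> np.ndarray | None:
    """Binary larva mask, or None (tracking failure) if no single
    plausible component is found."""
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    diff = frame.astype(np.float32) - background.astype(np.float32)
    contrast = float(diff.max())
    if contrast < params.min_contrast:
        return None
    mask = diff > params.threshold_frac * contrast
    lab = label(mask, connectivity=2)
    lo = params.min_area_mm2 * px_per_mm**2
    hi = params.max_area_mm2 * px_per_mm**2
    plausible = [r for r in regionprops(lab) if lo <= r.area <= hi]
    if len(plausible) != 1:
        return None
    return lab == plausible[0].label


def _longest_path(skel: np.ndarray) -> np.ndarray | None:
    """Longest geodesic pixel path through an 8-connected skeleton."""
    pix = np.argwhere(skel)
    if len(pix) < 3:
        return None
    pixset = {tuple(p) for p in map(tuple, pix)}

    def bfs(start):
        seen = {start: None}
        queue = deque([start])
        last = start
        while queue:
            r, c = queue.popleft()
            last = (r, c)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb != (r, c) and nb in pixset and nb not in seen:
                        seen[nb] = (r, c)
                        queue.append(nb)
        return last, seen

    far, _ = bfs(tuple(pix[0]))
    end, parents = bfs(far)
    path = [end]
    while parents[path[-1]] is not None:
        path.append(parents[path[-1]])
    return np.array(path)


def _head_tangent(pts: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Unit tangent of the midline at the head, pointing into the body.

    Models the body as a constant-curvature arc: in the frame of the
    head-to-far-point chord, the perpendicular deviation is fitted with a
    one-parameter sagitta shape; the tangent at the head is the chord
    rotated back by half the arc's total turn.  Degrades smoothly to the
    chord itself for a straight body.
    """
    far = int(np.flatnonzero(sel).max())
    chord = pts[far] - pts[0]
    length = float(np.linalg.norm(chord))
    if length < 1e-9:
        return np.array([1.0, 0.0])
    cu = chord / length
    cv = np.array([-cu[1], cu[0]])  # left normal of the chord
    rel = pts[sel] - pts[0]
    u = rel @ cu
    v = rel @ cv
    shape = 4.0 * u * (length - u) / length**2  # unit-sagitta parabola
    denom = float(shape @ shape)
    sagitta = float(shape @ v) / denom if denom > 1e-12 else 0.0
    # the arc bulges away from the circle centre: a clockwise (negative)
    # turn bulges toward the chord's left normal, hence the sign flip
    turn = -4.0 * math.atan2(2.0 * sagitta, length)
    ang = math.atan2(cu[1], cu[0]) - turn / 2.0
    return np.array([math.cos(ang), math.sin(ang)])


def _resample(path_xy: np.ndarray, n: int) -> np.ndarray:
    """Resample an ordered polyline to ``n`` points equally spaced in arc
    length."""
    seg = np.hypot(*np.diff(path_xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n)
    return np.stack([np.interp(target, s, path_xy[:, 0]),
                     np.interp(target, s, path_xy[:, 1])], axis=1)


def _refine_subpixel(points_px: np.ndarray, image: np.ndarray,
                     half_widths: np.ndarray) -> np.ndarray:
    """Sub-pixel midline refinement.

    Each point is moved to the intensity centroid of the background-
    subtracted image sampled along the local perpendicular cross-section;
    integer-pixel skeleton staircase noise (which persists across frames
    while the fish rests, so temporal smoothing cannot remove it) drops
    to a fraction of a pixel.
    """
    refined = points_px.astype(float).copy()
    tangents = np.gradient(refined, axis=0)
    norms = np.hypot(tangents[:, 0], tangents[:, 1]) + 1e-12
    normals = np.stack([-tangents[:, 1] / norms, tangents[:, 0] / norms], axis=1)
    for i, (p, nrm, hw) in enumerate(zip(points_px, normals, half_widths)):
        offsets = np.arange(-hw, hw + 0.25, 0.5)
        coords = p[None, :] + offsets[:, None] * nrm[None, :]
        vals = map_coordinates(image, coords.T, order=1, mode="constant")
        w = np.clip(vals - 0.3 * vals.max(), 0.0, None)
        total = w.sum()
        if total > 1e-9:
            refined[i] = p + (w @ offsets) / total * nrm
    return refined


def extract_midline(mask: np.ndarray, well: WellGeometry,
                    params: TrackerParams = TrackerParams(),
                    prev_head: tuple[float, float] | None = None,
                    image: np.ndarray | None = None,
                    ) -> Midline | None:
    """Midline (head, heading, 10 tail points) from a single-larva mask.

    The skeleton's longest path is oriented head-first (the head end has
    the larger local mask width; near-ties fall back to continuity with
    ``prev_head``), optionally refined to sub-pixel accuracy against the
    background-subtracted ``image``; the heading is the tangent of a
    constant-curvature fit at the head end, pointing away from the body.
    """
    # crop to the larva's bounding box (skeletonization cost scales with
    # image area); pad beyond the widest body radius so the distance
    # transform is unaffected
    pix = np.argwhere(mask)
    pad = 16
    r0 = max(int(pix[:, 0].min()) - pad, 0)
    c0 = max(int(pix[:, 1].min()) - pad, 0)
    r1 = min(int(pix[:, 0].max()) + pad + 1, mask.shape[0])
    c1 = min(int(pix[:, 1].max()) + pad + 1, mask.shape[1])
    offset = np.array([r0, c0], dtype=float)
    mask = mask[r0:r1, c0:c1]
    if image is not None:
        image = image[r0:r1, c0:c1]

    path = _longest_path(skeletonize(mask))
    if path is None or len(path) < 5:
        return None
    width = distance_transform_edt(mask)
    k = max(2, len(path) // 6)
    w0 = float(width[tuple(path[:k].T)].mean())
    w1 = float(width[tuple(path[-k:].T)].mean())
    head_first = True
    if abs(w0 - w1) > 0.15 * max(w0, w1) or prev_head is None:
        head_first = w0 >= w1
    else:  # ambiguous widths: temporal continuity
        x, y = px_to_mm(path[:, 0] + offset[0], path[:, 1] + offset[1], well)
        d0 = np.hypot(x[0] - prev_head[0], y[0] - prev_head[1])
        d1 = np.hypot(x[-1] - prev_head[0], y[-1] - prev_head[1])
        head_first = d0 <= d1
    if not head_first:
        path = path[::-1]

    if image is not None:
        dense = _resample(path.astype(float), max(N_TAIL_POINTS * 2 - 1, 9))
        hw = np.maximum(2.0, 1.6 * map_coordinates(width, dense.T, order=1))
        dense = _refine_subpixel(dense, image, hw) + offset
    else:
        dense = path.astype(float) + offset
    x, y = px_to_mm(dense[:, 0], dense[:, 1], well)
    pts = np.stack([x, y], axis=1)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] < params.min_path_mm:
        return None
    # heading: tangent at the head of a circle fitted to the midline
    # (the body is modelled as a constant-curvature arc; for a straight
    # body the fit degenerates and the chord is used directly)
    lo, hi = params.head_fit_mm
    sel = (arc >= lo) & (arc <= hi)
    if sel.sum() < 5:
        sel = np.ones(len(arc), dtype=bool)
    tangent = _head_tangent(pts, sel)
    heading = math.degrees(math.atan2(-tangent[1], -tangent[0]))
    tail = _resample(pts, N_TAIL_POINTS)
    quality = "ok" if len(path) >= 2 * N_TAIL_POINTS else "suspect"
    return Midline(head_xy=(float(pts[0, 0]), float(pts[0, 1])),
                   heading_deg=heading,
                   tail_points=[(float(px), float(py)) for px, py in tail],
                   quality=quality)


def compute_tail_angle(midline: Midline) -> float:
    """Signed angle (deg) between straight-behind and the head-to-tip
    vector; 0 for a straight body, positive toward the fish's left.

    Raises ``ValueError`` when the tip coincides with the head
    (degenerate midline).
    """
    hx, hy = midline.head_xy
    tx, ty = midline.tail_points[-1]
    vx, vy = tx - hx, ty - hy
    if math.hypot(vx, vy) < 1e-6:
        raise ValueError("tail tip coincides with the head")
    h = math.radians(midline.heading_deg)
    back = (-math.cos(h), -math.sin(h))
    left = (-math.sin(h), math.cos(h))
    return math.degrees(math.atan2(vx * left[0] + vy * left[1],
                                   vx * back[0] + vy * back[1]))


def track_stack(frames: np.ndarray, background: np.ndarray | None = None,
                well: WellGeometry = WellGeometry(), rate: float = 100.0,
                params: TrackerParams = TrackerParams()) -> pd.DataFrame:
    """Track an image stack into a standard trace table.

    Returns one row per frame (:data:`larvaswim.io.TRACE_COLUMNS` plus a
    ``flagged`` column); failed frames carry NaNs and ``flagged=1``.
    """
    if background is None:
        background = np.zeros(frames.shape[1:], dtype=frames.dtype)
    rows = []
    prev_head = None
    for i, frame in enumerate(frames):
        rec = {"frame_index": i, "time_s": i / rate, "x_mm": np.nan, "y_mm": np.nan,
               "heading_deg": np.nan, "tail_angle_deg": np.nan, FLAG_COLUMN: 1}
        mask = segment_larva(frame, background, well.px_per_mm, params)
        if mask is not None:
            diff = frame.astype(np.float32) - background.astype(np.float32)
            mid = extract_midline(mask, well, params, prev_head, image=diff)
            if mid is not None:
                try:
                    angle = compute_tail_angle(mid)
                except ValueError:
                    angle = None
                if angle is not None:
                    prev_head = mid.head_xy
                    rec.update({"x_mm": mid.head_xy[0], "y_mm": mid.head_xy[1],
                                "heading_deg": mid.heading_deg % 360.0,
                                "tail_angle_deg": angle, FLAG_COLUMN: 0})
        rows.append(rec)
    return pd.DataFrame(rows, columns=TRACE_COLUMNS + [FLAG_COLUMN])
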