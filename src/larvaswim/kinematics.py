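"""Bout segmentation and per-bout kinematics from tail-angle traces.

A swim bout is detected from the tail-angle time series alone: a sliding
RMS envelope of the (smoothed) tail angle crosses an onset threshold with
hysteresis, the interval edges are then refined to the quiet/motion
transition, and the signed tail-bend peaks inside the interval give the
oscillation count, the tail-beat frequency (TBF = oscillations / bout
duration) and the bend-amplitude statistics.  Distance travelled is the
path length of the (denoised) head trajectory across the bout's frame
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, savgol_filter

from .errors import SessionRejected
from .io import FLAG_COLUMN, trace_rate_hz

__all__ = ["Bout", "DetectionParams", "detect_bouts", "detect_bends",
           "compute_bout_kinematics", "bout_rate", "analyze_trace",
           "bouts_to_table", "BOUT_TABLE_COLUMNS"]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable bout-detection settings (defaults in seconds/degrees)."""

    rms_window_s: float = 0.05      # sliding RMS envelope window
    theta_on_deg: float = 3.0       # envelope onset threshold
    on_sustain_s: float = 0.02      # minimum time above theta_on
    theta_off_deg: float = 1.5      # envelope offset threshold (hysteresis)
    off_sustain_s: float = 0.05     # quiet time ending a bout
    merge_gap_s: float = 0.03       # merge intervals closer than this
    edge_theta_deg: float = 1.5     # raw |tail angle| level used to refine edges
    peak_prominence_deg: float = 1.5
    peaks_per_osc: int = 2          # one oscillation = left+right half-beat
    max_flag_frac: float = 0.2      # reject session above this flagged share
    angle_smooth_window: int = 5    # frames, Savitzky-Golay, order 2
    position_smooth_window: int = 7


@dataclass
class Bout:
    """One detected swim event and its kinematic parameters.

    ``onset_frame``/``offset_frame`` delimit a half-open frame interval;
    distance is the head path length summed over the interval's
    ``offset - onset`` displacement steps.
    """

    onset_frame: int
    offset_frame: int
    duration_s: float
    distance_mm: float
    speed_mm_s: float
    bends_deg: list[float]          # signed peak amplitudes, time order
    n_osc: int
    tbf_hz: float
    max_bend_deg: float
    median_bend_deg: float
    net_displacement_mm: float = float("nan")
    category: str | None = None


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    window = min(window, len(x) if len(x) % 2 else len(x) - 1)
    if window < 5:
        return x.astype(float)
    return savgol_filter(x, window, 2)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _prepare_angle(trace: pd.DataFrame, params: DetectionParams) -> np.ndarray:
    """Raw tail angle with flagged frames interpolated; rejects sessions
    whose flagged share exceeds ``max_flag_frac``."""
    ang = trace["tail_angle_deg"].to_numpy(dtype=float)
    if FLAG_COLUMN in trace.columns:
        flagged = trace[FLAG_COLUMN].to_numpy(dtype=bool)
        frac = flagged.mean() if len(flagged) else 0.0
        if frac > params.max_flag_frac:
            raise SessionRejected(
                f"{frac:.1%} of frames flagged (limit "
                f"{params.max_flag_frac:.0%})")
        if flagged.any() and not flagged.all():
            idx = np.arange(len(ang))
            ang = ang.copy()
            ang[flagged] = np.interp(idx[flagged], idx[~flagged], ang[~flagged])
    bad = ~np.isfinite(ang)
    if bad.any():
        idx = np.arange(len(ang))
        ang = ang.copy()
        ang[bad] = np.interp(idx[bad], idx[~bad], ang[~bad])
    return ang


#: smoothed-|angle| level treated as "back at baseline" when closing a bout
_BASELINE_DEG = 0.5
#: smallest smoothed extremum accepted while tracking trailing oscillations
_TRACK_FLOOR_DEG = 0.85
#: |amplitude| above which peaks are read from the raw trace: the
#: smoother's attenuation of a narrow lobe is multiplicative (several
#: percent, dozens of degrees for a C-bend) while raw-read noise is
#: additive (~the sensor noise), so the error modes cross a few degrees up
_READ_RAW_ABOVE_DEG = 6.0


def _read_amp(ang, ang_sm, idx):
    # large bends: raw read, tolerant to one frame of peak misalignment
    lo = max(0, idx - 1)
    seg = ang[lo:idx + 2]
    raw = float(seg[np.argmax(np.abs(seg))])
    return raw if abs(raw) >= _READ_RAW_ABOVE_DEG else float(ang_sm[idx])


def _find_bend_peaks(
    ang: np.ndarray,
    ang_sm: np.ndarray,
    s: int,
    e: int,
    e_max: int,
    params: DetectionParams,
) -> list[tuple[int, float]]:
    """Time-ordered ``(frame, signed amplitude)`` bend peaks.

    Peaks are located on the smoothed angle (prominence floor), collapsed
    to an alternating-sign sequence, then the decaying tail of the bout is
    followed beyond the envelope's reach: as long as an opposite-sign
    extremum of at least :data:`_TRACK_FLOOR_DEG` appears within ~1.8
    beat spacings (up to ``e_max``), it is appended.  Peak frames are
    located on the smoothed angle; amplitudes are read from the raw trace
    for large bends and from the smoothed one for small bends (see
    :data:`_READ_RAW_ABOVE_DEG`).
    """
    seg = ang_sm[s:e]
    pk_hi, _ = find_peaks(seg, prominence=params.peak_prominence_deg)
    pk_lo, _ = find_peaks(-seg, prominence=params.peak_prominence_deg)
    out: list[tuple[int, float]] = []
    for p in sorted(list(pk_hi) + list(pk_lo)):
        amp = _read_amp(ang, ang_sm, s + p)
        if not out or math.copysign(1, amp) != math.copysign(1, out[-1][1]):
            out.append((s + p, amp))
        elif abs(amp) > abs(out[-1][1]):
            out[-1] = (s + p, amp)
    # a bout's first bend is a genuine large deflection; drop leading
    # noise ripples below the prominence floor
    while out and abs(out[0][1]) < params.peak_prominence_deg:
        out.pop(0)
    # track the decaying oscillation past the last prominent peak; with a
    # single prominent peak the beat spacing is estimated from the
    # onset-to-peak rise (about half a lobe)
    while out:
        if len(out) >= 2:
            spacing = (out[-1][0] - out[0][0]) / (len(out) - 1)
        else:
            spacing = max(3.0, 2.0 * (out[0][0] - s + 1))
        last_i, last_a = out[-1]
        w0 = last_i + max(2, int(round(0.4 * spacing)))
        w1 = min(e_max, last_i + int(round(1.8 * spacing)) + 1)
        if w1 - w0 < 2:
            break
        expect = -math.copysign(1.0, last_a)
        win = expect * ang_sm[w0:w1]
        j = int(np.argmax(win))
        if win[j] < _TRACK_FLOOR_DEG:
            break
        out.append((w0 + j, _read_amp(ang, ang_sm, w0 + j)))
    # trailing guard: a genuine final bend continues the decaying train
    # (|ratio| to its predecessor ~0.8-0.95); post-bout noise ripples do
    # not, yet pass the prominence test against the previous deep lobe
    while (len(out) >= 2 and
           abs(out[-1][1]) < max(_TRACK_FLOOR_DEG, 0.35 * abs(out[-2][1]))):
        out.pop()
    return out


def detect_bouts(
    trace: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
    rate: float | None = None,
) -> list[tuple[int, int]]:
    """Detect non-overlapping bout intervals from a uniform trace.

    Returns time-ordered half-open ``(onset, offset)`` frame intervals.
    Envelope hysteresis (on at ``theta_on``, off below ``theta_off``
    sustained for ``off_sustain_s``) proposes candidate intervals; the
    onset is refined to the quiet/motion transition of the raw angle, the
    offset to the return to baseline after the last (tracked) bend peak.
    Intervals without a qualifying bend peak (micro-movements) are
    discarded.
    """
    rate = rate or trace_rate_hz(trace)
    ang = _prepare_angle(trace, params)
    ang_sm = _smooth(ang, params.angle_smooth_window)
    w = max(3, int(round(params.rms_window_s * rate)))
    # envelope on the raw angle: smoothing would attenuate the narrow
    # lobes of micro-bouts below the onset threshold, while the sensor
    # noise floor (~0.5 deg RMS) sits far below theta_on; the clamp
    # guards against tiny negative rounding on exactly quiet segments
    env = np.sqrt(np.maximum(uniform_filter1d(ang**2, size=w,
                                              mode="nearest"), 0.0))

    n_on = max(1, int(round(params.on_sustain_s * rate)))
    n_off = max(1, int(round(params.off_sustain_s * rate)))
    quiet = env < params.theta_off_deg
    # definite-quiet zones split the trace into candidate intervals
    active = np.ones(len(env), dtype=bool)
    for s, e in _runs(quiet):
        if e - s >= n_off:
            active[s:e] = False
    loud = env >= params.theta_on_deg
    intervals = []
    for s, e in _runs(active):
        if any(re - rs >= n_on for rs, re in _runs(loud[s:e])):
            intervals.append((s, e))

    # merge near-adjacent intervals (beat-and-glide glides are longer)
    gap = int(round(params.merge_gap_s * rate))
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    half_w = w // 2 + 1
    n = len(ang)
    out: list[tuple[int, int]] = []
    prev_end = 0
    for k, (s, e) in enumerate(merged):
        lo = max(prev_end, s - half_w)
        hi = min(n, e + half_w)
        # onset: two consecutive raw frames above edge_theta (a single
        # noise excursion never qualifies), stepped back by one frame
        above = np.abs(ang[lo:hi]) >= params.edge_theta_deg
        moving = above[:-1] & above[1:]
        idx = np.flatnonzero(moving)
        if idx.size == 0:
            continue
        onset = max(lo + idx[0] - 1, prev_end, 0)
        next_start = merged[k + 1][0] - half_w if k + 1 < len(merged) else n
        e_max = min(n, hi + int(round(0.5 * rate)), next_start)
        peaks = _find_bend_peaks(ang, ang_sm, onset, hi, e_max, params)
        if not peaks:
            continue  # micro-movement: envelope crossing without a peak
        # offset: return to baseline after the last bend peak
        last_i = peaks[-1][0]
        spacing = (max(2, (peaks[-1][0] - peaks[0][0]) // max(1, len(peaks) - 1))
                   if len(peaks) > 1 else max(2, int(round(0.05 * rate))))
        tail = np.abs(ang_sm[last_i:min(e_max, last_i + 2 * spacing)])
        calm = np.flatnonzero(tail <= _BASELINE_DEG)
        offset = last_i + (int(calm[0]) if calm.size else spacing)
        offset = int(min(max(offset, onset + 2), e_max))
        out.append((int(onset), offset))
        prev_end = offset
    return out


def detect_bends(
    trace: pd.DataFrame,
    interval: tuple[int, int],
    params: DetectionParams = DetectionParams(),
    _angles: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[float]:
    """Ordered signed tail-bend peak amplitudes within a bout interval.

    Local extrema of the smoothed tail angle above the prominence floor,
    collapsed to an alternating-sign sequence (consecutive same-sign
    extrema keep the larger), with the bout's decaying tail oscillations
    tracked down to the noise floor.  The first element is the bout's
    first bend.
    """
    if _angles is None:
        ang = _prepare_angle(trace, params)
        ang_sm = _smooth(ang, params.angle_smooth_window)
    else:
        ang, ang_sm = _angles
    s, e = interval
    return [amp for _, amp in _find_bend_peaks(ang, ang_sm, s, e, e, params)]


def compute_bout_kinematics(
    trace: pd.DataFrame,
    interval: tuple[int, int],
    bends: list[float],
    params: DetectionParams = DetectionParams(),
    rate: float | None = None,
    _xy_smooth: tuple[np.ndarray, np.ndarray] | None = None,
) -> Bout:
    """Assemble a :class:`Bout` from an interval and its bend sequence.

    distance = head path length over the ``offset - onset`` displacement
    steps of the half-open interval (computed on a denoised trajectory;
    the net start-to-end displacement is kept as a secondary measure);
    n_osc = ceil(n_bends / peaks_per_osc); TBF = n_osc / duration.
    """
    rate = rate or trace_rate_hz(trace)
    s, e = interval
    if _xy_smooth is None:
        x = _smooth(trace["x_mm"].to_numpy(dtype=float),
                    params.position_smooth_window)
        y = _smooth(trace["y_mm"].to_numpy(dtype=float),
                    params.position_smooth_window)
    else:
        x, y = _xy_smooth
    e_pos = min(e, len(x) - 1)
    dx = np.diff(x[s:e_pos + 1])
    dy = np.diff(y[s:e_pos + 1])
    distance = float(np.sum(np.hypot(dx, dy)))
    net = float(np.hypot(x[e_pos] - x[s], y[e_pos] - y[s]))
    duration = (e - s) / rate
    abs_bends = np.abs(bends) if len(bends) else np.array([np.nan])
    n_osc = int(math.ceil(len(bends) / params.peaks_per_osc))
    return Bout(
        onset_frame=int(s), offset_frame=int(e),
        duration_s=duration, distance_mm=distance,
        speed_mm_s=distance / duration,
        bends_deg=[float(b) for b in bends],
        n_osc=n_osc, tbf_hz=n_osc / duration,
        max_bend_deg=float(abs_bends.max()),
        median_bend_deg=float(np.median(abs_bends)),
        net_displacement_mm=net,
    )


def bout_rate(bouts, recording_duration_s: float) -> float:
    """Bouts per second over the recording."""
    if recording_duration_s <= 0:
        raise ValueError("recording duration must be > 0")
    return len(bouts) / recording_duration_s


BOUT_TABLE_COLUMNS = [
    "fish_id", "session_id", "bout_index", "onset_frame", "offset_frame",
    "onset_s", "duration_s", "distance_mm", "net_displacement_mm",
    "speed_mm_s", "n_osc", "tbf_hz", "max_bend_deg", "median_bend_deg",
    "first_bend_deg", "second_bend_deg", "n_bends",
]


def analyze_trace(
    trace: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
    rate: float | None = None,
    fish_id: str = "fish0",
    session_id: str = "session0",
) -> pd.DataFrame:
    """Full per-trace analysis: detect bouts, bends and kinematics.

    Returns one row per bout (columns :data:`BOUT_TABLE_COLUMNS`).
    """
    rate = rate or trace_rate_hz(trace)
    ang = _prepare_angle(trace, params)
    ang_sm = _smooth(ang, params.angle_smooth_window)
    x = _smooth(trace["x_mm"].to_numpy(dtype=float), params.position_smooth_window)
    y = _smooth(trace["y_mm"].to_numpy(dtype=float), params.position_smooth_window)
    rows = []
    i = 0
    for s, e in detect_bouts(trace, params, rate):
        bends = detect_bends(trace, (s, e), params, _angles=(ang, ang_sm))
        if not bends:
            continue  # peak at the interval edge only: treat as micro-movement
        bout = compute_bout_kinematics(trace, (s, e), bends, params, rate,
                                       _xy_smooth=(x, y))
        rows.append({
            "fish_id": fish_id, "session_id": session_id, "bout_index": i,
            "onset_frame": bout.onset_frame, "offset_frame": bout.offset_frame,
            "onset_s": bout.onset_frame / rate,
            "duration_s": bout.duration_s, "distance_mm": bout.distance_mm,
            "net_displacement_mm": bout.net_displacement_mm,
            "speed_mm_s": bout.speed_mm_s, "n_osc": bout.n_osc,
            "tbf_hz": bout.tbf_hz, "max_bend_deg": bout.max_bend_deg,
            "median_bend_deg": bout.median_bend_deg,
            "first_bend_deg": bout.bends_deg[0],
            "second_bend_deg": bout.bends_deg[1] if len(bout.bends_deg) > 1
            else np.nan,
            "n_bends": len(bout.bends_deg),
        })
        i += 1
    return pd.DataFrame(rows, columns=BOUT_TABLE_COLUMNS)


def bouts_to_table(bouts: list[Bout], rate: float, fish_id: str = "fish0",
                   session_id: str = "session0") -> pd.DataFrame:
    """Convert a list of :class:`Bout` objects to the standard table."""
    rows = []
    for i, b in enumerate(bouts):
        rows.append({
            "fish_id": fish_id, "session_id": session_id, "bout_index": i,
            "onset_frame": b.onset_frame, "offset_frame": b.offset_frame,
            "onset_s": b.onset_frame / rate, "duration_s": b.duration_s,
            "distance_mm": b.distance_mm,
            "net_displacement_mm": b.net_displacement_mm,
            "speed_mm_s": b.speed_mm_s, "n_osc": b.n_osc, "tbf_hz": b.tbf_hz,
            "max_bend_deg": b.max_bend_deg,
            "median_bend_deg": b.median_bend_deg,
            "first_bend_deg": b.bends_deg[0] if b.bends_deg else np.nan,
            "second_bend_deg": b.bends_deg[1] if len(b.bends_deg) > 1
            else np.nan,
            "n_bends": len(b.bends_deg),
        })
    return pd.DataFrame(rows, columns=BOUT_TABLE_COLUMNS)
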