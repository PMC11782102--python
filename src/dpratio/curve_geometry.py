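"""Centerline smoothing, equidistant resampling and moving frames.

The raw voxel centerline is noisy at the voxel scale, so it is smoothed
with a short moving average, resampled to equidistant points (0.5 mm by
default), and tangent vectors are taken as chords to a point 10 mm
ahead rather than to the immediate neighbor — local wiggles would
otherwise tilt the cross-section planes and produce outlier area
ratios.  Normal/binormal vectors are propagated along the curve with a
rotation-minimizing frame; cross-sectional areas are invariant to
in-plane rotation of the frame, so the particular twist chosen cannot
change the measured ratio.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "FrameSample",
    "smooth_polyline",
    "resample_polyline",
    "compute_tangents",
    "build_frames",
    "frames_for_centerline",
]


@dataclasses.dataclass(frozen=True)
class FrameSample:
    """A centerline point with an orthonormal (tangent, normal, binormal) frame."""

    point: np.ndarray       # (3,) mm
    tangent: np.ndarray     # unit
    normal: np.ndarray      # unit, orthogonal to tangent
    binormal: np.ndarray    # tangent x normal
    arc_s: float            # arc length from the tail end, mm


def smooth_polyline(points: np.ndarray, half_width: int = 2) -> np.ndarray:
    """Moving-average smoothing with a window of ``half_width`` points on
    each side plus the point itself.  Near the ends the window shrinks
    symmetrically (min(half_width, i, n-1-i) on each side), so the output
    has the same number of points, the endpoints are fixed, and collinear
    equally spaced input passes through unchanged."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n == 0:
        raise ValueError("cannot smooth an empty polyline")
    out = np.empty_like(pts)
    for i in range(n):
        w = min(half_width, i, n - 1 - i)
        out[i] = pts[i - w:i + w + 1].mean(axis=0)
    return out


def _cumulative_arc_length(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_length(points: np.ndarray) -> float:
    return float(_cumulative_arc_length(np.asarray(points, dtype=float))[-1])


def resample_polyline(points: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Resample a polyline at equal arc-length intervals.

    Output points lie on the input polyline at arc lengths 0, step,
    2*step, ...; the original final endpoint is appended when the total
    length is not an exact multiple of step, so the last segment may be
    shorter than ``step``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("resampling requires at least 2 points")
    if step <= 0:
        raise ValueError("step must be positive")
    arc = _cumulative_arc_length(pts)
    total = arc[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    targets = np.arange(0.0, total + step * 1e-9, step)
    out = np.column_stack([np.interp(targets, arc, pts[:, k]) for k in range(3)])
    if total - targets[-1] > step * 1e-9:
        out = np.vstack([out, pts[-1]])
    return out


def compute_tangents(points: np.ndarray, step: float, lookahead: float = 10.0) -> np.ndarray:
    """Chord tangents referencing a point ``lookahead`` mm ahead.

    For equidistant points the lookahead is ``k = round(lookahead/step)``
    indices.  Points whose lookahead overruns the end use the chord to
    the final point; the final point copies the previous tangent.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n < 2:
        raise ValueError("tangents require at least 2 points")
    if lookahead < step:
        raise ValueError("lookahead must be at least one step")
    k = max(1, int(round(lookahead / step)))
    tangents = np.empty_like(pts)
    for i in range(n - 1):
        j = min(i + k, n - 1)
        chord = pts[j] - pts[i]
        norm = np.linalg.norm(chord)
        if norm < 1e-12:
            # degenerate chord (closed/duplicated points): reuse neighbor
            tangents[i] = tangents[i - 1] if i > 0 else np.array([1.0, 0.0, 0.0])
        else:
            tangents[i] = chord / norm
    tangents[n - 1] = tangents[n - 2]
    return tangents


def _reference_normal(tangent: np.ndarray) -> np.ndarray:
    # world axis least aligned with the first tangent, projected orthogonal
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(tangent)))] = 1.0
    normal = axis - np.dot(axis, tangent) * tangent
    return normal / np.linalg.norm(normal)


def build_frames(points: np.ndarray, tangents: np.ndarray,
                 arc_s: np.ndarray | None = None) -> list[FrameSample]:
    """Orthonormal frames along the curve via the double-reflection
    rotation-minimizing scheme (Wang et al. 2008)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tans = np.atleast_2d(np.asarray(tangents, dtype=float))
    if len(pts) != len(tans):
        raise ValueError("points and tangents must have equal length")
    norms = np.linalg.norm(tans, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero tangent vector")
    tans = tans / norms[:, None]
    if arc_s is None:
        arc_s = _cumulative_arc_length(pts)

    frames: list[FrameSample] = []
    normal = _reference_normal(tans[0])
    for i in range(len(pts)):
        if i > 0:
            # double reflection: reflect previous frame across the chord
            # midplane, then across the new tangent's bisecting plane
            v1 = pts[i] - pts[i - 1]
            c1 = float(np.dot(v1, v1))
            if c1 > 1e-18:
                prev_t, prev_n = tans[i - 1], normal
                n_l = prev_n - (2.0 / c1) * np.dot(v1, prev_n) * v1
                t_l = prev_t - (2.0 / c1) * np.dot(v1, prev_t) * v1
                v2 = tans[i] - t_l
                c2 = float(np.dot(v2, v2))
                normal = n_l - (2.0 / c2) * np.dot(v2, n_l) * v2 if c2 > 1e-18 else n_l
            # re-orthogonalize against accumulated rounding
            normal = normal - np.dot(normal, tans[i]) * tans[i]
            normal = normal / np.linalg.norm(normal)
        binormal = np.cross(tans[i], normal)
        frames.append(FrameSample(point=pts[i].copy(), tangent=tans[i].copy(),
                                  normal=normal.copy(), binormal=binormal,
                                  arc_s=float(arc_s[i])))
    return frames


def frames_for_centerline(points: np.ndarray, *, smoothing_half_width: int = 2,
                          step: float = 0.5, lookahead: float = 10.0) -> list[FrameSample]:
    """Smooth, resample and frame a raw centerline polyline in one call."""
    smoothed = smooth_polyline(points, half_width=smoothing_half_width)
    resampled = resample_polyline(smoothed, step=step)
    tangents = compute_tangents(resampled, step=step, lookahead=lookahead)
    return build_frames(resampled, tangents)
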