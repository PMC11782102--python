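"""Cross-section extraction and the duct-to-parenchyma (DP) ratio profile.

For every frame along the centerline, the pancreas and duct masks are
resampled on a square grid spanned by the frame's normal and binormal
vectors (nearest-neighbor lookup; samples outside the volume count as
background).  In each section, connected regions through which the
centerline does not pass are removed — distant parts of the organ or
stray segmentation speckle can otherwise intersect an oblique plane and
inflate the areas.  The DP ratio of a section is

    duct_area / parenchyma_area,

where by default the parenchyma is the pancreas minus the duct (the duct
lumen is not parenchymal tissue); a whole-pancreas denominator is
available as a config option.  The per-case score is a percentile of
the per-section ratios (90th by default): high enough to respond to a
focal dilation or atrophy spanning a modest fraction of the organ, low
enough to shrug off a few outlier sections caused by segmentation or
centerline defects.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .curve_geometry import FrameSample
from .mask_io import VoxelMask, check_pair, world_to_voxel

__all__ = [
    "CrossSection",
    "DPRatioProfile",
    "extract_cross_section",
    "filter_traversed_components",
    "dp_profile",
    "percentile_score",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity in-plane

PARENCHYMA_EXCLUDES_DUCT = "parenchyma_excludes_duct"
WHOLE_PANCREAS = "whole_pancreas"


@dataclasses.dataclass
class CrossSection:
    pancreas_pixels: np.ndarray
    duct_pixels: np.ndarray
    pixel_area: float
    center_index: tuple[int, int]
    valid: bool


@dataclasses.dataclass
class DPRatioProfile:
    """Per-section areas and DP ratios along the centerline."""

    arc_s: np.ndarray           # mm
    pancreas_area: np.ndarray   # mm^2 (parenchyma under the active convention)
    duct_area: np.ndarray       # mm^2
    dp_ratio: np.ndarray
    valid: np.ndarray           # bool per section
    score_percentile: float = 90.0

    @property
    def score(self) -> float:
        return percentile_score(self, self.score_percentile)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "arc_s": self.arc_s,
            "pancreas_area": self.pancreas_area,
            "duct_area": self.duct_area,
            "dp_ratio": self.dp_ratio,
            "valid": self.valid.astype(int),
        })

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def case_report(self, case_id: str = "") -> dict:
        return {
            "case_id": case_id,
            "n_sections": int(len(self.arc_s)),
            "n_valid": self.n_valid,
            "score_percentile": self.score_percentile,
            "score": self.score,
        }

    def save_report(self, path: str | Path, case_id: str = "") -> None:
        Path(path).write_text(json.dumps(self.case_report(case_id), indent=2) + "\n")


def _plane_grid(frame: FrameSample, half_extent: float, in_plane_step: float
                ) -> tuple[np.ndarray, int]:
    n_half = int(round(half_extent / in_plane_step))
    offsets = np.arange(-n_half, n_half + 1) * in_plane_step
    uu, vv = np.meshgrid(offsets, offsets, indexing="ij")
    points = (frame.point[None, :]
              + uu.reshape(-1, 1) * frame.normal[None, :]
              + vv.reshape(-1, 1) * frame.binormal[None, :])
    return points, 2 * n_half + 1


def _sample_nearest(mask: VoxelMask, points: np.ndarray) -> np.ndarray:
    idx = np.rint(world_to_voxel(points, mask.geometry)).astype(int)
    shape = np.asarray(mask.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(points), dtype=np.uint8)
    if np.any(inside):
        ii = idx[inside]
        out[inside] = mask.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def extract_cross_section(mask: VoxelMask, frame: FrameSample,
                          half_extent: float = 40.0,
                          in_plane_step: float = 0.5) -> np.ndarray:
    """Nearest-neighbor resampling of the mask on the frame's plane.

    Returns a square binary grid of ``(2*half_extent/in_plane_step + 1)``
    samples per side; grid point (i, j) sits at
    ``point + u_i * normal + v_j * binormal``.
    """
    if half_extent <= 0 or in_plane_step <= 0:
        raise ValueError("half_extent and in_plane_step must be positive")
    points, side = _plane_grid(frame, half_extent, in_plane_step)
    return _sample_nearest(mask, points).reshape(side, side)


def filter_traversed_components(section_pancreas: np.ndarray,
                                section_duct: np.ndarray,
                                piercing_pixels: np.ndarray,
                                pixel_size_mm: float = 0.5,
                                fallback_mm: float = 2.0
                                ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Remove in-plane regions the centerline does not pass through.

    Pancreas components (8-connected) that contain no piercing pixel are
    dropped; if none contains one, the nearest component within
    ``fallback_mm`` of a piercing pixel is kept, else the section is
    invalid.  Duct components are kept only where their one-pixel
    dilation touches the retained pancreas (duct and parenchyma labels
    are disjoint under the excludes-duct convention, hence the dilation).
    """
    if section_pancreas.shape != section_duct.shape:
        raise ValueError("pancreas and duct sections must share shape")
    piercing = np.atleast_2d(np.asarray(piercing_pixels, dtype=int)) \
        if np.size(piercing_pixels) else np.empty((0, 2), dtype=int)
    shape = np.asarray(section_pancreas.shape)
    if len(piercing):
        ok = np.all((piercing >= 0) & (piercing < shape), axis=1)
        piercing = piercing[ok]

    labels, n = ndimage.label(section_pancreas, structure=_STRUCT8)
    keep = np.zeros(n + 1, dtype=bool)
    for px in piercing:
        lab = labels[px[0], px[1]]
        if lab > 0:
            keep[lab] = True
    if n > 0 and not keep.any() and len(piercing):
        # fallback: nearest component within fallback_mm of a piercing pixel
        best_lab, best_d = 0, np.inf
        fg = np.argwhere(labels > 0)
        if len(fg):
            d2 = ((fg[None, :, :] - piercing[:, None, :]) ** 2).sum(axis=2)
            flat = int(np.argmin(d2))
            best_d = np.sqrt(d2.ravel()[flat]) * pixel_size_mm
            best_lab = labels[tuple(fg[flat % len(fg)])]
        if best_d <= fallback_mm:
            keep[best_lab] = True
    retained_pancreas = keep[labels]

    valid = bool(retained_pancreas.any())
    if not valid:
        return np.zeros_like(section_pancreas), np.zeros_like(section_duct), False

    duct_labels, m = ndimage.label(section_duct, structure=_STRUCT8)
    duct_keep = np.zeros(m + 1, dtype=bool)
    for lab in range(1, m + 1):
        comp = duct_labels == lab
        dilated = ndimage.binary_dilation(comp, structure=_STRUCT8)
        if np.any(dilated & retained_pancreas) or np.any(comp & retained_pancreas):
            duct_keep[lab] = True
    retained_duct = duct_keep[duct_labels]
    return retained_pancreas.astype(np.uint8), retained_duct.astype(np.uint8), True


def _piercing_pixels(frame: FrameSample, centerline_points: np.ndarray,
                     half_extent: float, in_plane_step: float,
                     along_tol: float) -> np.ndarray:
    """Grid coordinates of centerline samples within ``along_tol`` mm of
    the section plane."""
    d = centerline_points - frame.point[None, :]
    along = d @ frame.tangent
    near = np.abs(along) <= along_tol
    if not np.any(near):
        return np.empty((0, 2), dtype=int)
    n_half = int(round(half_extent / in_plane_step))
    u = d[near] @ frame.normal
    v = d[near] @ frame.binormal
    iu = np.rint(u / in_plane_step).astype(int) + n_half
    iv = np.rint(v / in_plane_step).astype(int) + n_half
    return np.unique(np.column_stack([iu, iv]), axis=0)


def dp_profile(pancreas: VoxelMask, duct: VoxelMask, frames: list[FrameSample],
               half_extent: float = 40.0, in_plane_step: float = 0.5,
               along_step: float = 0.5,
               denominator: str = PARENCHYMA_EXCLUDES_DUCT,
               score_percentile: float = 90.0) -> DPRatioProfile:
    """Per-frame DP ratios along the centerline.

    A section with no detected duct scores 0 (under-segmented ducts bias
    the score downward rather than invalidating the section); a section
    with no retained pancreas, or zero parenchyma area, is invalid and
    excluded from the percentile.
    """
    check_pair(pancreas, duct)
    if not frames:
        raise ValueError("dp_profile needs at least one frame")
    if denominator not in (PARENCHYMA_EXCLUDES_DUCT, WHOLE_PANCREAS):
        raise ValueError(f"unknown denominator convention: {denominator}")

    pixel_area = in_plane_step ** 2
    pts = np.array([f.point for f in frames])
    n = len(frames)
    arc = np.array([f.arc_s for f in frames])
    panc_area = np.zeros(n)
    duct_area = np.zeros(n)
    ratio = np.zeros(n)
    valid = np.zeros(n, dtype=bool)

    for i, frame in enumerate(frames):
        sec_p = extract_cross_section(pancreas, frame, half_extent, in_plane_step)
        sec_d = extract_cross_section(duct, frame, half_extent, in_plane_step)
        piercing = _piercing_pixels(frame, pts, half_extent, in_plane_step,
                                    along_tol=along_step / 2.0)
        fp, fd, ok = filter_traversed_components(sec_p, sec_d, piercing,
                                                 pixel_size_mm=in_plane_step)
        if not ok:
            continue
        a_duct = float(fd.sum()) * pixel_area
        a_panc_total = float(fp.sum()) * pixel_area
        overlap = float(np.sum(fp & fd)) * pixel_area
        if denominator == PARENCHYMA_EXCLUDES_DUCT:
            a_parenchyma = a_panc_total - overlap
        else:
            a_parenchyma = a_panc_total + a_duct - overlap
        if a_parenchyma <= 0:
            continue
        panc_area[i] = a_parenchyma
        duct_area[i] = a_duct
        ratio[i] = a_duct / a_parenchyma
        valid[i] = True

    if not valid.any():
        raise ValueError("no valid cross-sections: centerline does not pierce "
                         "the pancreas or parenchyma area is zero everywhere")
    return DPRatioProfile(arc_s=arc, pancreas_area=panc_area, duct_area=duct_area,
                          dp_ratio=ratio, valid=valid,
                          score_percentile=score_percentile)


def percentile_score(profile: DPRatioProfile, level: float = 90.0) -> float:
    """Linear-interpolation percentile of the DP ratio over valid sections."""
    if not (0 < level <= 100):
        raise ValueError("percentile level must be in (0, 100]")
    values = profile.dp_ratio[profile.valid]
    if len(values) == 0:
        raise ValueError("no valid samples to take a percentile over")
    return float(np.percentile(values, level))
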