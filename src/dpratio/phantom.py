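"""Synthetic pancreas/duct phantoms with an analytic DP-ratio profile.

A phantom is a curved tube: a parametric generating curve (straight
segment, planar arc, or planar sinusoid), a parenchyma radius profile
R(s) and a duct radius profile r(s) over arc length s, and an optional
in-plane offset of the duct axis from the generating curve.  Because
cross-sections are circular, the duct-to-parenchyma area ratio has the
closed form

    DP(s) = r(s)^2 / (R(s)^2 - r(s)^2)

under the parenchyma-excludes-duct convention (r^2 / R^2 under the
whole-pancreas convention), which gives every downstream stage an exact
oracle.  Optional noise jitters the tube surface and adds speckle
components placed well clear of the main body, mimicking stray
false-positive segmentation islands.

Curves are laid out with s = 0 at the patient-left (+x) end, matching
the anatomical convention that the pancreatic tail is the patient-left
end of the organ.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .curve_geometry import build_frames, compute_tangents, resample_polyline
from .dp_ratio import PARENCHYMA_EXCLUDES_DUCT, WHOLE_PANCREAS
from .mask_io import VolumeGeometry, VoxelMask

__all__ = [
    "RadiusProfile",
    "NoiseSpec",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "analytic_dp_profile",
    "generate_cohort",
]

_TRUTH_STEP = 0.25  # mm, arc sampling of the generating curve


class RadiusProfile:
    """Piecewise-linear radius (mm) over arc length, from (s, value) knots.

    Constant segments and sharp steps are expressed with repeated knots
    an epsilon apart; :meth:`scaled_span` builds the focal dilation /
    atrophy profiles used for synthetic lesions.
    """

    def __init__(self, knots_s, knots_v):
        s = np.asarray(knots_s, dtype=float)
        v = np.asarray(knots_v, dtype=float)
        if len(s) != len(v) or len(s) == 0:
            raise ValueError("knots_s and knots_v must be equal-length, nonempty")
        if np.any(np.diff(s) < 0):
            raise ValueError("knots_s must be nondecreasing")
        if np.any(v < 0):
            raise ValueError("radii must be nonnegative")
        self.knots_s = s
        self.knots_v = v

    @classmethod
    def constant(cls, value: float) -> "RadiusProfile":
        return cls([0.0], [value])

    @classmethod
    def ramp(cls, length: float, v0: float, v1: float,
             ramp_start: float = 0.0) -> "RadiusProfile":
        """Constant v0 up to ramp_start, then linear to v1 at ``length``."""
        return cls([0.0, ramp_start, length], [v0, v0, v1])

    def __call__(self, s) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.knots_s, self.knots_v)

    def max(self) -> float:
        return float(self.knots_v.max())

    def scaled_span(self, s0: float, s1: float, factor: float,
                    total_length: float) -> "RadiusProfile":
        """Multiply the radius by ``factor`` on [s0, s1] (sharp edges)."""
        eps = 1e-6
        grid = np.unique(np.concatenate([
            self.knots_s, [0.0, total_length],
            [s0 - eps, s0, s1, s1 + eps],
        ]))
        grid = grid[(grid >= 0) & (grid <= total_length)]
        vals = self(grid)
        inside = (grid >= s0) & (grid <= s1)
        vals[inside] *= factor
        return RadiusProfile(grid, vals)

    def scaled(self, factor: float) -> "RadiusProfile":
        return RadiusProfile(self.knots_s, self.knots_v * factor)


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    surface_jitter_mm: float = 0.0
    n_speckle_components: int = 0
    speckle_radius_mm: float = 1.5

    @property
    def enabled(self) -> bool:
        return self.surface_jitter_mm > 0 or self.n_speckle_components > 0


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic tube phantom.

    curve: "straight" | "arc" | "sinusoid"; ``curve_params`` supplies
    ``radius_mm`` (arc) or ``amplitude_mm``/``wavelength_mm`` (sinusoid).
    """

    length: float = 120.0
    curve: str = "straight"
    curve_params: dict = dataclasses.field(default_factory=dict)
    parenchyma_radius: RadiusProfile = dataclasses.field(
        default_factory=lambda: RadiusProfile.constant(10.0))
    duct_radius: RadiusProfile = dataclasses.field(
        default_factory=lambda: RadiusProfile.constant(2.0))
    duct_offset: tuple[float, float] = (0.0, 0.0)  # (normal, binormal) mm
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    noise: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    seed: int = 0
    mpdd: bool = False
    ppa: bool = False

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("phantom length must be positive")
        if np.any(np.asarray(self.voxel_spacing) <= 0):
            raise ValueError("voxel_spacing must be positive")
        s = np.arange(0.0, self.length + _TRUTH_STEP, _TRUTH_STEP)
        offset = float(np.hypot(*self.duct_offset))
        if np.any(self.duct_radius(s) >= self.parenchyma_radius(s) - offset):
            raise ValueError(
                "duct must lie strictly inside the parenchyma: require "
                "r(s) < R(s) - |duct_offset| for all s")


@dataclasses.dataclass
class PhantomCase:
    pancreas: VoxelMask
    duct: VoxelMask
    truth_curve: np.ndarray     # (M, 3) mm, tail (s=0) first
    truth_s: np.ndarray         # (M,) arc length mm
    truth_profile: np.ndarray   # analytic DP(s) on truth_s
    labels: dict
    spec: PhantomSpec | None = None

    def save_truth(self, path) -> None:
        """Sidecar: s, R, r, DP as delimited text."""
        table = np.column_stack([
            self.truth_s,
            self.spec.parenchyma_radius(self.truth_s),
            self.spec.duct_radius(self.truth_s),
            self.truth_profile,
        ])
        np.savetxt(path, table, delimiter=",", header="s_mm,R_mm,r_mm,dp_ratio",
                   comments="")

    def score_truth(self, percentile: float = 90.0) -> float:
        return float(np.percentile(self.truth_profile, percentile))


def _curve_points(spec: PhantomSpec) -> np.ndarray:
    """Generating curve sampled at <= _TRUTH_STEP arc steps, tail first."""
    L = spec.length
    if spec.curve == "straight":
        t = np.arange(0.0, L + _TRUTH_STEP / 2, _TRUTH_STEP)
        pts = np.column_stack([L - t, np.zeros_like(t), np.zeros_like(t)])
    elif spec.curve == "arc":
        rho = float(spec.curve_params.get("radius_mm", 40.0))
        if L >= np.pi * rho:
            raise ValueError("arc sweep must stay below 180 degrees")
        t = np.arange(0.0, L + _TRUTH_STEP / 2, _TRUTH_STEP)
        phi = t / rho
        pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), np.zeros_like(phi)])
    elif spec.curve == "sinusoid":
        amp = float(spec.curve_params.get("amplitude_mm", 10.0))
        lam = float(spec.curve_params.get("wavelength_mm", 80.0))
        # parametrize by axial coordinate, then trim to the requested arc length
        x = np.arange(0.0, 2 * L + _TRUTH_STEP / 2, _TRUTH_STEP / 2)
        raw = np.column_stack([-x, amp * np.sin(2 * np.pi * x / lam), np.zeros_like(x)])
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(raw, axis=0), axis=1))])
        raw = raw[arc <= L + _TRUTH_STEP]
        raw[:, 0] += x[len(raw) - 1]  # shift so the tail end has the largest x
        pts = raw
    else:
        raise ValueError(f"unknown curve kind: {spec.curve}")
    pts = resample_polyline(pts, step=_TRUTH_STEP)
    return pts


def _arc_lengths(pts: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0],
                           np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Voxelize the phantom: a voxel belongs to the pancreas when its
    center is within R(s*) of the curve, s* being the arc length of the
    nearest curve point; the duct is analogous with r(s*) around the
    (possibly offset) duct axis.  Deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    curve = _curve_points(spec)
    s = _arc_lengths(curve)
    L = s[-1]

    # duct axis: generating curve displaced in the local (normal, binormal) plane
    tangents = compute_tangents(curve, step=_TRUTH_STEP, lookahead=max(2.0, 4 * _TRUTH_STEP))
    frames = build_frames(curve, tangents, arc_s=s)
    ou, ov = spec.duct_offset
    duct_axis = np.array([f.point + ou * f.normal + ov * f.binormal for f in frames])

    margin = spec.parenchyma_radius.max() + 3.0
    if spec.noise.n_speckle_components > 0:
        margin += 5.0 + 2.0 * spec.noise.speckle_radius_mm + 2.0
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    # fixed sub-voxel dither so the tube axis is never lattice-commensurate:
    # an exactly voxel-centered circle is the worst case for boundary
    # quantization and no real acquisition is aligned that way
    lo = curve.min(axis=0) - margin - np.array([0.277, 0.331, 0.413]) * spacing
    hi = curve.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    geometry = VolumeGeometry(spacing=spacing, origin=lo, direction=np.eye(3))

    ax = [lo[k] + spacing[k] * np.arange(shape[k]) for k in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    dist_p, idx_p = cKDTree(curve).query(centers, workers=-1)
    dist_d, idx_d = cKDTree(duct_axis).query(centers, workers=-1)
    R_here = spec.parenchyma_radius(s[idx_p])
    r_here = spec.duct_radius(s[idx_d])

    thresh_p = R_here
    thresh_d = r_here
    if spec.noise.surface_jitter_mm > 0:
        thresh_p = R_here + _smooth_field(shape, spec.noise.surface_jitter_mm, rng).ravel()
        thresh_d = r_here + _smooth_field(shape, spec.noise.surface_jitter_mm, rng).ravel()

    pancreas = (dist_p <= thresh_p).reshape(shape)
    duct = ((dist_d <= thresh_d) & (r_here > 0)).reshape(shape)
    if not spec.noise.enabled:
        duct &= pancreas  # duct strictly inside the parenchyma pre-noise

    if spec.noise.n_speckle_components > 0:
        clearance = dist_p.reshape(shape) - R_here.reshape(shape)
        _add_speckle(pancreas, duct, clearance, centers, shape, spec, rng)

    dp = _analytic_dp(spec, s)
    return PhantomCase(
        pancreas=VoxelMask(pancreas.astype(np.uint8), geometry, "pancreas"),
        duct=VoxelMask(duct.astype(np.uint8), geometry, "mpd"),
        truth_curve=curve, truth_s=s, truth_profile=dp,
        labels={"mpdd": spec.mpdd, "ppa": spec.ppa},
        spec=spec,
    )


def _smooth_field(shape, jitter_mm: float, rng) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    sd = field.std()
    return field * (jitter_mm / sd) if sd > 0 else field


def _add_speckle(pancreas, duct, clearance, centers, shape, spec, rng) -> None:
    """Spherical islands at least 5 mm clear of the tube surface."""
    rad = spec.noise.speckle_radius_mm
    candidates = np.flatnonzero(clearance.ravel() > 5.0 + rad)
    if len(candidates) == 0:
        raise ValueError("phantom grid too tight to place speckle components")
    for k in range(spec.noise.n_speckle_components):
        center = centers[rng.choice(candidates)]
        d = np.linalg.norm(centers - center, axis=1).reshape(shape)
        blob = d <= rad
        if k % 2 == 0:
            pancreas |= blob
        else:
            duct |= blob


def _analytic_dp(spec: PhantomSpec, s: np.ndarray,
                 denominator: str = PARENCHYMA_EXCLUDES_DUCT) -> np.ndarray:
    R = spec.parenchyma_radius(s)
    r = spec.duct_radius(s)
    if denominator == PARENCHYMA_EXCLUDES_DUCT:
        return r ** 2 / (R ** 2 - r ** 2)
    if denominator == WHOLE_PANCREAS:
        return r ** 2 / R ** 2
    raise ValueError(f"unknown denominator convention: {denominator}")


def analytic_dp_profile(spec: PhantomSpec, percentile: float = 90.0,
                        denominator: str = PARENCHYMA_EXCLUDES_DUCT
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form DP(s) on a fine arc grid plus its percentile summary.

    Returns ``(s, dp, score)``.  Circular sections make the ratio exact:
    duct area pi r^2, parenchyma area pi (R^2 - r^2).
    """
    spec.validate()
    s = np.arange(0.0, spec.length + _TRUTH_STEP / 2, _TRUTH_STEP)
    dp = _analytic_dp(spec, s, denominator)
    return s, dp, float(np.percentile(dp, percentile))


def _clamp_inside(duct: RadiusProfile, parenchyma: RadiusProfile,
                  base_spec: PhantomSpec, frac: float = 0.85) -> RadiusProfile:
    """Cap r(s) at ``frac`` of the available lumen so a dilated duct in an
    atrophied span never breaches the parenchyma wall."""
    grid = np.arange(0.0, base_spec.length + _TRUTH_STEP / 2, _TRUTH_STEP)
    offset = float(np.hypot(*base_spec.duct_offset))
    cap = frac * (parenchyma(grid) - offset)
    return RadiusProfile(grid, np.minimum(duct(grid), cap))


def generate_cohort(n_positive: int, n_negative: int,
                    positive_kind: str = "mpdd",
                    base_spec: PhantomSpec | None = None,
                    seed: int = 0,
                    dilation_factor: float = 3.0,
                    atrophy_factor: float = 0.6,
                    span_fraction: tuple[float, float] = (0.25, 0.5),
                    ) -> list[PhantomCase]:
    """Labeled synthetic cohort of phantoms.

    Negatives use ``base_spec`` unchanged (fresh per-case seeds); MPDD
    positives multiply r(s) by ``dilation_factor`` over a random
    contiguous span, PPA positives multiply R(s) by ``atrophy_factor``
    over such a span; ``positive_kind='both'`` applies both on the same
    span.  Per-case RNG streams derive from (seed, case index), so the
    cohort is reproducible and order-independent.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("cohort counts must be nonnegative")
    if positive_kind not in ("mpdd", "ppa", "both"):
        raise ValueError(f"unknown positive_kind: {positive_kind}")
    if base_spec is None:
        base_spec = PhantomSpec(length=80.0, voxel_spacing=(1.0, 1.0, 1.0),
                                parenchyma_radius=RadiusProfile.constant(10.0),
                                duct_radius=RadiusProfile.constant(2.0))
    cases: list[PhantomCase] = []
    for i in range(n_positive + n_negative):
        case_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(case_seed)
        positive = i < n_positive
        spec = dataclasses.replace(base_spec, seed=case_seed,
                                   mpdd=False, ppa=False)
        if positive:
            frac = rng.uniform(*span_fraction)
            span = frac * base_spec.length
            s0 = rng.uniform(0.0, base_spec.length - span)
            s1 = s0 + span
            duct = base_spec.duct_radius
            parenchyma = base_spec.parenchyma_radius
            if positive_kind in ("mpdd", "both"):
                duct = duct.scaled_span(s0, s1, dilation_factor, base_spec.length)
            if positive_kind in ("ppa", "both"):
                parenchyma = parenchyma.scaled_span(s0, s1, atrophy_factor,
                                                    base_spec.length)
            duct = _clamp_inside(duct, parenchyma, base_spec)
            spec = dataclasses.replace(
                spec, duct_radius=duct, parenchyma_radius=parenchyma,
                mpdd=positive_kind in ("mpdd", "both"),
                ppa=positive_kind in ("ppa", "both"))
        cases.append(generate_phantom(spec))
    return cases
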