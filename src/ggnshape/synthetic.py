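"""Synthetic nodule cross-sections with closed-form ground truth.

The generator family is the *bi-ellipse*: two half-ellipses with semi-major
axes ``a1`` (left) and ``a2`` (right) glued along a shared minor axis of
semi-length ``c``, with ``a1 >= a2 >= c > 0``.  This is the minimal shape
family whose chord-and-angle descriptors all have exact closed forms:

    LD      = a1 + a2            (the joined major axis, endpoints A, B)
    PD      = 2 c                (the shared minor axis, endpoints C, D)
    MA      = pi * c * (a1+a2)/2
    angle at the far endpoint  A = 2 atan(c / a1)
    angle at the near endpoint B = 2 atan(c / a2)
    BiA/SmA = atan(c/a2) / atan(c/a1)  >= 1, equality iff a1 = a2

Growing ``a1`` relative to ``a2`` makes the mass more lopsided about the
chord crossing O and strictly increases BiA/SmA — the same monotone link
between asymmetry and the angle ratio that motivates the descriptor on real
nodules.  Because every target (LD, LD/PD, BiA/SmA) inverts analytically up
to one 1-D root find, whole two-class cohorts can be drawn so their
descriptor distributions match a published summary table, giving every
pipeline stage an oracle without clinical data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .geometry import PlanarContour, resample_contour
from .published import (
    GROUP_NEGATIVE,
    GROUP_POSITIVE,
    LOBE_LEVELS,
    TABLE1_AGE,
    TABLE1_LOBE,
    TABLE1_SEX,
    TABLE2_STATS,
)
from .volume import VolumeMask

__all__ = [
    "BiEllipseParams",
    "GroundTruth",
    "CohortSpec",
    "FeasibilityError",
    "max_feasible_ratio",
    "make_biellipse_polygon",
    "make_biellipse_volume",
    "params_from_targets",
    "sample_cohort",
]


class FeasibilityError(ValueError):
    """Requested descriptor targets cannot be realised by any bi-ellipse."""


@dataclass(frozen=True)
class BiEllipseParams:
    """Bi-ellipse shape parameters (mm / degrees)."""

    a1: float
    a2: float
    c: float
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a1 >= self.a2 >= self.c > 0):
            raise ValueError("require a1 >= a2 >= c > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form descriptors of a noise-free bi-ellipse."""

    LD: float
    PD: float
    MA: float
    angle_at_far: float  # degrees, at the a1 (far) LD endpoint
    angle_at_near: float  # degrees, at the a2 (near) LD endpoint

    @property
    def BiA(self) -> float:
        return max(self.angle_at_far, self.angle_at_near)

    @property
    def SmA(self) -> float:
        return min(self.angle_at_far, self.angle_at_near)

    @property
    def ld_pd_ratio(self) -> float:
        return self.LD / self.PD

    @property
    def bia_sma_ratio(self) -> float:
        return self.BiA / self.SmA

    @classmethod
    def from_params(cls, p: BiEllipseParams) -> "GroundTruth":
        return cls(
            LD=p.a1 + p.a2,
            PD=2.0 * p.c,
            MA=math.pi * p.c * (p.a1 + p.a2) / 2.0,
            angle_at_far=math.degrees(2.0 * math.atan(p.c / p.a1)),
            angle_at_near=math.degrees(2.0 * math.atan(p.c / p.a2)),
        )


def _biellipse_base(p: BiEllipseParams, n_dense: int = 4096) -> np.ndarray:
    """Dense untransformed boundary: right half-ellipse (a2, c) for
    x >= 0, left half-ellipse (a1, c) for x <= 0."""
    phi = np.linspace(0.0, 2.0 * math.pi, n_dense, endpoint=False)
    a = np.where(np.cos(phi) >= 0.0, p.a2, p.a1)
    return np.column_stack([a * np.cos(phi), p.c * np.sin(phi)])


def make_biellipse_polygon(
    params: BiEllipseParams,
    n_vertices: int = 720,
    rng: np.random.Generator | None = None,
) -> tuple[PlanarContour, GroundTruth]:
    """Arc-length-uniform bi-ellipse polygon plus its analytic ground truth.

    Ground truth is computed from the parameters before rotation,
    translation and radial jitter are applied (rigid motions leave it
    unchanged; jitter with ``noise_sd > 0`` perturbs only the polygon).
    """
    if n_vertices < 64:
        raise ValueError("need at least 64 vertices")
    truth = GroundTruth.from_params(params)
    v = resample_contour(_biellipse_base(params), n=n_vertices)
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        r = np.linalg.norm(v, axis=1)
        jitter = rng.normal(0.0, params.noise_sd, len(v))
        v = v * ((r + jitter) / r)[:, None]
    th = math.radians(params.rotation)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    v = v @ rot.T + np.asarray(params.translation)
    return PlanarContour(v, plane="axial"), truth


def make_biellipse_volume(
    params: BiEllipseParams,
    spacing: float | tuple[float, float, float] = 0.1,
    half_height: float | None = None,
    extrusion_profile=None,
    lesion_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> VolumeMask:
    """Extrude the bi-ellipse into a 3D mask with a strictly peaked profile.

    Axial slice ``k`` is the base polygon scaled by ``profile(z_k)`` where
    ``z_k`` is the slice-centre offset from the volume midplane; the default
    profile sqrt(1 - |z|/H) with half-height ``H = 0.8 c`` is strictly
    peaked with a nonvanishing slope at the apex, so the central axial slice
    beats its neighbours by more than pixel-count quantisation and stays the
    unique maximal cross-section (coronal/sagittal sections stay smaller
    because H < c).  An odd slice count centres one slice exactly at z = 0.
    """
    from skimage.draw import polygon as draw_polygon

    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    dx, dy, dz = (float(s) for s in spacing)
    if min(dx, dy, dz) <= 0:
        raise ValueError("spacing must be positive")
    if params.c / min(dx, dy) < 4:
        warnings.warn(
            "in-plane spacing too coarse to resolve the minor axis "
            f"(c/spacing = {params.c / min(dx, dy):.1f} < 4)",
            stacklevel=2,
        )
    if half_height is None:
        half_height = 0.8 * params.c
    if extrusion_profile is None:
        def extrusion_profile(z):
            u = abs(z) / half_height if half_height > 0 else 0.0
            return math.sqrt(max(0.0, 1.0 - u))

    base, _ = make_biellipse_polygon(params, rng=rng)
    verts = base.vertices
    center = verts.mean(axis=0)
    if half_height <= 0:
        n_slices = 1
    else:
        n_slices = 2 * int(math.floor(half_height / dz)) + 1
    half_extent = max(abs(verts - center).max(), params.a1) + 2 * max(dx, dy)
    nx = int(math.ceil(2 * half_extent / dx)) + 4
    ny = int(math.ceil(2 * half_extent / dy)) + 4
    vol = np.zeros((nx, ny, n_slices), dtype=np.uint8)
    mid = (n_slices - 1) // 2
    for k in range(n_slices):
        z = (k - mid) * dz
        s = extrusion_profile(z)
        if s <= 0:
            continue
        sv = center + s * (verts - center)
        # physical mm -> fractional voxel index (centres at (i + 0.5) * d)
        ix = (sv[:, 0] - center[0] + half_extent) / dx - 0.5 + 2
        iy = (sv[:, 1] - center[1] + half_extent) / dy - 0.5 + 2
        rr, cc = draw_polygon(ix, iy, shape=(nx, ny))
        vol[rr, cc, k] = 1
    return VolumeMask(
        voxels=vol,
        spacing=(dx, dy, dz),
        lesion_id=lesion_id,
        meta={
            "origin_mm": (
                center[0] - half_extent - 1.5 * dx,
                center[1] - half_extent - 1.5 * dy,
            )
        },
    )


def max_feasible_ratio(ld: float, ld_pd: float) -> float:
    """Largest BiA/SmA a bi-ellipse can realise at given LD and LD/PD.

    Attained as a2 -> c: atan(1) / atan(c / (ld - c)) with c = ld/(2 ld_pd).
    Near-circular shapes (LD/PD -> 1) cannot be angle-asymmetric at all.
    """
    c = ld / (2.0 * ld_pd)
    if not 0 < c <= ld / 2.0:
        raise FeasibilityError(f"LD/PD must be >= 1 (got {ld_pd})")
    return (math.pi / 4.0) / math.atan(c / (ld - c))


def params_from_targets(
    ld: float, ld_pd: float, bia_sma: float, tol: float = 1e-12
) -> BiEllipseParams:
    """Invert the descriptor map: bi-ellipse with exactly these targets.

    Solves a1 + a2 = LD, 2c = LD / (LD/PD), and
    atan(c/a2)/atan(c/a1) = BiA/SmA by Brent root finding on a2 in
    [c, LD/2]; round-trips through ``GroundTruth`` to <= 1e-6.
    """
    if ld <= 0:
        raise FeasibilityError("LD must be positive")
    if ld_pd < 1.0:
        raise FeasibilityError(f"LD/PD must be >= 1 (got {ld_pd})")
    if bia_sma < 1.0:
        raise FeasibilityError(f"BiA/SmA must be >= 1 (got {bia_sma})")
    c = ld / (2.0 * ld_pd)
    if bia_sma == 1.0:
        return BiEllipseParams(a1=ld / 2.0, a2=ld / 2.0, c=c)
    rmax = max_feasible_ratio(ld, ld_pd)
    if bia_sma > rmax:
        raise FeasibilityError(
            f"BiA/SmA = {bia_sma:.4f} exceeds the bi-ellipse maximum "
            f"{rmax:.4f} at LD/PD = {ld_pd:.4f} (requires a2 >= c); "
            "lower the ratio or raise LD/PD"
        )

    def g(a2: float) -> float:
        return math.atan(c / a2) / math.atan(c / (ld - a2)) - bia_sma

    a2 = brentq(g, c, ld / 2.0, xtol=tol, rtol=8.881784197001252e-16)
    return BiEllipseParams(a1=ld - a2, a2=a2, c=c)


def _default_targets() -> dict:
    return {
        "LD_mm": TABLE2_STATS["LD_mm"],
        "LD_PD": TABLE2_STATS["LD_PD"],
        "BiA_SmA": TABLE2_STATS["BiA_SmA"],
    }


@dataclass
class CohortSpec:
    """Recipe for a two-class synthetic cohort.

    Defaults reproduce the study conditions: 39 preinvasive (PGL+MIA) and 59
    invasive (IAC) lesions whose LD, LD/PD and BiA/SmA target distributions
    take the published per-group means and SDs.  Draws are truncated
    normals: LD to [3, 30] mm (the <= 3 cm inclusion criterion), ratios to
    >= 1.001, and BiA/SmA additionally to the geometric maximum the
    bi-ellipse family allows at the drawn LD/PD.
    """

    n_per_group: dict = field(
        default_factory=lambda: {GROUP_NEGATIVE: 39, GROUP_POSITIVE: 59}
    )
    targets: dict = field(default_factory=_default_targets)
    seed: int = 0
    ld_bounds: tuple[float, float] = (3.0, 30.0)
    ratio_floor: float = 1.001
    noise_sd: float = 0.0
    max_infeasible_frac: float = 0.10

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")
        for feat, per_group in self.targets.items():
            for g, (_, sd) in per_group.items():
                if sd <= 0:
                    raise ValueError(f"SD for {feat}/{g} must be positive")


def _tnorm(rng, mean, sd, lo, hi, size=None):
    a = (lo - mean) / sd
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(
    spec: CohortSpec,
    shapes: str = "contour",
    n_vertices: int = 720,
    spacing: float = 0.1,
) -> tuple[pd.DataFrame, list]:
    """Draw a two-class cohort of bi-ellipse nodules.

    Returns the cohort table (one row per lesion with the ground-truth
    descriptors, group label and demographics sampled from the published
    cohort composition) and the lesion shapes: planar contours
    (``shapes="contour"``), extruded volume masks (``"volume"``), or no
    shapes (``"none"``).  Fully reproducible from ``spec.seed``.
    """
    if shapes not in {"contour", "volume", "none"}:
        raise ValueError("shapes must be 'contour', 'volume' or 'none'")
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    out_shapes: list = []
    lesion = 0
    for group in (GROUP_NEGATIVE, GROUP_POSITIVE):
        n = int(spec.n_per_group[group])
        m_ld, s_ld = spec.targets["LD_mm"][group]
        m_lp, s_lp = spec.targets["LD_PD"][group]
        m_r, s_r = spec.targets["BiA_SmA"][group]
        n_infeasible = 0
        sex_p = TABLE1_SEX[group][0] / sum(TABLE1_SEX[group])
        lobe_p = np.asarray(TABLE1_LOBE[group], float)
        lobe_p = lobe_p / lobe_p.sum()
        age_m, age_s = TABLE1_AGE[group]
        for _ in range(n):
            while True:
                ld = float(_tnorm(rng, m_ld, s_ld, *spec.ld_bounds))
                lp = float(_tnorm(rng, m_lp, s_lp, spec.ratio_floor, np.inf))
                rmax = max_feasible_ratio(ld, lp) - 1e-6
                if rmax <= spec.ratio_floor:
                    n_infeasible += 1
                    if n_infeasible > spec.max_infeasible_frac * n:
                        raise FeasibilityError(
                            "more than "
                            f"{spec.max_infeasible_frac:.0%} of draws have an "
                            "empty BiA/SmA feasibility window; widen the "
                            "LD/PD truncation bounds away from 1"
                        )
                    continue
                r = float(_tnorm(rng, m_r, s_r, spec.ratio_floor, rmax))
                break
            params = params_from_targets(ld, lp, r)
            params = BiEllipseParams(
                a1=params.a1,
                a2=params.a2,
                c=params.c,
                rotation=float(rng.uniform(0.0, 180.0)),
                translation=tuple(rng.uniform(-5.0, 5.0, 2)),
                noise_sd=spec.noise_sd,
            )
            truth = GroundTruth.from_params(params)
            lesion_id = f"syn{lesion:03d}"
            rows.append(
                {
                    "lesion_id": lesion_id,
                    "group": group,
                    "sex": "M" if rng.uniform() < sex_p else "F",
                    "age": float(np.clip(rng.normal(age_m, age_s), 29, 83)),
                    "lobe": LOBE_LEVELS[int(rng.choice(5, p=lobe_p))],
                    "plane": "axial",
                    "MA_mm2": truth.MA,
                    "LD_mm": truth.LD,
                    "PD_mm": truth.PD,
                    "BiA_deg": truth.BiA,
                    "SmA_deg": truth.SmA,
                    "LD_PD": truth.ld_pd_ratio,
                    "BiA_SmA": truth.bia_sma_ratio,
                    "a1": params.a1,
                    "a2": params.a2,
                    "c": params.c,
                    "rotation": params.rotation,
                }
            )
            if shapes == "contour":
                contour, _ = make_biellipse_polygon(
                    params, n_vertices=n_vertices, rng=rng
                )
                out_shapes.append(contour)
            elif shapes == "volume":
                out_shapes.append(
                    make_biellipse_volume(
                        params, spacing=spacing, lesion_id=lesion_id
                    )
                )
            lesion += 1
    return pd.DataFrame(rows), out_shapes
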