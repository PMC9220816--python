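"""Synthetic phantom cases with controlled capsule-contact geometry.

The phantom generator stands in for the upstream deep-learning cancer
detector: it produces a smooth cancer-probability volume, a binary
prostate mask and matching ground-truth cancer/EPE labelmaps whose
geometry is known analytically, so every downstream pipeline stage can be
tested against closed-form oracles.

Construction
------------
* The prostate is an axis-aligned ellipsoid; a voxel is prostate iff its
  center lies inside.
* Each lesion is a ball of radius ``R`` carrying a cosine-taper
  probability kernel ``peak * (1 + cos(pi * r / R)) / 2``.  The kernel is
  smooth, compactly supported, and — crucially — its super-level set at
  any threshold ``alpha`` is again a ball, of radius
  ``r_alpha = (R / pi) * arccos(2 * alpha / peak - 1)``, so the support
  the decision pipeline sees after thresholding is analytically known.
* The probability volume is the voxelwise maximum over lesion kernels
  plus uniform noise on ``[0, amplitude]``, clipped to [0, 1].
* The oracle tumor–capsule contact length of a lesion is computed from
  the analytic geometry: per axial slice the capsule cross-section is an
  ellipse, the ball cuts a single contiguous arc out of it, and the
  oracle is the maximum arc length over slices (matching the in-plane,
  max-over-slices convention of the pipeline's measurement).
  :func:`oracle_contact_length` evaluates it at any alpha.

Straddling lesions are placed by bisecting the lesion-center offset along
the outward capsule normal until the oracle arc matches the requested
target contact length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import EvalCase
from .volio import Volume3D

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomLesion",
    "PhantomCase",
    "make_prostate",
    "make_case",
    "make_cohort",
    "oracle_contact_length",
    "support_radius",
]

_ARC_SAMPLES = 4096  # ellipse samples per slice for the geometric oracle


def support_radius(radius_mm: float, peak: float, alpha: float) -> float:
    """Radius of the ball where the cosine-taper kernel exceeds ``alpha``."""
    if alpha <= 0:
        return radius_mm
    if alpha >= peak:
        return 0.0
    return radius_mm / math.pi * math.acos(2.0 * alpha / peak - 1.0)


@dataclass
class LesionSpec:
    """Requested geometry for one phantom lesion.

    placement : "interior" (ball strictly inside the capsule),
    "straddling" (crosses the capsule with a prescribed contact arc) or
    "exterior" (ball strictly outside, separated by ``gap_mm``).
    target_contact_mm : straddling only — requested capsule contact arc.
    contact_alpha : the threshold at which the target arc is measured
    (0.0 = on the full kernel support; set to the pipeline operating alpha
    to prescribe the arc the pipeline will actually see).
    direction_deg : in-plane angle selecting where on the capsule the
    lesion sits.  z_offset_frac : axial position as a fraction of the
    ellipsoid z semi-axis.  depth_frac : interior only — how far along
    the ray from the ellipsoid center toward the capsule.
    """

    radius_mm: float
    peak: float = 0.8
    placement: str = "straddling"
    target_contact_mm: float | None = None
    contact_alpha: float = 0.0
    direction_deg: float = 0.0
    z_offset_frac: float = 0.0
    depth_frac: float = 0.4
    gap_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        if not 0.0 < self.peak <= 1.0:
            raise ValueError("peak probability must lie in (0, 1]")
        if self.placement not in ("interior", "straddling", "exterior"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.placement == "straddling" and self.target_contact_mm is None:
            raise ValueError("straddling lesion needs target_contact_mm")


@dataclass
class PhantomSpec:
    """Grid, prostate ellipsoid and lesion layout of one synthetic case."""

    shape: tuple[int, int, int] = (224, 224, 20)
    spacing: tuple[float, float, float] = (0.29, 0.29, 3.0)
    center_mm: tuple[float, float, float] | None = None
    semi_axes_mm: tuple[float, float, float] = (20.0, 16.0, 14.0)
    lesions: list[LesionSpec] = field(default_factory=list)
    noise_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("degenerate ellipsoid semi-axis")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.center_mm is None:
            self.center_mm = tuple(
                (n - 1) * d / 2.0 for n, d in zip(self.shape, self.spacing)
            )
        extent = [(n - 1) * d for n, d in zip(self.shape, self.spacing)]
        for c, a, e in zip(self.center_mm, self.semi_axes_mm, extent):
            if c - a < 0 or c + a > e:
                raise ValueError(
                    f"prostate ellipsoid exceeds grid bounds: center {c} mm, "
                    f"semi-axis {a} mm, extent {e} mm"
                )


@dataclass
class PhantomLesion:
    """Realized lesion with its geometric oracle values."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak: float
    placement: str
    contact_mm: float  # oracle contact arc of the full support (alpha = 0)
    crosses_capsule: bool


@dataclass
class PhantomCase:
    """One synthetic case: volumes, labels and per-lesion oracle records."""

    p_ca: Volume3D
    prostate: Volume3D
    gt_cancer: Volume3D
    gt_epe: Volume3D
    lesions: list[PhantomLesion]
    spec: PhantomSpec

    def as_eval_case(self, case_id: str = "") -> EvalCase:
        return EvalCase(self.p_ca, self.prostate, self.gt_epe, case_id)


# ---------------------------------------------------------------------------
# analytic geometry


def _slice_ellipse(spec: PhantomSpec, z_mm: float) -> tuple[float, float] | None:
    """Semi-axes of the capsule cross-section at height z, or None."""
    cx, cy, cz = spec.center_mm
    a, b, c = spec.semi_axes_mm
    u = (z_mm - cz) / c
    if abs(u) >= 1.0:
        return None
    s = math.sqrt(1.0 - u * u)
    return a * s, b * s


def _contact_arc_analytic(
    spec: PhantomSpec, center_mm: np.ndarray, radius_mm: float
) -> float:
    """Max over slices of the capsule-ellipse arc length inside the ball."""
    if radius_mm <= 0:
        return 0.0
    cx, cy, _ = spec.center_mm
    dz = spec.spacing[2]
    nz = spec.shape[2]
    theta = np.linspace(0.0, 2.0 * np.pi, _ARC_SAMPLES, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    best = 0.0
    for k in range(nz):
        z = k * dz
        if abs(z - center_mm[2]) >= radius_mm:
            continue
        ell = _slice_ellipse(spec, z)
        if ell is None:
            continue
        az, bz = ell
        px = cx + az * ct
        py = cy + bz * st
        d2 = (px - center_mm[0]) ** 2 + (py - center_mm[1]) ** 2 + (z - center_mm[2]) ** 2
        inside = d2 < radius_mm**2
        if not inside.any():
            continue
        # the ball cuts a single contiguous arc out of the convex ellipse
        seg = np.sqrt(np.diff(px, append=px[0]) ** 2 + np.diff(py, append=py[0]) ** 2)
        if inside.all():
            best = max(best, float(seg.sum()))
            continue
        start = int(np.flatnonzero(~inside)[0])
        inside_r = np.roll(inside, -start)
        seg_r = np.roll(seg, -start)
        run = 0.0
        cur = 0.0
        for i in range(1, _ARC_SAMPLES):
            if inside_r[i] and inside_r[i - 1]:
                cur += seg_r[i - 1]
                run = max(run, cur)
            elif inside_r[i]:
                cur = 0.0
        best = max(best, float(run))
    return best


def oracle_contact_length(
    case_or_spec: "PhantomCase | PhantomSpec", lesion: PhantomLesion, alpha: float = 0.0
) -> float:
    """Geometric contact length of a lesion's support at threshold ``alpha``.

    At ``alpha = 0`` this is the contact arc of the full kernel support;
    at the pipeline operating alpha it is the arc of the thresholded
    component the pipeline measures.
    """
    spec = case_or_spec.spec if isinstance(case_or_spec, PhantomCase) else case_or_spec
    r = support_radius(lesion.radius_mm, lesion.peak, alpha)
    return _contact_arc_analytic(spec, np.asarray(lesion.center_mm), r)


# ---------------------------------------------------------------------------
# placement


def _capsule_ray(spec: PhantomSpec, direction_deg: float, z_mm: float):
    """Capsule surface point and outward in-plane unit normal direction.

    Returns ``(surface_point_mm, unit_dir, ray_length)`` where the ray runs
    from the ellipse center through the parametric point at the given
    angle; the direction is radial, which suffices for placement because
    offsets are solved against the arc oracle, not trigonometry.
    """
    ell = _slice_ellipse(spec, z_mm)
    if ell is None:
        raise ValueError(f"no capsule cross-section at z = {z_mm} mm")
    az, bz = ell
    t = math.radians(direction_deg)
    cx, cy, _ = spec.center_mm
    sx, sy = cx + az * math.cos(t), cy + bz * math.sin(t)
    v = np.array([sx - cx, sy - cy])
    length = float(np.linalg.norm(v))
    return np.array([sx, sy, z_mm]), v / length, length


def _check_ball_in_grid(spec: PhantomSpec, center: np.ndarray, r: float) -> None:
    extent = [(n - 1) * d for n, d in zip(spec.shape, spec.spacing)]
    for c, e in zip(center, extent):
        if c - r < 0 or c + r > e:
            raise ValueError(
                f"lesion ball (center {tuple(np.round(center, 2))} mm, radius {r} mm) "
                "exceeds grid bounds"
            )


def _place_lesion(spec: PhantomSpec, les: LesionSpec) -> np.ndarray:
    """Resolve a LesionSpec to a lesion center in mm."""
    z = spec.center_mm[2] + les.z_offset_frac * spec.semi_axes_mm[2]
    surface, u, ray_len = _capsule_ray(spec, les.direction_deg, z)
    if les.placement == "interior":
        center = np.array(
            [
                spec.center_mm[0] + (surface[0] - spec.center_mm[0]) * les.depth_frac,
                spec.center_mm[1] + (surface[1] - spec.center_mm[1]) * les.depth_frac,
                z,
            ]
        )
        if _contact_arc_analytic(spec, center, les.radius_mm) > 0 or np.any(
            _support_outside(spec, center, les.radius_mm)
        ):
            raise ValueError(
                "interior lesion touches or crosses the capsule; reduce radius_mm "
                "or depth_frac"
            )
        return center
    if les.placement == "exterior":
        center = surface + (les.radius_mm + les.gap_mm) * np.append(u, 0.0)
        _check_ball_in_grid(spec, center, les.radius_mm)
        return center
    # straddling: bisect the outward offset of the lesion center along the
    # capsule normal so the oracle arc of the support at contact_alpha
    # matches the target.  The arc is maximal with the center on the
    # capsule (offset 0) and decreases monotonically as the center moves
    # outward, vanishing as the offset approaches the support radius.
    r_ref = support_radius(les.radius_mm, les.peak, les.contact_alpha)
    if r_ref <= 0:
        raise ValueError("contact_alpha is at or above the lesion peak; support empty")
    target = float(les.target_contact_mm)

    def arc(offset: float) -> float:
        c = surface + offset * np.append(u, 0.0)
        return _contact_arc_analytic(spec, c, r_ref)

    lo, hi = 0.0, 0.95 * r_ref
    if arc(lo) < target:
        raise ValueError(
            f"target contact arc {target:.2f} mm infeasible: the widest straddling "
            f"placement reaches only {arc(lo):.2f} mm (support radius {r_ref:.2f} mm)"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if arc(mid) >= target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    center = surface + lo * np.append(u, 0.0)
    _check_ball_in_grid(spec, center, les.radius_mm)
    return center


def _support_outside(spec: PhantomSpec, center: np.ndarray, r: float) -> np.ndarray:
    """Sample points of the ball support that fall outside the ellipsoid."""
    # coarse check on the 6 axis poles of the ball
    cx, cy, cz = spec.center_mm
    a, b, c = spec.semi_axes_mm
    offs = np.array(
        [[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, -r, 0], [0, 0, r], [0, 0, -r]]
    )
    pts = center + 0.999 * offs
    val = ((pts[:, 0] - cx) / a) ** 2 + ((pts[:, 1] - cy) / b) ** 2 + ((pts[:, 2] - cz) / c) ** 2
    return val >= 1.0


# ---------------------------------------------------------------------------
# rasterization


def _voxel_coords(spec: PhantomSpec):
    dx, dy, dz = spec.spacing
    nx, ny, nz = spec.shape
    x = (np.arange(nx) * dx)[:, None, None]
    y = (np.arange(ny) * dy)[None, :, None]
    z = (np.arange(nz) * dz)[None, None, :]
    return x, y, z


def make_prostate(spec: PhantomSpec) -> Volume3D:
    """Binary ellipsoid mask: voxels whose centers lie inside."""
    x, y, z = _voxel_coords(spec)
    cx, cy, cz = spec.center_mm
    a, b, c = spec.semi_axes_mm
    inside = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 < 1.0
    return Volume3D(inside.astype(np.uint8), spec.spacing, kind="mask")


def _rasterize_lesion(
    spec: PhantomSpec, center: np.ndarray, radius: float, peak: float
) -> tuple[np.ndarray, np.ndarray]:
    """(kernel field, support mask) of one lesion over the full grid."""
    x, y, z = _voxel_coords(spec)
    r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    support = r < radius
    kern = np.zeros(spec.shape, dtype=float)
    kern[support] = peak * (1.0 + np.cos(np.pi * r[support] / radius)) / 2.0
    return kern, support


def make_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one synthetic case from a fully specified layout."""
    prostate = make_prostate(spec)
    rng = np.random.default_rng(spec.seed)
    p = np.zeros(spec.shape, dtype=float)
    gt_cancer = np.zeros(spec.shape, dtype=bool)
    gt_epe = np.zeros(spec.shape, dtype=bool)
    lesions: list[PhantomLesion] = []
    pr = prostate.astype_bool()
    for les in spec.lesions:
        center = _place_lesion(spec, les)
        kern, support = _rasterize_lesion(spec, center, les.radius_mm, les.peak)
        p = np.maximum(p, kern)
        gt_cancer |= support
        if les.placement in ("straddling", "exterior"):
            gt_epe |= support & ~pr
        contact = _contact_arc_analytic(spec, center, les.radius_mm)
        lesions.append(
            PhantomLesion(
                center_mm=tuple(float(v) for v in center),
                radius_mm=les.radius_mm,
                peak=les.peak,
                placement=les.placement,
                contact_mm=contact,
                crosses_capsule=les.placement == "straddling",
            )
        )
    if spec.noise_amplitude > 0:
        p = p + rng.uniform(0.0, spec.noise_amplitude, size=spec.shape)
    p = np.clip(p, 0.0, 1.0)
    return PhantomCase(
        p_ca=Volume3D(p, spec.spacing, kind="probability"),
        prostate=prostate,
        gt_cancer=Volume3D(gt_cancer.astype(np.uint8), spec.spacing, kind="mask"),
        gt_epe=Volume3D(gt_epe.astype(np.uint8), spec.spacing, kind="mask"),
        lesions=lesions,
        spec=spec,
    )


def make_cohort(
    n: int,
    epe_prevalence: float = 0.5,
    seed: int = 0,
    shape: tuple[int, int, int] = (224, 224, 20),
    spacing: tuple[float, float, float] = (0.29, 0.29, 3.0),
    noise_amplitude: float = 0.05,
) -> list[PhantomCase]:
    """Generate a reproducible cohort with randomized geometry.

    Each case draws from its own generator seeded by ``(seed, index)``,
    so a given case is bit-identical regardless of cohort size.  A case
    is EPE-positive (contains at least one straddling lesion) with
    probability ``epe_prevalence``; negative cases carry zero to two
    fully interior lesions.
    """
    if not 0.0 <= epe_prevalence <= 1.0:
        raise ValueError("epe_prevalence must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    cases = []
    for idx in range(n):
        rng = np.random.default_rng([seed, idx])
        hx, hy, hz = ((m - 1) * d / 2.0 for m, d in zip(shape, spacing))
        semi = (
            hx * rng.uniform(0.42, 0.52),
            hy * rng.uniform(0.36, 0.46),
            hz * rng.uniform(0.50, 0.62),
        )
        # periprostatic room bounds the feasible lesion size: the center
        # sits at offset t >= 0 outside the capsule and the ball must stay
        # on the grid, so reach <= t + R < 1.9 R for the arcs drawn below
        room = min(hx - semi[0], hy - semi[1]) - 1.0
        r_max = room / 1.9
        positive = rng.random() < epe_prevalence
        lesions: list[LesionSpec] = []
        if positive:
            n_straddle = int(rng.integers(1, 3))
            base_dir = rng.uniform(0.0, 360.0)
            for j in range(n_straddle):
                # prescribe the contact arc at alpha = 0.25 (inside the
                # recommended operating band) so detectability degrades
                # gradually over the threshold sweep, as with real lesions
                contact_alpha = 0.25
                peak = rng.uniform(0.60, 0.95)
                kappa = support_radius(1.0, peak, contact_alpha)
                target = 1.8 * kappa * r_max * rng.uniform(0.35, 0.95)
                radius = min(target / (kappa * rng.uniform(1.15, 1.6)), r_max)
                # snap the lesion to the nearest slice plane so the widest
                # in-plane cut of its support is actually sampled
                cz = (shape[2] - 1) * spacing[2] / 2.0
                z_mm = cz + rng.uniform(-0.2, 0.2) * semi[2]
                z_snap = np.clip(round(z_mm / spacing[2]), 0, shape[2] - 1) * spacing[2]
                spec_j = LesionSpec(
                    radius_mm=radius,
                    peak=peak,
                    placement="straddling",
                    target_contact_mm=target,
                    contact_alpha=contact_alpha,
                    direction_deg=base_dir + 180.0 * j + rng.uniform(-25, 25),
                    z_offset_frac=(z_snap - cz) / semi[2],
                )
                lesions.append(spec_j)
        n_interior = int(rng.integers(0, 3)) if not positive else int(rng.integers(0, 2))
        for j in range(n_interior):
            lesions.append(
                LesionSpec(
                    radius_mm=min(semi) * rng.uniform(0.18, 0.30),
                    peak=rng.uniform(0.50, 0.90),
                    placement="interior",
                    direction_deg=rng.uniform(0.0, 360.0),
                    depth_frac=rng.uniform(0.2, 0.45),
                    z_offset_frac=rng.uniform(-0.15, 0.15),
                )
            )
        spec = PhantomSpec(
            shape=shape,
            spacing=spacing,
            semi_axes_mm=semi,
            lesions=lesions,
            noise_amplitude=noise_amplitude,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for attempt in range(4):
            try:
                cases.append(make_case(spec))
                break
            except ValueError:
                # slice sampling or curvature can make an aggressive arc
                # infeasible; retry with the straddling targets scaled down
                if attempt == 3:
                    raise
                for les in spec.lesions:
                    if les.placement == "straddling":
                        les.target_contact_mm = 0.75 * les.target_contact_mm
    return cases
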