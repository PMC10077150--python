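"""Synthetic test substrates: vascular-tree scenes and calibrated cohorts.

Two families of generators live here.

**Scene generators** build binary vessel/disc mask pairs with known
ground-truth geometry: a recursive bifurcating vessel tree rooted on the
optic-disc rim, plus straight-tube and circular-arc fixtures whose caliber
and curvature are known analytically. Rasterization uses the pixel-center
rule: a pixel is vessel iff its center lies within caliber/2 of the
centerline polyline (exact point-to-segment distance, no sampling error).

**Cohort generator** draws per-eye metric tables of n = 146 children in six
one-year age groups, with each metric generated from a published linear (or
piecewise-linear, or log-linear) age model plus Gaussian noise whose
standard deviation is calibrated so that a refitted regression reproduces
the model's R². Vessel density and fractal dimension receive jointly drawn
residuals so their overall Pearson correlation hits a configured target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mask import BinaryMask, DEFAULT_FRAME_SHAPE, DEFAULT_SCALE_UM_PER_PX, save_mask

__all__ = [
    "VesselTreeParams",
    "TruthSegment",
    "SyntheticScene",
    "CohortParams",
    "MetricModel",
    "generate_vessel_tree",
    "generate_tube_scene",
    "generate_arc_scene",
    "calibrate_noise_sd",
    "generate_cohort",
    "save_scene",
    "AGE_GROUP_COUNTS",
    "DAYS_PER_YEAR",
    "BREAKPOINT_DAYS",
    "COHORT_COLUMNS",
]

DAYS_PER_YEAR = 365
#: Children per one-year age group, 0–1 y through 5–6 y.
AGE_GROUP_COUNTS = (43, 25, 24, 14, 16, 24)
#: Caliber growth-model breakpoint: 3 years, in days.
BREAKPOINT_DAYS = 1095

COHORT_COLUMNS = [
    "age_days",
    "sex",
    "eye",
    "gestational_age_weeks",
    "birth_weight_g",
    "disc_diameter_mm",
    "fractal_dimension",
    "caliber_um",
    "density_fraction",
    "curvature_px_inv",
]


# --------------------------------------------------------------------------
# Scene generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselTreeParams:
    """Parameters of the recursive bifurcating vessel-tree generator."""

    seed: int = 0
    image_height_px: int = DEFAULT_FRAME_SHAPE[0]
    image_width_px: int = DEFAULT_FRAME_SHAPE[1]
    disc_center: tuple[float, float] = (600.0, 700.0)
    disc_diameter_px: float = 110.6  # ~1.35 mm at 12.2 um/px
    n_roots: int = 6
    root_caliber_px: float = 9.0
    caliber_decay: float = 0.8
    branch_rate: float = 0.9  # expected bifurcations per 100 px of centerline
    tortuosity_amplitude_px: float = 3.0
    tortuosity_wavelength_px: float = 120.0
    max_depth: int = 5
    min_caliber_px: float = 1.5

    def validate(self) -> None:
        h, w = self.image_height_px, self.image_width_px
        if h <= 0 or w <= 0:
            raise ValueError("frame dimensions must be positive")
        r = self.disc_diameter_px / 2.0
        cr, cc = self.disc_center
        if not (cr - r >= 0 and cr + r <= h - 1 and cc - r >= 0 and cc + r <= w - 1):
            raise ValueError("optic disc does not fit inside the frame")
        if self.disc_diameter_px <= 0 or self.root_caliber_px <= 0:
            raise ValueError("disc diameter and root caliber must be positive")
        if not (0 < self.caliber_decay <= 1):
            raise ValueError("caliber_decay must lie in (0, 1]")
        if self.min_caliber_px <= 0 or self.min_caliber_px > self.root_caliber_px:
            raise ValueError("require 0 < min_caliber_px <= root_caliber_px")
        if self.n_roots < 1 or self.max_depth < 0:
            raise ValueError("n_roots >= 1 and max_depth >= 0 required")
        if self.branch_rate < 0 or self.tortuosity_amplitude_px < 0:
            raise ValueError("branch_rate and tortuosity amplitude must be >= 0")
        if self.tortuosity_wavelength_px <= 0:
            raise ValueError("tortuosity_wavelength_px must be positive")


@dataclass(frozen=True)
class TruthSegment:
    """One centerline segment of a generated scene, with known geometry.

    ``curvature_px_inv`` is 0.0 for straight segments, 1/R for circular
    arcs, and None when the centerline is sinusoidally perturbed (curvature
    varies along the segment).
    """

    polyline: np.ndarray  # (N, 2) float, (row, col) px
    caliber_px: float
    curvature_px_inv: float | None
    depth: int = 0
    parent: int | None = None


@dataclass
class SyntheticScene:
    """A vessel/disc mask pair plus the ground truth it was drawn from."""

    vessel_mask: BinaryMask
    disc_mask: BinaryMask
    truth_segments: list[TruthSegment]
    truth_density: float | None = None
    disc_center: tuple[float, float] | None = None
    disc_diameter_px: float | None = None

    def __post_init__(self) -> None:
        if self.vessel_mask.shape != self.disc_mask.shape:
            raise ValueError("vessel and disc masks must share dimensions")
        if self.vessel_mask.scale_um_per_px != self.disc_mask.scale_um_per_px:
            raise ValueError("vessel and disc masks must share scale")
        h, w = self.vessel_mask.shape
        for seg in self.truth_segments:
            p = seg.polyline
            if p[:, 0].min() < 0 or p[:, 0].max() > h - 1 or p[:, 1].min() < 0 or p[:, 1].max() > w - 1:
                raise ValueError("truth polyline leaves the frame")


def rasterize_tube(shape: tuple[int, int], polyline: np.ndarray, radius: float,
                   out: np.ndarray | None = None) -> np.ndarray:
    """Mark pixels whose center lies within ``radius`` of the polyline.

    Distance is the exact Euclidean point-to-segment distance over the
    polyline pieces, so axis-aligned tubes of odd integer width w rasterize
    to exactly w pixels per cross-section.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("polyline must be an (N, 2) array")
    if out is None:
        out = np.zeros(shape, dtype=bool)
    if len(pts) == 1:
        pts = np.vstack([pts, pts])
    h, w = shape
    r2 = radius * radius
    # chunk the polyline so each distance evaluation stays on a local window
    chunk = 16
    for s in range(0, len(pts) - 1, chunk):
        sub = pts[s:s + chunk + 1]
        rmin = max(0, int(math.floor(sub[:, 0].min() - radius)))
        rmax = min(h - 1, int(math.ceil(sub[:, 0].max() + radius)))
        cmin = max(0, int(math.floor(sub[:, 1].min() - radius)))
        cmax = min(w - 1, int(math.ceil(sub[:, 1].max() + radius)))
        if rmin > rmax or cmin > cmax:
            continue
        rr, cc = np.meshgrid(np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1),
                             indexing="ij")
        p = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        d2 = np.full(len(p), np.inf)
        for a, b in zip(sub[:-1], sub[1:]):
            ab = b - a
            ll = ab @ ab
            if ll == 0:
                proj = np.broadcast_to(a, p.shape)
            else:
                t = np.clip(((p - a) @ ab) / ll, 0.0, 1.0)
                proj = a + t[:, None] * ab
            d2 = np.minimum(d2, ((p - proj) ** 2).sum(axis=1))
        hit = (d2 <= r2 + 1e-9).reshape(rr.shape)
        out[rmin:rmax + 1, cmin:cmax + 1] |= hit
    return out


def _filled_disc(shape: tuple[int, int], center: tuple[float, float],
                 diameter: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= (diameter / 2.0) ** 2


def _annulus_membership(shape: tuple[int, int], center: tuple[float, float],
                        inner: float, outer: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 >= inner * inner) & (d2 <= outer * outer)


def generate_vessel_tree(params: VesselTreeParams,
                         scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX) -> SyntheticScene:
    """Grow a recursive bifurcating vessel tree rooted on the disc rim.

    Roots leave the disc rim radially at evenly spaced, jittered angles.
    Each segment's centerline is a straight baseline plus a sinusoidal
    perpendicular perturbation (zero offset at the proximal end so segments
    connect); its length is exponential with mean 100/branch_rate px. At a
    bifurcation both children inherit caliber × caliber_decay and deviate
    from the parent direction by a random 17–37°. Growth stops at
    ``max_depth``, below ``min_caliber_px``, or at the frame border.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height_px, params.image_width_px
    vessel = np.zeros((h, w), dtype=bool)
    segments: list[TruthSegment] = []

    def clip_to_frame(poly: np.ndarray) -> tuple[np.ndarray, bool]:
        inside = ((poly[:, 0] >= 1) & (poly[:, 0] <= h - 2)
                  & (poly[:, 1] >= 1) & (poly[:, 1] <= w - 2))
        if inside.all():
            return poly, False
        k = int(np.argmin(inside))  # first vertex outside
        return poly[: max(k, 0)], True

    def grow(start: np.ndarray, direction: np.ndarray, caliber: float,
             depth: int, parent: int | None) -> None:
        if params.branch_rate > 0:
            length = float(np.clip(rng.exponential(100.0 / params.branch_rate), 30.0, 600.0))
        else:
            length = 2.0 * max(h, w)
        t = np.arange(0.0, length + 1.0, 1.0)
        base = start[None, :] + t[:, None] * direction[None, :]
        amp, lam = params.tortuosity_amplitude_px, params.tortuosity_wavelength_px
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            normal = np.array([-direction[1], direction[0]])
            offset = amp * (np.sin(2 * np.pi * t / lam + phase) - np.sin(phase))
            poly = base + offset[:, None] * normal[None, :]
        else:
            poly = base
        poly, truncated = clip_to_frame(poly)
        if len(poly) < 2:
            return
        rasterize_tube((h, w), poly, caliber / 2.0, out=vessel)
        curv = 0.0 if amp == 0 else None
        segments.append(TruthSegment(poly, caliber, curv, depth, parent))
        idx = len(segments) - 1
        child_cal = caliber * params.caliber_decay
        if truncated or depth >= params.max_depth or child_cal < params.min_caliber_px:
            return
        end = poly[-1]
        for sign in (1.0, -1.0):
            ang = sign * rng.uniform(np.deg2rad(17), np.deg2rad(37))
            ca, sa = math.cos(ang), math.sin(ang)
            d = np.array([ca * direction[0] - sa * direction[1],
                          sa * direction[0] + ca * direction[1]])
            grow(end, d, child_cal, depth + 1, idx)

    cr, cc = params.disc_center
    rim = params.disc_diameter_px / 2.0
    for i in range(params.n_roots):
        theta = 2 * np.pi * i / params.n_roots + rng.uniform(-0.3, 0.3)
        d = np.array([math.sin(theta), math.cos(theta)])
        start = np.array([cr, cc]) + rim * d
        grow(start, d, params.root_caliber_px, 0, None)

    if not vessel.any():
        raise ValueError(
            "parameters produced zero vessel pixels "
            f"(n_roots={params.n_roots}, root_caliber_px={params.root_caliber_px})")

    disc = _filled_disc((h, w), params.disc_center, params.disc_diameter_px)
    ann = _annulus_membership((h, w), params.disc_center,
                              0.5 * params.disc_diameter_px,
                              3.0 * params.disc_diameter_px)
    truth_density = float((vessel & ann).sum() / ann.sum())
    return SyntheticScene(
        vessel_mask=BinaryMask(vessel, scale_um_per_px),
        disc_mask=BinaryMask(disc, scale_um_per_px),
        truth_segments=segments,
        truth_density=truth_density,
        disc_center=params.disc_center,
        disc_diameter_px=params.disc_diameter_px,
    )


def generate_tube_scene(width_px: float, orientation_deg: float, length_px: float,
                        frame_shape: tuple[int, int] = (400, 400),
                        scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX) -> SyntheticScene:
    """A single straight tube of constant width through the frame center.

    Orientation 0° runs along columns (horizontal); 90° along rows. For even
    integer widths the centerline is offset half a pixel along its normal so
    the pixel-center rule yields exactly ``width`` pixels per cross-section.
    Oblique tubes get a small (0.21 px) perpendicular offset: a centerline
    passing exactly through lattice points is a degenerate alignment (at 45°
    it quantizes the rasterized width to multiples of √2/2 around the wrong
    value) that real vasculature, with random sub-pixel offsets, never hits.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    h, w = frame_shape
    ang = math.radians(orientation_deg)
    d = np.array([math.sin(ang), math.cos(ang)])
    n = np.array([-d[1], d[0]])
    center = np.array([h / 2.0, w / 2.0])
    if float(width_px).is_integer() and int(width_px) % 2 == 0:
        center = center + 0.5 * n
    if orientation_deg % 90 != 0:
        center = center + 0.21 * n
    a = center - (length_px / 2.0) * d
    b = center + (length_px / 2.0) * d
    half = width_px / 2.0
    for p in (a, b):
        if not (half <= p[0] <= h - 1 - half and half <= p[1] <= w - 1 - half):
            raise ValueError("tube exceeds the frame")
    poly = np.vstack([a, b])
    vessel = rasterize_tube(frame_shape, poly, half)
    empty = BinaryMask(np.zeros(frame_shape, dtype=bool), scale_um_per_px)
    return SyntheticScene(
        vessel_mask=BinaryMask(vessel, scale_um_per_px),
        disc_mask=empty,
        truth_segments=[TruthSegment(poly, float(width_px), 0.0)],
    )


def generate_arc_scene(radius_px: float, width_px: float, arc_span_deg: float,
                       frame_shape: tuple[int, int] | None = None,
                       scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX) -> SyntheticScene:
    """A circular-arc tube; the centerline curvature is exactly 1/radius."""
    if radius_px <= width_px:
        raise ValueError("radius must exceed tube width")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    span = math.radians(arc_span_deg)
    n_steps = max(int(span * radius_px / 0.5), 8)  # ~0.5 px arclength steps
    theta = np.linspace(-span / 2.0, span / 2.0, n_steps + 1)
    rel = radius_px * np.stack([np.sin(theta), np.cos(theta)], axis=1)
    half = width_px / 2.0
    margin = half + 4.0
    if frame_shape is None:
        ext_r = rel[:, 0].max() - rel[:, 0].min()
        ext_c = rel[:, 1].max() - rel[:, 1].min()
        frame_shape = (int(math.ceil(ext_r + 2 * margin)) + 1,
                       int(math.ceil(ext_c + 2 * margin)) + 1)
    h, w = frame_shape
    shift = np.array([margin - rel[:, 0].min(), margin - rel[:, 1].min()])
    poly = rel + shift
    if (poly[:, 0].min() < half or poly[:, 0].max() > h - 1 - half
            or poly[:, 1].min() < half or poly[:, 1].max() > w - 1 - half):
        raise ValueError("arc exceeds the frame")
    vessel = rasterize_tube(frame_shape, poly, half)
    empty = BinaryMask(np.zeros(frame_shape, dtype=bool), scale_um_per_px)
    return SyntheticScene(
        vessel_mask=BinaryMask(vessel, scale_um_per_px),
        disc_mask=empty,
        truth_segments=[TruthSegment(poly, float(width_px), 1.0 / radius_px)],
    )


def save_scene(scene: SyntheticScene, out_dir: str | Path, stem: str,
               fmt: str = "png") -> dict[str, Path]:
    """Write a scene as paired masks plus a JSON sidecar of truth geometry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vessel": out_dir / f"{stem}_vessel.{fmt}",
        "disc": out_dir / f"{stem}_disc.{fmt}",
        "truth": out_dir / f"{stem}_truth.json",
    }
    save_mask(scene.vessel_mask, paths["vessel"])
    save_mask(scene.disc_mask, paths["disc"])
    truth = {
        "scale_um_per_px": scene.vessel_mask.scale_um_per_px,
        "truth_density": scene.truth_density,
        "disc_center": scene.disc_center,
        "disc_diameter_px": scene.disc_diameter_px,
        "segments": [
            {
                "caliber_px": s.caliber_px,
                "curvature_px_inv": s.curvature_px_inv,
                "depth": s.depth,
                "parent": s.parent,
                "polyline": np.round(s.polyline, 3).tolist(),
            }
            for s in scene.truth_segments
        ],
    }
    paths["truth"].write_text(json.dumps(truth))
    return paths


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricModel:
    """A linear age model y = slope·x + intercept with a target refit R²."""

    slope: float
    intercept: float
    r_squared: float

    def mean_at(self, age_days: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(age_days, dtype=float) + self.intercept


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the published pediatric FFA cohort: n = 146 in six
    one-year age groups, 64 girls, 86 left eyes, and per-metric age models
    with noise calibrated to the printed R² of each regression. The caliber
    model is piecewise with a fixed breakpoint at 1,095 days (3 years); the
    second piece continues from the first piece's value at the breakpoint.
    Curvature is generated on the natural-log scale and exponentiated.
    """

    seed: int = 0
    group_sizes: tuple[int, ...] = AGE_GROUP_COUNTS
    female_count: int = 64
    left_eye_count: int = 86
    disc_model: MetricModel = MetricModel(-0.00002, 1.362, 0.025)
    fd_model: MetricModel = MetricModel(-0.000026, 1.549, 0.075)
    density_model: MetricModel = MetricModel(-0.000007, 0.134, 0.023)
    caliber_left_model: MetricModel = MetricModel(-0.008, 84.861, 0.205)
    caliber_right_slope: float = 0.0001
    caliber_right_r_squared: float = 0.011
    lnc_model: MetricModel = MetricModel(-0.00001, -4.657, 0.001)
    density_fd_corr: float = 0.979
    breakpoint_days: int = BREAKPOINT_DAYS
    ga_mean_weeks: float = 38.60
    ga_sd_weeks: float = 2.02
    ga_range_weeks: tuple[float, float] = (26.00, 41.28)
    bw_mean_g: float = 3250.0
    bw_sd_g: float = 586.0
    bw_range_g: tuple[float, float] = (930.0, 4600.0)

    @property
    def n(self) -> int:
        return int(sum(self.group_sizes))

    def validate(self) -> None:
        if any(g < 0 for g in self.group_sizes) or self.n <= 0:
            raise ValueError("group sizes must be non-negative with positive total")
        if not (0 <= self.female_count <= self.n):
            raise ValueError("female_count must lie in [0, n]")
        if not (0 <= self.left_eye_count <= self.n):
            raise ValueError("left_eye_count must lie in [0, n]")
        for m in (self.disc_model, self.fd_model, self.density_model,
                  self.caliber_left_model, self.lnc_model):
            if not (0 < m.r_squared < 1):
                raise ValueError("every model R^2 must lie in (0, 1)")
        if not (0 < self.caliber_right_r_squared < 1):
            raise ValueError("caliber_right_r_squared must lie in (0, 1)")
        if not (abs(self.density_fd_corr) < 1):
            raise ValueError("|density_fd_corr| must be < 1")


def calibrate_noise_sd(slope: float, r_squared: float, predictor_sd: float) -> float:
    """Residual SD giving a regression of slope·x + noise on x the target R².

    From R² = slope²·Var(x) / (slope²·Var(x) + σ²):
    σ = |slope| · sd(x) · sqrt(1/R² − 1).
    """
    if not (0 < r_squared < 1):
        raise ValueError("r_squared must lie strictly within (0, 1)")
    if predictor_sd <= 0:
        raise ValueError("predictor_sd must be positive")
    return abs(slope) * predictor_sd * math.sqrt(1.0 / r_squared - 1.0)


def _uniform_mixture_stats(groups: list[tuple[float, float, float]]) -> tuple[float, float]:
    """Mean and SD of a mixture of uniform distributions (lo, hi, weight)."""
    wsum = sum(g[2] for g in groups)
    mean = sum(w * (lo + hi) / 2.0 for lo, hi, w in groups) / wsum
    ex2 = sum(w * (lo * lo + lo * hi + hi * hi) / 3.0 for lo, hi, w in groups) / wsum
    var = ex2 - mean * mean
    return mean, math.sqrt(var)


def _age_sd(params: CohortParams, side: str = "all") -> float:
    """Design SD of age in days over the whole cohort or one breakpoint side."""
    groups = []
    for k, n_k in enumerate(params.group_sizes):
        lo, hi = k * DAYS_PER_YEAR, (k + 1) * DAYS_PER_YEAR
        if side == "left" and lo >= params.breakpoint_days:
            continue
        if side == "right" and hi <= params.breakpoint_days:
            continue
        if n_k > 0:
            groups.append((float(lo), float(hi), float(n_k)))
    if not groups:
        raise ValueError(f"no age groups on side {side!r}")
    return _uniform_mixture_stats(groups)[1]


def _residual_corr(params: CohortParams, sd_density: float, sd_fd: float,
                   age_var: float) -> float:
    """Residual correlation making corr(density, FD) hit the configured target.

    Both metrics share age as a predictor, which already induces correlation
    a1·a2·Var(x); the residual correlation absorbs the remainder:
    rho = (r_target·sd_y1·sd_y2 − a1·a2·Var(x)) / (σ1·σ2).
    """
    a1, a2 = params.density_model.slope, params.fd_model.slope
    tot1 = math.sqrt(a1 * a1 * age_var + sd_density ** 2)
    tot2 = math.sqrt(a2 * a2 * age_var + sd_fd ** 2)
    rho = (params.density_fd_corr * tot1 * tot2 - a1 * a2 * age_var) / (sd_density * sd_fd)
    if not (-1.0 < rho < 1.0):
        raise ValueError(
            f"density_fd_corr={params.density_fd_corr} infeasible given the marginal "
            f"models (required residual correlation {rho:.4f})")
    return rho


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort table (one row per eye/child).

    Ages are uniform within each one-year group at the configured group
    counts; sex and eye labels are random permutations matching the
    configured marginals; gestational age and birth weight are truncated
    normals and carry no metric information. Each metric is its model mean
    at the child's age plus calibrated Gaussian noise; density and fractal
    dimension use jointly drawn (bivariate normal) residuals. Deterministic
    for a fixed seed. Returns a DataFrame with columns ``COHORT_COLUMNS``.
    """
    if params is None:
        params = CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    ages = np.concatenate([
        rng.integers(k * DAYS_PER_YEAR, (k + 1) * DAYS_PER_YEAR, size=n_k)
        for k, n_k in enumerate(params.group_sizes)
    ])
    sex = np.array(["female"] * params.female_count + ["male"] * (n - params.female_count))
    sex = rng.permutation(sex)
    eye = np.array(["left"] * params.left_eye_count + ["right"] * (n - params.left_eye_count))
    eye = rng.permutation(eye)

    ga = _truncated_normal(rng, params.ga_mean_weeks, params.ga_sd_weeks,
                           *params.ga_range_weeks, size=n)
    bw = _truncated_normal(rng, params.bw_mean_g, params.bw_sd_g,
                           *params.bw_range_g, size=n)

    sd_all = _age_sd(params, "all")
    age_var = sd_all * sd_all
    x = ages.astype(float)

    disc_sd = calibrate_noise_sd(params.disc_model.slope, params.disc_model.r_squared, sd_all)
    disc = params.disc_model.mean_at(x) + rng.normal(0.0, disc_sd, n)

    # density and FD: joint residuals so the overall correlation is on target
    den_sd = calibrate_noise_sd(params.density_model.slope,
                                params.density_model.r_squared, sd_all)
    fd_sd = calibrate_noise_sd(params.fd_model.slope, params.fd_model.r_squared, sd_all)
    rho = _residual_corr(params, den_sd, fd_sd, age_var)
    cov = np.array([[den_sd ** 2, rho * den_sd * fd_sd],
                    [rho * den_sd * fd_sd, fd_sd ** 2]])
    resid = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    density = np.clip(params.density_model.mean_at(x) + resid[:, 0], 0.0, 1.0)
    fd = params.fd_model.mean_at(x) + resid[:, 1]

    # caliber: piecewise at the breakpoint, right piece continuous with the left
    bp = float(params.breakpoint_days)
    left = x < bp
    cal = np.empty(n)
    left_model = params.caliber_left_model
    sd_left_x = _age_sd(params, "left")
    cal_left_sd = calibrate_noise_sd(left_model.slope, left_model.r_squared, sd_left_x)
    cal[left] = left_model.mean_at(x[left]) + rng.normal(0.0, cal_left_sd, int(left.sum()))
    if (~left).any():
        value_at_bp = left_model.mean_at(np.array([bp]))[0]
        sd_right_x = _age_sd(params, "right")
        cal_right_sd = calibrate_noise_sd(params.caliber_right_slope,
                                          params.caliber_right_r_squared, sd_right_x)
        cal[~left] = (value_at_bp + params.caliber_right_slope * (x[~left] - bp)
                      + rng.normal(0.0, cal_right_sd, int((~left).sum())))

    lnc_sd = calibrate_noise_sd(params.lnc_model.slope, params.lnc_model.r_squared, sd_all)
    curv = np.exp(params.lnc_model.mean_at(x) + rng.normal(0.0, lnc_sd, n))

    return pd.DataFrame({
        "age_days": ages.astype(int),
        "sex": sex,
        "eye": eye,
        "gestational_age_weeks": ga,
        "birth_weight_g": bw,
        "disc_diameter_mm": disc,
        "fractal_dimension": fd,
        "caliber_um": cal,
        "density_fraction": density,
        "curvature_px_inv": curv,
    }, columns=COHORT_COLUMNS)
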