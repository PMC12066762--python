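"""Synthetic inputs with machine-readable ground truth.

Every generator here returns the exact truth alongside the data so the
analysis modules can be validated without any physical instrument:

* rotation-series silhouettes of convex seed-like solids (with optional
  nozzle occlusion) together with their analytic morphometrics,
* tray images of a pot grid with node jitter, wall lines, soil texture
  and green plant blobs of requested pixel counts,
* leaf-area growth curves that are linear after germination and switch
  to an exponential phase,
* seed-trait batches drawn from a multivariate normal with requested
  means, SDs and correlation structure.

Generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import elliprg, gamma
from skimage.draw import line as draw_line
from scipy import ndimage

from .errors import DomainError
from .shape3d import Morphometrics, SilhouetteStack, UM3_PER_NL, UM2_PER_MM2

__all__ = [
    "ShapeSpec",
    "GrowthSpec",
    "PlantSpec",
    "TrayTruth",
    "render_silhouettes",
    "make_tray_image",
    "make_growth_curve",
    "make_seed_batch",
    "ellipsoid_surface_area",
    "DEFAULT_TRAIT_ORDER",
    "DEFAULT_TRAIT_CORRELATION",
]


# ---------------------------------------------------------------------------
# 3D shapes


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Exact triaxial-ellipsoid surface area via Carlson's R_G.

    ``A = 4π·abc·R_G(1/a², 1/b², 1/c²)``; reduces to 4πa² for a sphere.
    """
    return 4 * np.pi * a * b * c * elliprg(1 / a**2, 1 / b**2, 1 / c**2)


def _rotation_matrix(angles_deg: tuple[float, float, float]) -> np.ndarray:
    """Intrinsic z-y-x rotation from Euler angles in degrees."""
    az, ay, ax = np.deg2rad(angles_deg)
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx


@dataclass
class ShapeSpec:
    """A convex seed-like solid used as a carving oracle.

    semi_axes are in mm; orientation is Euler angles (z, y, x) in
    degrees applied to the body frame; occluded_fraction is the
    fraction of the solid's height hidden from the top by the nozzle.
    ``exponent`` only applies to superellipsoids (|x/a|^p + ... ≤ 1).
    """

    kind: str = "ellipsoid"  # sphere | ellipsoid | superellipsoid
    semi_axes: tuple[float, float, float] = (0.25, 0.155, 0.135)
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    occluded_fraction: float = 0.0
    exponent: float = 2.5

    def __post_init__(self):
        if self.kind == "sphere":
            r = self.semi_axes[0] if np.isscalar(self.semi_axes) else self.semi_axes[0]
            self.semi_axes = (r, r, r)
        if any(s <= 0 for s in self.semi_axes):
            raise DomainError("semi_axes must be positive")
        if not 0 <= self.occluded_fraction <= 0.5:
            raise DomainError("occluded_fraction must be in [0, 0.5]")

    @property
    def semi_axes_um(self) -> np.ndarray:
        return np.asarray(self.semi_axes, dtype=float) * 1000.0

    def analytic_morphometrics(self) -> Morphometrics:
        a, b, c = sorted(self.semi_axes, reverse=True)  # mm
        if self.kind in ("sphere", "ellipsoid"):
            vol_mm3 = 4 / 3 * np.pi * a * b * c
            area_mm2 = ellipsoid_surface_area(a, b, c)
        elif self.kind == "superellipsoid":
            p = self.exponent
            g = gamma(1 + 1 / p)
            vol_mm3 = 8 * a * b * c * g**3 / gamma(1 + 3 / p)
            area_mm2 = _superellipsoid_area_mm2(a, b, c, p)
        else:
            raise DomainError(f"unknown shape kind {self.kind!r}")
        vol_nl = vol_mm3 * 1000.0  # 1 mm³ = 1000 nl
        sph = 100.0 * np.pi ** (1 / 3) * (6 * vol_mm3) ** (2 / 3) / area_mm2
        return Morphometrics(
            volume=vol_nl, surface_area=area_mm2,
            length=2 * a, width=2 * b, height=2 * c, sphericity=float(sph),
        )


def _superellipsoid_area_mm2(a: float, b: float, c: float, p: float, n: int = 120) -> float:
    """Surface area by meshing the analytic inside-function at fine resolution."""
    from skimage import measure

    m = max(a, b, c) * 1.05
    ax = np.linspace(-m, m, n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    f = (np.abs(X / a) ** p + np.abs(Y / b) ** p + np.abs(Z / c) ** p)
    sp = ax[1] - ax[0]
    verts, faces, *_ = measure.marching_cubes(f, level=1.0, spacing=(sp, sp, sp))
    return measure.mesh_surface_area(verts, faces)


def _inside_fn(spec: ShapeSpec):
    """Return f(points µm, body-centered) -> bool inside, plus bounding radius µm."""
    axes = spec.semi_axes_um
    R = _rotation_matrix(spec.orientation)
    rmax = float(axes.max())
    if spec.kind in ("sphere", "ellipsoid"):
        M = R @ np.diag(1.0 / axes**2) @ R.T

        def inside(pts):
            return np.einsum("...i,ij,...j->...", pts, M, pts) <= 1.0
    else:
        p = spec.exponent

        def inside(pts):
            q = pts @ R  # body frame
            return (np.abs(q[..., 0] / axes[0]) ** p
                    + np.abs(q[..., 1] / axes[1]) ** p
                    + np.abs(q[..., 2] / axes[2]) ** p) <= 1.0

    return inside, rmax


def render_silhouettes(
    spec: ShapeSpec,
    angles: np.ndarray | None = None,
    pixel_size: float = 5.0,
    margin_px: int = 6,
    frame: tuple[int, int] | None = None,
) -> tuple[SilhouetteStack, Morphometrics]:
    """Render orthographic binary silhouettes of a solid at given angles.

    A pixel is foreground iff the orthographic ray through its center
    intersects the solid (exact discriminant test for ellipsoids, dense
    ray sampling for superellipsoids).  Returns the stack together with
    the solid's analytic morphometrics as ground truth.
    """
    if angles is None:
        angles = np.arange(0.0, 360.0, 10.0)  # 36 views at 10° steps
    angles = np.asarray(angles, dtype=float)

    inside, rmax = _inside_fn(spec)
    half = int(np.ceil(rmax / pixel_size)) + margin_px
    n_cols = 2 * half + 1
    n_rows = n_cols
    if frame is not None:
        n_rows, n_cols = frame
        if 2 * rmax / pixel_size + 2 > min(n_rows, n_cols):
            raise DomainError("shape larger than requested frame")
    axis_col = (n_cols - 1) / 2.0
    z_center = (n_rows - 1) / 2.0 * pixel_size

    cols = np.arange(n_cols)
    rows = np.arange(n_rows)
    u = (cols - axis_col) * pixel_size
    z = (n_rows - 1 - rows) * pixel_size - z_center

    masks = []
    for theta in np.deg2rad(angles):
        if spec.kind in ("sphere", "ellipsoid"):
            axes = spec.semi_axes_um
            R = _rotation_matrix(spec.orientation)
            M = R @ np.diag(1.0 / axes**2) @ R.T
            d = np.array([-np.sin(theta), np.cos(theta), 0.0])
            U, Z = np.meshgrid(u, z, indexing="xy")  # (n_rows, n_cols)
            p0 = np.stack([U * np.cos(theta), U * np.sin(theta), Z], axis=-1)
            dMd = d @ M @ d
            pMd = p0 @ (M @ d)
            pMp = np.einsum("...i,ij,...j->...", p0, M, p0)
            mask = pMp - pMd**2 / dMd <= 1.0
        else:
            ts = np.linspace(-1.2 * rmax, 1.2 * rmax, 241)
            U, Z = np.meshgrid(u, z, indexing="xy")
            mask = np.zeros(U.shape, dtype=bool)
            for t in ts:
                pts = np.stack(
                    [U * np.cos(theta) - t * np.sin(theta),
                     U * np.sin(theta) + t * np.cos(theta),
                     Z], axis=-1)
                mask |= inside(pts)
        masks.append(mask)

    occlusion_row = None
    if spec.occluded_fraction > 0:
        any_mask = np.logical_or.reduce(masks)
        occ_rows = np.nonzero(any_mask.any(axis=1))[0]
        top, bottom = occ_rows.min(), occ_rows.max()
        occlusion_row = int(top + np.round(spec.occluded_fraction * (bottom - top)))
        for m in masks:
            m[:occlusion_row] = False

    stack = SilhouetteStack(
        masks=masks, angles=angles, pixel_size=pixel_size,
        rotation_axis=axis_col, occlusion_row=occlusion_row,
    )
    return stack, spec.analytic_morphometrics()


# ---------------------------------------------------------------------------
# tray images


@dataclass
class PlantSpec:
    """A green blob of exactly ``n_pixels`` placed in pot (x, y).

    ``offset_mm`` displaces the blob from the (jittered) pot center.
    Alternatively ``at_wall`` ("left"/"right"/"top"/"bottom") places the
    blob just inside that (jittered) pot wall, its edge
    ``wall_clearance_mm`` away from the wall center line — the
    seedling-near-the-wall situation that motivates adaptive cropping.
    A negative clearance pushes the blob across the wall (straddling).
    """

    pot: tuple[int, int]
    n_pixels: int = 100
    offset_mm: tuple[float, float] = (0.0, 0.0)
    at_wall: str | None = None
    wall_clearance_mm: float = 2.0


@dataclass
class TrayTruth:
    nodes: np.ndarray  # (n_cols+1, n_rows+1, 2) of (x, y) px
    inner_crossings: np.ndarray  # ((n_cols-1)(n_rows-1), 2)
    blob_masks: list[np.ndarray] = field(default_factory=list)
    blob_pots: list[tuple[int, int]] = field(default_factory=list)
    mm_per_px: float = 1.0


SOIL_RGB = (115, 85, 60)
WALL_GREY = 205
PLANT_RGB = (45, 165, 45)


def make_tray_image(
    layout: tuple[int, int] = (5, 4),
    pitch_mm: float = 70.0,
    mm_per_px: float = 1.0,
    jitter_mm: float = 0.0,
    plants: list[PlantSpec] | None = None,
    rng_seed: int = 0,
    margin_px: int = 10,
    wall_width_px: int = 3,
) -> tuple[np.ndarray, TrayTruth]:
    """Synthesize a top-view tray image of ``n_cols × n_rows`` pots.

    Lattice nodes sit on a uniform grid of the given pitch and are
    independently jittered by up to ``jitter_mm`` in x and y (emulating
    fabrication inaccuracy and tray flex); walls are bright straight
    segments between adjacent nodes on noisy soil.  Truth contains the
    node lattice, the inner crossings and per-blob pixel masks.
    """
    if jitter_mm < 0:
        raise DomainError("jitter_mm must be >= 0")
    n_cols, n_rows = layout
    rng = np.random.default_rng(rng_seed)
    pitch = pitch_mm / mm_per_px
    jit = jitter_mm / mm_per_px
    if jit >= pitch / 4:
        raise DomainError("jitter too large relative to pot pitch; pots would overlap")

    W = int(2 * margin_px + n_cols * pitch) + 1
    H = int(2 * margin_px + n_rows * pitch) + 1

    nodes = np.zeros((n_cols + 1, n_rows + 1, 2))
    for i in range(n_cols + 1):
        for j in range(n_rows + 1):
            nodes[i, j] = (margin_px + i * pitch + rng.uniform(-jit, jit),
                           margin_px + j * pitch + rng.uniform(-jit, jit))

    soil = rng.integers(-20, 21, size=(H, W, 1))
    img = np.clip(np.array(SOIL_RGB)[None, None, :] + soil, 0, 255).astype(np.uint8)

    wall = np.zeros((H, W), dtype=bool)
    for i in range(n_cols + 1):
        for j in range(n_rows + 1):
            for di, dj in ((1, 0), (0, 1)):
                if i + di <= n_cols and j + dj <= n_rows:
                    x0, y0 = np.rint(nodes[i, j]).astype(int)
                    x1, y1 = np.rint(nodes[i + di, j + dj]).astype(int)
                    rr, cc = draw_line(y0, x0, y1, x1)
                    ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
                    wall[rr[ok], cc[ok]] = True
    wall = ndimage.binary_dilation(wall, iterations=wall_width_px // 2)
    img[wall] = WALL_GREY

    truth = TrayTruth(
        nodes=nodes,
        inner_crossings=nodes[1:-1, 1:-1].reshape(-1, 2).copy(),
        mm_per_px=mm_per_px,
    )

    for plant in plants or []:
        ix, iy = plant.pot
        cell = nodes[ix:ix + 2, iy:iy + 2].reshape(-1, 2)
        cx, cy = cell.mean(axis=0) + np.asarray(plant.offset_mm) / mm_per_px
        if plant.at_wall is not None:
            r_blob = np.sqrt(plant.n_pixels / np.pi)
            inset = plant.wall_clearance_mm / mm_per_px + r_blob
            walls = {
                "left": (nodes[ix, iy] + nodes[ix, iy + 1]) / 2,
                "right": (nodes[ix + 1, iy] + nodes[ix + 1, iy + 1]) / 2,
                "top": (nodes[ix, iy] + nodes[ix + 1, iy]) / 2,
                "bottom": (nodes[ix, iy + 1] + nodes[ix + 1, iy + 1]) / 2,
            }
            wx, wy = walls[plant.at_wall]
            direction = {"left": (1, 0), "right": (-1, 0),
                         "top": (0, 1), "bottom": (0, -1)}[plant.at_wall]
            cx = wx + direction[0] * inset
            cy = wy + direction[1] * inset
        yy, xx = np.mgrid[0:H, 0:W]
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        order = np.argsort(d2, axis=None)[: plant.n_pixels]
        mask = np.zeros((H, W), dtype=bool)
        mask.flat[order] = True
        img[mask] = PLANT_RGB
        truth.blob_masks.append(mask)
        truth.blob_pots.append((ix, iy))

    return img, truth


# ---------------------------------------------------------------------------
# growth curves


@dataclass
class GrowthSpec:
    """Piecewise linear-then-exponential leaf-area trajectory.

    The projected leaf area is zero before ``germination_time``, grows
    linearly at ``linear_rate`` (cotyledon expansion) until
    ``switch_time``, then exponentially at relative rate ``exp_rate``
    (first true leaf pair), value-matched at the switch.  Defaults
    reflect a typical well-watered Arabidopsis Col-0 seedling:
    germination near day 4, early rate ≈ 1 mm²/d, exponential phase
    starting ~4 days later with a relative growth rate of 0.5 /d.
    """

    germination_time: float = 3.77  # d after sowing
    linear_rate: float = 1.02  # mm²/d
    switch_time: float = 8.0  # d
    exp_rate: float = 0.5  # 1/d
    noise_sd: float = 0.05  # mm², additive on nonzero part
    days: int = 14
    pixel_area: float = 0.0013  # mm² per green pixel

    def __post_init__(self):
        if self.switch_time <= self.germination_time:
            raise DomainError("switch_time must exceed germination_time")

    def true_area(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lin = self.linear_rate * (t - self.germination_time)
        a_switch = self.linear_rate * (self.switch_time - self.germination_time)
        expo = a_switch * np.exp(self.exp_rate * (t - self.switch_time))
        out = np.where(t <= self.switch_time, lin, expo)
        return np.where(t < self.germination_time, 0.0, out)


def make_growth_curve(spec: GrowthSpec, rng_seed: int = 0):
    """Simulate a daily leaf-area series and return it with its spec as truth.

    Gaussian noise (sd ``spec.noise_sd``) is added wherever the true
    area is positive; negative values are clipped to zero.  Green-pixel
    counts are the areas divided by ``pixel_area`` and rounded.
    """
    from .growthfit import LeafAreaSeries

    rng = np.random.default_rng(rng_seed)
    times = np.arange(1.0, spec.days + 1.0)
    true = spec.true_area(times)
    noise = rng.normal(0.0, spec.noise_sd, size=times.shape)
    areas = np.where(true > 0, np.clip(true + noise, 0.0, None), 0.0)
    pixels = np.rint(areas / spec.pixel_area).astype(int)
    series = LeafAreaSeries(
        times=times, green_pixels=pixels, pixel_area=spec.pixel_area
    )
    return series, spec


# ---------------------------------------------------------------------------
# seed-trait batches

DEFAULT_TRAIT_ORDER = [
    "mass_ug", "volume_nl", "length_mm", "width_mm", "height_mm",
    "sphericity_pct", "brightness_pct", "germination_time_d",
    "growth_rate_mm2_d",
]

# Correlation structure mirroring the field's observed pattern: mass and
# volume nearly collinear; both moderately tied to each linear extent;
# width and height related to each other but not to length; length
# anti-correlated with sphericity; brightness anti-correlated with
# germination time; growth traits otherwise decoupled.
DEFAULT_TRAIT_CORRELATION = np.array([
    # m     v     L     W     H     S     B     G     R
    [1.00, 0.98, 0.60, 0.60, 0.55, 0.00, 0.00, 0.00, 0.00],  # mass
    [0.98, 1.00, 0.60, 0.60, 0.55, 0.00, 0.00, 0.00, 0.00],  # volume
    [0.60, 0.60, 1.00, 0.05, 0.05, -0.70, 0.00, 0.00, 0.00],  # length
    [0.60, 0.60, 0.05, 1.00, 0.45, 0.30, 0.00, 0.00, 0.00],  # width
    [0.55, 0.55, 0.05, 0.45, 1.00, 0.30, 0.00, 0.00, 0.00],  # height
    [0.00, 0.00, -0.70, 0.30, 0.30, 1.00, 0.00, 0.00, 0.00],  # sphericity
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00, -0.40, 0.00],  # brightness
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, -0.40, 1.00, 0.00],  # germination
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00],  # growth rate
])


def make_seed_batch(
    summary,
    n: int,
    correlation: np.ndarray | None = None,
    rng_seed: int = 0,
    batch_prefix: str | None = None,
):
    """Draw a table of per-seed trait records from a multivariate normal.

    ``summary`` is a :class:`seedtrack.seedstats.BatchSummary` whose
    means/SDs parameterize the marginals; ``correlation`` (default
    :data:`DEFAULT_TRAIT_CORRELATION`) couples them.  Physical traits
    are truncated at a small positive floor.  Returns a DataFrame with
    ``seed_id`` and one column per trait.
    """
    import pandas as pd

    traits = [t for t in DEFAULT_TRAIT_ORDER if t in summary.means]
    means = np.array([summary.means[t] for t in traits])
    sds = np.array([summary.sds[t] for t in traits])
    if correlation is None:
        idx = [DEFAULT_TRAIT_ORDER.index(t) for t in traits]
        correlation = DEFAULT_TRAIT_CORRELATION[np.ix_(idx, idx)]
    correlation = np.asarray(correlation, dtype=float)
    try:
        np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError as exc:
        raise DomainError("correlation matrix must be positive definite") from exc

    cov = np.outer(sds, sds) * correlation
    rng = np.random.default_rng(rng_seed)
    draws = rng.multivariate_normal(means, cov, size=n, method="cholesky")
    draws = np.clip(draws, 1e-6, None)

    prefix = batch_prefix or summary.name
    df = pd.DataFrame(draws, columns=traits)
    df.insert(0, "seed_id", [f"{prefix}-{i + 1:04d}" for i in range(n)])
    df.insert(1, "batch_id", prefix)
    return df
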