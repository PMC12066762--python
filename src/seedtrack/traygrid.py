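"""Tray-grid detection and single-pot cropping.

Trays of 5×4 pots are imaged from above; fabrication inaccuracies (up
to 3 mm) and tray flex move the pot walls away from their nominal
positions, so cropping along a fixed grid can cut plants in half.
Instead, the inner wall crossings are detected by template correlation,
grid lines are least-squares fitted through them, the outer crossings
are extrapolated assuming uniform pot pitch, and pots are cropped along
straight segments between adjacent lattice points (tolerating flex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template, peak_local_max

from .errors import DetectionFailureError, GridFitError

__all__ = [
    "GridModel",
    "PotCrop",
    "detect_crossings",
    "fit_and_extrapolate",
    "crop_pots",
    "regular_grid",
]


@dataclass
class GridModel:
    """Fitted tray grid: inner crossings, line families, full lattice.

    ``lattice[i, j]`` is the (x, y) position (px) of the lattice node at
    column boundary i ∈ 0..n_cols and row boundary j ∈ 0..n_rows, so the
    full lattice holds (n_cols+1)(n_rows+1) points; the outer ring of
    the lattice is extrapolated.  Vertical boundary lines are stored as
    ``x = m·y + b``, horizontal ones as ``y = m·x + b``.
    """

    layout: tuple[int, int]  # (n_cols, n_rows) pots
    lattice: np.ndarray  # (n_cols+1, n_rows+1, 2)
    inner_crossings: np.ndarray = field(default=None)
    vertical_lines: np.ndarray = field(default=None)  # (n_cols+1, 2) of (m, b)
    horizontal_lines: np.ndarray = field(default=None)  # (n_rows+1, 2)

    @property
    def outer_crossings(self) -> np.ndarray:
        ring = np.ones(self.lattice.shape[:2], dtype=bool)
        ring[1:-1, 1:-1] = False
        return self.lattice[ring]


def regular_grid(image_shape: tuple[int, int], layout: tuple[int, int]) -> GridModel:
    """Uniform (fixed) grid dividing the full image into layout cells.

    This is the fixed-grid baseline the adaptive detection replaces.
    """
    n_cols, n_rows = layout
    h, w = image_shape[:2]
    xs = np.linspace(0, w, n_cols + 1)
    ys = np.linspace(0, h, n_rows + 1)
    lattice = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    return GridModel(layout=layout, lattice=lattice,
                     inner_crossings=lattice[1:-1, 1:-1].reshape(-1, 2))


def nominal_grid(layout: tuple[int, int], pitch_px: float,
                 origin_px: tuple[float, float] = (0.0, 0.0)) -> GridModel:
    """Fixed grid at the nominal pot pitch (the pre-detection baseline).

    ``origin_px`` is the (x, y) of the tray's top-left lattice node.
    """
    n_cols, n_rows = layout
    xs = origin_px[0] + pitch_px * np.arange(n_cols + 1)
    ys = origin_px[1] + pitch_px * np.arange(n_rows + 1)
    lattice = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    return GridModel(layout=layout, lattice=lattice,
                     inner_crossings=lattice[1:-1, 1:-1].reshape(-1, 2))


def _cross_kernel(arm: int = 8, width: int = 3) -> np.ndarray:
    """Zero-mean plus-shaped template at the expected wall width."""
    size = 2 * arm + 1
    k = np.zeros((size, size))
    half_w = width // 2
    k[arm - half_w: arm + half_w + 1, :] = 1.0
    k[:, arm - half_w: arm + half_w + 1] = 1.0
    return k - k.mean()


def detect_crossings(
    image: np.ndarray,
    layout: tuple[int, int] = (5, 4),
    wall_width_px: int = 3,
    pitch_px: float | None = None,
) -> np.ndarray:
    """Locate the inner pot-wall crossings of a tray image.

    Correlates the greyscale image with a plus-shaped kernel (a 4-way
    wall crossing matches all four arms; border T-junctions match only
    three and score lower), suppresses non-maxima at half the pot pitch,
    and keeps the strongest (n_cols−1)(n_rows−1) peaks away from the
    image border.  Returns the points as (x, y), sorted row-major.
    """
    n_cols, n_rows = layout
    required = (n_cols - 1) * (n_rows - 1)
    if required == 0:
        return np.empty((0, 2))
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    if pitch_px is None:
        pitch_px = min(img.shape[1] / n_cols, img.shape[0] / n_rows)

    kernel = _cross_kernel(arm=max(4, int(0.1 * pitch_px)), width=wall_width_px)
    resp = match_template(img, kernel, pad_input=True)

    # inner crossings lie at least one pot pitch from the tray edge
    border = int(0.55 * pitch_px)
    resp_in = resp.copy()
    resp_in[:border] = resp_in[-border:] = -1
    resp_in[:, :border] = resp_in[:, -border:] = -1

    peaks = peak_local_max(
        resp_in, min_distance=int(0.4 * pitch_px), threshold_abs=0.2,
        num_peaks=required,
    )
    if len(peaks) < required:
        raise DetectionFailureError(found=len(peaks), required=required)

    pts = peaks[:, ::-1].astype(float)  # (x, y)
    # sort into row-major grid order
    order = np.argsort(pts[:, 1])
    pts = pts[order]
    rows = pts.reshape(n_rows - 1, n_cols - 1, 2)
    for r in rows:
        r[:] = r[np.argsort(r[:, 0])]
    return rows.reshape(-1, 2)


def _fit_line_family(points: np.ndarray, independent: int) -> np.ndarray:
    """LSQ lines through each group of crossings.

    ``points`` is (n_lines, pts_per_line, 2); each line is fitted as
    dependent = m·independent + b where ``independent`` indexes x (0)
    or y (1).
    """
    out = np.zeros((points.shape[0], 2))
    dep = 1 - independent
    for i, grp in enumerate(points):
        t = grp[:, independent]
        d = grp[:, dep]
        if len(grp) == 1 or np.ptp(t) == 0:
            out[i] = (0.0, d.mean())
        else:
            out[i] = np.polyfit(t, d, 1)
    return out


def fit_and_extrapolate(
    points: np.ndarray, layout: tuple[int, int] = (5, 4)
) -> GridModel:
    """Fit grid lines through the inner crossings and extrapolate the border.

    Points must be the (n_cols−1)(n_rows−1) inner crossings in row-major
    order (as returned by :func:`detect_crossings`).  Each inner line is
    least-squares fitted through its crossings; the two border lines of
    each family are extrapolated at the mean line spacing (uniform pot
    pitch), and the full (n_cols+1)(n_rows+1) lattice is returned as the
    pairwise line intersections.
    """
    n_cols, n_rows = layout
    pts = np.asarray(points, dtype=float).reshape(n_rows - 1, n_cols - 1, 2)
    if np.ptp(pts[..., 0]) == 0 or np.ptp(pts[..., 1]) == 0:
        raise GridFitError("crossings are collinear; cannot fit a 2D grid")

    # vertical family: one line per inner column boundary, x = m·y + b
    vert_inner = _fit_line_family(pts.transpose(1, 0, 2), independent=1)
    horiz_inner = _fit_line_family(pts, independent=0)

    def extend(lines: np.ndarray) -> np.ndarray:
        k = len(lines)
        slope = lines[:, 0].mean()
        if k == 1:
            raise GridFitError("cannot extrapolate pitch from a single line")
        db = (lines[-1, 1] - lines[0, 1]) / (k - 1)
        first = np.array([slope, lines[0, 1] - db])
        last = np.array([slope, lines[-1, 1] + db])
        return np.vstack([first, lines, last])

    vert = extend(vert_inner)
    horiz = extend(horiz_inner)

    lattice = np.zeros((n_cols + 1, n_rows + 1, 2))
    for i, (mv, bv) in enumerate(vert):  # x = mv·y + bv
        for j, (mh, bh) in enumerate(horiz):  # y = mh·x + bh
            denom = 1.0 - mv * mh
            x = (mv * bh + bv) / denom
            y = mh * x + bh
            lattice[i, j] = (x, y)
    # keep the measured crossings as the inner nodes: the walls flex, so
    # the observed points beat the straight-line smoothing there
    lattice[1:-1, 1:-1] = pts.transpose(1, 0, 2)

    return GridModel(
        layout=layout,
        lattice=lattice,
        inner_crossings=pts.reshape(-1, 2),
        vertical_lines=vert,
        horizontal_lines=horiz,
    )


@dataclass
class PotCrop:
    """One cropped pot image with its tray linkage."""

    image: np.ndarray
    tray_id: str
    x_index: int
    y_index: int
    origin: tuple[int, int]  # (row, col) of crop in the source image
    pixel_mask: np.ndarray  # True where the pixel belongs to this cell

    @property
    def name(self) -> str:
        return f"{self.tray_id}_{self.x_index}_{self.y_index}"


def assign_cells(image_shape, grid: GridModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel cell indices (col_map, row_map); −1 outside the tray.

    Cell boundaries are straight segments between adjacent lattice
    points (polylines), so the cells partition the tray even when the
    grid is flexed: every pixel inside the outer boundary belongs to
    exactly one cell.
    """
    h, w = image_shape[:2]
    n_cols, n_rows = grid.layout
    lat = grid.lattice

    col_map = np.full((h, w), -1, dtype=int)
    row_map = np.full((h, w), -1, dtype=int)

    ys = np.arange(h)
    # x-position of each vertical boundary polyline at every pixel row
    vx = np.empty((n_cols + 1, h))
    for i in range(n_cols + 1):
        nodes = lat[i]  # (n_rows+1, 2), ordered by j
        vx[i] = np.interp(ys, nodes[:, 1], nodes[:, 0])
    xs = np.arange(w)
    hy = np.empty((n_rows + 1, w))
    for j in range(n_rows + 1):
        nodes = lat[:, j]
        hy[j] = np.interp(xs, nodes[:, 0], nodes[:, 1])

    for y in range(h):
        col_map[y] = np.searchsorted(vx[:, y], xs, side="right") - 1
    row_idx = np.empty((h, w), dtype=int)
    for x in range(w):
        row_idx[:, x] = np.searchsorted(hy[:, x], ys, side="right") - 1
    row_map = row_idx

    outside = (col_map < 0) | (col_map >= n_cols) | (row_map < 0) | (row_map >= n_rows)
    col_map[outside] = -1
    row_map[outside] = -1
    return col_map, row_map


def crop_pots(image: np.ndarray, grid: GridModel, tray_id: str = "tray") -> list[PotCrop]:
    """Crop one image per pot along the grid lines.

    Each source pixel inside the tray is assigned to exactly one cell;
    a crop is the bounding box of its cell with out-of-cell pixels
    zeroed.  Crops are keyed by (tray_id, x_index, y_index) for seed-ID
    linkage.  Cells reaching outside the image are clipped.
    """
    img = np.asarray(image)
    n_cols, n_rows = grid.layout
    col_map, row_map = assign_cells(img.shape, grid)

    crops = []
    for i in range(n_cols):
        for j in range(n_rows):
            cell = (col_map == i) & (row_map == j)
            if not cell.any():
                raise GridFitError(f"cell ({i},{j}) is empty; grid outside image?")
            rows = np.nonzero(cell.any(axis=1))[0]
            cols = np.nonzero(cell.any(axis=0))[0]
            sl = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
            sub = img[sl].copy()
            sub_mask = cell[sl]
            sub[~sub_mask] = 0
            crops.append(PotCrop(
                image=sub, tray_id=tray_id, x_index=i, y_index=j,
                origin=(int(rows.min()), int(cols.min())), pixel_mask=sub_mask,
            ))
    return crops
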