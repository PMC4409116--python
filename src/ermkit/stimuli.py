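"""Gabor contour-integration stimulus synthesis.

A stimulus is a field of odd-symmetric Gabor elements arranged on an invisible
10x10 grid spanning 16.6 x 16.6 deg of visual angle.  The luminance of a
single element at offset (x, y) from its center is

    L(x, y) = L0 * (1 + s(x, y) * g(x, y))
    s(x, y) = C * sin(kx * x * cos(theta) + ky * y * sin(theta))
    g(x, y) = exp(-(x^2 + y^2) / (2 * sigma^2))

with Michelson contrast C = 0.9, spatial frequency f = 3 cycles/deg
(|k| = 2*pi*f), envelope sd sigma = 0.25 deg, and orientation theta measured
from vertical.  Note the carrier argument is kx*x*cos(theta) + ky*y*sin(theta)
as given, not the conventional rotated-coordinate Gabor.

Contour (CT) displays embed a path of 10 invisible line segments: the angle
between adjacent segments is the path angle alpha plus a uniform jitter, the
separation between neighbouring elements is 2 +/- 0.55 deg, no segment center
falls into the inner 2x2 grid cells and at least 4 fall into the inner 6x6.
Empty grid cells are then filled with randomly oriented distractor elements
placed at the cell center and jittered by +/- 0.55 deg.  A new element is not
drawn if its visible part would overlap an existing element by more than 5
pixels; the whole stimulus is withdrawn if more than 10 elements cannot be
drawn, so every accepted stimulus contains 90-100 elements.  Non-contour (NCT)
displays are derived from a CT display by rotating the path elements by
+/- 45 deg, keeping positions and element count identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GaborParams",
    "StimulusSpec",
    "GaborElement",
    "GaborField",
    "PathConstructionError",
    "StimulusWithdrawn",
    "gabor_luminance",
    "build_contour_path",
    "assemble_stimulus",
    "make_noncontour",
    "generate_stimulus",
    "generate_ct_nct_pair",
    "render_luminance",
    "write_pgm",
]

CT = "CT"
NCT = "NCT"


class PathConstructionError(RuntimeError):
    """No contour path satisfying the placement constraints could be built."""


class StimulusWithdrawn(RuntimeError):
    """More than 10 elements could not be drawn (or the count left [90, 100])."""


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a single Gabor element's luminance profile."""

    contrast: float = 0.9            # Michelson contrast C
    spatial_freq: float = 3.0        # f, cycles/deg
    envelope_sd: float = 0.25        # sigma, deg of visual angle
    background_luminance: float = 1.0  # L0, arbitrary luminance units
    orientation: float = 0.0         # theta, deg from vertical

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must be in [0, 1]")
        if self.spatial_freq <= 0:
            raise ValueError("spatial_freq must be > 0")
        if self.envelope_sd <= 0:
            raise ValueError("envelope_sd must be > 0")


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and construction parameters of a Gabor stimulus display.

    ``cell_size`` is derived from the inter-element separation s as
    2s / (1 + sqrt(2)), which for s = 2 deg gives 1.66 deg and makes the mean
    distractor spacing match the mean path-element spacing.  The field spans
    ``grid_cols * cell_size`` deg.  ``visible_radius`` is the radius of the
    disk treated as the visible part of an element for the 5-pixel overlap
    rule; default 2 sigma = 0.5 deg, where the Gaussian envelope has fallen
    to 13.5% of its peak.
    """

    grid_rows: int = 10
    grid_cols: int = 10
    path_angle: float = 25.0             # alpha, deg
    orientation_jitter_bound: float = 1.0  # bound on Delta-alpha, deg
    element_separation: float = 2.0      # deg, neighbouring path elements
    separation_jitter: float = 0.55      # deg
    distractor_jitter: float = 0.55      # deg, per axis
    condition: str = CT
    raster_resolution: float = 600.0 / 16.6  # pixels/deg (800x600 projector)
    visible_radius: float = 0.5          # deg, for the overlap rule
    max_overlap_pixels: int = 5
    element_retry_budget: int = 200      # placement attempts per element
    path_attempt_budget: int = 2000

    def __post_init__(self) -> None:
        if self.path_angle < 0:
            raise ValueError("path_angle must be >= 0")
        if self.element_separation <= 0:
            raise ValueError("element_separation must be > 0")
        if self.condition not in (CT, NCT):
            raise ValueError("condition must be 'CT' or 'NCT'")

    @property
    def cell_size(self) -> float:
        """Grid cell size in deg: 2s / (1 + sqrt(2))."""
        return 2.0 * self.element_separation / (1.0 + math.sqrt(2.0))

    @property
    def field_extent(self) -> float:
        """Side length of the stimulus field in deg."""
        return self.grid_cols * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Center of grid cell (row, col) in field coordinates (deg, origin at center)."""
        g = self.cell_size
        half = self.field_extent / 2.0
        return (-half + (col + 0.5) * g, -half + (row + 0.5) * g)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        g = self.cell_size
        half = self.field_extent / 2.0
        col = int((x + half) // g)
        row = int((y + half) // g)
        return row, col


@dataclass(frozen=True)
class GaborElement:
    center_x: float   # deg
    center_y: float   # deg
    orientation: float  # deg from vertical
    on_path: bool = False


@dataclass
class GaborField:
    """A stimulus: element list plus (optionally rendered) luminance raster."""

    elements: list[GaborElement]
    condition: str
    spec: StimulusSpec
    raster: np.ndarray | None = None
    n_failed: int = 0  # elements that could not be drawn

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def to_json(self) -> str:
        return json.dumps(
            {
                "condition": self.condition,
                "n_elements": self.n_elements,
                "elements": [
                    {
                        "center_x_deg": e.center_x,
                        "center_y_deg": e.center_y,
                        "orientation_deg": e.orientation,
                        "on_path": e.on_path,
                    }
                    for e in self.elements
                ],
            },
            indent=1,
        )


# ------------------------------------------------------------- luminance ----

def gabor_luminance(point: tuple[float, float], params: GaborParams) -> float:
    """Luminance of a single Gabor element at ``point`` (deg from its center)."""
    x, y = point
    k = 2.0 * math.pi * params.spatial_freq
    th = math.radians(params.orientation)
    s = params.contrast * math.sin(k * x * math.cos(th) + k * y * math.sin(th))
    g = math.exp(-(x * x + y * y) / (2.0 * params.envelope_sd**2))
    return params.background_luminance * (1.0 + s * g)


# ------------------------------------------------------------------ paths ----

def build_contour_path(
    spec: StimulusSpec, rng: np.random.Generator
) -> list[GaborElement]:
    """Build a contour path of 10 elements (segment centers + orientations).

    Consecutive orientations differ by +/- alpha plus a uniform jitter in
    [-bound, +bound]; the turn sign is drawn per segment.  The whole path is
    re-drawn until no center falls in the inner 2x2 grid cells, at least 4
    fall in the inner 6x6 cells and all centers lie inside the field, or the
    attempt budget is exhausted (PathConstructionError).
    """
    half = spec.field_extent / 2.0
    rows, cols = spec.grid_rows, spec.grid_cols
    # inner 2x2 and 6x6 blocks of the grid (grid must be at least 8x8)
    inner2 = {(r, c) for r in (rows // 2 - 1, rows // 2)
              for c in (cols // 2 - 1, cols // 2)}
    inner6 = {(r, c) for r in range(rows // 2 - 3, rows // 2 + 3)
              for c in range(cols // 2 - 3, cols // 2 + 3)}

    for _ in range(spec.path_attempt_budget):
        x = rng.uniform(-half, half)
        y = rng.uniform(-half, half)
        theta = rng.uniform(0.0, 360.0)
        pts = [(x, y, theta)]
        ok = True
        for _seg in range(9):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            jitter = rng.uniform(-spec.orientation_jitter_bound,
                                 spec.orientation_jitter_bound)
            theta = theta + sign * spec.path_angle + jitter
            sep = spec.element_separation + rng.uniform(
                -spec.separation_jitter, spec.separation_jitter)
            x = x + sep * math.cos(math.radians(theta))
            y = y + sep * math.sin(math.radians(theta))
            if not (-half < x < half and -half < y < half):
                ok = False
                break
            pts.append((x, y, theta))
        if not ok:
            continue
        cells = [spec.cell_of(px, py) for px, py, _ in pts]
        if any(c in inner2 for c in cells):
            continue
        if sum(c in inner6 for c in cells) < 4:
            continue
        return [GaborElement(px, py, pt % 180.0, on_path=True)
                for px, py, pt in pts]
    raise PathConstructionError(
        f"no valid path after {spec.path_attempt_budget} attempts"
    )


# ---------------------------------------------------------------- overlap ----

_DISK_CACHE: dict[int, np.ndarray] = {}


def _disk_offsets(radius_px: int) -> np.ndarray:
    """(dy, dx) integer offsets of pixels within ``radius_px`` of the origin."""
    if radius_px not in _DISK_CACHE:
        r = radius_px
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        mask = yy * yy + xx * xx <= r * r
        _DISK_CACHE[radius_px] = np.stack([yy[mask], xx[mask]], axis=1)
    return _DISK_CACHE[radius_px]


class _Occupancy:
    """Boolean raster of visible-disk pixels, for the 5-pixel overlap rule."""

    def __init__(self, spec: StimulusSpec):
        self.spec = spec
        self.n = int(round(spec.field_extent * spec.raster_resolution))
        self.grid = np.zeros((self.n, self.n), dtype=bool)
        self.r_px = int(round(spec.visible_radius * spec.raster_resolution))

    def _pixels(self, x: float, y: float) -> tuple[np.ndarray, np.ndarray]:
        half = self.spec.field_extent / 2.0
        res = self.spec.raster_resolution
        cx = int(round((x + half) * res))
        cy = int(round((y + half) * res))
        off = _disk_offsets(self.r_px)
        py = off[:, 0] + cy
        px = off[:, 1] + cx
        keep = (py >= 0) & (py < self.n) & (px >= 0) & (px < self.n)
        return py[keep], px[keep]

    def try_place(self, x: float, y: float) -> bool:
        py, px = self._pixels(x, y)
        if int(self.grid[py, px].sum()) > self.spec.max_overlap_pixels:
            return False
        self.grid[py, px] = True
        return True


# --------------------------------------------------------------- assembly ----

def assemble_stimulus(
    path_or_field: list[GaborElement] | GaborField | None,
    spec: StimulusSpec,
    rng: np.random.Generator,
) -> GaborField:
    """Assemble a full stimulus display.

    For a CT spec, ``path_or_field`` is the contour path from
    :func:`build_contour_path`; empty grid cells are filled with randomly
    oriented distractors at the cell center jittered by +/- 0.55 deg per axis.
    For an NCT spec, ``path_or_field`` is a CT GaborField to transform (see
    :func:`make_noncontour`).

    Raises
    ------
    StimulusWithdrawn
        If more than 10 elements could not be drawn under the overlap rule,
        or the final element count falls outside [90, 100].
    """
    if spec.condition == NCT:
        if not isinstance(path_or_field, GaborField):
            raise TypeError("NCT assembly requires a CT GaborField to transform")
        return make_noncontour(path_or_field, rng)
    if not isinstance(path_or_field, list):
        raise TypeError("CT assembly requires a contour path (list of elements)")

    occ = _Occupancy(spec)
    elements: list[GaborElement] = []
    n_failed = 0

    for el in path_or_field:
        if occ.try_place(el.center_x, el.center_y):
            elements.append(el)
        else:
            # a path that folds back onto itself; a CT display must carry all
            # 10 path elements, so withdraw rather than drop one
            raise StimulusWithdrawn("path elements overlap; path withdrawn")

    path_cells = {spec.cell_of(e.center_x, e.center_y) for e in path_or_field}
    for row in range(spec.grid_rows):
        for col in range(spec.grid_cols):
            if (row, col) in path_cells:
                continue
            cx, cy = spec.cell_center(row, col)
            placed = False
            for _ in range(spec.element_retry_budget):
                x = cx + rng.uniform(-spec.distractor_jitter, spec.distractor_jitter)
                y = cy + rng.uniform(-spec.distractor_jitter, spec.distractor_jitter)
                if occ.try_place(x, y):
                    elements.append(
                        GaborElement(x, y, rng.uniform(0.0, 180.0), on_path=False)
                    )
                    placed = True
                    break
            if not placed:
                n_failed += 1

    if n_failed > 10:
        raise StimulusWithdrawn(f"{n_failed} elements could not be drawn")
    if not 90 <= len(elements) <= 100:
        raise StimulusWithdrawn(f"element count {len(elements)} outside [90, 100]")
    return GaborField(elements=elements, condition=CT, spec=spec, n_failed=n_failed)


def make_noncontour(ct_field: GaborField, rng: np.random.Generator) -> GaborField:
    """Derive an NCT display from a CT display.

    Path elements are rotated by +/- 45 deg (sign drawn per element);
    positions, path flags and the element count are preserved, so the NCT
    display matches the CT display in spacing, positioning and element number.
    """
    if ct_field.condition != CT:
        raise ValueError("make_noncontour expects a CT field")
    out = []
    for el in ct_field.elements:
        if el.on_path:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out.append(replace(el, orientation=(el.orientation + sign * 45.0) % 180.0))
        else:
            out.append(el)
    return GaborField(
        elements=out,
        condition=NCT,
        spec=replace(ct_field.spec, condition=NCT),
        n_failed=ct_field.n_failed,
    )


def generate_stimulus(
    spec: StimulusSpec, rng: np.random.Generator, max_withdrawals: int = 50
) -> GaborField:
    """Build a CT stimulus, retrying withdrawn displays with fresh randomness."""
    if spec.condition != CT:
        raise ValueError("generate_stimulus builds CT displays; derive NCT from one")
    for _ in range(max_withdrawals):
        path = build_contour_path(spec, rng)
        try:
            return assemble_stimulus(path, spec, rng)
        except StimulusWithdrawn:
            continue
    raise StimulusWithdrawn(f"no acceptable stimulus in {max_withdrawals} draws")


def generate_ct_nct_pair(
    spec: StimulusSpec, rng: np.random.Generator
) -> tuple[GaborField, GaborField]:
    ct = generate_stimulus(spec, rng)
    return ct, make_noncontour(ct, rng)


# -------------------------------------------------------------- rendering ----

def render_luminance(
    field: GaborField,
    params: GaborParams | None = None,
    resolution: float | None = None,
) -> np.ndarray:
    """Render the luminance raster of a stimulus (element contributions summed).

    Each element contributes C * sin(...) * g(...) within 4 sigma of its
    center; the raster is L0 * (1 + sum of contributions).
    """
    params = params or GaborParams()
    spec = field.spec
    res = resolution if resolution is not None else spec.raster_resolution
    n = int(round(spec.field_extent * res))
    half = spec.field_extent / 2.0
    coords = (np.arange(n) + 0.5) / res - half
    contrib = np.zeros((n, n))
    k = 2.0 * math.pi * params.spatial_freq
    win = 4.0 * params.envelope_sd
    for el in field.elements:
        th = math.radians(el.orientation)
        ix = np.flatnonzero(np.abs(coords - el.center_x) <= win)
        iy = np.flatnonzero(np.abs(coords - el.center_y) <= win)
        if ix.size == 0 or iy.size == 0:
            continue
        dx = coords[ix] - el.center_x
        dy = coords[iy] - el.center_y
        dxg, dyg = np.meshgrid(dx, dy)
        s = params.contrast * np.sin(k * dxg * math.cos(th) + k * dyg * math.sin(th))
        g = np.exp(-(dxg**2 + dyg**2) / (2.0 * params.envelope_sd**2))
        contrib[np.ix_(iy, ix)] += s * g
    raster = params.background_luminance * (1.0 + contrib)
    field.raster = raster
    return raster


def write_pgm(path: str, raster: np.ndarray, max_gray: int = 255) -> None:
    """Write a luminance raster as a plain-text PGM (P2) image."""
    lo, hi = float(raster.min()), float(raster.max())
    scale = (max_gray / (hi - lo)) if hi > lo else 0.0
    img = np.round((raster - lo) * scale).astype(int)
    with open(path, "w") as fh:
        fh.write(f"P2\n{img.shape[1]} {img.shape[0]}\n{max_gray}\n")
        for row in img:
            fh.write(" ".join(map(str, row)) + "\n")
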