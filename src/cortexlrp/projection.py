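"""Mollweide projection of hemisphere charts onto square pixel rasters.

The Mollweide projection is the equal-area pseudocylindrical map with

    x = (2 * sqrt(2) / pi) * lon * cos(theta),    y = sqrt(2) * sin(theta),

where the auxiliary angle theta solves  2*theta + sin(2*theta) = pi * sin(lat).
For the full sphere (lon in [-pi, pi]) the image is an ellipse with a 2:1
width:height ratio.  Here each cortical hemisphere is treated as its own
half-sphere chart (lon in [-pi/2, pi/2]), whose image is a disc inscribed in
the square [-sqrt(2), sqrt(2)]^2 — hence one square raster per hemisphere.
Equal-area means a near-uniform vertex lattice lands near-uniformly in the
image, so simple bin-mean rasterization preserves regional areas.

Rasterization partitions the square into ``grid_size``^2 equal pixels; a
pixel's value is the mean of the vertices assigned to it (0 where empty), and
the vertex <-> pixel assignment is retained as an invertible
:class:`ProjectionMap` so relevance maps can be carried back to the cortex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cortexlrp.sourcespace import CorticalSourceSpace

__all__ = [
    "SQRT2",
    "MollweideCoords",
    "ProjectionMap",
    "solve_theta",
    "mollweide_planar",
    "project_hemisphere",
    "rasterize",
    "assemble_and_standardize",
]

SQRT2 = float(np.sqrt(2.0))


@dataclass
class MollweideCoords:
    """Auxiliary angle and planar coordinates for a set of vertices."""

    theta: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vertex_index: np.ndarray  # indices into the source space


def solve_theta(lat, tol: float = 1e-12) -> np.ndarray:
    """Solve 2*theta + sin(2*theta) = pi*sin(lat) for the auxiliary angle.

    Newton-Raphson from theta0 = lat, falling back to bisection on
    [-pi/2, pi/2] for any element not converged within 50 iterations.
    Poles are returned analytically (theta = +/- pi/2, where the Newton
    derivative vanishes).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lat = np.atleast_1d(np.asarray(lat, dtype=np.float64))
    if np.any(np.abs(lat) > np.pi / 2 + 1e-12):
        raise ValueError("latitude outside [-pi/2, pi/2]")
    target = np.pi * np.sin(lat)
    theta = lat.copy()
    pole = np.isclose(np.abs(lat), np.pi / 2)
    theta[pole] = np.sign(lat[pole]) * np.pi / 2

    active = ~pole
    for _ in range(50):
        if not np.any(active):
            break
        f = 2.0 * theta + np.sin(2.0 * theta) - target
        df = 2.0 + 2.0 * np.cos(2.0 * theta)
        step = np.zeros_like(theta)
        ok = active & (np.abs(df) > 1e-14)
        step[ok] = f[ok] / df[ok]
        theta = np.clip(theta - step, -np.pi / 2, np.pi / 2)
        active = active & (np.abs(2.0 * theta + np.sin(2.0 * theta) - target) >= tol)

    if np.any(active):  # bisection fallback for stragglers
        for i in np.flatnonzero(active):
            lo, hi = -np.pi / 2, np.pi / 2
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if 2.0 * mid + np.sin(2.0 * mid) - target[i] < 0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < tol:
                    break
            theta[i] = 0.5 * (lo + hi)
    return theta


def mollweide_planar(lat, lon, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form planar (x, y) for arbitrary (lat, lon) in radians.

    With lon spanning [-pi, pi] this covers the full sphere (2:1 ellipse);
    hemisphere charts pass lon in [-pi/2, pi/2].
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=np.float64))
    lon = np.atleast_1d(np.asarray(lon, dtype=np.float64))
    theta = solve_theta(lat, tol)
    x = (2.0 * SQRT2 / np.pi) * lon * np.cos(theta)
    y = SQRT2 * np.sin(theta)
    return x, y


def project_hemisphere(
    space: CorticalSourceSpace, hemisphere: str, tol: float = 1e-12
) -> MollweideCoords:
    """Project one hemisphere's vertices; the image lies in [-sqrt2, sqrt2]^2."""
    if hemisphere not in ("left", "right"):
        raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    idx = np.flatnonzero(space.hemisphere_mask(hemisphere))
    lat = space.lat[idx]
    lon = space.lon[idx]
    if np.any(np.abs(lon) > np.pi / 2 + 1e-12):
        raise ValueError("vertex longitude off the hemisphere chart")
    theta = solve_theta(lat, tol)
    x = (2.0 * SQRT2 / np.pi) * lon * np.cos(theta)
    y = SQRT2 * np.sin(theta)
    return MollweideCoords(theta=theta, x=x, y=y, vertex_index=idx)


@dataclass
class ProjectionMap:
    """Invertible vertex <-> pixel assignment for one hemisphere raster.

    rows/cols are per projected vertex (parallel to ``vertex_index``);
    ``pixel_vertices`` inverts the relation, listing for every (row, col) the
    source-space vertex indices that fell into that pixel.
    """

    grid_size: int
    vertex_index: np.ndarray
    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self) -> None:
        self._inverse: dict[tuple[int, int], np.ndarray] | None = None

    def pixel_vertices(self, row: int, col: int) -> np.ndarray:
        """Source-space vertex indices assigned to one pixel (may be empty)."""
        if self._inverse is None:
            inv: dict[tuple[int, int], list[int]] = {}
            for v, r, c in zip(self.vertex_index, self.rows, self.cols):
                inv.setdefault((int(r), int(c)), []).append(int(v))
            self._inverse = {k: np.array(sorted(v)) for k, v in inv.items()}
        return self._inverse.get((row, col), np.empty(0, dtype=int))

    def counts(self) -> np.ndarray:
        """(grid, grid) array of vertices per pixel."""
        out = np.zeros((self.grid_size, self.grid_size), dtype=int)
        np.add.at(out, (self.rows, self.cols), 1)
        return out


def _pixel_bins(coords: MollweideCoords, grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    # Half-open bins over [-sqrt2, sqrt2]; the far edge is closed so boundary
    # vertices stay on-grid.  Rows run top-down from +y.  Normalizing to
    # [0, 1] before scaling keeps exact pixel-edge hits (e.g. x = 0) on the
    # higher bin.
    cols = np.floor((coords.x + SQRT2) / (2.0 * SQRT2) * grid_size).astype(int)
    rows = np.floor((SQRT2 - coords.y) / (2.0 * SQRT2) * grid_size).astype(int)
    cols = np.clip(cols, 0, grid_size - 1)
    rows = np.clip(rows, 0, grid_size - 1)
    return rows, cols


def rasterize(
    coords: MollweideCoords, values: np.ndarray, grid_size: int = 60
) -> tuple[np.ndarray, ProjectionMap]:
    """Bin vertex values into a square raster by per-pixel arithmetic mean.

    ``values`` may be 1-D (n_hemi_vertices,) or 2-D (n_trials, n_hemi_vertices);
    the returned image has shape (grid, grid) or (n_trials, grid, grid).
    Pixels containing no vertex are 0.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    values = np.asarray(values, dtype=np.float64)
    n_vert = coords.x.shape[0]
    if values.shape[-1] != n_vert:
        raise ValueError("values length does not match projected vertex count")
    rows, cols = _pixel_bins(coords, grid_size)
    flat = rows * grid_size + cols
    counts = np.bincount(flat, minlength=grid_size**2)

    single = values.ndim == 1
    vals2d = values[None, :] if single else values
    n_trials = vals2d.shape[0]
    img = np.zeros((n_trials, grid_size**2))
    for t in range(n_trials):
        img[t] = np.bincount(flat, weights=vals2d[t], minlength=grid_size**2)
    nonzero = counts > 0
    img[:, nonzero] /= counts[nonzero]
    img = img.reshape(n_trials, grid_size, grid_size)

    pmap = ProjectionMap(
        grid_size=grid_size, vertex_index=coords.vertex_index, rows=rows, cols=cols
    )
    return (img[0] if single else img), pmap


def assemble_and_standardize(left_img: np.ndarray, right_img: np.ndarray) -> np.ndarray:
    """Concatenate hemisphere rasters (left | right) and z-score per image.

    Standardization is over all pixels of each image; a constant image maps
    to all zeros rather than dividing by a zero SD.  Accepts single images
    (grid, grid) or stacks (n, grid, grid).
    """
    left_img = np.asarray(left_img, dtype=np.float64)
    right_img = np.asarray(right_img, dtype=np.float64)
    if left_img.shape != right_img.shape:
        raise ValueError("hemisphere image shapes differ")
    if left_img.shape[-1] != left_img.shape[-2]:
        raise ValueError("hemisphere images must be square")
    img = np.concatenate([left_img, right_img], axis=-1)
    single = img.ndim == 2
    stack = img[None] if single else img
    mean = stack.mean(axis=(1, 2), keepdims=True)
    sd = stack.std(axis=(1, 2), keepdims=True)
    out = np.where(sd > 0, (stack - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out[0] if single else out


def make_trial_images(
    space: CorticalSourceSpace, windowed_data: np.ndarray, grid_size: int = 60
) -> tuple[np.ndarray, ProjectionMap, ProjectionMap]:
    """Project windowed per-vertex data to standardized (n, grid, 2*grid) images.

    Convenience wrapper: projects both hemispheres, rasterizes every trial,
    concatenates and z-scores.  Returns the image stack and the two
    hemisphere projection maps (left, right).
    """
    left = project_hemisphere(space, "left")
    right = project_hemisphere(space, "right")
    data = np.atleast_2d(np.asarray(windowed_data, dtype=np.float64))
    left_img, left_map = rasterize(left, data[:, left.vertex_index], grid_size)
    right_img, right_map = rasterize(right, data[:, right.vertex_index], grid_size)
    images = assemble_and_standardize(left_img, right_img)
    return images, left_map, right_map
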