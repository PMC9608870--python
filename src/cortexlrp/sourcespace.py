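"""Cortical source space: vertices on two hemisphere charts with region labels.

Each hemisphere is represented as a half-sphere chart with latitude
``lat`` in [-pi/2, pi/2] and longitude ``lon`` in [-pi/2, pi/2].  Treating a
hemisphere as its own half-sphere is what makes its Mollweide image square
(see :mod:`cortexlrp.projection`).  Vertices are placed on a deterministic
Fibonacci lattice, which is near-uniform in area, so an equal-area projection
of the lattice is near-uniform in the image plane.

Named regions are spherical caps on the chart; they stand in for an
anatomical parcellation and give the simulation (and the end-to-end recovery
tests) an exact ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REGION_NAMES",
    "BACKGROUND",
    "RegionCap",
    "CorticalSourceSpace",
    "default_region_spec",
    "generate_source_space",
]

BACKGROUND = "background"

#: Region vocabulary used by the default simulation.
REGION_NAMES = (
    "superior_frontal",
    "inferior_temporal",
    "insular",
    "superior_parietal",
    "lateral_occipital",
    "superior_temporal",
    BACKGROUND,
)

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0  # fractional part of the golden ratio


@dataclass(frozen=True)
class RegionCap:
    """A spherical cap defining one labeled region on one hemisphere chart."""

    name: str
    hemisphere: str  # "left" or "right"
    center_lat: float  # radians
    center_lon: float  # radians, within [-pi/2, pi/2]
    radius: float  # angular radius, radians

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if not 0.0 < self.radius < np.pi:
            raise ValueError("cap radius must be in (0, pi)")


def default_region_spec() -> list[RegionCap]:
    """Six caps mirroring the study's critical regions (five left, one right)."""
    return [
        RegionCap("superior_frontal", "left", 0.90, -0.90, 0.35),
        RegionCap("inferior_temporal", "left", -0.80, -0.30, 0.35),
        RegionCap("insular", "left", 0.00, 0.00, 0.30),
        RegionCap("superior_parietal", "left", 0.90, 0.90, 0.35),
        RegionCap("lateral_occipital", "left", -0.60, 1.00, 0.35),
        RegionCap("superior_temporal", "right", -0.10, -0.90, 0.35),
    ]


@dataclass
class CorticalSourceSpace:
    """Vertices on two half-sphere charts with one region label each.

    Attributes
    ----------
    lat, lon : float arrays, radians; chart coordinates of each vertex.
    hemisphere : array of "left"/"right" per vertex.
    region : array of region-label strings per vertex.
    """

    lat: np.ndarray
    lon: np.ndarray
    hemisphere: np.ndarray
    region: np.ndarray
    region_spec: list[RegionCap] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.lat.shape[0]

    @property
    def vertex_id(self) -> np.ndarray:
        return np.arange(self.n_vertices)

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        return self.hemisphere == hemisphere

    def region_mask(self, name: str, hemisphere: str | None = None) -> np.ndarray:
        mask = self.region == name
        if hemisphere is not None:
            mask &= self.hemisphere == hemisphere
        return mask

    def region_names(self, include_background: bool = False) -> list[str]:
        """Region labels present in the space, in cap-priority order."""
        listed = [c.name for c in self.region_spec if np.any(self.region == c.name)]
        seen = set(listed)
        extra = [n for n in np.unique(self.region) if n not in seen and n != BACKGROUND]
        names = listed + sorted(extra)
        if include_background and np.any(self.region == BACKGROUND):
            names.append(BACKGROUND)
        return names

    def validate(self) -> None:
        n = self.n_vertices
        if not (self.lon.shape == self.hemisphere.shape == self.region.shape == (n,)):
            raise ValueError("source-space field lengths disagree")
        if np.any(np.abs(self.lat) > np.pi / 2 + 1e-12):
            raise ValueError("latitude outside [-pi/2, pi/2]")
        if np.any(np.abs(self.lon) > np.pi / 2 + 1e-12):
            raise ValueError("longitude outside the hemisphere chart [-pi/2, pi/2]")
        n_left = int(np.sum(self.hemisphere == "left"))
        if abs(n - 2 * n_left) > 1:
            raise ValueError("hemisphere sizes differ by more than one vertex")


def _fibonacci_half_sphere(n: int, offset: float) -> tuple[np.ndarray, np.ndarray]:
    """Near-uniform-area spiral lattice on one half-sphere chart.

    A golden-angle sunflower lattice is laid out in the chart's (equal-area)
    Mollweide disc of radius sqrt(2) — with an explicit boundary ring of
    ~3*sqrt(n) points so the disc rim is covered — and mapped back to
    (lat, lon) through the inverse projection.  Because the projection
    preserves area, uniformity in the disc is uniformity on the half-sphere.
    ``offset`` rotates the spiral, making the lattice a deterministic
    function of the seed.
    """
    s = np.sqrt(2.0)
    n_rim = min(int(round(3.0 * np.sqrt(n))), max(n - 1, 1))
    k = np.arange(n)
    r = np.where(k >= n - n_rim, s, s * np.sqrt((k + 0.5) / (n - n_rim + 0.5)))
    ang = 2.0 * np.pi * ((k * _GOLDEN + offset) % 1.0)
    x = r * np.cos(ang)
    y = r * np.sin(ang)
    # inverse Mollweide on the half-sphere chart
    theta = np.arcsin(np.clip(y / s, -1.0, 1.0))
    lat = np.arcsin(np.clip((2.0 * theta + np.sin(2.0 * theta)) / np.pi, -1.0, 1.0))
    lon = np.pi * x / (2.0 * s * np.clip(np.cos(theta), 1e-12, None))
    return lat, np.clip(lon, -np.pi / 2, np.pi / 2)


def _great_circle_dist(lat1, lon1, lat2, lon2):
    """Central angle between points given in chart (lat, lon) radians."""
    c = np.sin(lat1) * np.sin(lat2) + np.cos(lat1) * np.cos(lat2) * np.cos(lon1 - lon2)
    return np.arccos(np.clip(c, -1.0, 1.0))


def generate_source_space(
    n_vertices: int = 15002,
    region_spec: list[RegionCap] | None = None,
    seed: int = 0,
) -> CorticalSourceSpace:
    """Build a two-hemisphere source space with cap-based region labels.

    Vertices are split as evenly as possible between hemispheres (left gets
    the extra one for odd counts).  Overlapping caps are resolved by listing
    priority (first cap listed wins) with a warning.
    """
    if region_spec is None:
        region_spec = default_region_spec()
    if n_vertices < 2:
        raise ValueError("need at least one vertex per hemisphere")
    if n_vertices < len(region_spec):
        raise ValueError(
            f"n_vertices={n_vertices} is smaller than the number of regions "
            f"({len(region_spec)})"
        )

    rng = np.random.default_rng(seed)
    offsets = rng.random(2)

    n_left = (n_vertices + 1) // 2
    n_right = n_vertices - n_left
    lats, lons, hemis = [], [], []
    for hemi, n_h, off in (("left", n_left, offsets[0]), ("right", n_right, offsets[1])):
        la, lo = _fibonacci_half_sphere(n_h, off)
        lats.append(la)
        lons.append(lo)
        hemis.append(np.full(n_h, hemi, dtype=object))
    lat = np.concatenate(lats)
    lon = np.concatenate(lons)
    hemisphere = np.concatenate(hemis).astype(str)

    region = np.full(n_vertices, BACKGROUND, dtype=object)
    claimed = np.zeros(n_vertices, dtype=bool)
    overlap = False
    # first-listed cap has priority on overlap
    for cap in region_spec:
        in_cap = (hemisphere == cap.hemisphere) & (
            _great_circle_dist(lat, lon, cap.center_lat, cap.center_lon) <= cap.radius
        )
        if np.any(in_cap & claimed):
            overlap = True
        take = in_cap & ~claimed
        region[take] = cap.name
        claimed |= in_cap
    if overlap:
        warnings.warn("overlapping region caps; labels assigned by listed priority")

    space = CorticalSourceSpace(
        lat=lat, lon=lon, hemisphere=hemisphere, region=region.astype(str),
        region_spec=list(region_spec),
    )
    space.validate()
    return space
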