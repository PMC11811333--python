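"""The user's initial sketch: a closed polygon on one slice.

The drawing replaces a GUI: the user supplies a small YAML file

    slice_index: 24
    vertices:
      - [40.0, 46.5]
      - [56.0, 44.0]
      - [50.0, 58.0]

with 0-based fractional pixel coordinates, x = column (first array index),
y = row. The polygon is implicitly closed (last vertex connects to the
first). From it we rasterize a seed mask and build the initial level-set
field phi0 as the signed 3D distance to a one-slice-thick slab, from which
the evolution grows the surface into 3D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

from .errors import ContourError, GeometryError, SeedError
from .grid_core import ImageVolume, LevelSetField, reinitialize


@dataclass
class InitialContour:
    """A simple closed polygon on one slice (>= 3 vertices)."""

    slice_index: int
    vertices: np.ndarray  # (n, 2) float, columns (x, y)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ContourError("vertices must be an (n, 2) array of (x, y) pairs")
        if len(self.vertices) < 3:
            raise ContourError(f"a contour needs >= 3 vertices, got {len(self.vertices)}")
        if not np.all(np.isfinite(self.vertices)):
            raise ContourError("contour vertices must be finite")
        poly = Polygon(self.vertices)
        if not poly.is_simple or poly.area == 0:
            raise ContourError("contour must be a simple (non-self-intersecting) polygon")
        self.slice_index = int(self.slice_index)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def shoelace_area(self) -> float:
        """Polygon area in pixel^2 (shoelace formula via shapely)."""
        return float(self.polygon().area)

    def validate_against(self, vol: ImageVolume) -> None:
        nx, ny, nz = vol.shape
        if not (0 <= self.slice_index < nz):
            raise GeometryError(
                f"slice_index {self.slice_index} outside volume (nz={nz})"
            )
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        if x.min() < 0 or y.min() < 0 or x.max() > nx - 1 or y.max() > ny - 1:
            raise GeometryError("contour vertices fall outside the slice bounds")


def load_contour(path) -> InitialContour:
    """Read a contour YAML file (schema documented in the module docstring)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return InitialContour(slice_index=raw["slice_index"], vertices=raw["vertices"])
    except (KeyError, TypeError) as exc:
        raise ContourError(f"malformed contour file {path}: {exc}") from exc


def save_contour(contour: InitialContour, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "slice_index": int(contour.slice_index),
                "vertices": [[float(x), float(y)] for x, y in contour.vertices],
            },
            fh,
            sort_keys=False,
        )


def rasterize(contour: InitialContour, vol: ImageVolume) -> np.ndarray:
    """2D boolean seed mask on the contour's slice.

    A pixel belongs to the seed iff its center lies inside the polygon;
    centers exactly on an edge count as interior (inclusive seeding — the
    contour is drawn *within* the tumor, so ties err toward the seed).
    """
    contour.validate_against(vol)
    nx, ny, _ = vol.shape
    poly = contour.polygon()
    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float), indexing="ij")
    # covers() includes the boundary, realizing the interior tie-break
    inside = shapely.covers(poly, shapely.points(np.stack([xs.ravel(), ys.ravel()], axis=1)))
    return inside.reshape(nx, ny)


def init_phi(contour: InitialContour, vol: ImageVolume) -> LevelSetField:
    """Initial phi0: signed 3D Euclidean distance (mm) to the one-slice slab
    of the rasterized contour interior; negative inside.

    The returned field already satisfies the signed-distance band invariant,
    so evolution can start without a separate reinitialization.
    """
    seed2d = rasterize(contour, vol)
    if not seed2d.any():
        raise SeedError("contour rasterizes to an empty seed region")
    slab = np.zeros(vol.shape, dtype=bool)
    slab[:, :, contour.slice_index] = seed2d
    # +-half-voxel staircase field whose interpolated zero set lies midway
    # between slab and non-slab voxel centers; reinitialize turns it into an
    # exact signed distance.
    hmin = min(vol.spacing)
    raw = np.where(slab, -0.5 * hmin, 0.5 * hmin)
    return reinitialize(LevelSetField(raw, vol.spacing))
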