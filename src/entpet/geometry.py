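"""Dual-panel CZT detector geometry.

Two opposing 15 x 20 cm^2 panels, each a 5 x 30 array of edge-on
40 x 5 x 40 mm^3 CZT crystals.  The crystals tile the panel contiguously
(30 x 5 mm = 150 mm along x, 5 x 40 mm = 200 mm along y, 40 mm deep along
z), so each panel is a solid box partitioned into crystals.  The panels face
each other across a configurable gap along the global z axis, with the
source at the origin.

Positions are discretised to 1 mm voxel centers on each crystal's local
grid, emulating the near-millimetre cross-strip readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DetectorGeometry"]

_VOXEL_PITCH_MM = 1.0


@dataclass(frozen=True)
class DetectorGeometry:
    """Two-panel geometry; all lengths in mm.

    ``panel_separation`` is the face-to-face gap between the panels.
    Panel 0 occupies z in [-(gap/2 + depth), -gap/2], panel 1 the mirror
    image; both span x in [-75, 75], y in [-100, 100].
    """

    panel_separation: float = 200.0
    crystal_size: tuple[float, float, float] = (5.0, 40.0, 40.0)  # x, y, z
    array_shape: tuple[int, int] = (30, 5)  # crystals along x, y
    voxel_pitch: float = _VOXEL_PITCH_MM

    half_x: float = field(init=False)
    half_y: float = field(init=False)
    depth: float = field(init=False)

    def __post_init__(self) -> None:
        if self.panel_separation <= 0:
            raise ValueError("panel separation must be positive")
        nx, ny = self.array_shape
        sx, sy, sz = self.crystal_size
        object.__setattr__(self, "half_x", nx * sx / 2.0)
        object.__setattr__(self, "half_y", ny * sy / 2.0)
        object.__setattr__(self, "depth", sz)

    @property
    def crystals_per_panel(self) -> int:
        return self.array_shape[0] * self.array_shape[1]

    def panel_bounds(self, panel: int) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the panel's bounding box."""
        g = self.panel_separation / 2.0
        lo_z, hi_z = (g, g + self.depth) if panel == 1 else (-(g + self.depth), -g)
        lo = np.array([-self.half_x, -self.half_y, lo_z])
        hi = np.array([self.half_x, self.half_y, hi_z])
        return lo, hi

    def panel_of(self, points: np.ndarray) -> np.ndarray:
        """Panel index (0/1) of each point; -1 if outside both."""
        points = np.atleast_2d(points)
        out = np.full(points.shape[0], -1, dtype=int)
        for p in (0, 1):
            lo, hi = self.panel_bounds(p)
            inside = np.all((points >= lo) & (points <= hi), axis=1)
            out[inside] = p
        return out

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.panel_of(points) >= 0

    def ray_panel_intersection(self, origins, directions, panel):
        """Entry distance and chord length of rays through a panel box.

        Slab-method intersection.  Returns ``(t_entry, chord, hits)`` where
        ``hits`` marks rays that intersect the box ahead of the origin;
        entries are NaN where there is no hit.
        """
        o = np.atleast_2d(np.asarray(origins, dtype=float))
        d = np.atleast_2d(np.asarray(directions, dtype=float))
        lo, hi = self.panel_bounds(panel)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / d
            t1 = (lo - o) * inv
            t2 = (hi - o) * inv
        tmin = np.maximum.reduce(np.minimum(t1, t2), axis=1)
        tmax = np.minimum.reduce(np.maximum(t1, t2), axis=1)
        with np.errstate(invalid="ignore"):
            hits = (tmax > np.maximum(tmin, 0.0)) & np.isfinite(tmin) & np.isfinite(tmax)
        t_entry = np.where(hits, np.maximum(tmin, 0.0), np.nan)
        chord = np.where(hits, tmax - np.maximum(tmin, 0.0), np.nan)
        return t_entry, chord, hits

    def chord_to_exit(self, points, directions, panel):
        """Distance from interior points to the panel-box exit along rays."""
        o = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.atleast_2d(np.asarray(directions, dtype=float))
        lo, hi = self.panel_bounds(panel)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / d
            t1 = (lo - o) * inv
            t2 = (hi - o) * inv
        return np.nanmin(np.maximum(t1, t2), axis=1)

    def voxelize(self, points: np.ndarray) -> np.ndarray:
        """Snap positions to 1 mm voxel centers on the crystal-local grid.

        Centers sit at half-integer offsets from each crystal's minimum
        corner; a point exactly on a voxel boundary rounds toward the lower
        voxel.  Because the crystal pitch is an integer multiple of the
        1 mm voxel pitch, the crystal-local grid coincides with the grid
        anchored at the panel's minimum corner.  Idempotent.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        panel = self.panel_of(pts)
        if np.any(panel < 0):
            raise ValueError("position outside all crystals")
        out = np.empty_like(pts)
        for p in (0, 1):
            m = panel == p
            if not np.any(m):
                continue
            lo, hi = self.panel_bounds(p)
            local = (pts[m] - lo) / self.voxel_pitch
            snapped = np.ceil(local) - 0.5
            size = (hi - lo) / self.voxel_pitch
            snapped = np.clip(snapped, 0.5, size - 0.5)
            out[m] = lo + snapped * self.voxel_pitch
        return out if np.asarray(points).ndim > 1 else out[0]
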