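"""Moving-sphere phantom geometry and voxelized rendering.

The phantom is a water-filled cylindrical insert containing a centrally fixed
30 mm plastic sphere whose contrast filling makes it ~1.5x brighter than the
surrounding water on T1-weighted imaging. The sphere oscillates along the
superior-inferior (SI) axis according to a programmed respiratory waveform.

Coordinate convention: all positions are in mm relative to the sphere's rest
center; voxel centers sit at ``(i + 0.5) * voxel - extent / 2`` along each
axis, so the grid is symmetric about the rest center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import OutOfFieldError

#: Sub-voxel supersampling factor (per axis) for partial-volume rendering of
#: voxels straddling the sphere surface.
SUPERSAMPLE = 5


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast of the moving-sphere phantom."""

    sphere_diameter: float = 30.0  # mm
    contrast_ratio: float = 1.5  # sphere : background intensity
    background_level: float = 1.0  # arbitrary units
    body_radius: float = 100.0  # mm, cylindrical insert cross-section (MR forward model)
    motion_axis: str = "SI"
    sphere_center_rest: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be positive")
        if self.contrast_ratio < 1:
            raise ValueError("contrast_ratio must be >= 1 (1 renders a uniform phantom)")

    @property
    def radius(self) -> float:
        return self.sphere_diameter / 2.0


@dataclass(frozen=True)
class Grid:
    """Regular 3-D voxel grid centered on the phantom rest position.

    ``axes`` names the anatomical meaning of each array axis, e.g.
    ``("SI", "LR", "AP")`` for a coronal stack (slice axis last).
    """

    shape: tuple[int, int, int]
    voxel: tuple[float, float, float]  # mm
    axes: tuple[str, str, str]

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one array axis, mm."""
        n, v = self.shape[axis], self.voxel[axis]
        return (np.arange(n) + 0.5) * v - n * v / 2.0

    def extent(self, axis: int) -> float:
        return self.shape[axis] * self.voxel[axis]

    @property
    def si_axis(self) -> int:
        return self.axes.index("SI")


def render_phantom(position_mm: float, spec: PhantomSpec, grid: Grid) -> np.ndarray:
    """Render the phantom with the sphere displaced ``position_mm`` along SI.

    Voxel intensity is ``background + (ratio - 1) * background * f`` where
    ``f`` is the fraction of the voxel inside the sphere. Boundary voxels are
    anti-aliased by deterministic 5^3 sub-voxel sampling; interior/exterior
    voxels are exact.
    """
    r = spec.radius
    center = np.asarray(spec.sphere_center_rest, dtype=float).copy()
    center[grid.si_axis] += position_mm
    si = grid.si_axis
    if abs(center[si]) + r > grid.extent(si) / 2.0 + 1e-9:
        raise OutOfFieldError(
            f"sphere at {center[si]:+.1f} mm SI (radius {r} mm) leaves the "
            f"{grid.extent(si):.0f} mm SI field of view"
        )

    cs = [grid.coords(ax) - center[ax] for ax in range(3)]
    d2 = cs[0][:, None, None] ** 2 + cs[1][None, :, None] ** 2 + cs[2][None, None, :] ** 2
    d = np.sqrt(d2)
    half_diag = 0.5 * float(np.linalg.norm(grid.voxel))
    frac = (d <= r).astype(float)

    boundary = np.abs(d - r) <= half_diag
    if boundary.any():
        bi = np.argwhere(boundary)
        centers = np.stack([cs[ax][bi[:, ax]] for ax in range(3)], axis=1)
        offs = [((np.arange(SUPERSAMPLE) + 0.5) / SUPERSAMPLE - 0.5) * grid.voxel[ax] for ax in range(3)]
        ox, oy, oz = np.meshgrid(*offs, indexing="ij")
        sub = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (S^3, 3)
        pts = centers[:, None, :] + sub[None, :, :]
        inside = (pts**2).sum(axis=2) <= r * r
        frac[boundary] = inside.mean(axis=1)

    bg = spec.background_level
    return bg + (spec.contrast_ratio - 1.0) * bg * frac


def default_ct_grid(
    spec: PhantomSpec,
    pp_mm: float,
    slice_thickness: float = 2.5,
    in_plane: float = 1.0,
    margin: float = 12.0,
) -> Grid:
    """Axial CT grid sized to hold the sphere over its full motion range."""
    half_si = spec.radius + pp_mm / 2.0 + margin
    n_si = int(np.ceil(2 * half_si / slice_thickness))
    half_ip = spec.radius + margin
    n_ip = int(np.ceil(2 * half_ip / in_plane))
    return Grid(
        shape=(n_ip, n_ip, n_si),
        voxel=(in_plane, in_plane, slice_thickness),
        axes=("LR", "AP", "SI"),
    )
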