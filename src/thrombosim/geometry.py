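"""Voxelized simulation domains: channel, tube, and stenosed tube.

All lengths are micrometres.  The domain is a uniform simple cubic lattice
with spacing ``h`` shared by the kinetic Monte Carlo, flow, and transport
solvers.  Voxel ``(i, j, k)`` has its center at ``((i+1/2)h, (j+1/2)h,
(k+1/2)h)``; ``x`` is the flow direction (inlet at ``i = 0``, outlet at
``i = nx-1``), ``z`` is channel height, and the tube axis lies along ``x``.

A domain carries four voxel masks:

``fluid_mask``
    voxels available to plasma and platelets (lumen);
``wall_mask``
    rigid solid voxels inside the bounding box (tube/stenosis walls).
    Voxels outside the box are implicitly solid for every geometry, so a
    rectangular channel has an all-``False`` wall mask;
``reactive_mask``
    wall-adjacent *fluid* voxels whose wall-facing face carries collagen
    (and tissue factor when ``tf_on``) — the injury patch.  A platelet
    occupying such a voxel may bind directly to the surface;
``film_mask``
    the thin-film coagulation zone: fluid voxels within ``film_thickness``
    (default 15 um) of a TF-bearing reactive face, where thrombin from the
    reduced coagulation cascade acts.  Empty whenever ``tf_on`` is False.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DEFAULT_H = 2.5  # um, ~ one platelet footprint on the lattice
DEFAULT_FILM_THICKNESS = 15.0  # um, fibrin-rich core of the clot

__all__ = [
    "LatticeDomain",
    "build_channel",
    "build_tube",
    "build_stenosis",
    "compute_film_mask",
    "wall_adjacent_mask",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


def _n_voxels(extent: float, h: float, name: str) -> int:
    """Number of voxels spanning ``extent``; must divide within one voxel."""
    if h > extent:
        raise ValueError(f"lattice spacing h={h} um exceeds {name}={extent} um")
    n = int(round(extent / h))
    if abs(n * h - extent) > h:
        raise ValueError(
            f"h={h} does not divide {name}={extent} within one voxel "
            f"(nearest lattice extent {n * h})"
        )
    return n


@dataclass
class LatticeDomain:
    """Voxelized geometry shared by all solvers.  See module docstring."""

    shape: tuple[int, int, int]
    h: float
    fluid_mask: np.ndarray
    wall_mask: np.ndarray
    reactive_mask: np.ndarray
    tf_on: bool
    film_mask: np.ndarray
    geometry_kind: str
    meta: dict = field(default_factory=dict)
    inlet_axis: int = 0  # inlet face: i == 0; outlet face: i == nx-1

    def __post_init__(self) -> None:
        for name in ("fluid_mask", "wall_mask", "reactive_mask", "film_mask"):
            m = getattr(self, name)
            if m.shape != tuple(self.shape):
                raise ValueError(f"{name} shape {m.shape} != domain shape {self.shape}")
        if np.any(self.fluid_mask & self.wall_mask):
            raise ValueError("fluid_mask and wall_mask overlap")
        if np.any(self.reactive_mask & ~self.fluid_mask):
            raise ValueError("reactive voxels must be fluid (wall-adjacent) voxels")
        if np.any(self.reactive_mask & ~wall_adjacent_mask(self)):
            raise ValueError("reactive voxels must border a wall face")
        if not self.tf_on and np.any(self.film_mask):
            raise ValueError("film_mask must be empty when tf_on is False")

    # -- derived views -------------------------------------------------

    @property
    def solid_mask(self) -> np.ndarray:
        """In-box voxels not available to fluid (walls only; platelets are
        tracked separately by the KMC population)."""
        return ~self.fluid_mask

    @property
    def n_fluid(self) -> int:
        return int(self.fluid_mask.sum())

    def cross_section_area(self, i: int) -> float:
        """Open (fluid) cross-sectional area at axial station ``i`` in um^2."""
        if not 0 <= i < self.shape[0]:
            raise IndexError(f"station {i} outside domain of length {self.shape[0]}")
        return float(self.fluid_mask[i].sum()) * self.h**2

    def lumen_volume(self) -> float:
        """Fluid volume in um^3."""
        return self.n_fluid * self.h**3


def wall_adjacent_mask(domain: LatticeDomain) -> np.ndarray:
    """Fluid voxels with at least one face on a wall (in-box solid voxel or
    the implicit solid outside the transverse bounding box)."""
    fluid = domain.fluid_mask
    solid = np.ones(tuple(np.array(domain.shape) + 2), dtype=bool)
    solid[1:-1, 1:-1, 1:-1] = ~fluid
    # inlet/outlet faces are open, not walls
    solid[0, 1:-1, 1:-1] = False
    solid[-1, 1:-1, 1:-1] = False
    adj = np.zeros_like(fluid)
    adj |= solid[2:, 1:-1, 1:-1] | solid[:-2, 1:-1, 1:-1]
    adj |= solid[1:-1, 2:, 1:-1] | solid[1:-1, :-2, 1:-1]
    adj |= solid[1:-1, 1:-1, 2:] | solid[1:-1, 1:-1, :-2]
    return adj & fluid


def compute_film_mask(domain: LatticeDomain, thickness: float = DEFAULT_FILM_THICKNESS) -> np.ndarray:
    """Thin-film coagulation zone: fluid voxels whose minimal distance to a
    TF-bearing reactive face is at most ``thickness``.

    The distance from a voxel center to the nearest reactive face is
    approximated as the Euclidean distance to the nearest reactive voxel
    center plus half a lattice spacing (exact for a flat patch).  A
    ``thickness`` of zero yields an empty mask.
    """
    if thickness < 0:
        raise ValueError("film thickness must be >= 0")
    mask = np.zeros(domain.shape, dtype=bool)
    if thickness == 0 or not domain.reactive_mask.any():
        return mask
    dist = ndimage.distance_transform_edt(~domain.reactive_mask, sampling=domain.h)
    mask = (dist + 0.5 * domain.h <= thickness) & domain.fluid_mask
    return mask


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_channel(
    length: float = 500.0,
    width: float = 250.0,
    height: float = 60.0,
    patch_start: float = 125.0,
    patch_length: float = 250.0,
    h: float = DEFAULT_H,
    tf_on: bool = True,
    film_thickness: float = DEFAULT_FILM_THICKNESS,
) -> LatticeDomain:
    """Rectangular microfluidic channel with a collagen(/TF) patch on the floor.

    Defaults reproduce the 500 x 250 x 60 um channel with a 250 x 250 um
    reactive surface used for microfluidic validation.  The patch spans the
    full channel width and ``x in [patch_start, patch_start + patch_length)``.
    """
    _check_positive(length=length, width=width, height=height, h=h)
    if patch_length < 0:
        raise ValueError("patch_length must be >= 0")
    if patch_length > 0 and not (0 <= patch_start and patch_start + patch_length <= length):
        raise ValueError(
            f"reactive patch [{patch_start}, {patch_start + patch_length}) um "
            f"falls outside the channel floor [0, {length}) um"
        )
    nx = _n_voxels(length, h, "length")
    ny = _n_voxels(width, h, "width")
    nz = _n_voxels(height, h, "height")
    shape = (nx, ny, nz)
    fluid = np.ones(shape, dtype=bool)
    wall = np.zeros(shape, dtype=bool)

    reactive = np.zeros(shape, dtype=bool)
    if patch_length > 0:
        x = (np.arange(nx) + 0.5) * h
        sel = (x >= patch_start) & (x < patch_start + patch_length)
        reactive[sel, :, 0] = True  # floor (z = 0 face)

    dom = LatticeDomain(
        shape=shape,
        h=h,
        fluid_mask=fluid,
        wall_mask=wall,
        reactive_mask=reactive,
        tf_on=bool(tf_on),
        film_mask=np.zeros(shape, dtype=bool),
        geometry_kind="channel",
        meta={
            "length": length,
            "width": width,
            "height": height,
            "patch_start": patch_start,
            "patch_length": patch_length,
        },
    )
    if tf_on:
        dom.film_mask = compute_film_mask(dom, film_thickness)
    return dom


def _tube_masks(nx: int, nd: int, h: float, radius_profile: np.ndarray):
    """Fluid mask for a (possibly narrowing) circular lumen along x."""
    c = nd * h / 2.0
    yz = (np.arange(nd) + 0.5) * h
    dy = yz - c
    r2 = dy[:, None] ** 2 + dy[None, :] ** 2
    fluid = r2[None, :, :] <= radius_profile[:, None, None] ** 2
    return fluid, c


def build_tube(
    length: float = 500.0,
    diameter: float = 60.0,
    patch_arc_fraction: float = 0.5,
    patch_length: float = 250.0,
    h: float = DEFAULT_H,
    tf_on: bool = True,
    film_thickness: float = DEFAULT_FILM_THICKNESS,
) -> LatticeDomain:
    """Straight cylindrical vessel with an axially centered arc-shaped injury.

    ``patch_arc_fraction = 0.5`` gives the semicylindrical collagen/TF
    surface (centered on the bottom of the tube); ``1.0`` is a fully
    annular injury.
    """
    _check_positive(length=length, diameter=diameter, h=h)
    if not 0 < patch_arc_fraction <= 1:
        raise ValueError("patch_arc_fraction must lie in (0, 1]")
    nd = _n_voxels(diameter, h, "diameter")
    if nd < 4:
        raise ValueError(
            f"h={h} um too coarse: only {nd} voxels across the {diameter} um lumen (need >= 4)"
        )
    nx = _n_voxels(length, h, "length")
    radius = np.full(nx, diameter / 2.0)
    fluid, c = _tube_masks(nx, nd, h, radius)
    shape = (nx, nd, nd)
    wall = ~fluid

    reactive = _arc_patch(
        fluid, h, c, arc_fraction=patch_arc_fraction,
        x_lo=(length - patch_length) / 2.0, x_hi=(length + patch_length) / 2.0,
    )
    dom = LatticeDomain(
        shape=shape,
        h=h,
        fluid_mask=fluid,
        wall_mask=wall,
        reactive_mask=reactive,
        tf_on=bool(tf_on),
        film_mask=np.zeros(shape, dtype=bool),
        geometry_kind="tube",
        meta={
            "length": length,
            "diameter": diameter,
            "patch_arc_fraction": patch_arc_fraction,
            "patch_length": patch_length,
        },
    )
    if tf_on:
        dom.film_mask = compute_film_mask(dom, film_thickness)
    return dom


def _arc_patch(fluid: np.ndarray, h: float, c: float, arc_fraction: float,
               x_lo: float, x_hi: float) -> np.ndarray:
    """Wall-adjacent fluid voxels within the axial window and the angular arc
    centered on the tube bottom (-z)."""
    nx, ny, nz = fluid.shape
    # wall-adjacent fluid voxels (transverse neighbors only: the injury sits
    # on the vessel wall, not on inlet/outlet faces)
    adj = np.zeros_like(fluid)
    solid = ~fluid
    for axis in (1, 2):
        for shift in (-1, 1):
            rolled = np.roll(solid, shift, axis=axis)
            edge = np.zeros_like(fluid)
            idx = [slice(None)] * 3
            idx[axis] = 0 if shift == 1 else -1
            edge[tuple(idx)] = True
            adj |= (rolled | edge) & fluid
    x = (np.arange(nx) + 0.5) * h
    in_x = (x >= x_lo) & (x < x_hi)
    yz = (np.arange(ny) + 0.5) * h - c
    phi = np.arctan2(yz[None, :], yz[:, None])  # angle of (y, z) from +y axis
    # arc centered on the bottom of the tube (phi = -pi/2)
    dphi = np.abs(np.angle(np.exp(1j * (phi + np.pi / 2.0))))
    in_arc = dphi <= arc_fraction * np.pi + 1e-12
    return adj & in_x[:, None, None] & in_arc[None, :, :]


def build_stenosis(
    length: float = 500.0,
    inlet_diameter: float = 60.0,
    stenosis_length: float = 250.0,
    area_reduction: float = 0.75,
    collagen_arc_fraction: float = 0.5,
    h: float = DEFAULT_H,
    tf_on: bool = False,
    film_thickness: float = DEFAULT_FILM_THICKNESS,
) -> LatticeDomain:
    """Cylindrical vessel with an axisymmetric stenosis at mid-length.

    The lumen radius narrows smoothly (cosine bump) from the inlet radius
    ``r0`` to the throat radius ``r_t = r0 * sqrt(1 - area_reduction)`` at
    the axial midpoint::

        r(x) = r0 - (r0 - r_t) * (1 + cos(2 pi (x - x_mid) / L_s)) / 2

    inside the stenotic segment of length ``L_s`` and ``r0`` elsewhere.
    Collagen covers the full stenotic axial extent over
    ``collagen_arc_fraction`` of the circumference (bottom-centered).
    The default is collagen without tissue factor (the arterial control
    condition); pass ``tf_on=True`` to add TF and the thin film.
    """
    _check_positive(length=length, inlet_diameter=inlet_diameter,
                    stenosis_length=stenosis_length, h=h)
    if not 0 <= area_reduction < 1:
        raise ValueError("area_reduction must lie in [0, 1)")
    if not 0 < collagen_arc_fraction <= 1:
        raise ValueError("collagen_arc_fraction must lie in (0, 1]")
    if stenosis_length >= length:
        raise ValueError("stenosis_length must be smaller than the vessel length")
    nd = _n_voxels(inlet_diameter, h, "inlet_diameter")
    if nd < 4:
        raise ValueError(f"h={h} um too coarse for a {inlet_diameter} um lumen")
    nx = _n_voxels(length, h, "length")
    r0 = inlet_diameter / 2.0
    r_t = r0 * np.sqrt(1.0 - area_reduction)
    if r_t / h < 3:
        raise ValueError(
            f"throat radius {r_t:.2f} um is narrower than 3 voxels at h={h} um"
        )
    x = (np.arange(nx) + 0.5) * h
    x_mid = length / 2.0
    radius = np.full(nx, r0)
    seg = np.abs(x - x_mid) <= stenosis_length / 2.0
    radius[seg] = r0 - (r0 - r_t) * 0.5 * (
        1.0 + np.cos(2.0 * np.pi * (x[seg] - x_mid) / stenosis_length)
    )
    fluid, c = _tube_masks(nx, nd, h, radius)
    shape = (nx, nd, nd)

    reactive = _arc_patch(
        fluid, h, c, arc_fraction=collagen_arc_fraction,
        x_lo=x_mid - stenosis_length / 2.0, x_hi=x_mid + stenosis_length / 2.0,
    )
    dom = LatticeDomain(
        shape=shape,
        h=h,
        fluid_mask=fluid,
        wall_mask=~fluid,
        reactive_mask=reactive,
        tf_on=bool(tf_on),
        film_mask=np.zeros(shape, dtype=bool),
        geometry_kind="stenosis",
        meta={
            "length": length,
            "inlet_diameter": inlet_diameter,
            "stenosis_length": stenosis_length,
            "area_reduction": area_reduction,
            "collagen_arc_fraction": collagen_arc_fraction,
            "throat_radius": float(r_t),
        },
    )
    if tf_on:
        dom.film_mask = compute_film_mask(dom, film_thickness)
    return dom
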